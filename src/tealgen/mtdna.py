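"""Sequence-based (mtDNA) analyses: haplotypes, diversity, structure.

Distances between sequences are nucleotide differences with ambiguous
positions (N or -) excluded pairwise, not column-wise.  Haplotype
collapsing treats N as a mismatch by default (conservative, appropriate
for museum-grade sequences); an optional wildcard mode merges sequences
that differ only at ambiguous positions.  AMOVA follows the classical
variance decomposition of squared inter-haplotype distances with the
standard unbalanced-design coefficients, and the network builder connects
haplotypes in increasing-distance order under a statistical-parsimony
connection limit, inserting inferred intermediates on multi-step edges and
retaining cycles created by equal-length alternative connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import SequenceAlignment

__all__ = [
    "HaplotypeTable",
    "collapse_haplotypes",
    "hap_diversity",
    "nuc_diversity",
    "tajimas_d",
    "phi_st",
    "AmovaResult",
    "amova",
    "TcsNetwork",
    "tcs_network",
    "parsimony_limit",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}


def _encode(aln: SequenceAlignment) -> np.ndarray:
    return np.array([[_CODE[c] for c in s] for s in aln.sequences], dtype=np.int8)


def pairwise_differences(aln: SequenceAlignment):
    """(diffs, comparable-site counts) matrices, ambiguity excluded pairwise."""
    enc = _encode(aln)
    known = enc >= 0
    n = enc.shape[0]
    diffs = np.zeros((n, n))
    comp = np.zeros((n, n))
    for i in range(n):
        both = known[i] & known
        diffs[i] = ((enc[i] != enc) & both).sum(axis=1)
        comp[i] = both.sum(axis=1)
    return diffs, comp


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def _roman(n: int) -> str:
    out = []
    for v, s in _ROMAN:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``counts`` is haplotypes x populations; labels are Roman numerals in
    discovery order; ``private`` flags haplotypes seen in exactly one
    population.
    """

    sequences: list
    labels: list
    counts: pd.DataFrame
    private: pd.Series

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)


def collapse_haplotypes(aln: SequenceAlignment, n_wildcard: bool = False) -> HaplotypeTable:
    """Merge identical sequences into haplotypes and tabulate per population.

    With ``n_wildcard`` an ambiguous position (N/-) matches any base and a
    sequence is assigned to the first previously-discovered haplotype it is
    compatible with (greedy, in input order).
    """
    pops = list(dict.fromkeys(aln.populations))
    haps: list[str] = []
    assign = []
    for s in aln.sequences:
        hit = None
        for h_idx, h in enumerate(haps):
            if s == h:
                hit = h_idx
                break
            if n_wildcard and all(
                a == b or a in "N-" or b in "N-" for a, b in zip(s, h)
            ):
                hit = h_idx
                break
        if hit is None:
            haps.append(s)
            hit = len(haps) - 1
        assign.append(hit)
    labels = [_roman(i + 1) for i in range(len(haps))]
    counts = pd.DataFrame(0, index=labels, columns=pops)
    for h_idx, pop in zip(assign, aln.populations):
        counts.loc[labels[h_idx], pop] += 1
    private = (counts > 0).sum(axis=1) == 1
    private.name = "private"
    return HaplotypeTable(sequences=haps, labels=labels, counts=counts, private=private)


def hap_diversity(counts) -> tuple[float, float]:
    """Haplotype diversity Hd = n(1 - sum p_i^2)/(n-1) and its variance.

    The sampling variance is Nei's standard formula
    V = 2/(n(n-1)) * {2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2},
    enabling Welch-style comparisons between populations downstream.
    """
    c = np.asarray(list(counts), float)
    n = c.sum()
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    p = c / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n * (1.0 - s2) / (n - 1.0)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return float(hd), float(var)


def nuc_diversity(aln: SequenceAlignment) -> float:
    """pi: mean pairwise proportion of differing sites (pairwise deletion)."""
    if aln.n_sequences < 2:
        raise ValueError("need >= 2 sequences")
    diffs, comp = pairwise_differences(aln)
    iu = np.triu_indices(aln.n_sequences, 1)
    d, c = diffs[iu], comp[iu]
    if (c == 0).all():
        raise ValueError("no comparable sites in any pair")
    ok = c > 0
    return float((d[ok] / c[ok]).mean())


def tajimas_d(aln: SequenceAlignment) -> float:
    """Tajima's D from an alignment (standard coefficients, natural scale).

    Negative values indicate an excess of rare variants (expansion after a
    bottleneck); positive values an excess of intermediate frequencies
    (contraction or structure).  Raises if there are no segregating sites.
    """
    n = aln.n_sequences
    if n < 4:
        raise ValueError("need n >= 4 sequences")
    enc = _encode(aln)
    seg = 0
    for col in enc.T:
        bases = col[col >= 0]
        if bases.size >= 2 and np.unique(bases).size > 1:
            seg += 1
    if seg == 0:
        raise ValueError("no segregating sites: Tajima's D undefined")
    diffs, _ = pairwise_differences(aln)
    iu = np.triu_indices(n, 1)
    pi_total = float(diffs[iu].mean())
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = np.sqrt(e1 * seg + e2 * seg * (seg - 1.0))
    return float((pi_total - seg / a1) / denom)


# ---------------------------------------------------------------------------
# AMOVA machinery

def _ss_within(d2: np.ndarray, groups: list) -> float:
    """Sum over groups of (sum of squared distances within)/(2 * size)."""
    ss = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * len(idx))
    return ss


def _phi_st_stat(d2: np.ndarray, pops: list) -> tuple[float, float, float]:
    """Two-level decomposition: returns (sigma_a, sigma_w, Phi_ST)."""
    N = d2.shape[0]
    P = len(pops)
    ss_total = d2.sum() / (2.0 * N)
    ss_w = _ss_within(d2, pops)
    ss_a = ss_total - ss_w
    df_a, df_w = P - 1, N - P
    if df_w <= 0 or df_a <= 0:
        raise ValueError("need >= 2 populations with replication")
    ms_w = ss_w / df_w
    ms_a = ss_a / df_a
    sizes = np.array([len(p) for p in pops], float)
    n0 = (N - np.sum(sizes**2) / N) / df_a
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0
    total = sigma_a + sigma_w
    phi = sigma_a / total if total != 0 else np.nan
    return sigma_a, sigma_w, phi


def phi_st(
    aln: SequenceAlignment,
    pops: tuple,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pairwise Phi_ST (AMOVA analogue of F_ST on sequence distances) + p.

    Squared distances are pairwise nucleotide differences; significance
    comes from permuting sequence-to-population assignment with the
    add-one convention.
    """
    if len(pops) != 2:
        raise ValueError("phi_st compares exactly two populations")
    members = [i for i, p in enumerate(aln.populations) if p in pops]
    labels = [aln.populations[i] for i in members]
    for p in pops:
        if labels.count(p) < 2:
            raise ValueError(f"population {p!r} needs >= 2 sequences")
    sub = SequenceAlignment(
        sequences=[aln.sequences[i] for i in members],
        sample_ids=[aln.sample_ids[i] for i in members],
        populations=labels,
    )
    d2, _ = pairwise_differences(sub)
    if not d2.any():
        raise ValueError("all sequences identical: Phi_ST undefined")
    lab = np.array(labels)
    idx_a = np.nonzero(lab == pops[0])[0]
    idx_b = np.nonzero(lab == pops[1])[0]
    _, _, phi_obs = _phi_st_stat(d2, [idx_a, idx_b])
    rng = np.random.default_rng(seed)
    n = len(members)
    n_a = idx_a.size
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, _, phi_p = _phi_st_stat(d2, [perm[:n_a], perm[n_a:]])
        if phi_p >= phi_obs:
            exceed += 1
    p_val = (1.0 + exceed) / (1.0 + n_permutations)
    return float(phi_obs), float(p_val)


@dataclass
class AmovaResult:
    """Three-level AMOVA: groups / populations within groups / within pops."""

    table: pd.DataFrame  # rows: among_groups, among_pops_within, within_pops
    phi: dict  # Phi_CT, Phi_SC, Phi_ST
    p_values: dict


def _amova_components(d2: np.ndarray, group_pops: list):
    """Variance components for a nested design.

    ``group_pops`` is a list of groups, each a list of per-population
    index arrays.  Returns (ss, df, sigma) triples for the three levels;
    undefined components come back as NaN.
    """
    N = d2.shape[0]
    all_pops = [idx for g in group_pops for idx in g]
    G = len(group_pops)
    P = len(all_pops)
    ss_total = d2.sum() / (2.0 * N)
    ss_wp = _ss_within(d2, all_pops)
    groups_flat = [np.concatenate(g) for g in group_pops]
    ss_wg = _ss_within(d2, groups_flat)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P
    sizes_p = {id(idx): len(idx) for idx in all_pops}
    n_g = [sum(len(idx) for idx in g) for g in group_pops]
    sum_np2_over_ng = sum(
        sum(len(idx) ** 2 for idx in g) / ng for g, ng in zip(group_pops, n_g)
    )
    sum_np2 = sum(len(idx) ** 2 for idx in all_pops)
    sum_ng2 = sum(ng**2 for ng in n_g)
    sigma_c = ss_wp / df_wp if df_wp > 0 else np.nan
    if df_ap > 0:
        n_prime = (N - sum_np2_over_ng) / df_ap
        ms_ap = ss_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime
    else:
        # one population per group: the level carries no variation
        sigma_b = 0.0
    if df_ag > 0:
        n_dprime = (sum_np2_over_ng - sum_np2 / N) / df_ag
        n_tprime = (N - sum_ng2 / N) / df_ag
        ms_ag = ss_ag / df_ag
        sb = 0.0 if np.isnan(sigma_b) else sigma_b
        sigma_a = (ms_ag - sigma_c - n_dprime * sb) / n_tprime
    else:
        sigma_a = np.nan
    return (ss_ag, df_ag, sigma_a), (ss_ap, df_ap, sigma_b), (ss_wp, df_wp, sigma_c)


def amova(
    aln: SequenceAlignment,
    groups: dict,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA on squared pairwise nucleotide distances.

    ``groups`` maps group label -> list of population labels.  Variation is
    partitioned among groups, among populations within groups, and among
    individuals within populations; percentages may be negative.  Each
    level is tested by its own permutation scheme: whole populations
    across groups (Phi_CT), individuals across populations within their
    group (Phi_SC), and individuals across all populations (Phi_ST).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pop_of = {}
    for g, pops_g in groups.items():
        for p in pops_g:
            pop_of[p] = g
    members = [i for i, p in enumerate(aln.populations) if p in pop_of]
    if not members:
        raise ValueError("no sequences belong to the listed populations")
    sub = SequenceAlignment(
        sequences=[aln.sequences[i] for i in members],
        sample_ids=[aln.sample_ids[i] for i in members],
        populations=[aln.populations[i] for i in members],
    )
    d2, _ = pairwise_differences(sub)
    labels = sub.populations

    def layout(pop_labels, group_assignment):
        by_group: dict = {}
        for i, p in enumerate(pop_labels):
            g = group_assignment[p]
            by_group.setdefault(g, {}).setdefault(p, []).append(i)
        return [
            [np.asarray(idx) for idx in pops.values()] for pops in by_group.values()
        ]

    gp = layout(labels, pop_of)
    (ss_a, df_a, s_a), (ss_b, df_b, s_b), (ss_c, df_c, s_c) = _amova_components(d2, gp)
    comps = np.array([s_a, s_b, s_c])
    total = np.nansum(comps)
    pct = 100.0 * comps / total if total != 0 else np.full(3, np.nan)
    phi_ct = s_a / total if total else np.nan
    phi_st_val = (s_a + s_b) / total if total else np.nan
    phi_sc = s_b / (s_b + s_c) if (s_b + s_c) else np.nan

    rng = np.random.default_rng(seed)
    pops_list = sorted({p for ps in groups.values() for p in ps if p in labels})
    group_sizes = {g: sum(1 for p in ps if p in labels) for g, ps in groups.items()}
    exceed = {"among_groups": 0, "among_pops_within": 0, "within_pops": 0}
    n = len(members)
    labels_arr = np.array(labels)
    for _ in range(n_permutations):
        # level 1: permute whole populations across groups
        perm_pops = rng.permutation(pops_list)
        new_assign = {}
        pos = 0
        for g in groups:
            for p in perm_pops[pos : pos + group_sizes[g]]:
                new_assign[p] = g
            pos += group_sizes[g]
        try:
            (_, _, s_a_p), (_, _, s_b_p), (_, _, s_c_p) = _amova_components(
                d2, layout(labels, new_assign)
            )
            tot = np.nansum([s_a_p, s_b_p, s_c_p])
            if tot and s_a_p / tot >= phi_ct:
                exceed["among_groups"] += 1
        except ValueError:
            exceed["among_groups"] += 1
        # level 2: permute individuals across populations within groups
        new_labels = labels_arr.copy()
        for g, ps in groups.items():
            idx = np.nonzero(np.isin(labels_arr, ps))[0]
            new_labels[idx] = labels_arr[idx[rng.permutation(idx.size)]]
        (_, _, s_a_p), (_, _, s_b_p), (_, _, s_c_p) = _amova_components(
            d2, layout(new_labels, pop_of)
        )
        denom = s_b_p + s_c_p
        if denom and s_b_p / denom >= phi_sc:
            exceed["among_pops_within"] += 1
        # level 3: permute individuals across everything
        new_labels = labels_arr[rng.permutation(n)]
        (_, _, s_a_p), (_, _, s_b_p), (_, _, s_c_p) = _amova_components(
            d2, layout(new_labels, pop_of)
        )
        tot = np.nansum([s_a_p, s_b_p, s_c_p])
        if tot and (s_a_p + s_b_p) / tot >= phi_st_val:
            exceed["within_pops"] += 1
    p_values = {
        k: (1.0 + v) / (1.0 + n_permutations) for k, v in exceed.items()
    }
    table = pd.DataFrame(
        {
            "sum_of_squares": [ss_a, ss_b, ss_c],
            "df": [df_a, df_b, df_c],
            "variance_component": comps,
            "percent_variation": pct,
        },
        index=["among_groups", "among_pops_within", "within_pops"],
    )
    return AmovaResult(
        table=table,
        phi={"Phi_CT": phi_ct, "Phi_SC": phi_sc, "Phi_ST": phi_st_val},
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# statistical-parsimony network

def parsimony_limit(seq_length: int, max_steps: int = 100, threshold: float = 0.95) -> int:
    """Largest mutational distance connectable at the parsimony threshold.

    For two sequences of length L differing at j sites, the per-site
    substitution intensity is the Jukes-Cantor-corrected distance
    lambda_j; under Poisson changes a differing site carries exactly one
    change with probability lambda e^-lambda / (1 - e^-lambda), and the
    probability that all j differences are single-step (parsimony) is that
    quantity to the j-th power.  The limit is the largest j keeping this
    probability >= ``threshold`` (at least 1).
    """
    limit = 1
    for j in range(1, max_steps + 1):
        p = j / seq_length
        if p >= 0.75:
            break
        lam = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        single = lam * np.exp(-lam) / (1.0 - np.exp(-lam))
        if single**j >= threshold:
            limit = j
        else:
            break
    return limit


@dataclass
class TcsNetwork:
    """Statistical-parsimony haplotype network.

    ``graph`` contains haplotype nodes (attribute ``frequency``) and
    inferred intermediate nodes (``inferred=True``); every edge is a
    single mutational step.  ``components`` lists node groups left
    unconnected at the connection limit.
    """

    graph: nx.Graph
    connection_limit: int
    components: list


def tcs_network(haps: HaplotypeTable, connection_limit=None) -> TcsNetwork:
    """Connect haplotypes in increasing distance order under a step limit.

    Pairs are processed distance level by distance level; a pair is linked
    only if its endpoints lay in different components before the level
    began, so shorter connections exhaust longer alternatives, while
    equal-length alternatives are all kept (cycles allowed).  Multi-step
    links insert inferred intermediate haplotypes.
    """
    if haps.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    aln = SequenceAlignment(
        sequences=haps.sequences,
        sample_ids=haps.labels,
        populations=["_"] * haps.n_haplotypes,
    )
    L = len(haps.sequences[0])
    if connection_limit is None:
        connection_limit = parsimony_limit(L)
    diffs, _ = pairwise_differences(aln)
    g = nx.Graph()
    freqs = haps.counts.sum(axis=1)
    for lab in haps.labels:
        g.add_node(lab, frequency=int(freqs[lab]), inferred=False)
    pairs_by_d: dict[int, list] = {}
    n = haps.n_haplotypes
    for i in range(n):
        for j in range(i + 1, n):
            d = int(diffs[i, j])
            if 1 <= d <= connection_limit:
                pairs_by_d.setdefault(d, []).append((haps.labels[i], haps.labels[j]))
    inferred_count = 0
    for d in sorted(pairs_by_d):
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        for a, b in pairs_by_d[d]:
            if comp_of[a] == comp_of[b]:
                continue
            prev = a
            for step in range(d - 1):
                inferred_count += 1
                mid = f"inferred_{inferred_count}"
                g.add_node(mid, frequency=0, inferred=True)
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, b, steps=1)
    components = [sorted(c) for c in nx.connected_components(g)]
    return TcsNetwork(graph=g, connection_limit=connection_limit, components=components)
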