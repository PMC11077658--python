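"""Nuclear-SNP diversity, kinship and differentiation statistics.

Estimators follow the conventions of the RAD-seq toolchain the synthetic
panel emulates: unbiased expected heterozygosity 2pq * n/(n-1) on allele
counts, F_IS as a ratio of averages (1 - mean H_O / mean H_E), the
KING-robust pairwise kinship coefficient on overlapping calls, and the
Weir-Cockerham F_ST variance-components estimator summed over loci with a
label-permutation null.  Permutation p-values use the add-one convention
(never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeMatrix

__all__ = [
    "DiversityStats",
    "diversity",
    "individual_heterozygosity",
    "KinshipMatrix",
    "kinship_king",
    "select_unrelated",
    "fst_wc",
]


@dataclass
class DiversityStats:
    """Per-population H_O, H_E, pi and F_IS (one row per population)."""

    table: pd.DataFrame
    mode: str  # "variant" or "all"


def _site_stats(calls: np.ndarray):
    """Per-site H_O, unbiased H_E and pi over non-missing calls.

    Returns (h_obs, h_exp, pi, n_called) arrays of length n_sites; sites
    with < 2 called individuals get NaN.
    """
    valid = calls != MISSING
    n_called = valid.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    n_alleles = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_alleles
        h_obs = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
        corr = n_alleles / np.maximum(n_alleles - 1.0, 1.0)
        h_exp = np.where(n_alleles > 1, 2.0 * p * (1.0 - p) * corr, np.nan)
    return h_obs, h_exp, h_exp.copy(), n_called


def diversity(
    G: GenotypeMatrix,
    pops=None,
    mode: str = "variant",
    total_length: float | None = None,
) -> DiversityStats:
    """Population diversity statistics from SNP genotypes.

    In "variant" mode the per-site values are averaged over SNP columns;
    in "all" mode the per-site sums are divided by ``total_length`` (the
    number of sequenced positions, polymorphic and not), which must then
    be supplied.  pi equals unbiased per-site heterozygosity at bi-allelic
    sites (average pairwise difference); F_IS = 1 - mean(H_O)/mean(H_E)
    (ratio of averages), reported as NaN when mean H_E is 0.
    """
    if mode not in ("variant", "all"):
        raise ValueError("mode must be 'variant' or 'all'")
    if mode == "all" and not total_length:
        raise ValueError("mode='all' requires total_length")
    if pops is None:
        pops = sorted(set(G.populations))
    rows = []
    for pop in pops:
        members = [i for i, p in enumerate(G.populations) if p == pop]
        if not members:
            raise ValueError(f"population {pop!r} not in the dataset")
        if len(members) < 2:
            raise ValueError(f"population {pop!r} has < 2 individuals")
        calls = G.calls[members]
        h_obs, h_exp, pi, n_called = _site_stats(calls)
        ok = n_called >= 2
        denom = total_length if mode == "all" else ok.sum()
        ho = float(np.nansum(h_obs[ok]) / denom) if denom else np.nan
        he = float(np.nansum(h_exp[ok]) / denom) if denom else np.nan
        pi_v = float(np.nansum(pi[ok]) / denom) if denom else np.nan
        fis = 1.0 - ho / he if he and he > 0 else np.nan
        rows.append((pop, len(members), ho, he, pi_v, fis))
    table = pd.DataFrame(rows, columns=["population", "n", "H_O", "H_E", "pi", "F_IS"])
    return DiversityStats(table=table.set_index("population"), mode=mode)


def individual_heterozygosity(G: GenotypeMatrix) -> pd.Series:
    """Proportion of heterozygous calls per individual over SNP columns.

    Individuals with no non-missing call are returned as NaN (flagged,
    excluded from summaries).
    """
    valid = G.calls != MISSING
    n_called = valid.sum(axis=1)
    het = (G.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        h = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    return pd.Series(h, index=G.individual_ids, name="H_O")


@dataclass
class KinshipMatrix:
    """Pairwise KING-robust kinship with per-pair overlap counts."""

    phi: pd.DataFrame
    n_overlap: pd.DataFrame
    min_overlap: int

    def reliable(self) -> np.ndarray:
        return self.n_overlap.to_numpy() >= self.min_overlap


def kinship_king(G: GenotypeMatrix, min_overlap: int = 100) -> KinshipMatrix:
    """KING-robust kinship: phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)).

    Counts are taken over SNPs where both individuals are called; the
    self-kinship of a non-inbred individual is 0.5 by construction.  Pairs
    with fewer than ``min_overlap`` overlapping calls are reported but
    flagged unreliable.
    """
    calls = G.calls
    valid = (calls != MISSING).astype(np.float64)
    het = ((calls == 1) & (calls != MISSING)).astype(np.float64)
    hom_ref = (calls == 0).astype(np.float64)
    hom_alt = (calls == 2).astype(np.float64)

    n_overlap = valid @ valid.T
    n_het_both = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    het_i = het @ valid.T  # heterozygous calls of i over the (i, j) overlap
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_het_both - 2.0 * n_opp) / denom, np.nan)
    ids = G.individual_ids
    return KinshipMatrix(
        phi=pd.DataFrame(phi, index=ids, columns=ids),
        n_overlap=pd.DataFrame(n_overlap.astype(int), index=ids, columns=ids),
        min_overlap=min_overlap,
    )


def select_unrelated(
    kin: KinshipMatrix,
    missingness,
    threshold: float = 0.0,
) -> list:
    """Greedy unrelated-set selection over the phi > threshold graph.

    Within each connected component, repeatedly drop the individual with
    the highest missingness (ties broken by id order) until no kinship
    edge remains, so among relatives the most complete individual is the
    one retained.  Pairs with unreliable overlap contribute no edge.
    """
    ids = list(kin.phi.index)
    if isinstance(missingness, pd.Series):
        miss = missingness.reindex(ids)
    else:
        miss = pd.Series(np.asarray(missingness, float), index=ids)
    phi = kin.phi.to_numpy()
    reliable = kin.reliable()
    n = len(ids)
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if reliable[i, j] and not np.isnan(phi[i, j]) and phi[i, j] > threshold
    }
    removed: set[int] = set()
    while True:
        live = [e for e in edges if e[0] not in removed and e[1] not in removed]
        if not live:
            break
        degree: dict[int, int] = {}
        for i, j in live:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        worst = max(degree, key=lambda i: (miss.iloc[i], ids[i]))
        removed.add(worst)
    return [ids[i] for i in range(n) if i not in removed]


def _wc_fst_batch(memberA: np.ndarray, valid: np.ndarray, alt: np.ndarray, het: np.ndarray):
    """Weir-Cockerham two-population F_ST for a batch of A/B splits.

    ``memberA`` is (batch, individuals) 0/1; ``valid``/``alt``/``het`` are
    (individuals, loci).  Returns F per batch row (ratio of summed
    components a / (a+b+c), loci with an empty side excluded).
    """
    r = 2.0
    tot_n = valid.sum(axis=0)[None, :]
    tot_alt = alt.sum(axis=0)[None, :]
    tot_het = het.sum(axis=0)[None, :]
    nA = memberA @ valid
    nB = tot_n - nA
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = (memberA @ alt) / np.maximum(2.0 * nA, 1e-12)
        pB = (tot_alt - memberA @ alt) / np.maximum(2.0 * nB, 1e-12)
        hA = (memberA @ het) / np.maximum(nA, 1e-12)
        hB = (tot_het - memberA @ het) / np.maximum(nB, 1e-12)
        n_bar = (nA + nB) / r
        n_c = (r * n_bar - (nA**2 + nB**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (nA * pA + nB * pB) / (r * n_bar)
        s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (nA * hA + nB * hB) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    usable = (nA >= 1) & (nB >= 1) & (n_bar > 1) & (n_c > 0)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    num = np.nansum(a, axis=1)
    den = np.nansum(a + b + c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0, num / den, np.nan)


def fst_wc(
    G: GenotypeMatrix,
    pops: tuple,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Multi-locus Weir-Cockerham F_ST between two populations + permutation p.

    F_ST = sum_l a_l / sum_l (a_l + b_l + c_l); the null permutes
    individual population labels (group sizes preserved), and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if len(pops) != 2:
        raise ValueError("fst_wc compares exactly two populations")
    members = [i for i, p in enumerate(G.populations) if p in pops]
    labels = np.array([G.populations[i] for i in members])
    in_a = labels == pops[0]
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each population needs >= 2 individuals")
    calls = G.calls[members]
    _, maf = _poly_check(calls)
    if (maf <= 0).all():
        raise ValueError("dataset monomorphic: F_ST undefined")
    valid = (calls != MISSING).astype(np.float64)
    alt = np.where(calls != MISSING, calls, 0).astype(np.float64)
    het = (calls == 1).astype(np.float64)

    f_obs = float(_wc_fst_batch(in_a[None, :].astype(float), valid, alt, het)[0])
    rng = np.random.default_rng(seed)
    n_ind = len(members)
    n_a = int(in_a.sum())
    perms = np.zeros((n_permutations, n_ind))
    for b in range(n_permutations):
        perms[b, rng.choice(n_ind, n_a, replace=False)] = 1.0
    f_perm = _wc_fst_batch(perms, valid, alt, het)
    exceed = int(np.sum(f_perm >= f_obs))
    p_val = (1.0 + exceed) / (1.0 + n_permutations)
    return f_obs, float(p_val)


def _poly_check(calls: np.ndarray):
    valid = calls != MISSING
    n_alleles = 2.0 * valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    return p, np.minimum(p, 1 - p)
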