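"""Structured-coalescent simulation engine for the two-deme model family.

Continuous-time coalescent with two contemporary demes, backwards
migration, a merge of the demes at the split time, and a piecewise-constant
ancestral size.  Two JIT-compiled kernels do the heavy lifting:

* :func:`_sim_spectrum` accumulates, over replicate genealogies, the total
  branch length subtending every (i ES, j IQ)-descendant configuration.
  Normalised, this is the Monte-Carlo expected joint site-frequency
  spectrum conditioned on polymorphism (a mutation falls on a branch with
  probability proportional to its length).
* :func:`_sim_trees` records full genealogies (parent pointers and node
  times) for overlaying mutations and building genotype datasets.

Sizes are haploid throughout: a pair of lineages in a deme of haploid size
N coalesces at rate 1/N per generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import DemographicModel

__all__ = ["Genealogies", "simulate_genealogies", "joint_branch_spectrum", "drop_mutations"]

#: iteration cap per replicate before declaring non-coalescence
DEFAULT_MAX_EVENTS = 5_000_000


@njit(cache=True)
def _sim_spectrum(n1, n2, N1, N2, m12, m21, bnd_times, bnd_sizes,
                  n_reps, seed, max_events):
    """Accumulate branch lengths by descendant configuration.

    Returns ``(out, heights, totlen, nfail)`` where ``out[i, j]`` is the
    summed branch length carrying i ES and j IQ descendants over all
    successful replicates, and replicates hitting the event cap are
    discarded and counted in ``nfail`` (their heights are NaN).
    """
    np.random.seed(seed)
    n = n1 + n2
    out = np.zeros((n1 + 1, n2 + 1))
    rep_out = np.zeros((n1 + 1, n2 + 1))
    heights = np.empty(n_reps)
    totlen = np.empty(n_reps)
    nfail = 0
    deme = np.empty(n, np.int8)
    c1 = np.empty(n, np.int64)
    c2 = np.empty(n, np.int64)
    birth = np.empty(n, np.float64)
    n_bnd = bnd_times.shape[0]
    for rep in range(n_reps):
        rep_out[:, :] = 0.0
        for i in range(n1):
            deme[i] = 0
            c1[i] = 1
            c2[i] = 0
            birth[i] = 0.0
        for i in range(n1, n):
            deme[i] = 1
            c1[i] = 0
            c2[i] = 1
            birth[i] = 0.0
        k = n
        t = 0.0
        phase = -1
        events = 0
        ok = True
        tl = 0.0
        while k > 1:
            events += 1
            if events > max_events:
                ok = False
                break
            if phase == -1:
                k1 = 0
                for i in range(k):
                    if deme[i] == 0:
                        k1 += 1
                k2 = k - k1
                rc1 = k1 * (k1 - 1) / 2.0 / N1
                rc2 = k2 * (k2 - 1) / 2.0 / N2
                rm1 = k1 * m12
                rm2 = k2 * m21
                total = rc1 + rc2 + rm1 + rm2
                next_bnd = bnd_times[0]
            else:
                rc1 = k * (k - 1) / 2.0 / bnd_sizes[phase]
                rc2 = 0.0
                rm1 = 0.0
                rm2 = 0.0
                total = rc1
                next_bnd = bnd_times[phase + 1] if phase + 1 < n_bnd else np.inf
            if total > 0.0:
                dt = np.random.exponential(1.0 / total)
            else:
                dt = np.inf
            if t + dt >= next_bnd:
                t = next_bnd
                phase += 1
                if phase == 0:
                    for i in range(k):
                        deme[i] = 0
                continue
            t += dt
            u = np.random.random() * total
            if u < rc1 + rc2:
                d = 0 if u < rc1 else 1
                if phase >= 0:
                    d = 0
                # draw two distinct lineages in deme d (phase>=0: all in 0)
                kd = 0
                for i in range(k):
                    if phase >= 0 or deme[i] == d:
                        kd += 1
                a = np.random.randint(kd)
                b = np.random.randint(kd - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                pos = 0
                for i in range(k):
                    if phase >= 0 or deme[i] == d:
                        if pos == a:
                            ia = i
                        if pos == b:
                            ib = i
                        pos += 1
                rep_out[c1[ia], c2[ia]] += t - birth[ia]
                rep_out[c1[ib], c2[ib]] += t - birth[ib]
                tl += (t - birth[ia]) + (t - birth[ib])
                c1[ia] += c1[ib]
                c2[ia] += c2[ib]
                birth[ia] = t
                k -= 1
                deme[ib] = deme[k]
                c1[ib] = c1[k]
                c2[ib] = c2[k]
                birth[ib] = birth[k]
            else:
                src = 0 if u < rc1 + rc2 + rm1 else 1
                kd = 0
                for i in range(k):
                    if deme[i] == src:
                        kd += 1
                a = np.random.randint(kd)
                pos = 0
                for i in range(k):
                    if deme[i] == src:
                        if pos == a:
                            deme[i] = 1 - src
                            break
                        pos += 1
        if ok:
            out += rep_out
            heights[rep] = t
            totlen[rep] = tl
        else:
            nfail += 1
            heights[rep] = np.nan
            totlen[rep] = np.nan
    return out, heights, totlen, nfail


@njit(cache=True)
def _sim_trees(n1, n2, N1, N2, m12, m21, bnd_times, bnd_sizes,
               n_loci, seed, max_events):
    """Simulate full genealogies; leaves 0..n1-1 are ES, n1..n-1 IQ.

    Internal nodes are numbered n..2n-2 in coalescence order, so every
    child index is smaller than its parent's.  Failed replicates (event
    cap) are flagged with ``parent[rep, 0] == -2``.
    """
    np.random.seed(seed)
    n = n1 + n2
    parent = np.full((n_loci, 2 * n - 1), -1, np.int64)
    node_time = np.zeros((n_loci, 2 * n - 1))
    nfail = 0
    active = np.empty(n, np.int64)
    deme = np.empty(n, np.int8)
    n_bnd = bnd_times.shape[0]
    for rep in range(n_loci):
        for i in range(n1):
            deme[i] = 0
            active[i] = i
        for i in range(n1, n):
            deme[i] = 1
            active[i] = i
        k = n
        nxt = n
        t = 0.0
        phase = -1
        events = 0
        ok = True
        while k > 1:
            events += 1
            if events > max_events:
                ok = False
                break
            if phase == -1:
                k1 = 0
                for i in range(k):
                    if deme[i] == 0:
                        k1 += 1
                k2 = k - k1
                rc1 = k1 * (k1 - 1) / 2.0 / N1
                rc2 = k2 * (k2 - 1) / 2.0 / N2
                rm1 = k1 * m12
                rm2 = k2 * m21
                total = rc1 + rc2 + rm1 + rm2
                next_bnd = bnd_times[0]
            else:
                rc1 = k * (k - 1) / 2.0 / bnd_sizes[phase]
                rc2 = 0.0
                rm1 = 0.0
                rm2 = 0.0
                total = rc1
                next_bnd = bnd_times[phase + 1] if phase + 1 < n_bnd else np.inf
            if total > 0.0:
                dt = np.random.exponential(1.0 / total)
            else:
                dt = np.inf
            if t + dt >= next_bnd:
                t = next_bnd
                phase += 1
                if phase == 0:
                    for i in range(k):
                        deme[i] = 0
                continue
            t += dt
            u = np.random.random() * total
            if u < rc1 + rc2:
                d = 0 if u < rc1 else 1
                if phase >= 0:
                    d = 0
                kd = 0
                for i in range(k):
                    if phase >= 0 or deme[i] == d:
                        kd += 1
                a = np.random.randint(kd)
                b = np.random.randint(kd - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                pos = 0
                for i in range(k):
                    if phase >= 0 or deme[i] == d:
                        if pos == a:
                            ia = i
                        if pos == b:
                            ib = i
                        pos += 1
                parent[rep, active[ia]] = nxt
                parent[rep, active[ib]] = nxt
                node_time[rep, nxt] = t
                active[ia] = nxt
                nxt += 1
                k -= 1
                active[ib] = active[k]
                deme[ib] = deme[k]
            else:
                src = 0 if u < rc1 + rc2 + rm1 else 1
                kd = 0
                for i in range(k):
                    if deme[i] == src:
                        kd += 1
                a = np.random.randint(kd)
                pos = 0
                for i in range(k):
                    if deme[i] == src:
                        if pos == a:
                            deme[i] = 1 - src
                            break
                        pos += 1
        if not ok:
            parent[rep, 0] = -2
            nfail += 1
    return parent, node_time, nfail


def _model_kernel_args(model: DemographicModel) -> tuple:
    times, sizes = model.ancestral_sizes_times()
    m = np.asarray(model.migration, float)
    return (model.theta_es, model.theta_iq, m[0, 1], m[1, 0], times, sizes)


@dataclass
class Genealogies:
    """A batch of per-locus genealogies from :func:`simulate_genealogies`.

    ``parent[l, v]`` is the parent node of v at locus l (-1 at the root),
    ``node_time[l, v]`` its time in generations before present.  Leaves
    ``0..n1-1`` belong to the first deme, ``n1..n1+n2-1`` to the second.
    """

    parent: np.ndarray
    node_time: np.ndarray
    samples_per_deme: tuple

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_deme)

    @property
    def n_loci(self) -> int:
        return self.parent.shape[0]

    def heights(self) -> np.ndarray:
        return self.node_time[:, -1]

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (loci x 2n-2)."""
        n_nodes = self.parent.shape[1]
        idx = np.arange(n_nodes - 1)
        return (
            np.take_along_axis(self.node_time, self.parent[:, :-1], axis=1)
            - self.node_time[:, idx]
        )

    def total_lengths(self) -> np.ndarray:
        return self.branch_lengths().sum(axis=1)

    def leaf_sets(self, locus: int) -> np.ndarray:
        """Boolean (2n-1, n) matrix: leaves below each node at one locus."""
        n = self.n_samples
        n_nodes = 2 * n - 1
        desc = np.zeros((n_nodes, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        par = self.parent[locus]
        for v in range(n_nodes - 1):
            desc[par[v]] |= desc[v]
        return desc


def simulate_genealogies(
    model: DemographicModel,
    samples_per_deme: tuple,
    n_loci: int,
    seed: int,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> Genealogies:
    """Simulate independent genealogies under ``model``.

    ``samples_per_deme`` counts HAPLOID lineages sampled at present from
    (ES, IQ); the second entry may be 0 for single-deme histories.
    """
    n1, n2 = int(samples_per_deme[0]), int(samples_per_deme[1])
    if n1 < 1 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages and >=1 in deme ES")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    args = _model_kernel_args(model)
    parent, node_time, nfail = _sim_trees(
        n1, n2, *args, n_loci, seed % (2**31), max_events
    )
    if nfail:
        raise RuntimeError(
            f"{nfail}/{n_loci} genealogies failed to coalesce within "
            f"{max_events} events under model {model!r}"
        )
    return Genealogies(parent=parent, node_time=node_time, samples_per_deme=(n1, n2))


def joint_branch_spectrum(
    model: DemographicModel,
    samples_per_deme: tuple,
    n_reps: int,
    seed: int,
    max_events: int = DEFAULT_MAX_EVENTS,
):
    """Monte-Carlo branch-length spectrum over descendant configurations.

    Returns ``(spectrum, heights, total_lengths, n_failed)``; the spectrum
    is the (n1+1) x (n2+1) matrix of summed branch lengths per
    configuration across successful replicates.
    """
    n1, n2 = int(samples_per_deme[0]), int(samples_per_deme[1])
    if n1 < 1 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages and >=1 in deme ES")
    args = _model_kernel_args(model)
    out, heights, totlen, nfail = _sim_spectrum(
        n1, n2, *args, n_reps, seed % (2**31), max_events
    )
    return out, heights, totlen, nfail


def drop_mutations(
    genealogies: Genealogies,
    mu: float,
    locus_length: int,
    seed: int,
) -> list[np.ndarray]:
    """Overlay infinite-sites mutations on each genealogy.

    Each mutation creates one bi-allelic column carried by exactly the
    leaves below the mutated branch; the per-branch mutation count is
    Poisson with mean ``mu * locus_length * branch_length``.  Returns one
    (n_haplotypes x S_l) 0/1 matrix per locus (S_l may be 0).
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    rng = np.random.default_rng(seed)
    n = genealogies.n_samples
    bl = genealogies.branch_lengths()
    counts = rng.poisson(mu * locus_length * bl)
    sites: list[np.ndarray] = []
    for l in range(genealogies.n_loci):
        s_total = counts[l].sum()
        if s_total == 0:
            sites.append(np.zeros((n, 0), dtype=np.int8))
            continue
        desc = genealogies.leaf_sets(l)
        cols = []
        for v in np.nonzero(counts[l])[0]:
            for _ in range(counts[l][v]):
                cols.append(desc[v, :])
        sites.append(np.array(cols, dtype=np.int8).T)
    return sites
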