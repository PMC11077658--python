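"""Genotype filtering and folded site-frequency spectra.

The observed-SFS protocol mirrors common RAD-seq practice: retain SNPs
called in at least a fraction R of individuals and with minor-allele
frequency >= a floor (both computed over non-missing calls, MAF boundary
inclusive), keep one uniformly-random SNP per RAD locus, downsample each
population to remove missing data entirely, then tally the folded joint
spectrum of minor-allele counts.  Folding follows the standard convention:
a configuration is merged with its complement once, with half weight
assigned to each member of a complementary pair lying exactly on the
fold line; monomorphic corner cells are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .simulate import MISSING, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "FoldedSFS",
    "filter_loci",
    "downsample_individuals",
    "folded_joint_sfs",
    "project_sfs",
    "fold_spectrum",
    "write_sfs",
    "read_sfs",
]


@dataclass
class FilterConfig:
    """SNP retention settings (defaults follow the ddRAD protocol)."""

    presence_threshold: float = 0.75
    maf_min: float = 0.01
    one_snp_per_locus: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.presence_threshold <= 1):
            raise ValueError("presence_threshold must be in (0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")


@dataclass
class FoldedSFS:
    """Folded 1-D or joint 2-D minor-allele-count spectrum.

    ``counts`` has shape (n//2 + 1,) for one deme (index = pooled minor
    count) or (n1 + 1, n2 + 1) for two demes (index = per-deme count of the
    pooled minor allele).  ``mask`` is True for excluded cells: monomorphic
    corners and, in 2-D, the half-grid folded away.
    """

    counts: np.ndarray
    sample_sizes: tuple
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        self.mask = np.asarray(self.mask, bool)
        if self.counts.shape != self.mask.shape:
            raise ValueError("counts and mask shapes differ")
        if (self.counts[~self.mask] < 0).any():
            raise ValueError("negative SFS mass")

    @property
    def dims(self) -> int:
        return self.counts.ndim

    @property
    def n_snps(self) -> float:
        return float(self.counts[~self.mask].sum())


def _allele_stats(calls: np.ndarray):
    valid = calls != MISSING
    n_called = valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    total = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    return n_called, maf


def filter_loci(G: GenotypeMatrix, f: FilterConfig) -> GenotypeMatrix:
    """Apply presence/MAF filters and (optionally) one random SNP per locus."""
    n_called, maf = _allele_stats(G.calls)
    keep = (n_called / G.n_individuals >= f.presence_threshold) & (maf >= f.maf_min)
    idx = np.nonzero(keep)[0]
    if f.one_snp_per_locus and idx.size:
        rng = np.random.default_rng(f.seed)
        chosen = []
        for locus in np.unique(G.locus_ids[idx]):
            members = idx[G.locus_ids[idx] == locus]
            chosen.append(rng.choice(members))
        idx = np.sort(np.asarray(chosen))
    if idx.size == 0:
        raise ValueError("all SNP columns removed by filtering")
    return G.subset(
        snps=idx,
        note=f"filter R>={f.presence_threshold} MAF>={f.maf_min} "
        f"one_snp_per_locus={f.one_snp_per_locus}",
    )


def downsample_individuals(
    G: GenotypeMatrix,
    targets: dict,
    strategy: str = "least-missing",
    seed: int = 0,
) -> GenotypeMatrix:
    """Downsample each population and drop columns with remaining missing data.

    ``targets`` maps population label -> number of individuals to keep.
    Strategy "least-missing" keeps the individuals with the most complete
    data (ties broken by id order); "random" takes a seeded random subset.
    Columns that still contain a missing call among the retained
    individuals are then removed, so the result is missing-free.
    """
    miss = G.missingness()
    keep: list[int] = []
    rng = np.random.default_rng(seed)
    for pop, target in targets.items():
        members = [i for i, p in enumerate(G.populations) if p == pop]
        if target > len(members):
            raise ValueError(
                f"target {target} exceeds available {len(members)} individuals in {pop!r}"
            )
        if strategy == "least-missing":
            ranked = sorted(members, key=lambda i: (miss[i], G.individual_ids[i]))
            keep.extend(ranked[:target])
        elif strategy == "random":
            keep.extend(rng.choice(members, size=target, replace=False))
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    keep = sorted(keep)
    sub = G.calls[keep]
    complete = ~(sub == MISSING).any(axis=0)
    if not complete.any():
        raise ValueError("no SNP column is complete after downsampling")
    return G.subset(
        individuals=keep,
        snps=np.nonzero(complete)[0],
        note=f"downsample {targets} strategy={strategy}",
    )


def fold_spectrum(unfolded: np.ndarray, sample_sizes: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Fold an unfolded (derived-count) spectrum; returns (folded, mask).

    1-D: entry i and n-i merge once onto min(i, n-i); the self-complementary
    cell (i = n/2) keeps its own mass.  2-D: cell (i, j) merges with
    (n1-i, n2-j); pairs with pooled count exactly n/2 carry half weight
    each (dadi convention), so total mass is conserved.  Monomorphic
    corners are masked.
    """
    arr = np.asarray(unfolded, float)
    if arr.ndim == 1:
        n = sample_sizes[0]
        half = n // 2
        folded = np.zeros(half + 1)
        for i in range(n + 1):
            # each complementary pair is merged once; the self-complementary
            # cell (i == n-i) is visited exactly once and keeps its own mass
            folded[min(i, n - i)] += arr[i]
        mask = np.zeros(half + 1, bool)
        mask[0] = True
        return folded, mask
    n1, n2 = sample_sizes
    n = n1 + n2
    folded = np.zeros_like(arr)
    mask = np.zeros(arr.shape, bool)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            tot = i + j
            ci, cj = n1 - i, n2 - j
            if 2 * tot < n:
                folded[i, j] = arr[i, j] + arr[ci, cj]
            elif 2 * tot == n:
                if (i, j) == (ci, cj):
                    folded[i, j] = arr[i, j]
                else:
                    folded[i, j] = 0.5 * (arr[i, j] + arr[ci, cj])
            else:
                mask[i, j] = True
    mask[0, 0] = True
    mask[n1, n2] = True
    return folded, mask


def folded_joint_sfs(G: GenotypeMatrix, pops) -> FoldedSFS:
    """Tally the folded (joint) SFS of a missing-free genotype matrix.

    ``pops`` is one label (1-D spectrum) or two labels (2-D joint
    spectrum); minor is defined on the pooled sample across the referenced
    populations.  SNPs monomorphic in the referenced individuals fall in
    masked corner cells and are excluded from ``n_snps``.
    """
    if isinstance(pops, str):
        pops = [pops]
    pops = list(pops)
    if len(pops) not in (1, 2):
        raise ValueError("pops must name one or two populations")
    groups = []
    for pop in pops:
        members = [i for i, p in enumerate(G.populations) if p == pop]
        if not members:
            raise ValueError(f"population {pop!r} not present")
        groups.append(np.asarray(members))
    sub = G.calls[np.concatenate(groups)]
    if (sub == MISSING).any():
        raise ValueError(
            "missing calls present; run downsample_individuals first to "
            "obtain a missing-free matrix"
        )
    sizes = tuple(2 * len(g) for g in groups)
    counts_per_pop = [G.calls[g].sum(axis=0) for g in groups]
    if len(pops) == 1:
        n = sizes[0]
        unfolded = np.bincount(counts_per_pop[0], minlength=n + 1).astype(float)
        folded, mask = fold_spectrum(unfolded, sizes)
        return FoldedSFS(counts=folded, sample_sizes=sizes, mask=mask)
    n1, n2 = sizes
    unfolded = np.zeros((n1 + 1, n2 + 1))
    np.add.at(unfolded, (counts_per_pop[0], counts_per_pop[1]), 1.0)
    folded, mask = fold_spectrum(unfolded, sizes)
    return FoldedSFS(counts=folded, sample_sizes=sizes, mask=mask)


def _unfold_half(s: FoldedSFS) -> np.ndarray:
    """Embed a folded spectrum into the unfolded grid (mass as stored)."""
    if s.dims == 1:
        n = s.sample_sizes[0]
        arr = np.zeros(n + 1)
        arr[: s.counts.shape[0]] = s.counts
        return arr
    arr = s.counts.copy()
    arr[s.mask] = 0.0
    return arr


def project_sfs(s: FoldedSFS, m: tuple) -> tuple[FoldedSFS, float]:
    """Hypergeometric projection of a folded SFS onto smaller sample sizes.

    Each cell's mass is redistributed according to sampling ``m_k`` alleles
    without replacement from ``n_k``; the projected spectrum is re-folded.
    Returns ``(projected, lost)`` where ``lost`` is the mass that became
    monomorphic under projection.
    """
    m = tuple(int(x) for x in m)
    if len(m) != len(s.sample_sizes):
        raise ValueError("dimension mismatch")
    if any(mk < 2 for mk in m):
        raise ValueError("projected sizes must be >= 2")
    if any(mk > nk for mk, nk in zip(m, s.sample_sizes)):
        raise ValueError("projected sizes must not exceed sample sizes")
    arr = _unfold_half(s)
    # projection matrices P_k[new, old] = P(draw new of old minor alleles)
    mats = []
    for mk, nk in zip(m, s.sample_sizes):
        P = np.zeros((mk + 1, nk + 1))
        for old in range(nk + 1):
            P[:, old] = hypergeom.pmf(np.arange(mk + 1), nk, old, mk)
        mats.append(P)
    if s.dims == 1:
        proj = mats[0] @ arr
    else:
        proj = mats[0] @ arr @ mats[1].T
    folded, mask = fold_spectrum(proj, m)
    lost = float(folded[mask].sum())
    folded = folded.copy()
    folded[mask] = 0.0
    return FoldedSFS(counts=folded, sample_sizes=m, mask=mask), lost


# ---------------------------------------------------------------------------
# flat-text serialization (dadi/fastsimcoal-style: header, counts, mask)

def write_sfs(s: FoldedSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write("# folded SFS; sample sizes (haploid): "
                 + " ".join(str(x) for x in s.sample_sizes) + "\n")
        fh.write(" ".join(str(x) for x in s.sample_sizes) + "\n")
        flat = s.counts.ravel()
        fh.write(" ".join(repr(float(x)) for x in flat) + "\n")
        fh.write(" ".join("1" if x else "0" for x in s.mask.ravel()) + "\n")


def read_sfs(path) -> FoldedSFS:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    sizes = tuple(int(x) for x in lines[0].split())
    counts = np.array([float(x) for x in lines[1].split()])
    mask = np.array([x == "1" for x in lines[2].split()])
    if len(sizes) == 2:
        shape = (sizes[0] + 1, sizes[1] + 1)
        counts = counts.reshape(shape)
        mask = mask.reshape(shape)
    return FoldedSFS(counts=counts, sample_sizes=sizes, mask=mask)
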