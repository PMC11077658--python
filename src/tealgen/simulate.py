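"""Synthetic-data generators: diploid SNP panels and mtDNA alignments.

Diploid genotypes are formed by random pairing of simulated haplotypes
(sizes in the demographic model are haploid).  Missing calls are inserted
i.i.d. per call.  A small pedigree layer can append related individuals
(Mendelian draws from named parents) to test kinship estimation.  The
mtDNA generator simulates a single non-recombining haploid genealogy with
deme sizes scaled by a configurable factor (default 0.5x the haploid
nuclear size, reflecting maternal haploid inheritance) and finite-sites
Jukes-Cantor mutations, so reverse and parallel changes are possible as in
real control-region data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescent import drop_mutations, simulate_genealogies
from .models import DemographicModel, SimConfig

__all__ = [
    "GenotypeMatrix",
    "SequenceAlignment",
    "PedigreeSpec",
    "simulate_dataset",
    "simulate_mtdna",
]

MISSING = -1  # genotype code for a missing call


@dataclass
class GenotypeMatrix:
    """Individuals x bi-allelic SNPs, coded 0/1/2 with -1 for missing.

    ``locus_ids`` groups SNP columns by their RAD locus of origin so the
    one-SNP-per-locus filter can be honoured downstream.
    """

    calls: np.ndarray
    locus_ids: np.ndarray
    individual_ids: list
    populations: list
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        self.locus_ids = np.asarray(self.locus_ids)
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if self.calls.shape[1] != len(self.locus_ids):
            raise ValueError("locus_ids length must equal SNP column count")
        if self.calls.shape[0] != len(self.individual_ids) or self.calls.shape[0] != len(
            self.populations
        ):
            raise ValueError("individual_ids/populations length mismatch")
        if self.calls.shape[1] and (self.calls == MISSING).all(axis=0).any():
            raise ValueError("every SNP column needs at least one non-missing call")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def missingness(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        if self.n_snps == 0:
            return np.zeros(self.n_individuals)
        return (self.calls == MISSING).mean(axis=1)

    def subset(self, individuals=None, snps=None, note: str | None = None) -> "GenotypeMatrix":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(ind, snp)],
            locus_ids=self.locus_ids[snp],
            individual_ids=[self.individual_ids[i] for i in ind],
            populations=[self.populations[i] for i in ind],
            provenance=self.provenance + ([note] if note else []),
        )


@dataclass
class SequenceAlignment:
    """Equal-length nucleotide sequences with population labels."""

    sequences: list
    sample_ids: list
    populations: list

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        if L == 0:
            raise ValueError("zero-length sequences")
        for sid, s in zip(self.sample_ids, self.sequences):
            if len(s) != L:
                raise ValueError(f"sequence {sid} has length {len(s)} != {L}")
        allowed = set("ACGTN-")
        for sid, s in zip(self.sample_ids, self.sequences):
            if set(s) - allowed:
                raise ValueError(f"sequence {sid} has characters outside ACGTN-")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def to_matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


@dataclass
class PedigreeSpec:
    """Relatives appended to the simulated unrelated panel.

    ``trios`` lists ``(parent_a, parent_b, child_id)``: the child's genotype
    is a Mendelian draw from the two named parents (full sibs are declared
    as two children of the same parent pair).  Parents must already exist
    (base panel or earlier children); ids must be unique.
    """

    trios: list = field(default_factory=list)

    def validate(self, known_ids: list) -> None:
        seen = set(known_ids)
        if len(seen) != len(known_ids):
            raise ValueError("duplicate ids in base panel")
        for pa, pb, child in self.trios:
            if pa not in seen or pb not in seen:
                raise ValueError(f"pedigree references unknown parent for child {child!r}")
            if child in seen:
                raise ValueError(f"duplicate child id {child!r}")
            seen.add(child)


def _mendelian_child(ga: np.ndarray, gb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a child genotype from two parental 0/1/2 vectors (no missing)."""
    def gamete(g):
        # allele transmitted per locus: het parents transmit 0/1 at random
        allele = (g == 2).astype(np.int8)
        het = g == 1
        allele[het] = rng.integers(0, 2, het.sum(), dtype=np.int8)
        return allele

    return (gamete(ga) + gamete(gb)).astype(np.int8)


def simulate_dataset(
    model: DemographicModel,
    cfg: SimConfig,
    pedigree: PedigreeSpec | None = None,
) -> GenotypeMatrix:
    """Simulate a diploid SNP dataset under ``model``.

    Returns a :class:`GenotypeMatrix` whose columns are grouped by RAD
    locus (``locus_ids``), with missing calls at ``cfg.missing_rate`` and,
    if a pedigree is given, additional related individuals drawn by
    Mendelian inheritance.  Deterministic under a fixed ``cfg.seed``.
    """
    n_es, n_iq = cfg.samples_per_deme
    hap = (2 * n_es, 2 * n_iq)
    gen = simulate_genealogies(model, hap, cfg.n_loci, seed=cfg.seed)
    site_mats = drop_mutations(gen, cfg.mu, cfg.locus_length, seed=cfg.seed + 1)

    rng = np.random.default_rng(cfg.seed + 2)
    cols = []
    locus_ids = []
    # pair haplotypes within each deme: shuffle deme haplotypes, take pairs
    perm_es = rng.permutation(2 * n_es)
    perm_iq = 2 * n_es + rng.permutation(2 * n_iq)
    hap_order = np.concatenate([perm_es, perm_iq])
    for l, sm in enumerate(site_mats):
        if sm.shape[1] == 0:
            continue
        h = sm[hap_order]  # haplotypes x S
        g = h[0::2] + h[1::2]  # individuals x S
        cols.append(g)
        locus_ids.extend([l] * sm.shape[1])
    if cols:
        calls = np.concatenate(cols, axis=1).astype(np.int8)
    else:
        calls = np.zeros((n_es + n_iq, 0), dtype=np.int8)
    locus_ids = np.asarray(locus_ids)

    ids = [f"ES_{i:03d}" for i in range(n_es)] + [f"IQ_{i:03d}" for i in range(n_iq)]
    pops = ["ES"] * n_es + ["IQ"] * n_iq

    if pedigree is not None:
        pedigree.validate(ids)
        index = {sid: i for i, sid in enumerate(ids)}
        rows = [calls]
        for pa, pb, child in pedigree.trios:
            ga = rows_lookup(rows, index[pa])
            gb = rows_lookup(rows, index[pb])
            gc = _mendelian_child(ga, gb, rng)
            rows.append(gc[None, :])
            index[child] = len(index)
            ids.append(child)
            pops.append(pops[index[pa]])
        calls = np.concatenate(rows, axis=0)

    if cfg.missing_rate > 0 and calls.shape[1]:
        mask = rng.random(calls.shape) < cfg.missing_rate
        # never blank out an entire column
        keep = mask.all(axis=0)
        mask[:, keep] = False
        calls = calls.copy()
        calls[mask] = MISSING

    return GenotypeMatrix(
        calls=calls,
        locus_ids=locus_ids,
        individual_ids=ids,
        populations=pops,
        provenance=[f"simulated seed={cfg.seed} n_loci={cfg.n_loci}"],
    )


def rows_lookup(rows: list, i: int) -> np.ndarray:
    """Row i of a list of stacked genotype blocks (parents may be children)."""
    for block in rows:
        if i < block.shape[0]:
            return block[i]
        i -= block.shape[0]
    raise IndexError(i)


_BASES = np.array(list("ACGT"))


def simulate_mtdna(
    model: DemographicModel,
    cfg: SimConfig,
    samples_per_deme: tuple | None = None,
) -> SequenceAlignment:
    """Simulate an mtDNA control-region alignment under ``model``.

    One haploid genealogy for the whole (non-recombining) fragment, deme
    sizes scaled by ``cfg.mt_ne_factor``, and Jukes-Cantor finite-sites
    mutations at ``cfg.mt_mu`` per site per generation.
    """
    if cfg.mt_seq_length <= 0:
        raise ValueError("mt_seq_length must be > 0")
    if samples_per_deme is None:
        samples_per_deme = cfg.samples_per_deme
    n1, n2 = samples_per_deme
    f = cfg.mt_ne_factor
    scaled = DemographicModel(
        theta_es=model.theta_es * f,
        theta_iq=model.theta_iq * f,
        t_div=model.t_div,
        theta_anc=model.theta_anc * f,
        migration=model.migration,
        anc_epochs=tuple((t, s * f) for t, s in model.anc_epochs),
    )
    gen = simulate_genealogies(scaled, (n1, n2), 1, seed=cfg.seed + 10)
    rng = np.random.default_rng(cfg.seed + 11)
    n = n1 + n2
    L = cfg.mt_seq_length
    root_seq = rng.integers(0, 4, L, dtype=np.int8)
    # propagate sequences down the tree, mutating along branches
    n_nodes = 2 * n - 1
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    seqs[n_nodes - 1] = root_seq
    bl = gen.branch_lengths()[0]
    order = np.argsort(gen.node_time[0])[::-1]  # root first
    par = gen.parent[0]
    for v in order:
        if par[v] == -1:
            continue
        seq = seqs[par[v]].copy()
        n_mut = rng.poisson(cfg.mt_mu * bl[v] * L)
        for _ in range(n_mut):
            pos = rng.integers(L)
            seq[pos] = (seq[pos] + rng.integers(1, 4)) % 4  # JC: any other base
        seqs[v] = seq
    sequences = ["".join(_BASES[s]) for s in seqs[:n]]
    ids = [f"ES_mt_{i:03d}" for i in range(n1)] + [f"IQ_mt_{i:03d}" for i in range(n2)]
    pops = ["ES"] * n1 + ["IQ"] * n2
    return SequenceAlignment(sequences=sequences, sample_ids=ids, populations=pops)
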