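"""Readers and writers: VCF 4.2 (GT only), population maps, FASTA, tables.

VCF is the single nuclear-genotype interchange format; only the GT field
is consumed, multi-allelic and indel records are skipped with a logged
count, and both phased and unphased separators are accepted.  A
two-column population map (id, pop[, group]) accompanies the genotypes,
and a locus-id sidecar table preserves the RAD-locus grouping that the
one-SNP-per-locus filter needs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .simulate import MISSING, GenotypeMatrix, SequenceAlignment

logger = logging.getLogger("tealgen")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_fasta",
    "write_fasta",
]


def read_vcf(path, popmap: dict | None = None, locus_ids: dict | None = None) -> GenotypeMatrix:
    """Load bi-allelic SNPs from a VCF into a GenotypeMatrix.

    ``popmap`` maps sample id -> population (defaults to one population
    "pop0"); ``locus_ids`` maps "CHROM:POS" -> RAD locus id (defaults to
    CHROM, the natural grouping when each RAD locus is written as one
    contig).  Multi-allelic and indel records are skipped and counted.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: no samples / missing GT format")
    cols = []
    loci = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        gts = rec.genotype.array()
        g = np.where((gts[:, :2] < 0).any(axis=1), MISSING, gts[:, :2].clip(min=0).sum(axis=1))
        cols.append(g.astype(np.int8))
        key = f"{rec.CHROM}:{rec.POS}"
        loci.append(locus_ids.get(key, rec.CHROM) if locus_ids else rec.CHROM)
    if skipped:
        logger.info("read_vcf: skipped %d non-bi-allelic-SNP records", skipped)
    if not cols:
        raise ValueError(f"{path}: empty VCF body (no usable SNP records)")
    calls = np.stack(cols, axis=1)
    if popmap is None:
        popmap = {s: "pop0" for s in samples}
    missing_samples = [s for s in samples if s not in popmap]
    if missing_samples:
        raise ValueError(f"samples missing from popmap: {missing_samples[:5]}")
    return GenotypeMatrix(
        calls=calls,
        locus_ids=np.asarray(loci),
        individual_ids=samples,
        populations=[popmap[s] for s in samples],
        provenance=[f"read_vcf {path}"],
    )


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only, './.' for missing).

    Each SNP is placed on a contig named after its RAD locus id, so
    reading the file back recovers the locus grouping from CHROM.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in pd.unique(G.locus_ids):
            fh.write(f"##contig=<ID=locus_{locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individual_ids)
            + "\n"
        )
        pos_in_locus: dict = {}
        for j in range(G.n_snps):
            locus = G.locus_ids[j]
            pos_in_locus[locus] = pos_in_locus.get(locus, 0) + 1
            row = [
                f"locus_{locus}",
                str(pos_in_locus[locus]),
                f"snp_{j}",
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt_str[int(g)] for g in G.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def read_popmap(path) -> tuple[dict, dict]:
    """Read a tab-separated id/population[/group] map.

    Returns (popmap, groupmap); groupmap is empty when the third column is
    absent.  Duplicate ids are an error.
    """
    popmap: dict = {}
    groupmap: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0] or parts[0].startswith("#"):
                continue
            if parts[0] in popmap:
                raise ValueError(f"duplicate id {parts[0]!r} in popmap")
            popmap[parts[0]] = parts[1]
            if len(parts) > 2 and parts[2]:
                groupmap[parts[0]] = parts[2]
    if not popmap:
        raise ValueError(f"{path}: empty popmap")
    return popmap, groupmap


def write_popmap(G: GenotypeMatrix, path, groups: dict | None = None) -> None:
    with open(path, "w") as fh:
        for sid, pop in zip(G.individual_ids, G.populations):
            if groups and pop in groups:
                fh.write(f"{sid}\t{pop}\t{groups[pop]}\n")
            else:
                fh.write(f"{sid}\t{pop}\n")


def read_fasta(path, popmap: dict | None = None) -> SequenceAlignment:
    """Read an aligned FASTA; ids are header tokens up to first whitespace.

    Sequences are upper-cased; ragged lengths and duplicate ids raise with
    the offending record named.  Population labels come from ``popmap``
    (default: a single population "pop0").
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = {i for i in ids if ids.count(i) > 1}
        raise ValueError(f"duplicate sequence id(s): {sorted(dup)}")
    seqs = [str(r.seq).upper() for r in records]
    L = len(seqs[0])
    for sid, s in zip(ids, seqs):
        if len(s) != L:
            raise ValueError(f"record {sid!r} has length {len(s)}, expected {L}")
    if popmap is None:
        pops = ["pop0"] * len(ids)
    else:
        missing = [i for i in ids if i not in popmap]
        if missing:
            raise ValueError(f"sequences missing from popmap: {missing[:5]}")
        pops = [popmap[i] for i in ids]
    return SequenceAlignment(sequences=seqs, sample_ids=ids, populations=pops)


def write_fasta(aln: SequenceAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sample_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")
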