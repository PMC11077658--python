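#!/usr/bin/env python
"""Kinship filtering and nuclear diversity of the synthetic panel.

Applies the ddRAD retention filters (R >= 0.75, MAF >= 0.01, one random
SNP per locus), estimates KING-robust kinship, retains the unrelated set
(among relatives, the individual with the least missing data), and
tabulates H_O / H_E / pi / F_IS per deme plus per-individual
heterozygosity and Weir-Cockerham F_ST with a permutation test.
"""

import argparse
from pathlib import Path

import pandas as pd

from tealgen.io import read_popmap, read_vcf
from tealgen.popgen import (
    diversity,
    fst_wc,
    individual_heterozygosity,
    kinship_king,
    select_unrelated,
)
from tealgen.sfs import FilterConfig, filter_loci


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--kinship-threshold", type=float, default=0.044)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    popmap, _ = read_popmap(args.data / "popmap.tsv")
    G = read_vcf(args.data / "snps.vcf", popmap)
    G = filter_loci(G, FilterConfig(seed=args.seed))
    print(f"after filters: {G.n_snps} unlinked SNPs")

    kin = kinship_king(G)
    kin.phi.round(5).to_csv(args.out / "kinship.tsv", sep="\t")
    flagged = [
        (a, b, kin.phi.loc[a, b])
        for i, a in enumerate(G.individual_ids)
        for b in G.individual_ids[i + 1:]
        if kin.phi.loc[a, b] > args.kinship_threshold
    ]
    print(f"{len(flagged)} pairs above phi > {args.kinship_threshold}:")
    for a, b, v in flagged[:10]:
        print(f"  {a} - {b}: {v:.3f}")

    keep = select_unrelated(kin, G.missingness(), threshold=args.kinship_threshold)
    (args.out / "unrelated_ids.txt").write_text("\n".join(keep) + "\n")
    idx = [i for i, s in enumerate(G.individual_ids) if s in set(keep)]
    G_u = G.subset(individuals=idx, note="unrelated")
    print(f"unrelated set: {len(keep)} of {G.n_individuals} individuals")

    div = diversity(G_u, ["ES", "IQ"], mode="variant")
    div.table.round(4).to_csv(args.out / "diversity_variant.tsv", sep="\t")
    print(div.table.round(3).to_string())

    het = individual_heterozygosity(G_u)
    het.round(4).to_frame().to_csv(args.out / "individual_heterozygosity.tsv", sep="\t")
    print(f"individual H_O range: {het.min():.3f} - {het.max():.3f}")

    f, p = fst_wc(G_u, ("ES", "IQ"), n_permutations=9999, seed=args.seed)
    pd.DataFrame({"F_ST": [f], "p": [p]}, index=["ES-IQ"]).round(5).to_csv(
        args.out / "fst.tsv", sep="\t"
    )
    print(f"Weir-Cockerham F_ST(ES, IQ) = {f:.4f} (permutation p = {p:.4f})")


if __name__ == "__main__":
    main()
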