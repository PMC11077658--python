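#!/usr/bin/env python
"""Build the folded joint site-frequency spectrum for demographic fitting.

Starts from the unrelated set of 02, re-filters WITHOUT the MAF floor
(rare variants carry most of the demographic signal), keeps one random
SNP per locus, downsamples each deme to 50% of individuals preferring the
most complete genotypes, and drops any column still containing a missing
call so the spectrum is missing-free.
"""

import argparse
from pathlib import Path

from tealgen.io import read_popmap, read_vcf
from tealgen.sfs import (
    FilterConfig,
    downsample_individuals,
    filter_loci,
    folded_joint_sfs,
    write_sfs,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    popmap, _ = read_popmap(args.data / "popmap.tsv")
    G = read_vcf(args.data / "snps.vcf", popmap)
    keep_ids = set((args.out / "unrelated_ids.txt").read_text().split())
    idx = [i for i, s in enumerate(G.individual_ids) if s in keep_ids]
    G = G.subset(individuals=idx, note="unrelated")

    # no MAF floor for the SFS; presence filter and 1 SNP/locus still apply
    G = filter_loci(G, FilterConfig(maf_min=0.0, seed=args.seed))
    counts = {p: G.populations.count(p) for p in ("ES", "IQ")}
    targets = {p: max(2, round(0.5 * n)) for p, n in counts.items()}
    G_d = downsample_individuals(G, targets, strategy="least-missing")
    print(f"downsampled to {targets} individuals; "
          f"{G_d.n_snps} missing-free SNPs")

    joint = folded_joint_sfs(G_d, ["ES", "IQ"])
    write_sfs(joint, args.out / "joint_sfs.txt")
    print(f"joint folded SFS: sample sizes {joint.sample_sizes} haploid, "
          f"{joint.n_snps:.0f} polymorphic SNPs")
    for pop in ("ES", "IQ"):
        marg = folded_joint_sfs(G_d, pop)
        write_sfs(marg, args.out / f"sfs_{pop}.txt")


if __name__ == "__main__":
    main()
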