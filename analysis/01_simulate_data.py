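#!/usr/bin/env python
"""Generate the synthetic study system: a two-deme ddRAD-like SNP panel
and an mtDNA control-region alignment under the best-supported divergence
model (one-epoch ancestral population, symmetric migration) at its point
estimates, plus a handful of pedigreed relatives to exercise kinship
filtering.

Writes VCF + popmap + FASTA under results/data/.
"""

import argparse
from pathlib import Path

from tealgen.io import write_fasta, write_popmap, write_vcf
from tealgen.models import DemographicModel, SimConfig
from tealgen.simulate import PedigreeSpec, simulate_dataset, simulate_mtdna

POINT_ESTIMATES = dict(
    theta_es=16388.0, theta_iq=48654.0, t_div=407.0, theta_anc=3225.0, m_sym=8.71e-7
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--n-loci", type=int, default=75_000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    m = POINT_ESTIMATES
    model = DemographicModel(
        theta_es=m["theta_es"], theta_iq=m["theta_iq"], t_div=m["t_div"],
        theta_anc=m["theta_anc"],
        migration=((0.0, m["m_sym"]), (m["m_sym"], 0.0)),
    )
    cfg = SimConfig(seed=args.seed, n_loci=args.n_loci, locus_length=140,
                    missing_rate=0.02, samples_per_deme=(24, 12))
    # a related trio and a full-sib pair inside the ES deme
    ped = PedigreeSpec(trios=[
        ("ES_000", "ES_001", "ES_rel_a"),
        ("ES_002", "ES_003", "ES_rel_b"),
        ("ES_002", "ES_003", "ES_rel_c"),
    ])
    G = simulate_dataset(model, cfg, ped)
    write_vcf(G, args.out / "snps.vcf")
    write_popmap(G, args.out / "popmap.tsv", groups={"ES": "west_med", "IQ": "sw_asia"})
    print(f"SNP panel: {G.n_individuals} individuals x {G.n_snps} SNPs "
          f"({args.n_loci} loci simulated)")

    aln = simulate_mtdna(model, cfg, samples_per_deme=(32, 12))
    write_fasta(aln, args.out / "mtdna.fasta")
    with open(args.out / "mt_popmap.tsv", "w") as fh:
        for sid, pop in zip(aln.sample_ids, aln.populations):
            group = "west_med" if pop == "ES" else "sw_asia"
            fh.write(f"{sid}\t{pop}\t{group}\n")
    n_hap = len(set(aln.sequences))
    print(f"mtDNA alignment: {aln.n_sequences} x {aln.length} bp, {n_hap} haplotypes")
    with open(args.out / "siminfo.tsv", "w") as fh:
        fh.write(f"n_loci\t{args.n_loci}\nlocus_length\t140\nseed\t{args.seed}\n")


if __name__ == "__main__":
    main()
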