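#!/usr/bin/env python
"""mtDNA analyses: haplotypes, diversity, differentiation, AMOVA, network.

Collapses the control-region alignment into haplotypes with per-deme
counts, computes Hd (with sampling variance), per-site pi and Tajima's D
per deme, tests differentiation (Phi_ST) and the hierarchical AMOVA over
flyway groups, and writes the statistical-parsimony network.
"""

import argparse
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from tealgen.io import read_fasta, read_popmap
from tealgen.mtdna import (
    amova,
    collapse_haplotypes,
    hap_diversity,
    nuc_diversity,
    phi_st,
    tajimas_d,
    tcs_network,
)
from tealgen.simulate import SequenceAlignment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--permutations", type=int, default=9999)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    popmap, groupmap = read_popmap(args.data / "mt_popmap.tsv")
    aln = read_fasta(args.data / "mtdna.fasta", popmap)
    haps = collapse_haplotypes(aln)
    haps.counts.assign(private=haps.private).to_csv(args.out / "haplotypes.tsv", sep="\t")
    print(f"{haps.n_haplotypes} haplotypes in {aln.n_sequences} sequences; "
          f"{int(haps.private.sum())} private to one deme")

    rows = []
    for pop in ("ES", "IQ"):
        idx = [i for i, p in enumerate(aln.populations) if p == pop]
        sub = SequenceAlignment(
            sequences=[aln.sequences[i] for i in idx],
            sample_ids=[aln.sample_ids[i] for i in idx],
            populations=[pop] * len(idx),
        )
        counts = haps.counts[pop][haps.counts[pop] > 0]
        hd, var = hap_diversity(counts)
        try:
            d = tajimas_d(sub)
        except ValueError:
            d = np.nan
        rows.append((pop, len(idx), len(counts), hd, np.sqrt(var),
                     nuc_diversity(sub), d))
    stats = pd.DataFrame(
        rows, columns=["population", "n", "H", "Hd", "Hd_sd", "pi", "tajimas_D"]
    ).set_index("population")
    stats.round(4).to_csv(args.out / "mtdna_diversity.tsv", sep="\t")
    print(stats.round(3).to_string())

    phi, p = phi_st(aln, ("ES", "IQ"), n_permutations=args.permutations,
                    seed=args.seed)
    pd.DataFrame({"Phi_ST": [phi], "p": [p]}, index=["ES-IQ"]).round(4).to_csv(
        args.out / "phist.tsv", sep="\t"
    )
    print(f"Phi_ST(ES, IQ) = {phi:.3f} (p = {p:.4f})")

    groups: dict = {}
    for pop in set(aln.populations):
        sid = next(s for s, p_ in zip(aln.sample_ids, aln.populations) if p_ == pop)
        groups.setdefault(groupmap.get(sid, pop), []).append(pop)
    if len(groups) >= 2:
        res = amova(aln, groups, n_permutations=args.permutations, seed=args.seed)
        res.table.round(4).to_csv(args.out / "amova.tsv", sep="\t")
        pd.Series(res.p_values).round(4).to_csv(args.out / "amova_pvalues.tsv", sep="\t")
        print(res.table.round(3).to_string())

    net = tcs_network(haps)
    print(f"parsimony network: limit {net.connection_limit} steps, "
          f"{len(net.components)} component(s)")
    pd.DataFrame(list(net.graph.edges), columns=["a", "b"]).to_csv(
        args.out / "network_edges.tsv", sep="\t", index=False
    )
    nx.write_graphml(net.graph, args.out / "network.graphml")


if __name__ == "__main__":
    main()
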