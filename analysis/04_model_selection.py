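#!/usr/bin/env python
"""Fit the nine divergence models to the joint SFS and rank them by AIC.

The contemporary IQ size is fixed from its all-positions nucleotide
diversity (theta = pi / 2mu), the other parameters are estimated by
multi-start direct search on the Monte-Carlo composite likelihood, and
the winner gets percentile bootstrap confidence intervals.  Replicate
counts here are reduced relative to a full production protocol (100
starts, 100 bootstrap draws); raise --replicates/--bootstrap for final
figures.
"""

import argparse
from pathlib import Path

import pandas as pd

from tealgen.demofit import (
    fit_model,
    generations_to_years,
    model_selection,
    parametric_bootstrap,
    theta_from_pi,
    warm_start_params,
)
from tealgen.io import read_popmap, read_vcf
from tealgen.models import MODEL_IDS
from tealgen.popgen import diversity
from tealgen.sfs import read_sfs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--models", nargs="*", default=list(MODEL_IDS))
    ap.add_argument("--replicates", type=int, default=3)
    ap.add_argument("--bootstrap", type=int, default=20)
    ap.add_argument("--mu", type=float, default=4.83e-9)
    args = ap.parse_args()

    joint = read_sfs(args.out / "joint_sfs.txt")
    popmap, _ = read_popmap(args.data / "popmap.tsv")
    G = read_vcf(args.data / "snps.vcf", popmap)
    siminfo = dict(
        line.split("\t") for line in (args.data / "siminfo.tsv").read_text().splitlines()
    )
    total_length = int(siminfo["n_loci"]) * int(siminfo["locus_length"])
    pi_iq = diversity(G, ["IQ"], mode="all", total_length=total_length).table["pi"].iloc[0]
    theta_iq = theta_from_pi(pi_iq, args.mu)
    print(f"pi(IQ, all positions) = {pi_iq:.3e} -> fixed theta_IQ = {theta_iq:.0f} haploid")

    # each richer model is warm-started from its nested parent's optimum
    parent = {"A2": "A1", "A3": "A2", "B1": "A1", "B2": "B1", "B3": "B2",
              "C1": "B1", "C2": "C1", "C3": "C2"}
    fits: dict = {}
    for mid in args.models:
        extra = None
        pid = parent.get(mid)
        if pid in fits:
            extra = [warm_start_params(mid, pid, fits[pid].params)]
        fit = fit_model(joint, mid, theta_iq, n_replicates=args.replicates,
                        n_sim_snps=10_000, polish_sim=50_000, seed=args.seed,
                        extra_starts=extra)
        fits[mid] = fit
        print(f"model {mid}: lnL = {fit.lnL:.2f} (k = {fit.k}, "
              f"converged = {fit.converged})")
    fits = list(fits.values())
    tab = model_selection(fits)
    tab.round(4).to_csv(args.out / "model_selection.tsv", sep="\t", index=False)
    print(tab.round(3).to_string(index=False))

    best = next(f for f in fits if f.model_id == tab.iloc[0]["model"])
    pd.Series(best.params).to_csv(args.out / "best_model_params.tsv", sep="\t")
    if "t_div" in best.params:
        yrs = generations_to_years(best.params["t_div"])
        print(f"best model {best.model_id}: split {best.params['t_div']:.0f} "
              f"generations (~{yrs:.0f} years) before present")

    if args.bootstrap > 0:
        ci = parametric_bootstrap(joint, best, theta_iq, B=args.bootstrap,
                                  seed=args.seed, n_replicates=1)
        ci.table.round(4).to_csv(args.out / "bootstrap_ci.tsv", sep="\t")
        print(ci.table.round(2).to_string())
        if ci.n_failed:
            print(f"({ci.n_failed} bootstrap refits non-convergent, excluded)")


if __name__ == "__main__":
    main()
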