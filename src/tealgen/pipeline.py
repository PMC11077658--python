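"""End-to-end pipeline: filter -> kinship -> stats -> SFS -> fit -> mtDNA.

The stage order enforces the analysis dependency of the study design:
kinship-based unrelated-set selection precedes diversity statistics and
SFS construction, model fitting consumes the downsampled missing-free
joint SFS with the IQ size fixed from its diversity, and the mtDNA
analyses run independently from the alignment.  Every stage writes its
table under the output directory and is recorded in a manifest
(inputs, settings, seed, package version) sufficient to reproduce the
run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demofit import (
    fit_model,
    fit_stairway,
    model_selection,
    theta_from_pi,
)
from .io import read_fasta, read_popmap, read_vcf
from .mtdna import amova, collapse_haplotypes, hap_diversity, nuc_diversity, phi_st, tajimas_d, tcs_network
from .popgen import diversity, individual_heterozygosity, kinship_king, select_unrelated, fst_wc
from .sfs import FilterConfig, downsample_individuals, filter_loci, folded_joint_sfs, write_sfs

logger = logging.getLogger("tealgen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for a full pipeline run (paths + analysis parameters)."""

    vcf: str
    popmap: str
    outdir: str
    seed: int
    fasta: str | None = None
    mt_popmap: str | None = None
    presence_threshold: float = 0.75
    maf_min: float = 0.01
    one_snp_per_locus: bool = True
    kinship_threshold: float = 0.044  # third-degree cutoff; see methods note
    downsample_fraction: float = 0.5
    pops: tuple = ("ES", "IQ")
    models: tuple = ("A1", "A2", "A3")
    n_replicates: int = 10
    n_sim_snps: int = 10_000
    fit_maxfev: int | None = None
    mu: float = 4.83e-9
    generation_time: float = 4.0
    stairway_breaks: tuple = (100.0, 1000.0, 10_000.0, 100_000.0)
    total_length: float | None = None  # sequenced positions for stairway scale
    amova_groups: dict | None = None
    n_permutations: int = 999

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vcf", "popmap"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"config missing required path {name!r}")
            if not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")
        if self.fasta and not Path(self.fasta).exists():
            raise ValueError(f"fasta path does not exist: {self.fasta}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.models and not self.total_length:
            raise ValueError(
                "total_length (sequenced positions) is required to fix "
                "theta_IQ for model fitting"
            )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    A stage failure aborts the run with the stage name while keeping the
    outputs of earlier stages on disk.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "settings": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stages": [],
    }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        popmap, groupmap = read_popmap(cfg.popmap)
        G = read_vcf(cfg.vcf, popmap)
        manifest["n_input_snps"] = int(G.n_snps)

        stage("filter")
        G_f = filter_loci(
            G,
            FilterConfig(
                presence_threshold=cfg.presence_threshold,
                maf_min=cfg.maf_min,
                one_snp_per_locus=cfg.one_snp_per_locus,
                seed=cfg.seed,
            ),
        )
        manifest["n_filtered_snps"] = int(G_f.n_snps)

        stage("kinship")
        kin = kinship_king(G_f)
        kin.phi.round(6).to_csv(outdir / "kinship.tsv", sep="\t")

        stage("unrelated")
        keep_ids = select_unrelated(kin, G_f.missingness(), threshold=cfg.kinship_threshold)
        (outdir / "unrelated_ids.txt").write_text("\n".join(keep_ids) + "\n")
        keep_idx = [i for i, s in enumerate(G_f.individual_ids) if s in set(keep_ids)]
        G_u = G_f.subset(individuals=keep_idx, note="unrelated set")
        manifest["n_unrelated"] = len(keep_ids)

        stage("diversity")
        div = diversity(G_u, list(cfg.pops), mode="variant")
        _write(div.table, outdir / "diversity.tsv")
        het = individual_heterozygosity(G_u)
        het.to_frame().to_csv(outdir / "individual_heterozygosity.tsv", sep="\t")

        stage("fst")
        f_st, p_fst = fst_wc(G_u, tuple(cfg.pops), cfg.n_permutations, seed=cfg.seed)
        _write(
            pd.DataFrame({"F_ST": [f_st], "p": [p_fst]}, index=["-".join(cfg.pops)]),
            outdir / "fst.tsv",
        )

        stage("sfs")
        counts = {p: sum(1 for x in G_u.populations if x == p) for p in cfg.pops}
        targets = {p: max(2, int(round(cfg.downsample_fraction * n))) for p, n in counts.items()}
        G_d = downsample_individuals(G_u, targets, strategy="least-missing")
        joint = folded_joint_sfs(G_d, list(cfg.pops))
        write_sfs(joint, outdir / "joint_sfs.txt")
        manifest["n_sfs_snps"] = float(joint.n_snps)
        manifest["downsample_targets"] = targets

        stage("fit")
        pi_iq = diversity(
            G_u, [cfg.pops[1]], mode="all", total_length=cfg.total_length
        ).table["pi"].iloc[0]
        theta_iq = theta_from_pi(pi_iq, cfg.mu)
        fits = [
            fit_model(
                joint,
                mid,
                theta_iq,
                n_replicates=cfg.n_replicates,
                n_sim_snps=cfg.n_sim_snps,
                maxfev=cfg.fit_maxfev,
                seed=cfg.seed,
            )
            for mid in cfg.models
        ]
        stage("select")
        tab = model_selection(fits)
        _write(tab.set_index("model"), outdir / "model_selection.tsv")
        best = tab.iloc[0]["model"]
        best_fit = next(f for f in fits if f.model_id == best)
        pd.Series(best_fit.params).to_csv(outdir / "best_model_params.tsv", sep="\t")
        manifest["best_model"] = str(best)
        manifest["theta_iq_fixed"] = float(theta_iq)

        if cfg.total_length:
            stage("stairway")
            marg = folded_joint_sfs(G_d, cfg.pops[0])
            traj = fit_stairway(
                marg,
                cfg.total_length,
                cfg.mu,
                [b for b in cfg.stairway_breaks if b > 1],
                B=0,
                seed=cfg.seed,
                generation_time=cfg.generation_time,
            )
            _write(
                pd.DataFrame(
                    {
                        "time_gen": traj.times_gen,
                        "time_years": traj.times_years,
                        "Ne_haploid": traj.point,
                    }
                ),
                outdir / "ne_trajectory.tsv",
            )

        if cfg.fasta:
            stage("mtdna")
            mt_pop, mt_group = read_popmap(cfg.mt_popmap or cfg.popmap)
            aln = read_fasta(cfg.fasta, mt_pop)
            haps = collapse_haplotypes(aln)
            haps.counts.to_csv(outdir / "haplotypes.tsv", sep="\t")
            rows = []
            for pop in sorted(set(aln.populations)):
                idx = [i for i, p in enumerate(aln.populations) if p == pop]
                if len(idx) < 2:
                    continue
                sub_counts = haps.counts[pop][haps.counts[pop] > 0]
                hd, var = hap_diversity(sub_counts)
                from .simulate import SequenceAlignment

                sub = SequenceAlignment(
                    sequences=[aln.sequences[i] for i in idx],
                    sample_ids=[aln.sample_ids[i] for i in idx],
                    populations=[pop] * len(idx),
                )
                pi = nuc_diversity(sub)
                try:
                    d = tajimas_d(sub)
                except ValueError:
                    d = np.nan
                rows.append((pop, len(idx), int((sub_counts > 0).sum()), hd, var, pi, d))
            _write(
                pd.DataFrame(
                    rows, columns=["population", "n", "H", "Hd", "Hd_var", "pi", "tajimas_D"]
                ).set_index("population"),
                outdir / "mtdna_diversity.tsv",
            )
            mt_pops = [p for p in dict.fromkeys(aln.populations)
                       if aln.populations.count(p) >= 2]
            if len(mt_pops) >= 2:
                phi, p_phi = phi_st(aln, tuple(mt_pops[:2]), cfg.n_permutations, seed=cfg.seed)
                _write(
                    pd.DataFrame({"Phi_ST": [phi], "p": [p_phi]},
                                 index=["-".join(mt_pops[:2])]),
                    outdir / "phist.tsv",
                )
            if cfg.amova_groups:
                res = amova(aln, cfg.amova_groups, cfg.n_permutations, seed=cfg.seed)
                _write(res.table, outdir / "amova.tsv")
                pd.Series(res.p_values).to_csv(outdir / "amova_pvalues.tsv", sep="\t")
            net = tcs_network(haps)
            nx_edges = pd.DataFrame(
                [(a, b) for a, b in net.graph.edges], columns=["node_a", "node_b"]
            )
            nx_edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
            import networkx as nx

            nx.write_graphml(net.graph, outdir / "network.graphml")
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
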