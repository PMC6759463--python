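"""End-to-end pipeline: QC -> dedup -> LD prune -> structure -> F_ST/trees
-> phenotype statistics -> GWAS, with one master seed and a manifest.

Every stage is a pure function of (inputs, parameters, seed); the master
seed deterministically derives independent per-stage streams so that the
multi-run procedures (admixture restarts, bootstrap replicates) are
reproducible yet mutually independent.  The manifest records every file
written with its producing stage and parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distance, gwas, pheno, qc, redundancy, simulate, structure
from .io import (
    GenotypeMatrix,
    PhenoTable,
    read_geno_tsv,
    read_hapmap,
    read_phenotypes,
    read_vcf,
    write_geno_tsv,
    write_newick,
    write_qmatrix,
    write_square_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds, with the study defaults."""

    genotypes: str | None = None          # path; None -> simulate
    genotype_format: str = "tsv"          # tsv | vcf | hapmap
    phenotypes: str | None = None
    replicate_ids: list[str] = field(default_factory=list)
    out_dir: str = "results/pipeline"
    seed: int = 0
    sim_n_loci: int = 3000        # loci for the synthetic fixture

    min_maf: float = 0.05
    min_call_rate: float = 0.80
    min_inbreeding: float = 0.8
    sample_call_rate: float = 0.80
    r2_max: float = 0.5
    q_min: float = 0.6
    k_max: int = 40
    admix_k_range: tuple[int, int] = (1, 7)
    admix_runs: int = 10
    n_boot: int = 100
    fst_flags: tuple[float, float] = (0.8, 0.95)
    fdr: float = 0.05
    gwas_trait: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("admix_k_range", "fst_flags"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: list(v) if isinstance(v, tuple) else v
                                 for k, v in asdict(config).items()},
                      "stages": {}, "files": {}}
    written: dict[str, dict] = manifest["files"]

    def emit(path: Path, stage: str, **params) -> None:
        written[str(path.relative_to(out))] = {
            "stage": stage, "params": params, "sha256": _sha256(path)
        }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- inputs ----------------------------------------------------------
    truth = None
    replicate_ids = list(config.replicate_ids)
    ptable: PhenoTable | None = None
    if config.genotypes is None:
        spec = simulate.SimSpec(seed=stage_seed(config.seed, "simulate"),
                                n_loci=config.sim_n_loci)
        g, truth = simulate.simulate_genotypes(spec)
        ptable = simulate.simulate_phenotypes(truth.labels, g, spec, truth.ancestry)
        replicate_ids = replicate_ids or truth.replicate_ids
        write_geno_tsv(g, out / "simulated_genotypes.tsv")
        simulate.write_truth_tsv(truth, g.sample_ids, out / "simulated_truth.tsv")
        emit(out / "simulated_genotypes.tsv", "simulate", seed=spec.seed)
        emit(out / "simulated_truth.tsv", "simulate", seed=spec.seed)
    else:
        reader = {"tsv": read_geno_tsv, "vcf": read_vcf, "hapmap": read_hapmap}[
            config.genotype_format
        ]
        g = reader(config.genotypes)
        if config.phenotypes:
            ptable = read_phenotypes(config.phenotypes)

    # -- qc --------------------------------------------------------------
    try:
        g_qc, report = qc.qc_cascade(
            g, config.min_maf, config.min_call_rate, config.min_inbreeding,
            config.sample_call_rate,
        )
    except Exception as exc:
        fail("qc", exc)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    emit(out / "qc_report.tsv", "qc", min_maf=config.min_maf,
         min_call_rate=config.min_call_rate, min_inbreeding=config.min_inbreeding)
    manifest["stages"]["qc"] = {
        "loci_in": report.n_loci_in, "loci_kept": report.n_loci_kept,
        "samples_dropped": report.samples_dropped,
        "ts_tv_ratio": report.ts_tv_ratio,
    }
    logger.info("qc: %d -> %d loci, %d samples dropped", report.n_loci_in,
                report.n_loci_kept, len(report.samples_dropped))

    # -- dedup -----------------------------------------------------------
    try:
        sim_m = redundancy.ibs_matrix(g_qc)
        reps = [r for r in replicate_ids if r in g_qc.sample_ids]
        if len(reps) >= 2:
            threshold, mean, sd = redundancy.calibrate_threshold(sim_m, reps)
        else:
            threshold, mean, sd = 0.96, float("nan"), float("nan")
            logger.warning("dedup: no replicate set; using fallback threshold 0.96")
        g_nr, red = redundancy.collapse_redundant(g_qc, sim_m, threshold)
    except Exception as exc:
        fail("dedup", exc)
    write_square_matrix(np.nan_to_num(sim_m.values), sim_m.sample_ids,
                        out / "ibs_matrix.tsv")
    emit(out / "ibs_matrix.tsv", "dedup")
    manifest["stages"]["dedup"] = {
        "threshold": red.threshold, "replicate_mean": mean, "replicate_sd": sd,
        "n_groups": len(red.groups),
        "n_samples_kept": g_nr.n_samples,
        "groups": red.groups,
    }

    # -- prune -----------------------------------------------------------
    try:
        g_ld, ld_report = qc.ld_prune(g_nr, config.r2_max)
    except Exception as exc:
        fail("prune", exc)
    manifest["stages"]["prune"] = ld_report

    # -- structure -------------------------------------------------------
    try:
        scan = structure.find_clusters(
            g_ld, k_max=min(config.k_max, g_ld.n_samples - 1),
            seed=stage_seed(config.seed, "kmeans"),
        )
        labels = scan.assignments[scan.k_selected]
        dapc_model = structure.dapc(g_ld, labels,
                                    seed=stage_seed(config.seed, "dapc"))
        k_lo, k_hi = config.admix_k_range
        run_ll: dict[int, list[float]] = {}
        best_fits: dict[int, structure.AdmixtureFit] = {}
        for k in range(k_lo, k_hi + 1):
            best, runs = structure.admixture_em(
                g_ld, k, n_runs=config.admix_runs,
                seed=stage_seed(config.seed, f"admix{k}"),
            )
            run_ll[k] = [r.log_likelihood for r in runs]
            best_fits[k] = best
        deltak = structure.evanno_delta_k(run_ll)
        k_admix = deltak.k_best or scan.k_selected
        membership = structure.assign_membership(best_fits[k_admix], config.q_min)
    except Exception as exc:
        fail("structure", exc)
    scan.to_frame().to_csv(out / "kmeans_bic.tsv", sep="\t", index=False)
    deltak.to_frame().to_csv(out / "delta_k.tsv", sep="\t", index=False)
    write_qmatrix(best_fits[k_admix].q, g_ld.sample_ids, out / "qmatrix.tsv")
    for f in ("kmeans_bic.tsv", "delta_k.tsv", "qmatrix.tsv"):
        emit(out / f, "structure", seed=config.seed)
    manifest["stages"]["structure"] = {
        "k_selected_bic": scan.k_selected,
        "k_best_delta_k": deltak.k_best,
        "dapc_pcs": dapc_model.n_pcs,
        "n_admixed": membership.count(structure.ADMIXED),
    }

    # -- fst / trees -----------------------------------------------------
    try:
        cluster_labels = np.array([f"C{a}" for a in labels])
        fst = distance.wc_fst_pairwise(g_ld, cluster_labels)
        locus_report = distance.wc_fst_one_vs_rest(g_ld, cluster_labels,
                                                   config.fst_flags)
        nei = distance.nei_distance(g_ld, cluster_labels)
        if len(fst.group_names) >= 3:
            tree, _ = distance.bootstrap_support(
                g_ld, cluster_labels, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "boot"),
            )
            write_newick(tree, out / "cluster_nj.nwk")
            emit(out / "cluster_nj.nwk", "tree", n_boot=config.n_boot)
        dendro, _ = distance.allele_sharing_ward(g_ld)
        write_newick(dendro, out / "individual_ward.nwk")
        emit(out / "individual_ward.nwk", "dendro")
    except Exception as exc:
        fail("fst", exc)
    fst.to_frame().to_csv(out / "fst_pairwise.tsv", sep="\t")
    locus_report.to_csv(out / "fst_per_locus.tsv", sep="\t", index=False)
    write_square_matrix(nei.values, nei.group_names, out / "nei_distance.tsv")
    for f in ("fst_pairwise.tsv", "fst_per_locus.tsv", "nei_distance.tsv"):
        emit(out / f, "fst")
    manifest["stages"]["fst"] = {
        "max_pairwise": float(np.nanmax(fst.values)) if fst.values.size else None,
        "min_pairwise_offdiag": float(
            np.nanmin(fst.values[~np.eye(len(fst.group_names), dtype=bool)])
        ) if len(fst.group_names) > 1 else None,
    }

    # -- phenotypes + gwas ----------------------------------------------
    if ptable is not None:
        try:
            id2cluster = dict(zip(g_ld.sample_ids, cluster_labels))
            pheno_rows, herit_rows = [], []
            for trait in ptable.traits:
                at = pheno.rcbd_anova(ptable, trait)
                h = pheno.heritability(at, r=2)
                tk = pheno.cluster_tukey(ptable, id2cluster, trait)
                pheno_rows.append(tk.summary.assign(trait=trait))
                herit_rows.append({"trait": trait, "F": at.f_statistic,
                                   "p": at.p_value, "H2": h.h2})
            pd.concat(pheno_rows).to_csv(out / "cluster_traits.tsv",
                                         sep="\t", index=False)
            pd.DataFrame(herit_rows).to_csv(
                out / "heritability.tsv", sep="\t", index=False)
            emit(out / "cluster_traits.tsv", "pheno")
            emit(out / "heritability.tsv", "pheno")

            traits = [config.gwas_trait] if config.gwas_trait else ptable.traits
            kin = redundancy.ibs_matrix(g_ld)
            gwas_summaries = {}
            for trait in traits:
                y = ptable.genotype_means(trait)
                res = gwas.mlmm_forward(g_ld, y, kin, fdr=config.fdr)
                res.scan.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
                emit(out / f"gwas_{trait}.tsv", "gwas", trait=trait, fdr=config.fdr)
                gwas_summaries[trait] = res.cofactors
            manifest["stages"]["gwas"] = gwas_summaries
        except Exception as exc:
            fail("pheno/gwas", exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
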