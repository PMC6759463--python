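"""Population-structure inference on the nonredundant panel.

LD-prunes the SNPs (r^2 < 0.5), then runs the three structure routes:
k-means with BIC selection over k = 1..40, DAPC with cross-validated PC
choice, and EM admixture over K = 1..7 with the Evanno ΔK diagnostic and
the q > 0.6 membership rule.
"""

import argparse
from pathlib import Path

import pandas as pd

from lenspop.io import read_geno_tsv, write_geno_tsv, write_qmatrix
from lenspop.qc import ld_prune
from lenspop.structure import (
    ADMIXED,
    admixture_em,
    assign_membership,
    dapc,
    evanno_delta_k,
    find_clusters,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results/analysis")
    ap.add_argument("--k-admix-max", type=int, default=7)
    args = ap.parse_args()
    out = Path(args.out_dir)

    g = read_geno_tsv(out / "genotypes_nonredundant.tsv")
    g_ld, ld_report = ld_prune(g, r2_max=0.5)
    write_geno_tsv(g_ld, out / "genotypes_pruned.tsv")
    print(f"LD pruning: {ld_report['n_in']} -> {ld_report['n_kept']} loci")

    scan = find_clusters(g_ld, k_max=min(40, g_ld.n_samples - 1), seed=args.seed)
    scan.to_frame().to_csv(out / "kmeans_bic.tsv", sep="\t", index=False)
    labels = scan.assignments[scan.k_selected]
    pd.DataFrame({"sample": g_ld.sample_ids, "kmeans_cluster": labels}).to_csv(
        out / "kmeans_assignments.tsv", sep="\t", index=False)
    print(f"k-means/BIC: k = {scan.k_selected} "
          f"({scan.n_pcs} PCs retained for the sweep)")

    model = dapc(g_ld, labels, seed=args.seed + 1)
    pd.DataFrame(model.scores, index=g_ld.sample_ids).to_csv(
        out / "dapc_scores.tsv", sep="\t")
    print(f"DAPC: {model.n_pcs} PCs retained by cross-validation, "
          f"held-out error {min(model.xval_error):.3f}, "
          f"{model.scores.shape[1]} discriminant axes")

    run_ll, fits = {}, {}
    for k in range(1, args.k_admix_max + 1):
        best, runs = admixture_em(g_ld, k, n_runs=10, max_iter=300, tol=1e-3,
                                  seed=args.seed + 10 + k)
        run_ll[k] = [r.log_likelihood for r in runs]
        fits[k] = best
    table = evanno_delta_k(run_ll)
    table.to_frame().to_csv(out / "delta_k.tsv", sep="\t", index=False)
    k_best = table.k_best or scan.k_selected
    write_qmatrix(fits[k_best].q, g_ld.sample_ids, out / f"qmatrix_K{k_best}.tsv")
    membership = assign_membership(fits[k_best], q_min=0.6)
    pd.DataFrame({"sample": g_ld.sample_ids, "admixture_label": membership}).to_csv(
        out / "admixture_membership.tsv", sep="\t", index=False)
    print(f"admixture/ΔK: best K = {k_best}; "
          f"{membership.count(ADMIXED)} accessions classified admixed")


if __name__ == "__main__":
    main()
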