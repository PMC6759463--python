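"""Phenotype statistics: RCBD ANOVA, broad-sense heritability, and Tukey
cluster comparisons for every trait, producing a cluster x trait summary
(mean +/- SD with compact letters)."""

import argparse
from pathlib import Path

import pandas as pd

from lenspop.io import read_phenotypes
from lenspop.pheno import cluster_tukey, heritability, rcbd_anova


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out_dir)

    ptable = read_phenotypes(out / "phenotypes.csv")
    km = pd.read_csv(out / "kmeans_assignments.tsv", sep="\t", index_col=0)
    labels = {s: f"C{c}" for s, c in km["kmeans_cluster"].items()}

    anova_rows, summaries = [], []
    for trait in ptable.traits:
        at = rcbd_anova(ptable, trait)
        h = heritability(at, r=2)
        tk = cluster_tukey(ptable, labels, trait)
        anova_rows.append({
            "trait": trait, "F": at.f_statistic, "p": at.p_value,
            "sigma2_g": h.sigma2_g, "H2": h.h2,
        })
        summaries.append(tk.summary.assign(trait=trait))
    anova_df = pd.DataFrame(anova_rows)
    anova_df.to_csv(out / "anova_heritability.tsv", sep="\t", index=False)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "cluster_traits.tsv", sep="\t", index=False)

    print("genotypic effects and heritability:")
    print(anova_df.round(3).to_string(index=False))
    print("\ncluster means +/- SD with Tukey letters (per trait):")
    for trait in ptable.traits:
        sub = summary[summary.trait == trait]
        line = ", ".join(
            f"{r.cluster}: {r['mean']:.1f}±{r.sd:.1f}{r.letters}"
            for _, r in sub.iterrows()
        )
        print(f"  {trait}: {line}")


if __name__ == "__main__":
    main()
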