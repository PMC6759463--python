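"""Generate the synthetic germplasm panel the downstream analyses run on.

Emulates a Mediterranean inbred-lentil collection: five subpopulations
(33 accessions each) at differentiation 0.25-0.35, 19 admixed accessions,
a four-way replicate set of one reference line plus planted duplicate
groups, 3,000 biallelic GBS SNPs, 5% missing calls, near-complete selfing,
and six agronomic/seed traits with cluster effects and one shared
large-effect seed-size marker.
"""

import argparse
from pathlib import Path

from lenspop.io import write_geno_tsv
from lenspop.simulate import (
    SimSpec,
    simulate_genotypes,
    simulate_phenotypes,
    write_truth_tsv,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = SimSpec(seed=args.seed)
    g, truth = simulate_genotypes(spec)
    pheno = simulate_phenotypes(truth.labels, g, spec, truth.ancestry)

    write_geno_tsv(g, out / "genotypes.tsv")
    pheno.data.to_csv(out / "phenotypes.csv", index=False)
    write_truth_tsv(truth, g.sample_ids, out / "truth.tsv")
    (out / "replicates.txt").write_text("\n".join(truth.replicate_ids) + "\n")

    n_dups = len(truth.duplicates)
    n_adm = truth.labels.count("admixed")
    print(f"panel: {g.n_samples} accessions x {g.n_loci} SNPs")
    print(f"  planted: {n_adm} admixed, {n_dups} duplicate copies, "
          f"replicate set {truth.replicate_ids}")
    print(f"  causal marker: {truth.causal_locus} (seed-size traits)")
    print(f"wrote genotypes.tsv, phenotypes.csv, truth.tsv to {out}")


if __name__ == "__main__":
    main()
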