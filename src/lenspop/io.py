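"""Genotype and phenotype file input/output.

The canonical in-memory container is :class:`GenotypeMatrix`: a samples x
loci matrix of alternate-allele counts (0, 1, 2) with a single missing
sentinel (-1).  Genotypes are unphased (0/1 and 1/0 are the same call) and
no imputation happens at I/O time -- each downstream stage states its own
missing-data policy.

Supported on-disk formats: VCF 4.x (GT field, biallelic SNPs only), the
TASSEL HapMap-style tab-separated table, a plain samples x loci 0/1/2 TSV,
a phenotype CSV, labeled square-matrix TSV (plus the PHYLIP square
dialect), Newick trees and ancestry (Q) matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved code for a missing genotype call.
MISSING = -1

_IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}


class GenotypeIOError(ValueError):
    """Raised for malformed or unusable genotype/phenotype files."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci alternate-allele-count matrix.

    Parameters
    ----------
    sample_ids : ordered unique sample identifiers.
    locus_ids : ordered unique locus identifiers.
    calls : ``(n_samples, n_loci)`` int8 array with entries in {0, 1, 2}
        or :data:`MISSING`.
    alleles : per-locus ``(ref, alt)`` nucleotide pair, or ``None`` when
        the source format (plain TSV) does not carry allele letters.
    positions : optional per-locus (chrom, pos) metadata carried from VCF.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    alleles: list[tuple[str, str]] | None = None
    positions: list[tuple[str, int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != m:
            raise GenotypeIOError("call matrix shape does not match id lists")
        if len(set(self.sample_ids)) != n:
            raise GenotypeIOError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise GenotypeIOError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeIOError("calls must be 0, 1, 2 or the missing sentinel")
        if self.alleles is not None:
            if len(self.alleles) != m:
                raise GenotypeIOError("alleles length does not match locus count")
            for lid, pair in zip(self.locus_ids, self.alleles):
                if len(pair) != 2 or pair[0] == pair[1]:
                    raise GenotypeIOError(f"locus {lid}: need two distinct alleles, got {pair!r}")

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def calls_float(self) -> np.ndarray:
        """Calls as float64 with missing encoded as NaN."""
        out = self.calls.astype(np.float64)
        out[self.calls == MISSING] = np.nan
        return out

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
            self.calls[idx],
            None if self.alleles is None else list(self.alleles),
            None if self.positions is None else list(self.positions),
        )

    def take_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.locus_ids[j] for j in idx],
            self.calls[:, idx],
            None if self.alleles is None else [self.alleles[j] for j in idx],
            None if self.positions is None else [self.positions[j] for j in idx],
        )


@dataclass
class PhenoTable:
    """Genotype x block x trait observations from a randomized block trial."""

    data: pd.DataFrame  # columns: genotype, block, one column per trait

    def __post_init__(self) -> None:
        for col in ("genotype", "block"):
            if col not in self.data.columns:
                raise GenotypeIOError(f"phenotype table lacks mandatory column {col!r}")
        dup = self.data.duplicated(subset=["genotype", "block"])
        if dup.any():
            pair = self.data.loc[dup.idxmax(), ["genotype", "block"]].tolist()
            raise GenotypeIOError(f"duplicated (genotype, block) pair {pair}")
        vals = self.data[self.traits].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise GenotypeIOError("non-finite trait value")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("genotype", "block")]

    def genotype_means(self, trait: str) -> pd.Series:
        """Per-genotype trait mean over blocks (the GWAS/Tukey analysis unit)."""
        return self.data.groupby("genotype")[trait].mean().dropna()


# -- readers -------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF with GT fields.

    Multiallelic and non-SNP records are skipped (counted in the log);
    half-missing or missing GT becomes the missing sentinel.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"no such file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeIOError(f"unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeIOError(f"{path}: VCF has no sample/GT columns")
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    positions: list[tuple[str, int]] = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        g = np.full(len(samples), MISSING, dtype=np.int8)
        for s, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            g[s] = a + b
        locus_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        alleles.append((var.REF, var.ALT[0]))
        positions.append((var.CHROM, var.POS))
        rows.append(g)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise GenotypeIOError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(samples, locus_ids, np.column_stack(rows), alleles, positions)


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    """Load a TASSEL HapMap-style TSV (rs#, alleles, ..., per-sample genotypes).

    Two-letter ("AG") or single IUPAC genotypes are recoded to 0/1/2 against
    the locus allele pair; "N"/"NN" become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    if first not in ("rs#", "rs"):
        raise GenotypeIOError(f"{path}: not a HapMap table (first column {first!r})")
    if "alleles" not in df.columns:
        raise GenotypeIOError(f"{path}: missing 'alleles' column")
    meta_cols = {
        "rs#", "rs", "alleles", "chrom", "pos", "strand", "assembly#",
        "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
    }
    samples = [c for c in df.columns if c not in meta_cols]
    if not samples:
        raise GenotypeIOError(f"{path}: no sample columns")
    locus_ids = df[first].tolist()
    alleles: list[tuple[str, str]] = []
    calls = np.full((len(samples), len(df)), MISSING, dtype=np.int8)
    for j, (lid, pair_s) in enumerate(zip(locus_ids, df["alleles"])):
        pair = tuple(pair_s.split("/"))
        if len(pair) != 2:
            raise GenotypeIOError(f"locus {lid}: bad allele field {pair_s!r}")
        ref, alt = pair
        alleles.append((ref, alt))
        for s, sid in enumerate(samples):
            raw = df.at[j, sid]
            raw = "" if pd.isna(raw) else str(raw).strip().upper()
            if raw in ("", "N", "NN", "NA", "./.", "."):
                continue
            if len(raw) == 1:
                if raw in _IUPAC_HET:
                    letters = _IUPAC_HET[raw]
                    if set(letters) != {ref, alt}:
                        raise GenotypeIOError(
                            f"locus {lid}, sample {sid}: genotype {raw!r} not in alleles {ref}/{alt}"
                        )
                    calls[s, j] = 1
                    continue
                letters = (raw, raw)
            elif len(raw) == 2:
                letters = (raw[0], raw[1])
            else:
                raise GenotypeIOError(f"locus {lid}, sample {sid}: bad genotype {raw!r}")
            for ch in letters:
                if ch not in (ref, alt):
                    raise GenotypeIOError(
                        f"locus {lid}, sample {sid}: allele {ch!r} not in {ref}/{alt}"
                    )
            calls[s, j] = sum(ch == alt for ch in letters)
    return GenotypeMatrix(samples, locus_ids, calls, alleles)


def read_geno_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the plain genotype TSV dialect: samples as rows, loci as columns,
    cells 0/1/2/NA.  Allele letters are not part of this dialect."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    calls = df.to_numpy(dtype=float)
    out = np.full(calls.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(calls)
    out[ok] = calls[ok].astype(np.int8)
    return GenotypeMatrix(
        [str(s) for s in df.index], [str(c) for c in df.columns], out, None
    )


def write_geno_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    vals = g.calls_float()
    df = pd.DataFrame(vals, index=g.sample_ids, columns=g.locus_ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    if g.alleles is None:
        raise GenotypeIOError("cannot write VCF without allele letters")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j, lid in enumerate(g.locus_ids):
            chrom, pos = ("0", j + 1) if g.positions is None else g.positions[j]
            ref, alt = g.alleles[j]
            gts = "\t".join(gt_map[int(c)] for c in g.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t{lid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_phenotypes(
    path: str | Path,
    genotype_col: str = "genotype",
    block_col: str = "block",
) -> PhenoTable:
    """Read a phenotype CSV (genotype id, block id, one column per trait).

    Non-numeric trait cells become absent values with a logged warning.
    """
    df = pd.read_csv(path, dtype=str)
    for col in (genotype_col, block_col):
        if col not in df.columns:
            raise GenotypeIOError(f"{path}: missing mandatory column {col!r}")
    out = pd.DataFrame(
        {"genotype": df[genotype_col].astype(str), "block": df[block_col].astype(str)}
    )
    for trait in (c for c in df.columns if c not in (genotype_col, block_col)):
        vals = pd.to_numeric(df[trait], errors="coerce")
        bad = vals.isna() & df[trait].notna() & (df[trait].str.strip() != "")
        if bad.any():
            logger.warning(
                "read_phenotypes: %d non-numeric cells in trait %r set to missing",
                int(bad.sum()), trait,
            )
        out[trait] = vals
    return PhenoTable(out)


# -- matrix / tree / Q writers -------------------------------------------


def write_square_matrix(
    values: np.ndarray,
    labels: Sequence[str],
    path: str | Path,
    phylip: bool = False,
) -> None:
    """Write a labeled symmetric square matrix as TSV (default) or in the
    PHYLIP square distance dialect."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise GenotypeIOError("matrix is not square")
    if not np.allclose(values, values.T, equal_nan=True):
        raise GenotypeIOError("matrix is not symmetric")
    if phylip:
        with open(path, "w") as fh:
            fh.write(f"{len(labels)}\n")
            for lab, row in zip(labels, values):
                fh.write(lab + "  " + " ".join(f"{v:.6f}" for v in row) + "\n")
    else:
        pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(
            path, sep="\t", float_format="%.6f"
        )


def read_square_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_newick(tree, path: str | Path) -> None:
    """Serialize a scikit-bio ``TreeNode`` (or anything with ``write``) to Newick."""
    tree.write(str(path), format="newick")


def write_qmatrix(
    q: np.ndarray, sample_ids: Sequence[str], path: str | Path
) -> None:
    """Write per-sample ancestry proportions (rows summing to 1) as TSV."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != len(sample_ids):
        raise GenotypeIOError("Q matrix shape does not match sample list")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise GenotypeIOError("Q rows must sum to 1")
    cols = [f"q{k + 1}" for k in range(q.shape[1])]
    pd.DataFrame(q, index=list(sample_ids), columns=cols).to_csv(
        path, sep="\t", float_format="%.6f"
    )
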