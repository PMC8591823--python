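"""Genotype container and dosage I/O (VCF and TSV).

Dosages count copies of the alternate (A2) allele, so a diploid genotype is
0, 1 or 2; missing calls are stored as NaN.  SNP metadata (chromosome label,
1-based position, alleles, per-SNP imputation-accuracy score) travel with the
dosage matrix in a pandas DataFrame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Columns required in the SNP metadata table.
SNP_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "accuracy"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    samples
        Sample identifiers, one per matrix row.
    snps
        DataFrame with columns ``id, chrom, pos, ref, alt, accuracy``;
        one row per matrix column.
    dosages
        Float array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}`` or NaN for missing calls.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        missing = set(SNP_COLUMNS) - set(self.snps.columns)
        if missing:
            raise DataError(f"SNP table lacks columns: {sorted(missing)}")
        if (self.snps["pos"] <= 0).any():
            raise DataError("SNP positions must be strictly positive (1-based)")
        if self.snps["id"].duplicated().any():
            dupes = self.snps.loc[self.snps["id"].duplicated(), "id"].tolist()
            raise DataError(f"duplicate SNP ids: {dupes[:5]}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise DataError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing calls skipped)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-SNP mean."""
        out = self.dosages.copy()
        if np.isnan(out).any():
            col_mean = np.nanmean(out, axis=0)
            idx = np.where(np.isnan(out))
            out[idx] = col_mean[idx[1]]
        return out

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the SNPs where ``keep`` is true."""
        keep = np.asarray(keep, dtype=bool)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.loc[keep].reset_index(drop=True),
            dosages=self.dosages[:, keep],
        )


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a dosage TSV: SNP metadata columns followed by one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"dosage TSV lacks columns: {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in SNP_COLUMNS]
    if not sample_cols:
        raise DataError("dosage TSV has no sample columns")
    return GenotypeMatrix(
        samples=sample_cols,
        snps=df[SNP_COLUMNS].copy(),
        dosages=df[sample_cols].to_numpy(dtype=float).T,
    )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = geno.snps.copy()
    for i, s in enumerate(geno.samples):
        df[s] = geno.dosages[:, i]
    df.to_csv(path, sep="\t", index=False, float_format="%g")


def read_vcf(path, accuracy_key: str = "DR2") -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    The per-SNP imputation-accuracy score is taken from INFO field
    ``accuracy_key`` (default Beagle's DR2); records without it get 1.0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        acc = var.INFO.get(accuracy_key)
        if acc is None:
            acc = 1.0
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
                "accuracy": float(acc),
            }
        )
        dosage_cols.append(dos)
    vcf.close()
    if not rows:
        raise DataError(f"no biallelic records found in {path}")
    return GenotypeMatrix(
        samples=samples,
        snps=pd.DataFrame(rows),
        dosages=np.column_stack(dosage_cols),
    )


def write_vcf(geno: GenotypeMatrix, path, accuracy_key: str = "DR2") -> None:
    """Write the matrix as a minimal uncompressed VCF (GT field only)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    chroms = geno.snps["chrom"].astype(str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={accuracy_key},Number=1,Type=Float,'
            f'Description="Imputation accuracy">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(chroms):  # insertion order, unique
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j, rec in geno.snps.iterrows():
            gts = [
                gt_map.get(geno.dosages[i, j], "./.")
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{rec['id']}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\tPASS\t{accuracy_key}={rec['accuracy']:g}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
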