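"""Variant quality control: imputation accuracy, MAF, HWE and autosome filters.

The filters mirror common practice for imputed whole-genome sequence panels:
drop SNPs with imputation accuracy < 0.95, minor allele frequency < 0.05, an
exact Hardy-Weinberg test p-value < 1e-4, or a chromosome outside the autosome
set (cattle: 29 autosomes).  All cutoffs are strict in the "remove if below"
direction, so a SNP sitting exactly on a threshold is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import ConfigError, DataError
from .genotypes import GenotypeMatrix

#: Cattle autosome labels (ARS-UCD style: "1".."29").
CATTLE_AUTOSOMES = frozenset(str(i) for i in range(1, 30))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value for one biallelic SNP.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count that is no more probable than the observed one
    (the summed-probability two-sided rule).  Probabilities follow the exact
    distribution of heterozygote counts given fixed allele counts:

        P(n_het = h) = C(n, (n_minor-h)/2, h, rest) * 2^h * n_minor! n_major! / (2n)!

    Returns 1.0 for monomorphic SNPs (single possible configuration).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise DataError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise DataError("all-zero genotype counts: HWE test undefined")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    # possible het counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    log_prob = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(log_prob - log_prob.max())
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:  # inconsistent het count for these allele totals
        raise DataError(
            f"heterozygote count {n_het} impossible with minor-allele count {n_minor}"
        )
    # tolerance guards ties computed in floating point
    p = prob[prob <= obs[0] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


@dataclass
class QCReport:
    """Per-filter removal counts; removed + retained equals the input count.

    A SNP failing several filters is attributed to the first failing one in
    the order: non-autosome, accuracy, MAF, HWE.
    """

    n_input: int
    n_non_autosome: int
    n_low_accuracy: int
    n_low_maf: int
    n_hwe_fail: int
    n_retained: int

    def __post_init__(self):
        total = (
            self.n_non_autosome
            + self.n_low_accuracy
            + self.n_low_maf
            + self.n_hwe_fail
            + self.n_retained
        )
        assert total == self.n_input, "QC bookkeeping does not reconcile"


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    col = dosages[~np.isnan(dosages)]
    return (
        int((col == 0).sum()),
        int((col == 1).sum()),
        int((col == 2).sum()),
    )


def filter_variants(
    geno: GenotypeMatrix,
    min_accuracy: float = 0.95,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-4,
    autosomes_only: bool = True,
    autosome_labels: frozenset[str] = CATTLE_AUTOSOMES,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the variant filters; returns the retained matrix and a QCReport.

    Removal is strict: accuracy < ``min_accuracy``, MAF < ``min_maf`` (from
    observed dosages, missing calls skipped) or HWE p < ``hwe_alpha`` drops
    the SNP.  Filters are conjunctive, so the retained set is order-free; the
    report attributes each removal to the first failing filter.
    """
    if not (0 <= min_accuracy <= 1):
        raise ConfigError(f"min_accuracy must be in [0,1], got {min_accuracy}")
    if not (0 <= min_maf <= 0.5):
        raise ConfigError(f"min_maf must be in [0,0.5], got {min_maf}")
    if not (0 < hwe_alpha < 1):
        raise ConfigError(f"hwe_alpha must be in (0,1), got {hwe_alpha}")

    m = geno.n_snps
    autosomal = (
        geno.snps["chrom"].astype(str).isin(autosome_labels).to_numpy()
        if autosomes_only
        else np.ones(m, dtype=bool)
    )
    acc_ok = geno.snps["accuracy"].to_numpy(dtype=float) >= min_accuracy
    maf_ok = geno.minor_allele_frequencies() >= min_maf

    hwe_ok = np.ones(m, dtype=bool)
    for j in range(m):
        if not (autosomal[j] and acc_ok[j] and maf_ok[j]):
            continue  # p-value not needed for already-failed SNPs
        hwe_ok[j] = hwe_exact_test(*_genotype_counts(geno.dosages[:, j])) >= hwe_alpha

    keep = autosomal & acc_ok & maf_ok & hwe_ok
    report = QCReport(
        n_input=m,
        n_non_autosome=int((~autosomal).sum()),
        n_low_accuracy=int((autosomal & ~acc_ok).sum()),
        n_low_maf=int((autosomal & acc_ok & ~maf_ok).sum()),
        n_hwe_fail=int((autosomal & acc_ok & maf_ok & ~hwe_ok).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        warnings.warn("all SNPs removed by QC filters", stacklevel=2)
    return geno.subset_snps(keep), report
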