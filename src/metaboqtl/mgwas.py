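"""Mixed-linear-model association scan (MLMA) for metabolite phenotypes.

For each SNP j the model is

    y = mu + b_j x_j + a + e,   a ~ N(0, G sigma_a^2),  e ~ N(0, I sigma_e^2)

with the variance components estimated once per phenotype under the null
(no SNP) and held fixed across all SNP tests.  The SNP effect b_j and its
standard error come from generalized least squares with V = G s2_a + I s2_e;
significance is a Wald chi-square test on 1 df by default, with an exact
F(1, n-2) option.  The scan runs in the eigenbasis of G, so the per-SNP cost
is O(n) after one rotation of the dosage matrix.

The variance explained by a significant SNP is 2 p q beta^2 / S^2 (in
percent), with p the alternate-allele frequency and S^2 the phenotypic
variance of the adjusted metabolite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .genotypes import GenotypeMatrix
from .grm import GRM
from .reml import VarianceComponents

log = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Settings for the per-SNP scan."""

    alpha: float = 1e-5
    test: str = "wald"  # "wald" (chi-square 1 df) or "f" (F(1, n-2))

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigError(f"significance threshold must be in (0,1): {self.alpha}")
        if self.test not in ("wald", "f"):
            raise ConfigError(f"test must be 'wald' or 'f', got {self.test!r}")


def snp_variance_explained(beta: float, allele_freq: float, phenotypic_var: float) -> float:
    """Percent of phenotypic variance from one SNP: 100 * 2 p q beta^2 / S^2."""
    if not (0 < allele_freq < 1):
        raise DataError(f"allele frequency must be in (0,1), got {allele_freq}")
    if phenotypic_var <= 0:
        raise DataError(f"phenotypic variance must be positive, got {phenotypic_var}")
    p = allele_freq
    return float(100.0 * 2.0 * p * (1.0 - p) * beta * beta / phenotypic_var)


def mlma_scan(
    y,
    geno: GenotypeMatrix,
    grm: GRM,
    vc: VarianceComponents,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """GLS single-SNP scan with the polygenic covariance held fixed.

    ``y`` is the adjusted metabolite vector aligned with ``geno.samples``
    (and with the GRM).  Monomorphic SNPs are skipped with a log entry.
    Returns one row per tested SNP: ``snp, chrom, pos, freq, beta, se, p,
    vsnp_vp_pct``.
    """
    config = config or ScanConfig()
    y = np.asarray(y, dtype=float)
    n = geno.n_samples
    if y.shape != (n,):
        raise DataError("phenotype length does not match genotype samples")
    if grm.n_samples != n:
        raise DataError("GRM size does not match genotype samples")

    d, U = grm.eigendecompose()
    d = np.maximum(d, 0.0)
    v = vc.sigma2_a * d + vc.sigma2_e
    if (v <= 0).any():
        jitter = 1e-8 * (vc.sigma2_a + vc.sigma2_e)
        log.warning("singular V in MLMA scan; adding jitter %g", jitter)
        v = v + jitter
        if (v <= 0).any():
            raise DataError("covariance V not positive definite even after jitter")
    w = 1.0 / v

    X = geno.mean_imputed()
    freq = X.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    n_skip = int((~poly).sum())
    if n_skip:
        log.info("skipping %d monomorphic SNPs", n_skip)

    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    Xt = U.T @ X[:, poly]

    # per-SNP 2x2 weighted normal equations, vectorized across SNPs
    a11 = np.sum(w * ones_t * ones_t)
    b1 = np.sum(w * ones_t * yt)
    wXt = w[:, None] * Xt
    a12 = ones_t @ wXt
    a22 = np.einsum("ij,ij->j", Xt, wXt)
    b2 = yt @ wXt
    det = a11 * a22 - a12 * a12
    beta = (a11 * b2 - a12 * b1) / det
    se = np.sqrt(a11 / det)

    chi2 = (beta / se) ** 2
    if config.test == "wald":
        p = stats.chi2.sf(chi2, df=1)
    else:
        p = stats.f.sf(chi2, 1, n - 2)

    s2 = float(np.var(y, ddof=1))
    pf = freq[poly]
    vsnp = 100.0 * 2.0 * pf * (1.0 - pf) * beta**2 / s2

    out = geno.snps.loc[poly, ["id", "chrom", "pos"]].reset_index(drop=True)
    out = out.rename(columns={"id": "snp"})
    out["freq"] = pf
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["vsnp_vp_pct"] = vsnp
    return out


def select_significant(records: pd.DataFrame, alpha: float = 1e-5) -> pd.DataFrame:
    """Records with p strictly below ``alpha``, in genomic order.

    Chromosome labels sort numerically when possible, then lexically.
    """
    if records.empty:
        return records.copy()
    sig = records[records["p"] < alpha].copy()

    def chrom_key(c):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    sig["_ck"] = sig["chrom"].map(chrom_key)
    sig = sig.sort_values(["_ck", "pos"]).drop(columns="_ck")
    return sig.reset_index(drop=True)
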