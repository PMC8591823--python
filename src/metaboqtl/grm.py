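"""Genomic relationship matrix from SNP dosages.

Uses the allele-frequency-standardized form (Yang et al. / second VanRaden
formulation): with dosage x_ij for SNP i in animal j and observed alternate
allele frequency p_i,

    G_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the m polymorphic SNPs.  Missing dosages are mean-imputed per SNP, which
zeroes their centered contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .genotypes import GenotypeMatrix


@dataclass
class GRM:
    matrix: np.ndarray = field(repr=False)
    sample_ids: list[str]
    n_snps: int

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise DataError("GRM shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise DataError("GRM must be symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors, cached after first call."""
        if not hasattr(self, "_eig"):
            vals, vecs = np.linalg.eigh(self.matrix)
            self._eig = (vals, vecs)
        return self._eig


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """Allele-frequency-standardized GRM over all polymorphic SNPs."""
    X = geno.mean_imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DataError("all SNPs monomorphic: GRM undefined")
    X = X[:, poly]
    p = p[poly]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = Z.shape[1]
    G = (Z @ Z.T) / m
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GRM(matrix=G, sample_ids=list(geno.samples), n_snps=m)


def write_grm_tsv(grm: GRM, ids_path, values_path) -> None:
    """Plain-text GRM: one id per line, and a lower-triangle triplet table."""
    pd.Series(grm.sample_ids).to_csv(ids_path, index=False, header=False)
    i, j = np.tril_indices(grm.n_samples)
    pd.DataFrame({"i": i + 1, "j": j + 1, "value": grm.matrix[i, j]}).to_csv(
        values_path, sep="\t", index=False
    )


def read_grm_tsv(ids_path, values_path, n_snps: int = 0) -> GRM:
    ids = pd.read_csv(ids_path, header=None)[0].astype(str).tolist()
    tri = pd.read_csv(values_path, sep="\t")
    n = len(ids)
    G = np.zeros((n, n))
    i = tri["i"].to_numpy() - 1
    j = tri["j"].to_numpy() - 1
    G[i, j] = tri["value"].to_numpy()
    G[j, i] = tri["value"].to_numpy()
    return GRM(matrix=G, sample_ids=ids, n_snps=n_snps)
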