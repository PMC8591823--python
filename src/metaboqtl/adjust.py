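"""Pre-adjustment of traits and metabolites for systematic effects.

Each phenotype is regressed on the recorded systematic effects -- animal type,
birth year, herd, feedlot pen (categorical), age at test (numeric) and genomic
breed-composition fractions -- and the residuals carry forward to every
association stage.  Residuals farther than three sample standard deviations
from the residual mean are masked as outliers (single pass, no re-fit).

Breed fractions sum to one, so only K-1 of the K fractions enter the design;
dropping the last column avoids structural collinearity with the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

CATEGORICAL_COVARIATES = ["animal_type", "birth_year", "herd", "pen"]
NUMERIC_COVARIATES = ["age"]


def breed_columns(covars: pd.DataFrame) -> list[str]:
    return sorted(c for c in covars.columns if c.startswith("breed"))


def validate_covariates(covars: pd.DataFrame) -> None:
    needed = set(CATEGORICAL_COVARIATES) | set(NUMERIC_COVARIATES)
    missing = needed - set(covars.columns)
    if missing:
        raise DataError(f"covariate table lacks columns: {sorted(missing)}")
    breeds = breed_columns(covars)
    if breeds:
        frac = covars[breeds].to_numpy(dtype=float)
        if (frac < -1e-9).any() or (frac > 1 + 1e-9).any():
            raise DataError("breed fractions must lie in [0, 1]")
        if not np.allclose(frac.sum(axis=1), 1.0, atol=1e-6):
            raise DataError("breed fractions must sum to 1 per animal")


def build_design(covars: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded fixed-effect design with intercept.

    Categorical factors are reference-coded (first level dropped); breed
    fractions enter as the first K-1 columns.
    """
    validate_covariates(covars)
    parts = [pd.Series(1.0, index=covars.index, name="intercept")]
    for col in CATEGORICAL_COVARIATES:
        dummies = pd.get_dummies(
            covars[col].astype("category"), prefix=col, drop_first=True, dtype=float
        )
        parts.append(dummies)
    for col in NUMERIC_COVARIATES:
        parts.append(covars[col].astype(float))
    breeds = breed_columns(covars)
    if breeds:
        parts.append(covars[breeds[:-1]].astype(float))
    return pd.concat(parts, axis=1)


@dataclass
class AdjustedPhenotype:
    """Residuals after systematic-effect adjustment, with outlier mask.

    ``residuals`` has one entry per input animal (NaN where the input value
    was missing); ``keep`` is False for residual outliers and missing values.
    """

    residuals: np.ndarray
    keep: np.ndarray
    coefficients: pd.Series = field(repr=False)
    r_squared: float = float("nan")

    @property
    def retained(self) -> np.ndarray:
        return self.residuals[self.keep]


def flag_outliers(residuals, k: float = 3.0) -> np.ndarray:
    """Mask residuals more than ``k`` sample SDs from the residual mean.

    One pass: the mean and SD include the outliers themselves.  Returns a
    boolean array, True where the value is an outlier.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise DataError("need >= 3 residuals to flag outliers")
    sd = r.std(ddof=1)
    if sd == 0:
        warnings.warn("zero residual SD: no outliers flagged", stacklevel=2)
        return np.zeros(r.size, dtype=bool)
    return np.abs(r - r.mean()) > k * sd


def adjust_phenotype(
    values, covars: pd.DataFrame, outlier_sd: float = 3.0
) -> AdjustedPhenotype:
    """OLS adjustment of one phenotype for the systematic effects.

    Missing phenotype values are excluded from the fit and masked in the
    output; covariates must be complete for animals with a phenotype.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size != len(covars):
        raise DataError("phenotype and covariate table lengths differ")
    X = build_design(covars)
    obs = ~np.isnan(y)
    if X.loc[obs].isna().any().any():
        raise DataError("missing covariates for animals with phenotype records")
    Xo = X.loc[obs].to_numpy(dtype=float)
    if obs.sum() <= Xo.shape[1]:
        raise DataError(
            f"{int(obs.sum())} observations cannot identify {Xo.shape[1]} coefficients"
        )
    rank = np.linalg.matrix_rank(Xo)
    if rank < Xo.shape[1]:
        aliased = _aliased_columns(Xo, X.columns)
        raise DataError(f"rank-deficient adjustment design; aliased columns: {aliased}")

    beta, *_ = np.linalg.lstsq(Xo, y[obs], rcond=None)
    resid = np.full(y.size, np.nan)
    resid[obs] = y[obs] - Xo @ beta
    tss = np.sum((y[obs] - y[obs].mean()) ** 2)
    rss = np.sum(resid[obs] ** 2)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    keep = obs.copy()
    keep[obs] &= ~flag_outliers(resid[obs], k=outlier_sd)
    return AdjustedPhenotype(
        residuals=resid,
        keep=keep,
        coefficients=pd.Series(beta, index=X.columns),
        r_squared=float(r2),
    )


def _aliased_columns(X: np.ndarray, names) -> list[str]:
    """Columns that add no rank when appended left to right (QR sweep)."""
    aliased, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            aliased.append(str(name))
    return aliased


def adjust_table(
    table: pd.DataFrame, covars: pd.DataFrame, outlier_sd: float = 3.0
) -> dict[str, AdjustedPhenotype]:
    """Adjust every column of a phenotype table independently."""
    return {
        col: adjust_phenotype(table[col].to_numpy(dtype=float), covars, outlier_sd)
        for col in table.columns
    }
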