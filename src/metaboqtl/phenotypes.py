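"""Derivation of the four feed-efficiency traits from raw feedlot records.

Traits (all per animal):

* standardized DMI -- mean daily dry-matter intake scaled by the ratio of the
  diet's energy content to a reference energy content (kg/day);
* ADG -- average daily gain, the slope of an ordinary least-squares fit of
  serial body weight on day on test (kg/day);
* initial BW -- the intercept of that fit (kg);
* midpoint BW -- initial BW + ADG * days_on_test / 2 (kg);
* MWT -- metabolic body weight, midpoint BW ** 0.75 (kg);
* RFI -- residual feed intake, the residual of standardized DMI regressed on
  ADG and MWT (kg DMI/day); lower is more feed-efficient.

By construction RFI has mean zero and zero sample covariance with ADG and
MWT (OLS residual orthogonality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


def fit_growth_curve(days, weights) -> tuple[float, float]:
    """OLS of body weight on day on test: returns (initial BW, ADG).

    Requires at least three time points with non-zero day variance.
    """
    days = np.asarray(days, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if days.ndim != 1 or days.shape != weights.shape:
        raise DataError("days and weights must be equal-length 1-D arrays")
    if days.size < 3:
        raise DataError(f"need >= 3 serial weights, got {days.size}")
    if np.ptp(days) == 0 or np.var(days) == 0:
        raise DataError("zero variance in measurement days: singular design")
    slope, intercept = np.polyfit(days, weights, 1)
    return float(intercept), float(slope)


def compute_mwt(initial_bw: float, adg: float, days_on_test: float) -> tuple[float, float]:
    """Midpoint body weight and metabolic body weight (midpoint ** 0.75)."""
    midpoint = initial_bw + adg * days_on_test / 2.0
    if not np.isfinite(midpoint) or midpoint <= 0:
        raise DataError(f"non-positive midpoint body weight: {midpoint}")
    return float(midpoint), float(midpoint**0.75)


def standardize_dmi(dmi_raw, diet_energy: float, reference_energy: float):
    """Scale raw DMI by diet energy relative to a reference diet.

    Elementwise: ``dmi_raw * diet_energy / reference_energy``.
    """
    if diet_energy <= 0 or reference_energy <= 0:
        raise DataError("diet and reference energy contents must be positive")
    return np.asarray(dmi_raw, dtype=float) * (diet_energy / reference_energy)


@dataclass
class RFIFit:
    """RFI vector plus the expected-DMI regression it came from."""

    rfi: np.ndarray
    coefficients: pd.DataFrame  # one row per group: intercept, b_adg, b_mwt


def compute_rfi(dmi_std, adg, mwt, groups=None) -> RFIFit:
    """Residual feed intake: residuals of DMI on intercept + ADG + MWT.

    With ``groups`` given, the expected-DMI regression is fitted within each
    group separately (e.g. per feedlot-test group); default is one pooled fit.
    """
    dmi_std = np.asarray(dmi_std, dtype=float)
    adg = np.asarray(adg, dtype=float)
    mwt = np.asarray(mwt, dtype=float)
    if not (dmi_std.shape == adg.shape == mwt.shape):
        raise DataError("DMI, ADG and MWT vectors must have equal length")
    n = dmi_std.size
    if n < 4:
        raise DataError(f"need >= 4 animals to fit expected DMI, got {n}")

    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    rfi = np.empty(n)
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        X = np.column_stack([np.ones(sel.sum()), adg[sel], mwt[sel]])
        if np.linalg.matrix_rank(X) < 3:
            raise DataError(f"collinear ADG/MWT design in group {g!r}")
        beta, *_ = np.linalg.lstsq(X, dmi_std[sel], rcond=None)
        rfi[sel] = dmi_std[sel] - X @ beta
        rows.append({"group": g, "intercept": beta[0], "b_adg": beta[1], "b_mwt": beta[2]})
    return RFIFit(rfi=rfi, coefficients=pd.DataFrame(rows))


def derive_feed_phenotypes(
    serial_weights: pd.DataFrame,
    intake: pd.DataFrame,
    days_on_test: float | None = None,
    diet_energy: float = 1.0,
    reference_energy: float = 1.0,
    groups=None,
) -> pd.DataFrame:
    """Full trait derivation from long-format records.

    Parameters
    ----------
    serial_weights
        Columns ``animal, day, weight``; >= 3 rows per animal.
    intake
        Columns ``animal, dmi`` (mean daily dry-matter intake, kg/day) or
        ``animal, day, dmi`` which is averaged per animal first.
    days_on_test
        Test length used for the midpoint; default: per-animal last weigh day.

    Returns one row per animal: ``dmi_std, adg, initial_bw, midpoint_bw,
    mwt, rfi``.
    """
    required = {"animal", "day", "weight"}
    if not required.issubset(serial_weights.columns):
        raise DataError(f"serial weights need columns {sorted(required)}")
    if "day" in intake.columns:
        intake = intake.groupby("animal", as_index=False)["dmi"].mean()

    rows = []
    for animal, sub in serial_weights.groupby("animal", sort=False):
        sub = sub.sort_values("day")
        if sub["day"].duplicated().any():
            raise DataError(f"duplicate weigh days for animal {animal!r}")
        init_bw, adg = fit_growth_curve(sub["day"], sub["weight"])
        dot = days_on_test if days_on_test is not None else float(sub["day"].max())
        midpoint, mwt = compute_mwt(init_bw, adg, dot)
        rows.append(
            {
                "animal": animal,
                "initial_bw": init_bw,
                "adg": adg,
                "midpoint_bw": midpoint,
                "mwt": mwt,
            }
        )
    pheno = pd.DataFrame(rows).merge(intake, on="animal", how="inner")
    if len(pheno) < len(rows):
        raise DataError("some animals have weights but no intake record")
    pheno["dmi_std"] = standardize_dmi(pheno["dmi"], diet_energy, reference_energy)
    fit = compute_rfi(pheno["dmi_std"], pheno["adg"], pheno["mwt"], groups=groups)
    pheno["rfi"] = fit.rfi
    return pheno.drop(columns=["dmi"])
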