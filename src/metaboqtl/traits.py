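"""Trait-metabolite regression screen and variance explained.

Each adjusted feed-efficiency trait is regressed on each adjusted metabolite
(simple OLS); metabolites with a two-sided p-value below 0.1 are carried
forward.  The proportion of trait phenotypic variance explained by the
selected metabolites (V_m/V_P, in percent) is the R-squared of the joint
multiple regression of the trait on all of them; a per-metabolite univariate
R-squared column is also reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import AdjustedPhenotype
from .errors import DataError


def regress_trait_on_metabolite(trait_adj, metab_adj) -> tuple[float, float]:
    """Simple OLS of trait on metabolite: returns (slope b, two-sided p)."""
    y = np.asarray(trait_adj, dtype=float)
    x = np.asarray(metab_adj, dtype=float)
    if y.shape != x.shape:
        raise DataError("trait and metabolite vectors must have equal length")
    ok = ~(np.isnan(y) | np.isnan(x))
    if ok.sum() < 4:
        raise DataError(f"need >= 4 paired observations, got {int(ok.sum())}")
    x, y = x[ok], y[ok]
    if np.var(x) == 0:
        raise DataError("zero metabolite variance: slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def association_table(
    traits: dict[str, AdjustedPhenotype],
    metabolites: dict[str, AdjustedPhenotype],
) -> pd.DataFrame:
    """All trait x metabolite regressions on jointly retained animals."""
    rows = []
    for tname, t in traits.items():
        for mname, m in metabolites.items():
            keep = t.keep & m.keep
            b, p = regress_trait_on_metabolite(t.residuals[keep], m.residuals[keep])
            rows.append(
                {"trait": tname, "metabolite": mname, "b": b, "p": p, "n": int(keep.sum())}
            )
    return pd.DataFrame(rows)


def select_associated_metabolites(
    results: pd.DataFrame, alpha: float = 0.1
) -> dict[str, list[str]]:
    """Metabolites with p strictly below ``alpha``, per trait.

    Sorted ascending by p; ties broken by metabolite name for stability.
    """
    selected: dict[str, list[str]] = {}
    if results.empty:
        return selected
    for trait, sub in results.groupby("trait", sort=False):
        hits = sub[sub["p"] < alpha].sort_values(["p", "metabolite"])
        selected[trait] = hits["metabolite"].tolist()
    return selected


def joint_variance_explained(
    trait_adj, selected: dict[str, np.ndarray] | pd.DataFrame
) -> float:
    """V_m/V_P in percent: 100 x R^2 of the trait on all selected metabolites.

    Collinear metabolite columns are dropped (with a warning) before the fit.
    """
    if isinstance(selected, dict):
        selected = pd.DataFrame(selected)
    if selected.shape[1] == 0:
        raise DataError("no selected metabolites: V_m/V_P undefined")
    y = np.asarray(trait_adj, dtype=float)
    M = selected.to_numpy(dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(M).any(axis=1)
    y, M = y[ok], M[ok]

    keep_cols, kept = [], np.ones((len(y), 1))
    for j, name in enumerate(selected.columns):
        cand = np.column_stack([kept, M[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
            keep_cols.append(name)
        else:
            warnings.warn(f"dropping collinear metabolite {name!r}", stacklevel=2)
    X = kept
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise DataError("zero trait variance")
    return float(100.0 * (1.0 - resid @ resid / tss))


def trait_metabolite_screen(
    traits: dict[str, AdjustedPhenotype],
    metabolites: dict[str, AdjustedPhenotype],
    alpha: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, float]]:
    """Full screen: regression table, per-trait selection, per-trait V_m/V_P.

    The joint R^2 per trait is computed on animals retained for the trait and
    every selected metabolite simultaneously.
    """
    results = association_table(traits, metabolites)
    # univariate R^2 (fraction of trait variance, percent) for information
    r2 = []
    for _, row in results.iterrows():
        t, m = traits[row["trait"]], metabolites[row["metabolite"]]
        keep = t.keep & m.keep
        r = np.corrcoef(t.residuals[keep], m.residuals[keep])[0, 1]
        r2.append(100.0 * r * r)
    results["vm_vp_single_pct"] = r2

    selected = select_associated_metabolites(results, alpha=alpha)
    joint: dict[str, float] = {}
    for trait, metab_names in selected.items():
        if not metab_names:
            warnings.warn(f"no metabolites selected for trait {trait!r}", stacklevel=2)
            continue
        t = traits[trait]
        keep = t.keep.copy()
        for m in metab_names:
            keep &= metabolites[m].keep
        block = pd.DataFrame(
            {m: metabolites[m].residuals[keep] for m in metab_names}
        )
        joint[trait] = joint_variance_explained(t.residuals[keep], block)
    return results, selected, joint
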