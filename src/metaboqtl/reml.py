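"""REML variance components for the single-GRM animal model.

Model: y = mu * 1 + a + e with a ~ N(0, G sigma_a^2), e ~ N(0, I sigma_e^2).
Estimation is average-information (AI) REML with EM fallback steps, run in
the eigenbasis of G so each iteration is O(n) after one O(n^3)
eigendecomposition.  A step is accepted only if the restricted log-likelihood
does not decrease; an AI step that would decrease it, or push a component
negative, is replaced by an EM step.  Components are floored at
1e-8 x var(y).  Convergence: |delta logL| < 1e-6, at most 100 iterations.

Standard errors come from the inverse AI matrix at the optimum; the SE of
h^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2) by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, DataError
from .grm import GRM


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    se_a: float
    se_e: float
    h2: float
    se_h2: float
    loglik: float
    n_iter: int
    converged: bool


def _profile(theta, d, x, y):
    """Restricted log-likelihood pieces in the eigenbasis.

    Returns (logL, w, Py, xtvx) where w are the inverse eigen-variances,
    Py the projected data and xtvx = x' V^-1 x for the intercept column.
    """
    v = theta[0] * d + theta[1]
    if (v <= 0).any():
        return -np.inf, None, None, None
    w = 1.0 / v
    xtvx = np.sum(w * x * x)
    beta = np.sum(w * x * y) / xtvx
    r = y - x * beta
    ypy = np.sum(w * r * r)
    logl = -0.5 * (np.sum(np.log(v)) + np.log(xtvx) + ypy)
    return logl, w, w * r, xtvx


def _score_ai(theta, d, x, y, w, Py, xtvx):
    """REML score vector and average-information matrix for (s2_a, s2_e)."""
    # tr(P A) = tr(V^-1 A) - x'V^-1 A V^-1 x / xtvx, A in {diag(d), I}
    wx = w * x
    tr_pa = np.sum(w * d) - np.sum(wx * d * wx) / xtvx
    tr_pe = np.sum(w) - np.sum(wx * wx) / xtvx

    def apply_p(t):
        return w * t - wx * (np.sum(wx * t) / xtvx)

    a_py = d * Py
    p_a_py = apply_p(a_py)
    p_e_py = apply_p(Py)
    score = np.array(
        [
            -0.5 * (tr_pa - np.sum(a_py * Py)),  # y'P A P y = (A Py)' Py
            -0.5 * (tr_pe - np.sum(Py * Py)),
        ]
    )
    ai = 0.5 * np.array(
        [
            [np.sum(a_py * p_a_py), np.sum(a_py * p_e_py)],
            [np.sum(Py * p_a_py), np.sum(Py * p_e_py)],
        ]
    )
    return score, ai


def reml_variance_components(
    y,
    grm: GRM,
    max_iter: int = 100,
    tol: float = 1e-6,
    verbose: bool = False,
) -> VarianceComponents:
    """AI-REML fit of (sigma_a^2, sigma_e^2) for one phenotype vector.

    ``y`` must be ordered like ``grm.sample_ids``.  Raises ConvergenceError
    (carrying the last iterate) if the likelihood has not stabilised after
    ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float)
    n = grm.n_samples
    if y.shape != (n,):
        raise DataError(f"phenotype length {y.shape} does not match GRM size {n}")
    if np.isnan(y).any():
        raise DataError("phenotype contains missing values; drop them first")

    d, U = grm.eigendecompose()
    if np.ptp(d) < 1e-8:
        warnings.warn(
            "GRM eigenvalues are (near-)constant: sigma_a^2 and sigma_e^2 are "
            "not separately identifiable",
            stacklevel=2,
        )
    d = np.maximum(d, 0.0)  # clip tiny negative eigenvalues
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    vary = float(np.var(y, ddof=1))
    if vary == 0:
        raise DataError("zero phenotypic variance")
    floor = 1e-8 * vary
    theta = np.array([0.5 * vary, 0.5 * vary])
    logl, w, Py, xtvx = _profile(theta, d, xt, yt)
    n_r = n - 1  # residual dof with one fixed effect

    converged = False
    ai = np.eye(2)
    for it in range(1, max_iter + 1):
        score, ai = _score_ai(theta, d, xt, yt, w, Py, xtvx)
        # AI proposal, then EM fallback, then step halving toward the
        # current iterate until the restricted likelihood does not drop
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = None
        proposal = None
        if step is not None:
            # clamp at the floor so boundary solutions are reached directly;
            # halve the step while it would decrease the likelihood
            frac = 1.0
            for _ in range(8):
                cand = np.maximum(theta + frac * step, floor)
                cand_logl, *rest = _profile(cand, d, xt, yt)
                if cand_logl >= logl - 1e-10:
                    proposal = (cand, cand_logl, rest)
                    break
                frac /= 2.0
        if proposal is None:
            # EM-type update: s2_new = s2 + s2^2 (y'P A P y - tr(P A)) / n_r
            ypapy = np.array([np.sum((d * Py) * Py), np.sum(Py * Py)])
            tr_pa = score * (-2.0)  # score = -0.5 (tr - ypapy)
            tr = ypapy + tr_pa
            cand = theta + theta**2 * (ypapy - tr) / n_r
            cand = np.maximum(cand, floor)
            cand_logl, *rest = _profile(cand, d, xt, yt)
            shrink = 0
            while cand_logl < logl - 1e-10 and shrink < 30:
                cand = (cand + theta) / 2.0
                cand_logl, *rest = _profile(cand, d, xt, yt)
                shrink += 1
            proposal = (cand, cand_logl, rest)

        new_theta, new_logl, (w, Py, xtvx) = proposal
        delta = new_logl - logl
        theta, logl = new_theta, new_logl
        if verbose:
            print(f"iter {it}: logL={logl:.6f} s2_a={theta[0]:.6g} s2_e={theta[1]:.6g}")
        if abs(delta) < tol:
            converged = True
            break

    s2a, s2e = theta
    total = s2a + s2e
    h2 = s2a / total
    # SEs from the inverse AI matrix; delta method for h2
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
        warnings.warn("singular AI matrix: SEs from pseudo-inverse", stacklevel=2)
    se_a, se_e = np.sqrt(np.maximum(np.diag(cov), 0.0))
    grad = np.array([s2e, -s2a]) / total**2
    se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    vc = VarianceComponents(
        sigma2_a=float(s2a),
        sigma2_e=float(s2e),
        se_a=float(se_a),
        se_e=float(se_e),
        h2=float(h2),
        se_h2=se_h2,
        loglik=float(logl),
        n_iter=it,
        converged=converged,
    )
    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", last_iterate=vc
        )
    return vc
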