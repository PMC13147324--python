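"""Regression of the drug-solvent binary interaction parameter k_ij.

The headline use case is the single-point fit: one measured solubility
(T, x) fixes k_ij by a one-dimensional root find on the log-solubility
residual.  A multi-point least-squares variant is provided for comparison
with conventional fitting that consumes whole solubility curves.

Residuals live in ln x: solubilities span many orders of magnitude and
multiplicative error is the empirical norm, so the log scale makes the
objective scale-free.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .constants import P_REF
from .parameters import MeltingProps, PureComponentParams
from .sle import SolubilityPoint, solve_solubility

logger = logging.getLogger(__name__)

BRACKET_INITIAL = (-0.2, 0.2)
BRACKET_MAX = (-0.5, 0.5)
_EXPAND_STEP = 0.1


@dataclass(frozen=True)
class FitReport:
    """Outcome of a k_ij regression.

    For the single-point root find, ``converged`` implies
    ``residual_lnx < 1e-8``.  For the least-squares variant on noisy data
    ``residual_lnx`` is the RMS ln-residual at the optimum and ``converged``
    reflects the scalar minimisation.
    """

    k_ij: float
    residual_lnx: float
    bracket: tuple[float, float]
    iterations: int
    converged: bool


def _forward_lnx(api, mp, solvent, T, k, P):
    K = np.array([[0.0, k], [k, 0.0]])
    res = solve_solubility(api, mp, [solvent], [1.0], K, T, P=P)
    return math.log(res.x_API)


def fit_kij_single_point(
    api: PureComponentParams,
    mp: MeltingProps,
    solvent: PureComponentParams,
    T_exp: float,
    x_exp: float,
    P: float = P_REF,
    tol: float = 1e-8,
) -> FitReport:
    """Fit k_ij so the model reproduces one measured solubility point.

    Solves f(k) = ln x_calc(k) - ln x_exp = 0, bracketed in [-0.2, 0.2] and
    expanded stepwise to [-0.5, 0.5] if needed.  If no sign change exists in
    the maximal bracket a non-converged report with the best k found is
    returned (no exception).
    """
    if not 0.0 < x_exp < 1.0:
        raise ValueError("x_exp must be in (0, 1)")
    ln_x_exp = math.log(x_exp)
    nfev = 0

    def f(k: float) -> float:
        nonlocal nfev
        nfev += 1
        return _forward_lnx(api, mp, solvent, T_exp, k, P) - ln_x_exp

    lo, hi = BRACKET_INITIAL
    flo, fhi = f(lo), f(hi)
    evaluated = [(lo, flo), (hi, fhi)]
    while flo * fhi > 0 and (lo > BRACKET_MAX[0] or hi < BRACKET_MAX[1]):
        lo = max(lo - _EXPAND_STEP, BRACKET_MAX[0])
        hi = min(hi + _EXPAND_STEP, BRACKET_MAX[1])
        flo, fhi = f(lo), f(hi)
        evaluated += [(lo, flo), (hi, fhi)]
    if flo * fhi > 0:
        k_best, f_best = min(evaluated, key=lambda t: abs(t[1]))
        logger.warning(
            "no sign change of the solubility residual in k bracket %s; "
            "best |residual| %.3g at k=%.3g",
            (lo, hi),
            abs(f_best),
            k_best,
        )
        return FitReport(
            k_ij=k_best,
            residual_lnx=abs(f_best),
            bracket=(lo, hi),
            iterations=nfev,
            converged=False,
        )

    root = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    resid = abs(f(root))
    return FitReport(
        k_ij=float(root),
        residual_lnx=resid,
        bracket=(lo, hi),
        iterations=nfev,
        converged=resid < tol,
    )


def fit_kij_least_squares(
    api: PureComponentParams,
    mp: MeltingProps,
    solvent: PureComponentParams,
    points: Sequence[SolubilityPoint],
    P: float = P_REF,
) -> FitReport:
    """Least-squares k_ij over several points, minimising sum (ln x residual)^2.

    A single point reduces exactly to :func:`fit_kij_single_point`.  All
    points at one temperature are degenerate (the objective still has a
    minimum; a warning is emitted).
    """
    points = list(points)
    if not points:
        raise ValueError("at least one point required")
    if len(points) == 1:
        return fit_kij_single_point(api, mp, solvent, points[0].T, points[0].x, P=P)
    temps = {p.T for p in points}
    if len(temps) == 1:
        warnings.warn(
            "all points at a single temperature: least-squares fit is "
            "degenerate with the single-point fit",
            stacklevel=2,
        )
    ln_exp = np.array([math.log(p.x) for p in points])
    nfev = 0

    def sse(k: float) -> float:
        nonlocal nfev
        nfev += 1
        ln_calc = np.array(
            [_forward_lnx(api, mp, solvent, p.T, k, P) for p in points]
        )
        return float(np.sum((ln_calc - ln_exp) ** 2))

    lo, hi = BRACKET_INITIAL
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    # expand if the optimum sits on the bracket edge
    while res.success and (
        abs(res.x - lo) < 1e-6 or abs(res.x - hi) < 1e-6
    ) and (lo > BRACKET_MAX[0] or hi < BRACKET_MAX[1]):
        lo = max(lo - _EXPAND_STEP, BRACKET_MAX[0])
        hi = min(hi + _EXPAND_STEP, BRACKET_MAX[1])
        res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    rms = math.sqrt(res.fun / len(points))
    return FitReport(
        k_ij=float(res.x),
        residual_lnx=rms,
        bracket=(lo, hi),
        iterations=nfev,
        converged=bool(res.success),
    )


__all__ = ["FitReport", "fit_kij_single_point", "fit_kij_least_squares",
           "BRACKET_INITIAL", "BRACKET_MAX"]
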