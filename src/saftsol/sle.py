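"""Solid-liquid equilibrium: saturation mole fraction of a crystalline drug.

Equating the chemical potential of the pure crystal with that of the drug in
the saturated solution gives

    x_API * gamma_API(x, T) = exp[ -dH_SL/(R T) * (T_SL - T)/T_SL
                                   - dCp_SL/R * (ln(T_SL/T) + (T - T_SL)/T) ]

with the hypothetical subcooled liquid as reference state.  The right-hand
side depends only on the melting properties of the polymorph; all solvent
and mixture effects enter through the PC-SAFT activity coefficient
gamma_API.  The equation is solved by a damped fixed point on ln x with a
bisection fallback.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import P_REF, R
from .parameters import KijStore, MeltingProps, PureComponentParams
from .pcsaft import LiquidGammaTracker, PcSaftError, kij_matrix

logger = logging.getLogger(__name__)

_LN_X_CAP = -1e-12  # ln x is kept strictly below 0 during iteration


@dataclass(frozen=True)
class SolubilityPoint:
    """One solubility record: drug, solvent system, temperature, mole fraction.

    ``solvent_ids`` is the ordered tuple of solvent ids; for binary blends
    ``w1`` is the API-free weight fraction of the first-named solvent.
    """

    api_id: str
    solvent_ids: tuple[str, ...]
    T: float
    x: float
    w1: float | None = None
    source: str = "experimental"


@dataclass(frozen=True)
class SolubilityResult:
    """Converged saturation state of the drug in one solvent system."""

    x_API: float
    gamma_API: float
    T: float
    iterations: int
    residual: float
    converged: bool = True
    fully_miscible: bool = False
    S_gL: float | None = None


class SolubilityIterationError(RuntimeError):
    """Fixed point and bisection fallback both failed; carries the trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _ln_sle_rhs(mp: MeltingProps, T: float) -> float:
    """ln of the ideal (gamma = 1) saturation mole fraction, uncapped."""
    if T <= 0:
        raise ValueError("T must be > 0")
    t1 = -mp.dH_SL / (R * T) * (mp.T_SL - T) / mp.T_SL
    t2 = -mp.dCp_SL / R * (math.log(mp.T_SL / T) + (T - mp.T_SL) / T)
    return t1 + t2


def ideal_solubility(mp: MeltingProps, T: float) -> float:
    """Ideal (gamma = 1) saturation mole fraction at temperature T.

    At T = T_SL both exponent terms vanish and the result is exactly 1.
    Above the melting point the expression can exceed 1; the return value is
    then capped at 1 with a warning (the drug is a liquid there).
    """
    val = math.exp(_ln_sle_rhs(mp, T))
    if val > 1.0:
        warnings.warn(
            f"ideal solubility expression {val:.4g} > 1 at T={T} K; capped at 1",
            stacklevel=2,
        )
        return 1.0
    return val


def _compose(x_api: float, ratio: np.ndarray) -> np.ndarray:
    """Full mole-fraction vector [x_API, (1-x_API)*ratio...]."""
    return np.concatenate([[x_api], (1.0 - x_api) * ratio])


def solve_solubility(
    api: PureComponentParams,
    mp: MeltingProps,
    solvents: Sequence[PureComponentParams],
    solvent_ratio: Sequence[float],
    kij_store: KijStore | np.ndarray | None,
    T: float,
    P: float = P_REF,
    tol: float = 1e-10,
    max_iter: int = 200,
    damping: float | None = None,
    compute_gL: bool = False,
    rho_solvent_gL: float | None = None,
) -> SolubilityResult:
    """Saturation mole fraction of the drug in a (mixed) solvent at T.

    The solvent mole fractions are rescaled to ``(1 - x_API) * ratio`` at
    every step, so the API-free solvent ratio is held fixed.  Iteration is a
    damped fixed point on ln x starting from the ideal solubility; if it
    oscillates without converging, bisection on the equilibrium residual
    takes over.  A saturation composition driven to x -> 1 is reported with
    ``fully_miscible=True`` rather than as an error.

    With ``compute_gL=True`` the result also carries the solubility in g/L,
    using the PC-SAFT density of the API-free solvent (blend) at (T, P)
    unless an experimental ``rho_solvent_gL`` is supplied.
    """
    ratio = np.asarray(solvent_ratio, dtype=float)
    if ratio.ndim != 1 or len(ratio) != len(solvents):
        raise ValueError("solvent_ratio length must match number of solvents")
    if np.any(ratio < 0) or abs(ratio.sum() - 1.0) > 1e-10:
        raise ValueError("solvent_ratio must be >= 0 and sum to 1")

    components = [api, *solvents]
    if isinstance(kij_store, np.ndarray):
        K = kij_store
    else:
        K = kij_matrix(components, kij_store)
    tracker = LiquidGammaTracker(components, K, index=0, P=P)

    ln_rhs = _ln_sle_rhs(mp, T)
    ln_x = min(ln_rhs, math.log(0.5))
    trace: list[float] = []
    hit_cap = False
    ln_gamma = 0.0
    residual = math.inf
    # equilibrium residual g(ln x) = ln x + ln gamma(x) - ln rhs; the plain
    # fixed point is a Newton step with unit slope, which crawls when
    # ln gamma depends strongly on ln x.  A secant estimate of the true
    # slope 1 + d ln gamma/d ln x accelerates it; damped fixed-point steps
    # are the safeguard whenever the secant slope is unusable.
    prev_lnx: float | None = None
    prev_g: float | None = None
    lam = 0.5 if damping is None else damping
    for it in range(1, max_iter + 1):
        x = math.exp(ln_x)
        ln_gamma = tracker.ln_gamma(_compose(x, ratio), T)
        g_val = ln_x + ln_gamma - ln_rhs
        if ln_rhs - ln_gamma >= 0.0:
            hit_cap = True
        step = None
        if damping is None and prev_lnx is not None and prev_lnx != ln_x:
            slope = (g_val - prev_g) / (ln_x - prev_lnx)
            if slope > 0.05:
                step = -g_val / slope
        if step is None:
            step = -lam * g_val
        if abs(step) > 10.0:
            step = math.copysign(10.0, step)
        prev_lnx, prev_g = ln_x, g_val
        ln_x_new = min(ln_x + step, _LN_X_CAP)
        residual = abs(ln_x_new - ln_x)
        trace.append(ln_x_new)
        ln_x = ln_x_new
        if residual < tol:
            x = math.exp(ln_x)
            miscible = hit_cap and ln_x > math.log(0.99)
            result = SolubilityResult(
                x_API=x,
                gamma_API=math.exp(ln_gamma),
                T=T,
                iterations=it,
                residual=residual,
                converged=True,
                fully_miscible=miscible,
            )
            if compute_gL:
                result = _attach_gL(result, api, solvents, ratio, tracker, T, rho_solvent_gL)
            return result

    # fallback: bisection on g(ln x) = ln x + ln gamma(x) - ln_rhs
    logger.info("fixed point did not converge at T=%.2f K; bisection fallback", T)

    def g(lnx: float) -> float:
        return lnx + tracker.ln_gamma(_compose(math.exp(lnx), ratio), T) - ln_rhs

    lo, hi = -60.0, _LN_X_CAP
    glo, ghi = g(lo), g(hi)
    if glo > 0 or ghi < 0:
        if ghi < 0:
            # equilibrium pushes x past 1: fully miscible at this T
            return SolubilityResult(
                x_API=math.exp(_LN_X_CAP),
                gamma_API=math.exp(tracker.ln_gamma(_compose(math.exp(_LN_X_CAP), ratio), T)),
                T=T,
                iterations=max_iter,
                residual=abs(ghi),
                converged=True,
                fully_miscible=True,
            )
        raise SolubilityIterationError(
            f"no equilibrium root bracketed at T={T} K", trace
        )
    for it2 in range(200):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if gm > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    ln_x = 0.5 * (lo + hi)
    x = math.exp(ln_x)
    ln_gamma = tracker.ln_gamma(_compose(x, ratio), T)
    result = SolubilityResult(
        x_API=x,
        gamma_API=math.exp(ln_gamma),
        T=T,
        iterations=max_iter + it2 + 1,
        residual=hi - lo,
        converged=(hi - lo) < tol,
        fully_miscible=False,
    )
    if compute_gL:
        result = _attach_gL(result, api, solvents, ratio, tracker, T, rho_solvent_gL)
    return result


def _attach_gL(result, api, solvents, ratio, tracker, T, rho_solvent_gL):
    Mw_solvent = float(np.dot(ratio, [s.Mw for s in solvents]))
    if rho_solvent_gL is None:
        solvent_tracker = LiquidGammaTracker(list(solvents), None, index=0, P=tracker.P)
        rho_mol = solvent_tracker.liquid_density(ratio, T)
        rho_solvent_gL = rho_mol * Mw_solvent / 1000.0  # mol/m^3 * g/mol -> g/L
    S = to_g_per_L(result.x_API, api.Mw, Mw_solvent, rho_solvent_gL)
    from dataclasses import replace

    return replace(result, S_gL=S)


def to_g_per_L(
    x_API: float, Mw_API: float, Mw_solvent: float, rho_solvent: float
) -> float:
    """Convert saturation mole fraction to solubility in g/L.

    S = rho_solvent[g/L] * x/(1-x) * M_API/M_solvent: x/(1-x) is moles of
    drug per mole of solvent, the molar-mass ratio turns it into grams of
    drug per gram of solvent, and the solvent mass density per litre of
    solution completes the conversion.  x = 1 returns +inf with a warning
    (fully miscible; no finite g/L value exists).
    """
    if not 0.0 <= x_API <= 1.0:
        raise ValueError("x_API must be in [0, 1]")
    if x_API == 1.0:
        warnings.warn("x_API = 1: infinite solubility (fully miscible)", stacklevel=2)
        return math.inf
    return rho_solvent * (x_API / (1.0 - x_API)) * (Mw_API / Mw_solvent)


def from_g_per_L(
    S_gL: float, Mw_API: float, Mw_solvent: float, rho_solvent: float
) -> float:
    """Inverse of :func:`to_g_per_L`: mole fraction from g/L solubility."""
    if S_gL < 0:
        raise ValueError("S must be >= 0")
    r = S_gL * Mw_solvent / (rho_solvent * Mw_API)
    return r / (1.0 + r)


def solubility_curve(
    api: PureComponentParams,
    mp: MeltingProps,
    solvents: Sequence[PureComponentParams],
    solvent_ratio: Sequence[float],
    kij_store: KijStore | np.ndarray | None,
    T_grid: Sequence[float],
    **kwargs,
) -> list[SolubilityResult | None]:
    """Solubility at every temperature of an ascending grid.

    Per-point failures are logged and recorded as ``None`` without aborting
    the sweep.
    """
    T_grid = list(T_grid)
    if any(b < a for a, b in zip(T_grid, T_grid[1:])):
        raise ValueError("T_grid must be sorted ascending")
    out: list[SolubilityResult | None] = []
    for T in T_grid:
        try:
            out.append(
                solve_solubility(api, mp, solvents, solvent_ratio, kij_store, T, **kwargs)
            )
        except (PcSaftError, SolubilityIterationError, ValueError) as exc:
            logger.warning("solubility failed at T=%.2f K: %s", T, exc)
            out.append(None)
    return out


__all__ = [
    "SolubilityPoint",
    "SolubilityResult",
    "SolubilityIterationError",
    "ideal_solubility",
    "solve_solubility",
    "solubility_curve",
    "to_g_per_L",
    "from_g_per_L",
]
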