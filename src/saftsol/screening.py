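"""Cosolvent blend screening: solubility across binary solvent mixtures.

Sweeps the API-free weight fraction w1 of the first-named solvent, solving
the solid-liquid equilibrium at each grid point with the API-free solvent
ratio held fixed, and reports discrete solubility maxima, minima and
turning points.  Blends often show solubility synergies (an interior
maximum above both pure-solvent values), which is what a formulation
screen is after.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import P_REF
from .parameters import MeltingProps, PureComponentParams
from .pcsaft import PcSaftError
from .sle import SolubilityIterationError, SolubilityResult, solve_solubility

logger = logging.getLogger(__name__)

#: minimum ln-solubility contrast for an extremum to be reported
EXTREMUM_MIN_CONTRAST = 1e-6


@dataclass(frozen=True)
class BlendPoint:
    """Solubility at one API-free blend composition."""

    w1: float
    T: float
    result: SolubilityResult | None


def blend_to_mole_ratio(w1: float, Mw1: float, Mw2: float) -> tuple[float, float]:
    """API-free mole-fraction pair from the weight fraction of solvent 1."""
    if not 0.0 <= w1 <= 1.0:
        raise ValueError("w1 must be in [0, 1]")
    a = w1 / Mw1
    b = (1.0 - w1) / Mw2
    n1 = a / (a + b)
    return n1, 1.0 - n1


def solubility_blend_sweep(
    api: PureComponentParams,
    mp: MeltingProps,
    solvent1: PureComponentParams,
    solvent2: PureComponentParams,
    kij_api_s1: float,
    kij_api_s2: float,
    kij_s1_s2: float,
    T: float,
    w1_grid: Sequence[float] | None = None,
    P: float = P_REF,
    **kwargs,
) -> list[BlendPoint]:
    """Solubility across a binary solvent blend at fixed temperature.

    The endpoints w1 = 0 and w1 = 1 are computed as the plain binary
    API-solvent problems (identical code path to a single-solvent
    prediction), interior points as the ternary problem with all three
    binary parameters.  The solvent-solvent k_ij must come from
    vapor-liquid-equilibrium data or another external source; a default of
    0 is accepted but loudly warned about, since it ignores the solvent
    pair's non-ideality.
    """
    if w1_grid is None:
        w1_grid = np.linspace(0.0, 1.0, 41)
    w1_grid = np.asarray(w1_grid, dtype=float)
    if np.any(w1_grid < 0) or np.any(w1_grid > 1):
        raise ValueError("w1 grid must lie in [0, 1]")
    if kij_s1_s2 == 0.0:
        warnings.warn(
            "solvent-solvent k_ij is 0 (pure combining rules); blend "
            "non-ideality between the solvents is ignored",
            stacklevel=2,
        )

    out: list[BlendPoint] = []
    for w1 in w1_grid:
        try:
            if w1 == 0.0:
                K = np.array([[0.0, kij_api_s2], [kij_api_s2, 0.0]])
                res = solve_solubility(api, mp, [solvent2], [1.0], K, T, P=P, **kwargs)
            elif w1 == 1.0:
                K = np.array([[0.0, kij_api_s1], [kij_api_s1, 0.0]])
                res = solve_solubility(api, mp, [solvent1], [1.0], K, T, P=P, **kwargs)
            else:
                n1, n2 = blend_to_mole_ratio(float(w1), solvent1.Mw, solvent2.Mw)
                K = np.array(
                    [
                        [0.0, kij_api_s1, kij_api_s2],
                        [kij_api_s1, 0.0, kij_s1_s2],
                        [kij_api_s2, kij_s1_s2, 0.0],
                    ]
                )
                res = solve_solubility(
                    api, mp, [solvent1, solvent2], [n1, n2], K, T, P=P, **kwargs
                )
        except (PcSaftError, SolubilityIterationError) as exc:
            logger.warning("blend point w1=%.3f failed: %s", w1, exc)
            res = None
        out.append(BlendPoint(w1=float(w1), T=T, result=res))
    return out


def detect_extrema(
    points: Sequence[BlendPoint],
    min_contrast: float = EXTREMUM_MIN_CONTRAST,
) -> list[tuple[float, str]]:
    """Discrete extrema of ln-solubility along a blend sweep.

    Maxima/minima are sign changes of the first differences exceeding
    ``min_contrast`` in ln x against both neighbours; sign changes of the
    second differences are flagged as inflections.  Fewer than 3 valid
    points yield an empty list with a warning.
    """
    valid = [p for p in points if p.result is not None]
    if len(valid) < 3:
        warnings.warn("fewer than 3 valid points: no extremum detection", stacklevel=2)
        return []
    if any(b.w1 < a.w1 for a, b in zip(valid, valid[1:])):
        raise ValueError("points must be sorted by w1")
    w = np.array([p.w1 for p in valid])
    lnx = np.array([np.log(p.result.x_API) for p in valid])
    d1 = np.diff(lnx)
    out: list[tuple[float, str]] = []
    for i in range(1, len(valid) - 1):
        left, right = d1[i - 1], d1[i]
        if left > min_contrast and right < -min_contrast:
            out.append((float(w[i]), "max"))
        elif left < -min_contrast and right > min_contrast:
            out.append((float(w[i]), "min"))
    d2 = np.diff(lnx, n=2)
    for i in range(1, len(d2)):
        if d2[i - 1] * d2[i] < 0 and min(abs(d2[i - 1]), abs(d2[i])) > min_contrast:
            out.append((float(w[i + 1]), "inflection"))
    return sorted(out)


__all__ = [
    "BlendPoint",
    "blend_to_mole_ratio",
    "solubility_blend_sweep",
    "detect_extrema",
    "EXTREMUM_MIN_CONTRAST",
]
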