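"""Statistical scoring of solubility predictions against experiment.

Three metrics, all standard in the solubility-modeling literature:

* AARD = (1/n) * sum |1 - A_i/B_i| * 100, the average absolute relative
  deviation in percent of values A against references B;
* MAE = (1/n) * sum |A_i - B_i|, the mean absolute error;
* R^2 on ln x, the coefficient of determination of calculated against
  experimental log solubility (solubilities span orders of magnitude, so
  parity is judged on the natural-log scale).

``evaluate_dataset`` is the comparison harness for the two data-availability
scenarios: predict with k_ij values as given (e.g. machine-learned or from
literature), or first refit each system's k_ij to a single designated anchor
point and then predict everything.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import P_REF
from .fitting import fit_kij_single_point
from .parameters import BinaryParam, Database, KijStore
from .pcsaft import PcSaftError
from .screening import blend_to_mole_ratio
from .sle import SolubilityIterationError, SolubilityPoint, solve_solubility

logger = logging.getLogger(__name__)

SCENARIOS = ("given_kij", "single_point_fit")


def _as_arrays(A, B):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    if A.size == 0:
        raise ValueError("empty input")
    return A, B


def aard(A, B) -> float:
    """Average absolute relative deviation of A against reference B, in %."""
    A, B = _as_arrays(A, B)
    if np.any(B == 0):
        raise ValueError("reference values must be nonzero for AARD")
    return float(np.mean(np.abs(1.0 - A / B)) * 100.0)


def mae(A, B) -> float:
    """Mean absolute error, in the units of the inputs."""
    A, B = _as_arrays(A, B)
    return float(np.mean(np.abs(A - B)))


def r_squared_lnx(lnx_calc, lnx_exp) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the experimental
    mean; may be negative.  Zero experimental variance returns NaN with a
    warning (the statistic is undefined)."""
    A, B = _as_arrays(lnx_calc, lnx_exp)
    if A.size < 2:
        raise ValueError("need at least 2 points")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("inputs must be finite")
    ss_tot = float(np.sum((B - B.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero experimental variance: R^2 undefined", stacklevel=2)
        return math.nan
    ss_res = float(np.sum((A - B) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class MetricReport:
    """Summary metrics for one evaluated dataset."""

    n: int
    r_squared: float
    mae: float
    aard_pct: float
    aard_scale: str  # "lnx" | "linear"
    skipped: int = 0
    per_api: Mapping[str, tuple[int, float, float, float]] = field(default_factory=dict)


def _predict_lnx(db: Database, store: KijStore, pt: SolubilityPoint, P: float) -> float:
    api = db.component(pt.api_id)
    mp = db.melting_props(pt.api_id)
    solvents = [db.component(s) for s in pt.solvent_ids]
    if len(solvents) == 1:
        ratio = [1.0]
    elif len(solvents) == 2:
        if pt.w1 is None:
            raise ValueError(f"blend point without w1: {pt}")
        ratio = list(blend_to_mole_ratio(pt.w1, solvents[0].Mw, solvents[1].Mw))
    else:
        raise ValueError("only single solvents and binary blends supported")
    res = solve_solubility(api, mp, solvents, ratio, store, pt.T, P=P)
    return math.log(res.x_API)


def _default_anchor(points: list[SolubilityPoint]) -> SolubilityPoint:
    """Anchor = the point at the median temperature of the system."""
    pts = sorted(points, key=lambda p: p.T)
    return pts[len(pts) // 2]


def evaluate_dataset(
    points: Sequence[SolubilityPoint],
    scenario: str,
    kij_store: KijStore,
    db: Database,
    anchors: Mapping[tuple[str, str], SolubilityPoint] | None = None,
    include_anchors: bool = True,
    aard_scale: str = "lnx",
    P: float = P_REF,
) -> tuple[MetricReport, pd.DataFrame]:
    """Score a dataset of experimental solubilities under one scenario.

    ``given_kij`` uses the stored binary parameters unchanged.
    ``single_point_fit`` first refits k_ij for every single-solvent system
    to its anchor point (by default the point at the system's median
    temperature, or the entry of ``anchors`` keyed (api_id, solvent_id)),
    then predicts; the anchors stay in the evaluated set unless
    ``include_anchors=False``.  Failed points are skipped with a log entry
    and counted in the report.

    Returns the metric report and a parity table with columns
    api_id, solvent_ids, T_K, lnx_exp, lnx_calc, abs_err in deterministic
    (api, solvent, T) order.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if aard_scale not in ("lnx", "linear"):
        raise ValueError("aard_scale must be 'lnx' or 'linear'")
    points = list(points)
    if not points:
        raise ValueError("empty dataset")

    store = kij_store
    anchor_keys: set[tuple[str, tuple[str, ...], float, float]] = set()
    if scenario == "single_point_fit":
        store = KijStore(list(kij_store))
        systems: dict[tuple[str, str], list[SolubilityPoint]] = {}
        for pt in points:
            if len(pt.solvent_ids) == 1:
                systems.setdefault((pt.api_id, pt.solvent_ids[0]), []).append(pt)
        for (api_id, solv_id), pts in sorted(systems.items()):
            anchor = None
            if anchors is not None:
                anchor = anchors.get((api_id, solv_id))
            if anchor is None:
                anchor = _default_anchor(pts)
            anchor_keys.add((anchor.api_id, anchor.solvent_ids, anchor.T, anchor.x))
            report = fit_kij_single_point(
                db.component(api_id),
                db.melting_props(api_id),
                db.component(solv_id),
                anchor.T,
                anchor.x,
                P=P,
            )
            if not report.converged:
                logger.warning(
                    "single-point fit did not converge for (%s, %s); using k=%.4g",
                    api_id,
                    solv_id,
                    report.k_ij,
                )
            store.add(
                BinaryParam(api_id, solv_id, report.k_ij, source="fitted_single_point")
            )

    rows = []
    skipped = 0
    for pt in points:
        if not include_anchors and (pt.api_id, pt.solvent_ids, pt.T, pt.x) in anchor_keys:
            continue
        try:
            lnx_calc = _predict_lnx(db, store, pt, P)
        except (PcSaftError, SolubilityIterationError, ValueError, KeyError) as exc:
            logger.warning("skipping point %s: %s", pt, exc)
            skipped += 1
            continue
        lnx_exp = math.log(pt.x)
        rows.append(
            {
                "api_id": pt.api_id,
                "solvent_ids": "+".join(pt.solvent_ids),
                "T_K": pt.T,
                "lnx_exp": lnx_exp,
                "lnx_calc": lnx_calc,
                "abs_err": abs(lnx_calc - lnx_exp),
            }
        )
    if not rows:
        raise ValueError("no evaluable points in dataset")
    parity = (
        pd.DataFrame(rows)
        .sort_values(["api_id", "solvent_ids", "T_K"], kind="mergesort")
        .reset_index(drop=True)
    )

    def _metrics(df: pd.DataFrame) -> tuple[int, float, float, float]:
        calc, exp = df["lnx_calc"].to_numpy(), df["lnx_exp"].to_numpy()
        r2 = r_squared_lnx(calc, exp) if len(df) >= 2 else math.nan
        m = mae(calc, exp)
        if aard_scale == "lnx":
            a = aard(calc, exp)
        else:
            a = aard(np.exp(calc), np.exp(exp))
        return len(df), r2, m, a

    n, r2, m, a = _metrics(parity)
    per_api = {
        api_id: _metrics(group) for api_id, group in parity.groupby("api_id", sort=True)
    }
    logger.info("AARD computed on %s scale", aard_scale)
    report = MetricReport(
        n=n,
        r_squared=r2,
        mae=m,
        aard_pct=a,
        aard_scale=aard_scale,
        skipped=skipped,
        per_api=per_api,
    )
    return report, parity


__all__ = [
    "aard",
    "mae",
    "r_squared_lnx",
    "MetricReport",
    "SolubilityPoint",
    "evaluate_dataset",
    "SCENARIOS",
]
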