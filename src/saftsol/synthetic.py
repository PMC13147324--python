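"""Deterministic synthetic fixtures with known ground truth.

Generators for toy components, pseudo-experimental solubility datasets and
benchmark collections of drug-solvent systems.  Every fitting and
evaluation path of the package can be exercised against data whose
generating parameters (in particular the true k_ij) are known exactly.

All randomness flows from a single integer seed through numpy's PCG64
generator, so fixtures are bitwise reproducible across platforms.  Noise is
additive in ln x, matching the evaluation scale: multiplicative solubility
error is the empirical norm for this kind of data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import P_REF
from .parameters import (
    Database,
    KijStore,
    BinaryParam,
    MeltingProps,
    PureComponentParams,
    default_database,
)
from .pcsaft import PcSaftError
from .sle import SolubilityIterationError, SolubilityPoint, solve_solubility

logger = logging.getLogger(__name__)

# Parameter spans of the bundled drug table; toy components stay inside them.
_M_RANGE = (3.5, 12.1)
_SIGMA_RANGE = (2.8, 3.9)
_U_RANGE = (247.0, 353.0)
_EPS_RANGE = (900.0, 3000.0)  # within the observed [0, 4339] span
_KAPPA_RANGE = (0.005, 0.046)
_MW_RANGE = (130.0, 510.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one pseudo-experimental dataset."""

    seed: int
    n_points: int = 6
    T_range: tuple[float, float] = (278.15, 323.15)
    noise_sd_lnx: float = 0.0
    k_true: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_lnx < 0:
            raise ValueError("noise_sd_lnx must be >= 0")
        lo, hi = self.T_range
        if not (200.0 < lo <= hi < 600.0):
            raise ValueError("T_range must lie within (200, 600) K")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


def make_toy_component(seed: int, associating: bool = True) -> PureComponentParams:
    """Deterministic drug-like component within the bundled parameter spans."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(*_M_RANGE)
    sigma = rng.uniform(*_SIGMA_RANGE)
    u = rng.uniform(*_U_RANGE)
    if associating:
        eps = rng.uniform(*_EPS_RANGE)
        kappa = rng.uniform(*_KAPPA_RANGE)
        scheme = "2B"
    else:
        eps = kappa = 0.0
        scheme = "none"
    return PureComponentParams(
        id=f"TOY{seed}{'A' if associating else 'N'}",
        name=f"toy component (seed {seed})",
        m_seg=float(m),
        sigma=float(sigma),
        u_kB=float(u),
        eps_AB_kB=float(eps),
        kappa_AB=float(kappa),
        assoc_scheme=scheme,
        Mw=float(rng.uniform(*_MW_RANGE)),
    )


def make_toy_solvent(seed: int, associating: bool = False) -> PureComponentParams:
    """Deterministic small-molecule solvent (lighter than the drug span)."""
    rng = np.random.default_rng(seed + 10_000)
    if associating:
        eps = rng.uniform(1800.0, 2700.0)
        kappa = rng.uniform(0.01, 0.04)
        scheme = "2B"
    else:
        eps = kappa = 0.0
        scheme = "none"
    return PureComponentParams(
        id=f"SOLV{seed}{'A' if associating else 'N'}",
        name=f"toy solvent (seed {seed})",
        m_seg=float(rng.uniform(1.8, 3.6)),
        sigma=float(rng.uniform(3.0, 3.8)),
        u_kB=float(rng.uniform(190.0, 300.0)),
        eps_AB_kB=float(eps),
        kappa_AB=float(kappa),
        assoc_scheme=scheme,
        Mw=float(rng.uniform(30.0, 120.0)),
    )


def make_toy_melting(seed: int) -> MeltingProps:
    """Deterministic melting properties for a toy drug."""
    rng = np.random.default_rng(seed + 20_000)
    T_SL = float(rng.uniform(340.0, 470.0))
    dH = float(rng.uniform(20_000.0, 55_000.0))
    return MeltingProps(T_SL=T_SL, dH_SL=dH, dCp_SL=dH / T_SL, dCp_approximated=True)


def generate_pseudo_experimental(
    api: PureComponentParams,
    mp: MeltingProps,
    solvent: PureComponentParams,
    spec: FixtureSpec,
    P: float = P_REF,
) -> list[SolubilityPoint]:
    """Noisy synthetic solubility points on the forward-model curve.

    ln x_i = ln x_model(T_i; k_true) + eps_i with eps_i ~ N(0, noise_sd_lnx)
    from the seeded generator.  Grid temperatures where the forward model
    fails are dropped with a log entry; points are returned sorted by T.
    """
    rng = np.random.default_rng(spec.seed)
    T_grid = np.linspace(spec.T_range[0], spec.T_range[1], spec.n_points)
    K = np.array([[0.0, spec.k_true], [spec.k_true, 0.0]])
    noise = rng.normal(0.0, spec.noise_sd_lnx, size=spec.n_points)
    out: list[SolubilityPoint] = []
    for T, eps in zip(T_grid, noise):
        try:
            res = solve_solubility(api, mp, [solvent], [1.0], K, float(T), P=P)
        except (PcSaftError, SolubilityIterationError) as exc:
            logger.warning("dropping fixture point at T=%.2f K: %s", T, exc)
            continue
        lnx = np.log(res.x_API) + eps
        out.append(
            SolubilityPoint(
                api_id=api.id,
                solvent_ids=(solvent.id,),
                T=float(T),
                x=float(np.exp(lnx)),
                source="synthetic",
            )
        )
    return sorted(out, key=lambda p: p.T)


# Drug/solvent pools for benchmark sampling: the bundled tables, minus
# pairings that sit very close to full miscibility (little SLE content).
_BENCH_APIS = (
    "ACF", "ASP", "ATN", "BEN", "BIF", "CIM", "CIN", "DAP", "EST",
    "FFB", "IBU", "MAC", "NDO", "NIM", "RIV", "RVC", "g-IND",
)
_BENCH_SOLVENTS = ("EtOH", "MeOH", "2PrOH", "1BuOH", "ACT", "EA", "TOL")


@dataclass(frozen=True)
class BenchmarkSystem:
    """One drug-solvent system of a synthetic benchmark."""

    api_id: str
    solvent_id: str
    k_true: float
    points: tuple[SolubilityPoint, ...]


def make_benchmark(
    seed: int,
    n_systems: int = 20,
    n_points: int = 5,
    T_range: tuple[float, float] = (278.15, 323.15),
    noise_sd_lnx: float = 0.1,
    k_range: tuple[float, float] = (-0.05, 0.05),
    db: Database | None = None,
) -> tuple[list[BenchmarkSystem], Database]:
    """Seeded benchmark of drug-solvent systems with known true k_ij.

    Pairs are drawn without replacement from the bundled drug and solvent
    tables, each with a uniform k_true and a pseudo-experimental dataset of
    ``n_points`` noisy solubilities.  Systems whose forward model fails on
    part of the grid are replaced by the next draw.
    """
    rng = np.random.default_rng(seed)
    if db is None:
        db = default_database()
    pairs = [(a, s) for a in _BENCH_APIS for s in _BENCH_SOLVENTS]
    order = rng.permutation(len(pairs))
    systems: list[BenchmarkSystem] = []
    for idx in order:
        if len(systems) >= n_systems:
            break
        api_id, solv_id = pairs[idx]
        k_true = float(rng.uniform(*k_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = FixtureSpec(
            seed=sub_seed,
            n_points=n_points,
            T_range=T_range,
            noise_sd_lnx=noise_sd_lnx,
            k_true=k_true,
        )
        try:
            pts = generate_pseudo_experimental(
                db.component(api_id), db.melting_props(api_id),
                db.component(solv_id), spec,
            )
        except (PcSaftError, SolubilityIterationError) as exc:
            logger.warning("benchmark pair (%s, %s) failed: %s", api_id, solv_id, exc)
            continue
        if len(pts) < n_points:
            logger.warning("benchmark pair (%s, %s) incomplete; skipped", api_id, solv_id)
            continue
        systems.append(
            BenchmarkSystem(api_id=api_id, solvent_id=solv_id, k_true=k_true,
                            points=tuple(pts))
        )
    if len(systems) < n_systems:
        logger.warning("only %d of %d benchmark systems generated", len(systems), n_systems)
    return systems, db


def benchmark_kij_stores(
    systems: list[BenchmarkSystem],
    seed: int,
    perturbation: float = 0.02,
) -> tuple[KijStore, KijStore]:
    """(true, perturbed) k_ij stores for a benchmark.

    The perturbed store adds +/- ``perturbation`` (random sign) to every
    true k_ij, emulating imperfectly estimated 'given' parameters.
    """
    rng = np.random.default_rng(seed)
    true_store, given_store = KijStore(), KijStore()
    for s in systems:
        true_store.add(BinaryParam(s.api_id, s.solvent_id, s.k_true, source="literature"))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        given_store.add(
            BinaryParam(s.api_id, s.solvent_id, s.k_true + sign * perturbation,
                        source="ml_given")
        )
    return true_store, given_store


__all__ = [
    "FixtureSpec",
    "BenchmarkSystem",
    "make_toy_component",
    "make_toy_solvent",
    "make_toy_melting",
    "generate_pseudo_experimental",
    "make_benchmark",
    "benchmark_kij_stores",
]
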