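"""PC-SAFT residual Helmholtz energy and derived thermodynamic properties.

The residual Helmholtz energy per molecule, reduced by k_B*T, is the sum of
a hard-chain reference, a second-order dispersion perturbation and (for
associating species) a Wertheim association term restricted to the 2B
scheme: every associating molecule carries one donor-like site A and one
acceptor-like site B, and only A-B bonds form.

Everything downstream — compressibility factor, pressure, liquid/vapor
density roots, fugacity coefficients and activity coefficients — is obtained
from that single scalar function.  Its exact first derivatives (in density
and in mole numbers) are evaluated by complex-step differentiation, which is
free of truncation and cancellation error; the test suite cross-checks them
against centered finite differences and against an independent transcription
of the published expressions.

Internal unit conventions: temperature K, lengths Angstrom, number density
in molecules per cubic Angstrom; pressures enter and leave in Pa, densities
in mol m^-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import K_B, N_A, P_REF
from .parameters import KijStore, PureComponentParams

MAX_PACKING = 0.7405  # close packing of equal spheres
_H = 1e-100  # complex-step size

# Universal dispersion-series constants of the perturbed-chain model
# (model constants, fixed once; rows i = 0..6).
_A0 = np.array(
    [0.9105631445, 0.6361281449, 2.6861347891, -26.547362491,
     97.759208784, -159.59154087, 91.297774084])
_A1 = np.array(
    [-0.3084016918, 0.1860531159, -2.5030047259, 21.419793629,
     -65.255885330, 83.318680481, -33.746922930])
_A2 = np.array(
    [-0.0906148351, 0.4527842806, 0.5962700728, -1.7241829131,
     -4.1302112531, 13.776631870, -8.6728470368])
_B0 = np.array(
    [0.7240946941, 2.2382791861, -4.0025849485, -21.003576815,
     26.855641363, 206.55133841, -355.60235612])
_B1 = np.array(
    [-0.5755498075, 0.6995095521, 3.8925673390, -17.215471648,
     192.67226447, -161.82646165, -165.20769346])
_B2 = np.array(
    [0.0976883116, -0.2557574982, -9.1558561530, 20.642075974,
     -38.804430052, 93.626774077, -29.666905585])
_POW = np.arange(7)


class PcSaftError(Exception):
    """Base class for equation-of-state failures."""


class PackingError(PcSaftError):
    """Packing fraction at or above the close-packing limit."""


class DensityRootError(PcSaftError):
    """No density root of the requested phase at the given (T, P)."""


class SiteFractionError(PcSaftError):
    """Association mass balance did not converge."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"site fractions not converged after {iterations} iterations "
            f"(residual {residual:.3e})"
        )


class PureLiquidRootError(PcSaftError):
    """No pure-liquid reference root for a component at (T, P)."""

    def __init__(self, component_id: str, T: float, P: float):
        self.component_id = component_id
        super().__init__(
            f"no pure-liquid density root for {component_id!r} "
            f"at T={T} K, P={P} Pa"
        )


# ---------------------------------------------------------------------------
# parameter packing


@dataclass(frozen=True)
class _Packed:
    """Component parameters as arrays, for fast vector evaluation."""

    m: np.ndarray
    sigma: np.ndarray
    u: np.ndarray
    eps: np.ndarray
    kappa: np.ndarray
    assoc: np.ndarray  # bool mask: participates in association


def pack(components: Sequence[PureComponentParams]) -> _Packed:
    return _Packed(
        m=np.array([c.m_seg for c in components], dtype=float),
        sigma=np.array([c.sigma for c in components], dtype=float),
        u=np.array([c.u_kB for c in components], dtype=float),
        eps=np.array([c.eps_AB_kB for c in components], dtype=float),
        kappa=np.array([c.kappa_AB for c in components], dtype=float),
        assoc=np.array(
            [c.assoc_scheme == "2B" and c.kappa_AB > 0 for c in components],
            dtype=bool,
        ),
    )


def kij_matrix(components: Sequence[PureComponentParams], store: KijStore | None) -> np.ndarray:
    n = len(components)
    K = np.zeros((n, n))
    if store is not None:
        for i in range(n):
            for j in range(i + 1, n):
                K[i, j] = K[j, i] = store.lookup(components[i].id, components[j].id)
    return K


def effective_diameter(p: PureComponentParams, T: float) -> float:
    """Temperature-dependent segment diameter d(T) in Angstrom.

    d = sigma * (1 - 0.12 exp(-3 u/(k_B T))); the soft-repulsion correction
    keeps 0.88 sigma <= d < sigma for all T > 0.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    return p.sigma * (1.0 - 0.12 * np.exp(-3.0 * p.u_kB / T))


# ---------------------------------------------------------------------------
# residual Helmholtz energy


def _site_fractions(x, rho, delta, damping=0.5, tol=1e-12, max_iter=500):
    """Solve the 2B association mass balance by damped successive substitution.

    ``rho`` may be an array (leading axes); ``delta`` then has matching
    leading axes before its (n, n) pair axes.  Returns (X_A, X_B) with
    component axis last.  Raises :class:`SiteFractionError` on
    non-convergence.
    """
    rho = np.asarray(rho)
    n = delta.shape[-1]
    shape = np.broadcast_shapes(rho.shape, delta.shape[:-2]) + (n,)
    dtype = np.result_type(rho.dtype, delta.dtype, np.asarray(x).dtype)
    XA = np.ones(shape, dtype=dtype)
    XB = np.ones(shape, dtype=dtype)
    rho_e = rho[..., None]
    xv = np.asarray(x)
    resid = 0.0
    for it in range(max_iter):
        XA_new = 1.0 / (1.0 + rho_e * np.einsum("...ij,...j->...i", delta, xv * XB))
        XB_new = 1.0 / (1.0 + rho_e * np.einsum("...ij,...j->...i", delta, xv * XA))
        resid = max(np.max(np.abs(XA_new - XA)), np.max(np.abs(XB_new - XB)))
        XA = (1.0 - damping) * XA + damping * XA_new
        XB = (1.0 - damping) * XB + damping * XB_new
        if resid < tol:
            return XA, XB
    raise SiteFractionError(float(resid), max_iter)


def _a_res_terms(p: _Packed, x, T: float, rho, K: np.ndarray):
    """Reduced residual Helmholtz terms (a_hc, a_disp, a_assoc).

    ``rho`` is the total number density in molecules/A^3 and may be a scalar
    or an array (vectorized density grids); ``x`` and ``rho`` may be complex
    for complex-step differentiation.
    """
    x = np.asarray(x)
    rho = np.asarray(rho)
    rho_e = rho[..., None]

    d = p.sigma * (1.0 - 0.12 * np.exp(-3.0 * p.u / T))  # (n,)
    xm = x * p.m
    mbar = np.sum(xm)

    z0 = (np.pi / 6.0) * rho * np.sum(xm)
    z1 = (np.pi / 6.0) * rho * np.sum(xm * d)
    z2 = (np.pi / 6.0) * rho * np.sum(xm * d * d)
    z3 = (np.pi / 6.0) * rho * np.sum(xm * d * d * d)
    eta = z3
    if np.any(eta.real >= MAX_PACKING):
        raise PackingError(
            f"packing fraction {np.max(eta.real):.4f} >= {MAX_PACKING}"
        )
    om3 = 1.0 - z3

    # Boublik-Mansoori hard-sphere mixture term (per segment)
    a_hs = (1.0 / z0) * (
        3.0 * z1 * z2 / om3
        + z2**3 / (z3 * om3**2)
        + (z2**3 / z3**2 - z0) * np.log(om3)
    )

    # radial distribution function of hard spheres at contact, g_ij(d_ij)
    dd = d[:, None] * d[None, :] / (d[:, None] + d[None, :])  # (n, n)
    om3_e = om3[..., None, None]
    z2_e = z2[..., None, None]
    g = (
        1.0 / om3_e
        + dd * 3.0 * z2_e / om3_e**2
        + dd**2 * 2.0 * z2_e**2 / om3_e**3
    )  # (..., n, n)
    g_ii = np.diagonal(g, axis1=-2, axis2=-1)  # (..., n)

    a_hc = mbar * a_hs - np.sum(x * (p.m - 1.0) * np.log(g_ii), axis=-1)

    # dispersion
    sij = 0.5 * (p.sigma[:, None] + p.sigma[None, :])
    uij = np.sqrt(p.u[:, None] * p.u[None, :]) * (1.0 - K)
    xmm = np.outer(x * p.m, x * p.m)
    m2es3 = np.sum(xmm * (uij / T) * sij**3)
    m2e2s3 = np.sum(xmm * (uij / T) ** 2 * sij**3)

    mf1 = (mbar - 1.0) / mbar
    mf2 = mf1 * (mbar - 2.0) / mbar
    a_i = _A0 + mf1 * _A1 + mf2 * _A2
    b_i = _B0 + mf1 * _B1 + mf2 * _B2
    eta_pow = eta[..., None] ** _POW  # (..., 7)
    I1 = np.sum(a_i * eta_pow, axis=-1)
    I2 = np.sum(b_i * eta_pow, axis=-1)
    C1 = 1.0 / (
        1.0
        + mbar * (8.0 * eta - 2.0 * eta**2) / (1.0 - eta) ** 4
        + (1.0 - mbar)
        * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
        / ((1.0 - eta) * (2.0 - eta)) ** 2
    )
    a_disp = -2.0 * np.pi * rho * I1 * m2es3 - np.pi * rho * mbar * C1 * I2 * m2e2s3

    # 2B association with Wolbach-Sandler cross rules
    if p.assoc.any():
        epsij = 0.5 * (p.eps[:, None] + p.eps[None, :])
        kapij = np.sqrt(p.kappa[:, None] * p.kappa[None, :]) * (
            np.sqrt(p.sigma[:, None] * p.sigma[None, :]) / sij
        ) ** 3
        delta = sij**3 * g * kapij * np.expm1(epsij / T)
        if np.max(np.abs(delta)) == 0.0:
            a_assoc = np.zeros_like(a_hc)
        else:
            XA, XB = _site_fractions(x, rho, delta)
            a_assoc = np.sum(
                x * (np.log(XA) + np.log(XB) - 0.5 * (XA + XB) + 1.0), axis=-1
            )
    else:
        a_assoc = np.zeros_like(a_hc)

    return a_hc, a_disp, a_assoc


def _a_res(p: _Packed, x, T: float, rho, K: np.ndarray):
    a_hc, a_disp, a_assoc = _a_res_terms(p, x, T, rho, K)
    return a_hc + a_disp + a_assoc


# ---------------------------------------------------------------------------
# state containers


@dataclass(frozen=True)
class HelmholtzBreakdown:
    """Reduced residual Helmholtz contributions, per molecule per k_B*T."""

    a_hc: float
    a_disp: float
    a_assoc: float
    a_res: float


@dataclass(frozen=True)
class SiteFractions:
    """Non-bonded site fractions X per component, columns (A, B)."""

    X: np.ndarray  # shape (n, 2)


@dataclass
class MixtureState:
    """Composition/temperature/density snapshot of one liquid or vapor phase.

    ``rho`` is the total molar density in mol m^-3; internally the equation
    of state works in molecules per cubic Angstrom.
    """

    components: list[PureComponentParams]
    x: np.ndarray
    T: float
    rho: float  # mol/m^3
    kij_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        n = len(self.components)
        if self.x.shape != (n,):
            raise ValueError("x length must match number of components")
        if np.any(self.x < 0) or abs(self.x.sum() - 1.0) > 1e-12:
            raise ValueError("mole fractions must be >= 0 and sum to 1")
        if not self.rho > 0:
            raise ValueError("rho must be > 0")
        if self.kij_matrix is None:
            self.kij_matrix = np.zeros((n, n))
        else:
            self.kij_matrix = np.asarray(self.kij_matrix, dtype=float)
        eta = self.packing_fraction
        if eta >= 0.74:
            raise PackingError(f"packing fraction {eta:.4f} >= 0.74")

    @property
    def rho_number(self) -> float:
        """Number density in molecules per cubic Angstrom."""
        return self.rho * N_A / 1e30

    @property
    def packing_fraction(self) -> float:
        p = pack(self.components)
        d = p.sigma * (1.0 - 0.12 * np.exp(-3.0 * p.u / self.T))
        return float((np.pi / 6.0) * self.rho_number * np.sum(self.x * p.m * d**3))


def helmholtz_residual(state: MixtureState) -> HelmholtzBreakdown:
    """Residual Helmholtz breakdown for a mixture state."""
    p = pack(state.components)
    a_hc, a_disp, a_assoc = _a_res_terms(
        p, state.x, state.T, state.rho_number, state.kij_matrix
    )
    return HelmholtzBreakdown(
        a_hc=float(np.real(a_hc)),
        a_disp=float(np.real(a_disp)),
        a_assoc=float(np.real(a_assoc)),
        a_res=float(np.real(a_hc + a_disp + a_assoc)),
    )


def solve_site_fractions(state: MixtureState) -> SiteFractions:
    """Fraction of non-bonded A and B sites for every component.

    Non-associating components report X = 1 (all sites free, vacuously).
    """
    p = pack(state.components)
    n = len(state.components)
    T, rho = state.T, state.rho_number
    d = p.sigma * (1.0 - 0.12 * np.exp(-3.0 * p.u / T))
    xm = state.x * p.m
    z2 = (np.pi / 6.0) * rho * np.sum(xm * d * d)
    z3 = (np.pi / 6.0) * rho * np.sum(xm * d**3)
    om3 = 1.0 - z3
    dd = d[:, None] * d[None, :] / (d[:, None] + d[None, :])
    g = 1.0 / om3 + dd * 3.0 * z2 / om3**2 + dd**2 * 2.0 * z2**2 / om3**3
    sij = 0.5 * (p.sigma[:, None] + p.sigma[None, :])
    epsij = 0.5 * (p.eps[:, None] + p.eps[None, :])
    kapij = np.sqrt(p.kappa[:, None] * p.kappa[None, :]) * (
        np.sqrt(p.sigma[:, None] * p.sigma[None, :]) / sij
    ) ** 3
    delta = sij**3 * g * kapij * np.expm1(epsij / T)
    if np.max(np.abs(delta)) == 0.0:
        return SiteFractions(X=np.ones((n, 2)))
    XA, XB = _site_fractions(state.x, rho, delta)
    return SiteFractions(X=np.column_stack([XA.real, XB.real]))


# ---------------------------------------------------------------------------
# pressure, density, fugacity, activity


def _Z_from_rho(p: _Packed, x, T: float, rho, K: np.ndarray):
    """Compressibility factor Z = 1 + rho * d(a_res)/d(rho), complex step."""
    rho_c = np.asarray(rho) * (1.0 + 1j * _H)
    a = _a_res(p, x, T, rho_c, K)
    return 1.0 + np.imag(a) / _H


def pressure(state: MixtureState) -> tuple[float, float]:
    """Pressure in Pa and compressibility factor Z of a mixture state."""
    p = pack(state.components)
    Z = float(_Z_from_rho(p, state.x, state.T, state.rho_number, state.kij_matrix))
    P = Z * state.rho_number * 1e30 * K_B * state.T
    return P, Z


def _pressure_number(p: _Packed, x, T: float, rho_number, K: np.ndarray):
    Z = _Z_from_rho(p, x, T, rho_number, K)
    return Z * np.asarray(rho_number) * 1e30 * K_B * T


def _eta_to_rho(p: _Packed, x, T: float, eta):
    d = p.sigma * (1.0 - 0.12 * np.exp(-3.0 * p.u / T))
    md3 = np.sum(np.asarray(x) * p.m * d**3)
    return eta / ((np.pi / 6.0) * md3)


def _secant_eta(p, x, T, P, K, eta0, eta1=None, tol_rel=1e-10, max_iter=40):
    """Secant refinement of P(eta) = P; returns (eta, slope) or None."""

    def fval(eta):
        return float(
            _pressure_number(p, x, T, _eta_to_rho(p, x, T, eta), K).real - P
        )

    e0 = eta0
    e1 = eta1 if eta1 is not None else eta0 * (1.0 + 1e-7) + 1e-12
    f0, f1 = fval(e0), fval(e1)
    for _ in range(max_iter):
        if abs(f1) <= tol_rel * P:
            slope = (f1 - f0) / (e1 - e0) if e1 != e0 else 1.0
            return e1, slope
        if f1 == f0:
            return None
        e2 = e1 - f1 * (e1 - e0) / (f1 - f0)
        if not (1e-12 < e2 < MAX_PACKING - 1e-4):
            return None
        e0, f0, e1 = e1, f1, e2
        f1 = fval(e1)
    return None


def _solve_eta(
    p: _Packed,
    x,
    T: float,
    P: float,
    phase: str,
    K: np.ndarray,
    eta0: float | None = None,
) -> float:
    """Packing-fraction root of P(eta) = P on the requested phase branch.

    An optional warm start ``eta0`` (from a nearby previous solve) skips the
    bracketing scan; the warm-started root must stay on a mechanically
    stable branch or the full scan is repeated.
    """
    if P <= 0:
        raise ValueError("P must be > 0")
    if eta0 is not None:
        res = _secant_eta(p, x, T, P, K, eta0)
        if res is not None and res[1] > 0:
            return res[0]

    eta_grid = np.concatenate(
        [np.geomspace(1e-12, 1e-3, 15, endpoint=False), np.linspace(1e-3, 0.74, 90)]
    )
    rho_grid = _eta_to_rho(p, x, T, eta_grid)
    P_grid = _pressure_number(p, x, T, rho_grid, K)
    f = P_grid - P
    sign = np.sign(f)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise DensityRootError(
            f"no density root in eta (1e-12, 0.74) at T={T} K, P={P} Pa"
        )

    def fscalar(eta):
        return float(
            _pressure_number(p, x, T, _eta_to_rho(p, x, T, eta), K).real - P
        )

    # liquid wants the largest stable root, vapor the smallest: refine only
    # the relevant bracket(s), preferring those with positive slope dP/deta.
    order = idx[::-1] if phase == "liquid" else idx
    fallback = None
    for i in order:
        lo, hi = eta_grid[i], eta_grid[i + 1]
        stable = f[i + 1] > f[i]
        try:
            r = brentq(fscalar, lo, hi, xtol=1e-14, rtol=1e-12)
        except ValueError:
            continue
        polished = _secant_eta(p, x, T, P, K, r, r * (1 + 1e-9))
        if polished is not None:
            r = polished[0]
        if stable:
            return r
        if fallback is None:
            fallback = r
    if fallback is None:
        raise DensityRootError(f"bracketing failed at T={T} K, P={P} Pa")
    return fallback


def solve_density(
    components: Sequence[PureComponentParams],
    x,
    T: float,
    P: float,
    phase: str = "liquid",
    kij: np.ndarray | KijStore | None = None,
) -> float:
    """Molar density (mol m^-3) of the requested phase branch at (T, P).

    The liquid branch returns the highest-density mechanically stable root,
    the vapor branch the lowest.  Raises :class:`DensityRootError` when no
    root exists in the physical packing range.
    """
    if phase not in ("liquid", "vapor"):
        raise ValueError("phase must be 'liquid' or 'vapor'")
    p = pack(components)
    K = kij if isinstance(kij, np.ndarray) else kij_matrix(components, kij)
    x = np.asarray(x, dtype=float)
    eta = _solve_eta(p, x, T, P, phase, K)
    rho_number = _eta_to_rho(p, x, T, eta)
    return float(rho_number * 1e30 / N_A)


def _ln_phi_at_rho(p: _Packed, x, T: float, rho_number: float, K: np.ndarray):
    """ln(fugacity coefficients) at a known density (molecules/A^3)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    a = float(np.real(_a_res(p, x, T, rho_number, K)))
    Z = float(_Z_from_rho(p, x, T, rho_number, K))
    dadx = np.empty(n)
    for i in range(n):
        xc = x.astype(complex)
        xc[i] += 1j * _H
        dadx[i] = np.imag(_a_res(p, xc, T, rho_number, K)) / _H
    mu_res = a + (Z - 1.0) + dadx - float(np.dot(x, dadx))
    return mu_res - np.log(Z)


def ln_fugacity_coefficients(
    components: Sequence[PureComponentParams],
    x,
    T: float,
    P: float,
    phase: str = "liquid",
    kij: np.ndarray | KijStore | None = None,
) -> np.ndarray:
    """ln(phi_i) for every component at fixed (T, P) on the given branch."""
    p = pack(components)
    K = kij if isinstance(kij, np.ndarray) else kij_matrix(components, kij)
    x = np.asarray(x, dtype=float)
    eta = _solve_eta(p, x, T, P, phase, K)
    rho_number = _eta_to_rho(p, x, T, eta)
    return _ln_phi_at_rho(p, x, T, rho_number, K)


@lru_cache(maxsize=8192)
def _pure_ln_phi_cached(comp: PureComponentParams, T: float, P: float) -> float:
    """Pure-liquid ln(phi), cached; the API reference state below melting is
    the hypothetical subcooled liquid on the liquid branch."""
    p = pack([comp])
    K = np.zeros((1, 1))
    try:
        eta = _solve_eta(p, np.array([1.0]), T, P, "liquid", K)
    except DensityRootError as exc:
        raise PureLiquidRootError(comp.id, T, P) from exc
    rho_number = _eta_to_rho(p, np.array([1.0]), T, eta)
    return float(_ln_phi_at_rho(p, np.array([1.0]), T, rho_number, K)[0])


def activity_coefficients(
    components: Sequence[PureComponentParams],
    x,
    T: float,
    P: float = P_REF,
    kij: np.ndarray | KijStore | None = None,
) -> np.ndarray:
    """Mole-fraction activity coefficients gamma_i at fixed (T, P).

    gamma_i = exp(ln phi_i(T, P, x) - ln phi_i^pure(T, P)), both on the
    liquid branch; gamma_i -> 1 as x_i -> 1.
    """
    components = list(components)
    ln_phi = ln_fugacity_coefficients(components, x, T, P, "liquid", kij)
    ln_phi_pure = np.array(
        [_pure_ln_phi_cached(c, float(T), float(P)) for c in components]
    )
    return np.exp(ln_phi - ln_phi_pure)


def ln_gamma_one(
    components: Sequence[PureComponentParams],
    x,
    T: float,
    index: int = 0,
    P: float = P_REF,
    kij: np.ndarray | KijStore | None = None,
) -> float:
    """ln(gamma) of a single component (cheaper than the full vector)."""
    components = list(components)
    p = pack(components)
    K = kij if isinstance(kij, np.ndarray) else kij_matrix(components, kij)
    x = np.asarray(x, dtype=float)
    eta = _solve_eta(p, x, T, P, "liquid", K)
    rho_number = _eta_to_rho(p, x, T, eta)
    ln_phi = _ln_phi_at_rho(p, x, T, rho_number, K)
    return float(ln_phi[index]) - _pure_ln_phi_cached(components[index], float(T), float(P))


class LiquidGammaTracker:
    """Repeated ln(gamma) evaluations for one component along an iteration.

    Keeps the packed parameters and warm-starts the liquid-density solve
    from the previous call, which makes the fixed-point and root-finding
    loops of the solubility and k_ij modules cheap.  Not thread-safe.
    """

    def __init__(
        self,
        components: Sequence[PureComponentParams],
        kij: np.ndarray | KijStore | None = None,
        index: int = 0,
        P: float = P_REF,
    ) -> None:
        self.components = list(components)
        self._p = pack(self.components)
        self._K = kij if isinstance(kij, np.ndarray) else kij_matrix(self.components, kij)
        self.index = index
        self.P = float(P)
        self._last_eta: float | None = None

    def ln_gamma(self, x, T: float) -> float:
        x = np.asarray(x, dtype=float)
        eta = _solve_eta(self._p, x, T, self.P, "liquid", self._K, eta0=self._last_eta)
        self._last_eta = eta
        rho_number = _eta_to_rho(self._p, x, T, eta)
        ln_phi = _ln_phi_at_rho(self._p, x, T, rho_number, self._K)
        pure = _pure_ln_phi_cached(self.components[self.index], float(T), self.P)
        return float(ln_phi[self.index]) - pure

    def liquid_density(self, x, T: float) -> float:
        """Molar liquid density (mol m^-3) at the tracker's pressure."""
        x = np.asarray(x, dtype=float)
        eta = _solve_eta(self._p, x, T, self.P, "liquid", self._K, eta0=None)
        return float(_eta_to_rho(self._p, x, T, eta) * 1e30 / N_A)


__all__ = [
    "LiquidGammaTracker",
    "MixtureState",
    "HelmholtzBreakdown",
    "SiteFractions",
    "PcSaftError",
    "PackingError",
    "DensityRootError",
    "SiteFractionError",
    "PureLiquidRootError",
    "effective_diameter",
    "helmholtz_residual",
    "solve_site_fractions",
    "pressure",
    "solve_density",
    "ln_fugacity_coefficients",
    "activity_coefficients",
    "ln_gamma_one",
    "kij_matrix",
    "pack",
]
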