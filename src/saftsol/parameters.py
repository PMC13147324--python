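"""Pure-component parameters, melting properties and binary parameters.

The package describes every substance by the five-parameter PC-SAFT set
(segment number ``m_seg``, segment diameter ``sigma`` in Angstrom, dispersion
energy ``u_kB`` in K, association energy ``eps_AB_kB`` in K and association
volume ``kappa_AB``) plus the molar mass, and every crystalline drug
polymorph by its three melting properties (melting temperature, melting
enthalpy and the solid-liquid heat-capacity difference).

Tables are stored at rest in the units they are conventionally printed in
(sigma in Angstrom, energies divided by k_B in K, melting enthalpy in
kJ/mol); the loaders convert to the internal SI-coherent system (J, mol, K)
once, at the boundary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

ASSOC_SCHEMES = ("none", "2B")

#: Aliases accepted in the ``assoc_scheme`` CSV column.
_SCHEME_ALIASES = {"": "none", "-": "none", "none": "none", "2b": "2B", "2B": "2B"}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a physical invariant; message names row and field."""


@dataclass(frozen=True)
class PureComponentParams:
    """PC-SAFT pure-component parameter set for one substance.

    Parameters follow the five-parameter convention with a 2B association
    scheme (one donor-like A site and one acceptor-like B site) or no
    association.  A 2B record may carry ``kappa_AB > 0`` with
    ``eps_AB_kB == 0``: such a molecule does not self-associate (the
    association strength vanishes) but cross-associates with associating
    partners through the combining rules (induced association).
    """

    id: str
    name: str
    m_seg: float
    sigma: float  # Angstrom
    u_kB: float  # K
    eps_AB_kB: float  # K
    kappa_AB: float  # dimensionless
    assoc_scheme: str  # "none" | "2B"
    Mw: float  # g/mol

    def __post_init__(self) -> None:
        if self.assoc_scheme not in ASSOC_SCHEMES:
            raise ValidationError(
                f"{self.id}: assoc_scheme must be one of {ASSOC_SCHEMES}, "
                f"got {self.assoc_scheme!r}"
            )
        for fname in ("m_seg", "sigma", "u_kB", "Mw"):
            if not getattr(self, fname) > 0:
                raise ValidationError(f"{self.id}: {fname} must be > 0")
        if self.eps_AB_kB < 0:
            raise ValidationError(f"{self.id}: eps_AB_kB must be >= 0")
        if self.kappa_AB < 0:
            raise ValidationError(f"{self.id}: kappa_AB must be >= 0")
        if self.assoc_scheme == "none" and (self.eps_AB_kB != 0 or self.kappa_AB != 0):
            raise ValidationError(
                f"{self.id}: non-associating component must have "
                "eps_AB_kB = kappa_AB = 0"
            )

    @property
    def associating(self) -> bool:
        return self.assoc_scheme == "2B" and self.kappa_AB > 0


@dataclass(frozen=True)
class MeltingProps:
    """Melting properties of one crystal polymorph (internal SI units).

    ``dCp_approximated`` flags values estimated as the melting entropy
    ``dH_SL / T_SL`` instead of being measured.
    """

    T_SL: float  # K
    dH_SL: float  # J/mol
    dCp_SL: float  # J/(mol K)
    dCp_approximated: bool = False

    def __post_init__(self) -> None:
        if not self.T_SL > 0:
            raise ValidationError("T_SL must be > 0")
        if not self.dH_SL > 0:
            raise ValidationError("dH_SL must be > 0")
        if self.dCp_SL < 0:
            raise ValidationError("dCp_SL must be >= 0")


@dataclass(frozen=True)
class BinaryParam:
    """One binary interaction parameter k_ij with its provenance."""

    id_i: str
    id_j: str
    k_ij: float
    source: str = "literature"  # ml_given | fitted_single_point | literature

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_i, self.id_j)))  # type: ignore[return-value]


def approximate_dcp(dH_SL: float, T_SL: float) -> float:
    """Estimate the solid-liquid heat-capacity difference as dH_SL / T_SL.

    Equates the heat-capacity difference with the melting entropy, the
    common fallback when no calorimetric value is available.

    Parameters
    ----------
    dH_SL : melting enthalpy, J/mol (>= 0)
    T_SL : melting temperature, K (> 0)

    Returns
    -------
    float : J/(mol K)
    """
    if T_SL <= 0:
        raise ValueError(f"T_SL must be > 0, got {T_SL}")
    if dH_SL < 0:
        raise ValueError(f"dH_SL must be >= 0, got {dH_SL}")
    return dH_SL / T_SL


# ---------------------------------------------------------------------------
# k_ij store


class KijStore:
    """Symmetric store of binary interaction parameters.

    Lookup of an absent pair returns 0 (pure Berthelot-Lorentz combining
    rules) with a logged notice; ``k_ii`` is always 0.
    """

    def __init__(self, params: Iterable[BinaryParam] = ()) -> None:
        self._data: dict[tuple[str, str], BinaryParam] = {}
        for p in params:
            self.add(p)

    def add(self, p: BinaryParam) -> None:
        if p.id_i == p.id_j and p.k_ij != 0:
            raise ValidationError(f"k_ii must be 0 for {p.id_i}")
        self._data[p.key()] = p

    def lookup(self, id_i: str, id_j: str) -> float:
        if id_i == id_j:
            return 0.0
        p = self._data.get(tuple(sorted((id_i, id_j))))
        if p is None:
            logger.info("no k_ij stored for (%s, %s); defaulting to 0", id_i, id_j)
            return 0.0
        return p.k_ij

    def get(self, id_i: str, id_j: str) -> BinaryParam | None:
        return self._data.get(tuple(sorted((id_i, id_j))))

    def __len__(self) -> int:
        return len(self._data)

    def __iter__(self):
        return iter(self._data.values())


def lookup_kij(store: KijStore, id_i: str, id_j: str) -> float:
    """Symmetric k_ij lookup; absent pair defaults to 0 (logged)."""
    return store.lookup(id_i, id_j)


# ---------------------------------------------------------------------------
# CSV loaders / writers

_COMPONENT_COLUMNS = (
    "id",
    "name",
    "m_seg",
    "sigma",
    "u_kB",
    "eps_AB_kB",
    "kappa_AB",
    "assoc_scheme",
    "Mw",
)
_MELTING_COLUMNS = ("id", "T_SL_K", "dH_SL_kJ_mol", "dCp_SL_J_molK", "approximated")
_KIJ_COLUMNS = ("id_i", "id_j", "k_ij", "source")

_TRUTHY = {"true", "1", "yes", "y"}
_FALSY = {"false", "0", "no", "n", ""}


def _check_header(reader: csv.DictReader, required: tuple[str, ...], path) -> None:
    have = set(reader.fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def load_component_table(path) -> list[PureComponentParams]:
    """Load a pure-component parameter CSV.

    Extra columns (e.g. a free-text ``smiles`` or ``citation`` column) are
    tolerated and ignored.  Duplicate ids and invariant violations raise
    :class:`ValidationError` naming the offending row.
    """
    records: list[PureComponentParams] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, _COMPONENT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            cid = row["id"].strip()
            if cid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate id {cid!r}")
            seen.add(cid)
            scheme_raw = row["assoc_scheme"].strip()
            scheme = _SCHEME_ALIASES.get(scheme_raw, scheme_raw)
            try:
                rec = PureComponentParams(
                    id=cid,
                    name=row["name"].strip(),
                    m_seg=float(row["m_seg"]),
                    sigma=float(row["sigma"]),
                    u_kB=float(row["u_kB"]),
                    eps_AB_kB=float(row["eps_AB_kB"]),
                    kappa_AB=float(row["kappa_AB"]),
                    assoc_scheme=scheme,
                    Mw=float(row["Mw"]),
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_component_table(path, records: Iterable[PureComponentParams]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COMPONENT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.name,
                    repr(r.m_seg),
                    repr(r.sigma),
                    repr(r.u_kB),
                    repr(r.eps_AB_kB),
                    repr(r.kappa_AB),
                    r.assoc_scheme,
                    repr(r.Mw),
                ]
            )


def load_melting_table(path) -> dict[str, MeltingProps]:
    """Load a melting-property CSV; enthalpies convert kJ/mol -> J/mol."""
    out: dict[str, MeltingProps] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, _MELTING_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            cid = row["id"].strip()
            if cid in out:
                raise ValidationError(f"{path}:{lineno}: duplicate id {cid!r}")
            flag_raw = row["approximated"].strip().lower()
            if flag_raw in _TRUTHY:
                flag = True
            elif flag_raw in _FALSY:
                flag = False
            else:
                raise ValidationError(
                    f"{path}:{lineno}: approximated must be boolean, got {flag_raw!r}"
                )
            try:
                out[cid] = MeltingProps(
                    T_SL=float(row["T_SL_K"]),
                    dH_SL=float(row["dH_SL_kJ_mol"]) * 1000.0,
                    dCp_SL=float(row["dCp_SL_J_molK"]),
                    dCp_approximated=flag,
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_melting_table(path, table: Mapping[str, MeltingProps]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MELTING_COLUMNS)
        for cid, mp in table.items():
            writer.writerow(
                [
                    cid,
                    repr(mp.T_SL),
                    repr(mp.dH_SL / 1000.0),
                    repr(mp.dCp_SL),
                    "true" if mp.dCp_approximated else "false",
                ]
            )


def load_kij_table(path) -> KijStore:
    store = KijStore()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, _KIJ_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                store.add(
                    BinaryParam(
                        id_i=row["id_i"].strip(),
                        id_j=row["id_j"].strip(),
                        k_ij=float(row["k_ij"]),
                        source=row["source"].strip(),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return store


def write_kij_table(path, store: KijStore) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_KIJ_COLUMNS)
        for p in store:
            writer.writerow([p.id_i, p.id_j, repr(p.k_ij), p.source])


# ---------------------------------------------------------------------------
# Bundled tables and config


def _bundled(name: str):
    return resources.files("saftsol.data").joinpath(name)


def load_bundled_apis() -> list[PureComponentParams]:
    """The bundled drug (API) pure-component parameter table."""
    with resources.as_file(_bundled("components.csv")) as p:
        return load_component_table(p)


def load_bundled_melting() -> dict[str, MeltingProps]:
    """The bundled melting-property table for the drug set."""
    with resources.as_file(_bundled("melting.csv")) as p:
        return load_melting_table(p)


def load_bundled_solvents() -> list[PureComponentParams]:
    """Bundled literature PC-SAFT solvent parameter sets."""
    with resources.as_file(_bundled("solvents.csv")) as p:
        return load_component_table(p)


@dataclass
class Database:
    """All parameter tables needed for a solubility calculation."""

    components: dict[str, PureComponentParams] = field(default_factory=dict)
    melting: dict[str, MeltingProps] = field(default_factory=dict)
    kij: KijStore = field(default_factory=KijStore)

    def component(self, cid: str) -> PureComponentParams:
        try:
            return self.components[cid]
        except KeyError:
            raise KeyError(f"unknown component id {cid!r}") from None

    def melting_props(self, cid: str) -> MeltingProps:
        try:
            return self.melting[cid]
        except KeyError:
            raise KeyError(f"no melting properties for {cid!r}") from None


def default_database() -> Database:
    """Bundled drugs + solvents, bundled melting table, empty k_ij store."""
    comps = {c.id: c for c in load_bundled_apis()}
    for s in load_bundled_solvents():
        comps[s.id] = s
    return Database(components=comps, melting=load_bundled_melting())


def load_config(path) -> Database:
    """Build a :class:`Database` from a YAML config.

    Recognised keys: ``components``, ``solvents`` (optional second component
    table), ``melting``, ``kij`` — each a CSV path, resolved relative to the
    config file.  Missing keys fall back to the bundled tables.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    base = path.parent

    def _resolve(key):
        p = cfg.get(key)
        return None if p is None else (base / p)

    comps_path = _resolve("components")
    if comps_path is None:
        comps = {c.id: c for c in load_bundled_apis()}
    else:
        comps = {c.id: c for c in load_component_table(comps_path)}
    solv_path = _resolve("solvents")
    if solv_path is None:
        for s in load_bundled_solvents():
            comps.setdefault(s.id, s)
    else:
        for s in load_component_table(solv_path):
            comps.setdefault(s.id, s)
    melt_path = _resolve("melting")
    melting = (
        load_bundled_melting() if melt_path is None else load_melting_table(melt_path)
    )
    kij_path = _resolve("kij")
    kij = KijStore() if kij_path is None else load_kij_table(kij_path)
    return Database(components=comps, melting=melting, kij=kij)


__all__ = [
    "PureComponentParams",
    "MeltingProps",
    "BinaryParam",
    "KijStore",
    "Database",
    "SchemaError",
    "ValidationError",
    "approximate_dcp",
    "lookup_kij",
    "load_component_table",
    "load_melting_table",
    "load_kij_table",
    "write_component_table",
    "write_melting_table",
    "write_kij_table",
    "load_bundled_apis",
    "load_bundled_melting",
    "load_bundled_solvents",
    "default_database",
    "load_config",
]
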