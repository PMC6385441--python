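"""Mössbauer-pool bookkeeping and the canonicalized observation tables.

Mössbauer spectroscopy resolves the iron of a sample into four spectral
groups: non-heme high-spin (NHHS) Fe(II), the central doublet (CD,
[Fe4S4]2+ clusters plus low-spin Fe(II) hemes), Fe(III)-oxyhydroxide
nanoparticles, and NHHS Fe(III).  Given the assumed labile cytosolic iron
concentration [C], these whole-cell and mitochondrial group concentrations
map linearly (and invertibly) onto the nine-component model pools:

    FeII_cell  = f_cyt*C  + f_mit*FM + f_vac*F2
    CD_cell    = f_cyt*CIA + f_mit*FS
    NP_cell    = f_mit*MP + f_vac*VP
    FeIII_cell = f_vac*F3
    FeII_mit = FM;  CD_mit = FS;  NPplusFeIII_mit = MP

The bundled ``observations.csv`` canonicalizes the published observation
tables (growth rates, whole-cell iron, compartment iron, component pools and
data-based fluxes for the 8 strain x N conditions).  The published tables are
typographically run together, so each cell was validated against the
steady-state algebra (rate = alpha * pool, compartment sums); cells that could
not be validated carry status ``unparsed`` or ``discrepant`` and are excluded
from programmatic use, and ``branch`` marks simulated cells that correspond to
a coexisting steady branch (see docs/methods.md on bistability).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .params import CompartmentGeometry, Condition, normalize_strain
from .rate_laws import RateVector

__all__ = [
    "MbGroups",
    "ObservationRecord",
    "POOL_NAMES",
    "pools_from_groups",
    "groups_from_pools",
    "data_based_fluxes",
    "load_fixture_tables",
    "load_fixture_frame",
    "validate_fixtures",
    "FIXTURE_SHA256",
]

POOL_NAMES = ("C", "CIA", "FM", "FS", "MP", "F2", "F3", "VP")

#: checksum of the bundled observations.csv; the loader refuses corrupt files
FIXTURE_SHA256 = "0073224d69ca89d33ef290e2020b218f69194e7b0c8291ea51d29d820ce3b852"

#: rounding tolerance of the printed tables (2 significant figures, compounded)
PRINT_TOL = 0.10


@dataclass(frozen=True)
class MbGroups:
    """Spectral-group iron concentrations (uM).

    ``*_cell`` entries are on the whole-cell volume basis, ``*_mit`` on the
    mitochondrial basis.
    """

    FeII_cell: float
    CD_cell: float
    NP_cell: float
    FeIII_cell: float
    FeII_mit: float
    CD_mit: float
    NPplusFeIII_mit: float

    def cell_total(self) -> float:
        return self.FeII_cell + self.CD_cell + self.NP_cell + self.FeIII_cell


def pools_from_groups(
    groups: MbGroups, C_assumed: float, g: CompartmentGeometry
) -> dict[str, float]:
    """Invert the group-assignment map into the nine model pools.

    The map is linear and square once [C] is assumed (labile cytosolic iron is
    below Mössbauer detection and is taken from independent chelator-based
    estimates).  A negative inferred pool signals mutually inconsistent inputs
    and raises with the offending pool named.
    """
    if C_assumed < 0:
        raise ValueError("C_assumed must be >= 0")
    FM = groups.FeII_mit
    FS = groups.CD_mit
    MP = groups.NPplusFeIII_mit
    pools = {
        "C": C_assumed,
        "FM": FM,
        "FS": FS,
        "MP": MP,
        "F2": (groups.FeII_cell - g.f_cyt * C_assumed - g.f_mit * FM) / g.f_vac,
        "CIA": (groups.CD_cell - g.f_mit * FS) / g.f_cyt,
        "VP": (groups.NP_cell - g.f_mit * MP) / g.f_vac,
        "F3": groups.FeIII_cell / g.f_vac,
    }
    tol = 1e-9 * max(1.0, groups.cell_total())  # forgive float cancellation
    for name in POOL_NAMES:
        if pools[name] < -tol:
            raise ValueError(
                f"inferred pool {name} is negative ({pools[name]:.4g} uM): "
                "group concentrations are inconsistent with the assumed [C]"
            )
    return {name: max(pools[name], 0.0) for name in POOL_NAMES}


def groups_from_pools(pools: dict[str, float], g: CompartmentGeometry) -> MbGroups:
    """Forward map: model pools -> spectral-group concentrations (exact)."""
    return MbGroups(
        FeII_cell=g.f_cyt * pools["C"] + g.f_mit * pools["FM"] + g.f_vac * pools["F2"],
        CD_cell=g.f_cyt * pools["CIA"] + g.f_mit * pools["FS"],
        NP_cell=g.f_mit * pools["MP"] + g.f_vac * pools["VP"],
        FeIII_cell=g.f_vac * pools["F3"],
        FeII_mit=pools["FM"],
        CD_mit=pools["FS"],
        NPplusFeIII_mit=pools["MP"],
    )


@dataclass(frozen=True)
class ObservationRecord:
    """One strain x N condition's data-based quantities."""

    condition: Condition
    alpha_dat: float
    Fe_cell_dat: float
    pools_dat: dict[str, float]
    compartments_dat: dict[str, float] = field(default=None)  # type: ignore[assignment]
    fluxes_dat: RateVector = field(default=None)  # type: ignore[assignment]
    geometry: CompartmentGeometry = field(default_factory=CompartmentGeometry)

    def __post_init__(self) -> None:
        if self.compartments_dat is None:
            c = self.pools_dat
            object.__setattr__(
                self,
                "compartments_dat",
                {
                    "Fe_cyt": c["C"] + c["CIA"],
                    "Fe_mit": c["FM"] + c["FS"] + c["MP"],
                    "Fe_vac": c["F2"] + c["F3"] + c["VP"],
                },
            )
        if self.fluxes_dat is None:
            object.__setattr__(self, "fluxes_dat", data_based_fluxes(self, self.geometry))

    def whole_cell_from_pools(self) -> float:
        g, c = self.geometry, self.compartments_dat
        return g.f_cyt * c["Fe_cyt"] + g.f_mit * c["Fe_mit"] + g.f_vac * c["Fe_vac"]


def data_based_fluxes(rec: ObservationRecord, g: CompartmentGeometry) -> RateVector:
    """Data-based formation fluxes from measured alpha and pools.

    At the expanding steady state every pool's production balances growth
    dilution, so each flux is alpha times a pool (organelle import fluxes pick
    up the compartment volume ratio to stay on the cytosol concentration
    basis):

        R_cell = alpha*[Fe_cell]        R_cyt = R_cell / f_cyt
        R_mit = (f_mit/f_cyt)*alpha*[Fe_mit]
        R_vac = (f_vac/f_cyt)*alpha*[Fe_vac]
        R_cia = alpha*[CIA]   R_isu = alpha*[FS]   R_mp = alpha*[MP]
        R_vp = alpha*[VP]     R_23  = R_vp + alpha*[F3]
    """
    a = rec.alpha_dat
    if a < 0:
        raise ValueError("alpha_dat must be >= 0")
    p = rec.pools_dat
    missing = [n for n in POOL_NAMES if n not in p or p[n] is None or math.isnan(p[n])]
    if missing:
        raise ValueError(f"missing pools for flux computation: {missing}")
    comp = rec.compartments_dat
    R_cell = a * rec.Fe_cell_dat
    R_vp = a * p["VP"]
    return RateVector(
        alpha=a,
        R_cell=R_cell,
        R_cyt=R_cell / g.f_cyt,
        R_mit=g.mit_over_cyt * a * comp["Fe_mit"],
        R_vac=g.vac_over_cyt * a * comp["Fe_vac"],
        R_cia=a * p["CIA"],
        R_isu=a * p["FS"],
        R_vp=R_vp,
        R_23=R_vp + a * p["F3"],
        R_mp=a * p["MP"],
    )


# ---------------------------------------------------------------------------
# bundled fixture tables
# ---------------------------------------------------------------------------

def _fixture_bytes() -> bytes:
    return resources.files("yeastiron.data").joinpath("observations.csv").read_bytes()


def load_fixture_frame(verify: bool = True) -> pd.DataFrame:
    """The raw canonicalized observation table as a tidy DataFrame."""
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != FIXTURE_SHA256:
            raise ValueError(
                f"bundled observations.csv checksum mismatch: {digest} != {FIXTURE_SHA256}"
            )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    expected = {"table", "strain", "N", "basis", "quantity", "value", "status", "note"}
    if set(df.columns) != expected:
        raise ValueError(f"fixture schema mismatch: {sorted(df.columns)}")
    df["strain"] = df["strain"].map(normalize_strain)
    return df


def _cell(df: pd.DataFrame, table: str, strain: str, N: float, basis: str, q: str) -> float:
    m = df[
        (df.table == table)
        & (df.strain == strain)
        & (df.N == N)
        & (df.basis == basis)
        & (df.quantity == q)
    ]
    if len(m) != 1:
        raise KeyError(f"fixture cell ({table},{strain},{N},{basis},{q}) not unique")
    return float(m.value.iloc[0])


def load_fixture_tables(g: CompartmentGeometry | None = None) -> list[ObservationRecord]:
    """The 8 canonical strain x N observation records (data basis)."""
    if g is None:
        g = CompartmentGeometry()
    df = load_fixture_frame()
    records = []
    for strain in ("WT", "DD"):
        for N in (1.0, 2.0, 11.0, 41.0):
            pools = {q: _cell(df, "t3", strain, N, "data", q) for q in POOL_NAMES}
            # compartment totals come from the whole-cell table (independently
            # printed f-weighted values), not from summing the pool table
            compartments = {
                "Fe_cyt": _cell(df, "t1", strain, N, "data", "fw_Fe_cyt") / g.f_cyt,
                "Fe_mit": _cell(df, "t1", strain, N, "data", "fw_Fe_mit") / g.f_mit,
                "Fe_vac": _cell(df, "t1", strain, N, "data", "fw_Fe_vac") / g.f_vac,
            }
            records.append(
                ObservationRecord(
                    condition=Condition(strain, N),
                    alpha_dat=_cell(df, "t1", strain, N, "data", "alpha"),
                    Fe_cell_dat=_cell(df, "t1", strain, N, "data", "Fe_cell"),
                    pools_dat=pools,
                    compartments_dat=compartments,
                    geometry=g,
                )
            )
    return records


def validate_fixtures(g: CompartmentGeometry | None = None) -> pd.DataFrame:
    """Run the internal consistency audit over the bundled tables.

    For every record, checks (a) the volume-weighted pool sum against the
    printed whole-cell iron and (b) the recomputed fluxes against the printed
    data-based rates, both within the documented printed-rounding tolerance.
    Returns a tidy report; raises on any 'ok'-status violation.
    """
    if g is None:
        g = CompartmentGeometry()
    df = load_fixture_frame()
    # a check is only binding if every fixture cell it touches has status 'ok'
    deps = {
        "Fe_cell_sum": [("t3", q) for q in POOL_NAMES] + [("t1", "Fe_cell")],
        "R_cell": [("t1", "alpha"), ("t1", "Fe_cell"), ("t1", "R_cell")],
        "R_mit": [("t1", "alpha"), ("t1", "fw_Fe_mit"), ("t1", "R_mit")],
        "R_vac": [("t1", "alpha"), ("t1", "fw_Fe_vac"), ("t1", "R_vac")],
    }

    def all_ok(strain: str, N: float, cells) -> bool:
        for table, q in cells:
            m = df[(df.table == table) & (df.strain == strain) & (df.N == N)
                   & (df.basis == "data") & (df.quantity == q)]
            if len(m) != 1 or m.status.iloc[0] != "ok":
                return False
        return True

    rows = []
    for rec in load_fixture_tables(g):
        strain, N = rec.condition.strain, rec.condition.N
        checks = {
            "Fe_cell_sum": (rec.whole_cell_from_pools(), rec.Fe_cell_dat),
            "R_cell": (rec.fluxes_dat.R_cell, _cell(df, "t1", strain, N, "data", "R_cell")),
            "R_mit": (rec.fluxes_dat.R_mit, _cell(df, "t1", strain, N, "data", "R_mit")),
            "R_vac": (rec.fluxes_dat.R_vac, _cell(df, "t1", strain, N, "data", "R_vac")),
        }
        for name, (got, printed) in checks.items():
            if not all_ok(strain, N, deps[name]):
                rows.append(dict(strain=strain, N=N, check=name, recomputed=got,
                                 printed=printed, rel_err=float("nan"), ok=True))
                continue
            denom = max(abs(printed), abs(got), 1e-12)
            rel = abs(got - printed) / denom
            ok = rel <= PRINT_TOL
            rows.append(dict(strain=strain, N=N, check=name, recomputed=got,
                             printed=printed, rel_err=rel, ok=ok))
            if not ok:
                raise ValueError(
                    f"fixture audit failed: {strain} N={N} {name}: "
                    f"recomputed {got:.4g} vs printed {printed:.4g}"
                )
    return pd.DataFrame(rows)
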