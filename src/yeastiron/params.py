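"""Domain types and the canonical optimized parameter set.

Units are fixed package-wide: concentrations in uM, time in hours, rates in
uM/hr.  Two genetic strains are supported out of the box: wild type (``WT``)
and the Mrs3/4 double-deletion strain (``DD``, written DeltaDelta in the
literature), which lacks the high-affinity mitochondrial iron importers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import yaml

__all__ = [
    "CompartmentGeometry",
    "StrainParameters",
    "Condition",
    "canonical_parameters",
    "normalize_strain",
    "STRAINS",
    "PARAM_FIELDS",
    "STRAIN_SPECIFIC_PARAMS",
]

STRAINS = ("WT", "DD")

#: aliases accepted anywhere a strain label is taken
_STRAIN_ALIASES = {
    "WT": "WT",
    "wt": "WT",
    "DD": "DD",
    "dd": "DD",
    "ΔΔ": "DD",
    "deltadelta": "DD",
    "mrs3/4": "DD",
}


def normalize_strain(strain: str) -> str:
    """Map a strain label (including the ΔΔ spelling) to 'WT' or 'DD'."""
    try:
        return _STRAIN_ALIASES[strain if strain in _STRAIN_ALIASES else strain.lower()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown strain label: {strain!r} (expected WT or DD/ΔΔ)") from None


@dataclass(frozen=True)
class CompartmentGeometry:
    """Fractional volumes of the three modelled cell regions.

    Only volume *ratios* ever enter the equations (e.g. the transfer factor
    f_cyt/f_mit when cytosolic iron moves into mitochondria), so absolute
    volumes are never stored.  Canonical values for respiring W303 yeast are
    0.8 / 0.1 / 0.1.
    """

    f_cyt: float = 0.8
    f_mit: float = 0.1
    f_vac: float = 0.1

    def __post_init__(self) -> None:
        for name in ("f_cyt", "f_mit", "f_vac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if abs(self.f_cyt + self.f_mit + self.f_vac - 1.0) > 1e-12:
            raise ValueError("volume fractions must sum to 1 within 1e-12")

    @property
    def mit_over_cyt(self) -> float:
        return self.f_mit / self.f_cyt

    @property
    def vac_over_cyt(self) -> float:
        return self.f_vac / self.f_cyt


# parameter name -> (units, is_exponent)
PARAM_FIELDS = {
    "alpha_max": ("1/hr", False),
    "K_alpha": ("uM", False),
    "R_cell_max": ("uM/hr", False),
    "K_N": ("uM", False),
    "sens": ("", True),
    "R_cyt_max": ("uM/hr", False),
    "k_mit_c3": ("1/hr", False),
    "k_mit": ("1/hr", False),
    "R_vac_max": ("uM/hr", False),
    "K_vac": ("uM", False),
    "nvac": ("", True),
    "R_cia_max": ("uM/hr", False),
    "K_cia": ("uM", False),
    "ncia": ("", True),
    "R_isu_max": ("uM/hr", False),
    "K_isu": ("uM", False),
    "nisu": ("", True),
    "k_vp": ("uM^(1-nvp)/hr", False),
    "nvp": ("", True),
    "k_23": ("1/hr", False),
    "FS_sp": ("uM", False),
    "n23": ("", True),
    "k_mp": ("1/(uM hr)", False),
    "k_O2": ("1/hr", False),
    "k_res": ("1/(uM hr)", False),
    "O2_cyt": ("uM", False),
}

#: parameters that differ between the two canonical strains.  R_cell_max and
#: R_cyt_max are one linked choice (whole-cell vs cytosolic basis of the same
#: importer Vmax), so the canonical WT/DD sets differ in the four-parameter
#: family {R_cell_max/R_cyt_max, k_mit (with k_mit_c3), k_vp, K_alpha}.
STRAIN_SPECIFIC_PARAMS = frozenset(
    {"R_cell_max", "R_cyt_max", "k_mit", "k_mit_c3", "k_vp", "K_alpha"}
)


@dataclass(frozen=True)
class StrainParameters:
    """Complete kinetic/regulatory parameter set for one strain.

    All values strictly positive; Hill/mass-action exponents >= 1.  ``K_alpha``
    is carried in uM: it appears as the half-saturation constant of the growth
    law alpha(N) and is therefore a concentration (see docs/methods.md for the
    units note).
    """

    strain: str
    alpha_max: float
    K_alpha: float
    R_cell_max: float
    K_N: float
    sens: float
    R_cyt_max: float
    k_mit_c3: float
    k_mit: float
    R_vac_max: float
    K_vac: float
    nvac: float
    R_cia_max: float
    K_cia: float
    ncia: float
    R_isu_max: float
    K_isu: float
    nisu: float
    k_vp: float
    nvp: float
    k_23: float
    FS_sp: float
    n23: float
    k_mp: float
    k_O2: float
    k_res: float
    O2_cyt: float

    def __post_init__(self) -> None:
        for name, (_, is_exp) in PARAM_FIELDS.items():
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"parameter {name} must be strictly positive, got {v}")
            if is_exp and v < 1.0:
                raise ValueError(f"exponent {name} must be >= 1, got {v}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StrainParameters":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StrainParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "StrainParameters":
        return dataclasses.replace(self, **changes)

    def diff(self, other: "StrainParameters") -> list[str]:
        """Names of kinetic parameters whose values differ from ``other``."""
        return [
            name
            for name in PARAM_FIELDS
            if getattr(self, name) != getattr(other, name)
        ]


@dataclass(frozen=True)
class Condition:
    """One growth condition: strain and total nutrient iron N (uM).

    N is total medium iron, i.e. added ferric citrate plus the ~1 uM of
    endogenous iron in minimal medium; the canonical data grid is
    {1, 2, 11, 41} uM.
    """

    strain: str
    N: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain", normalize_strain(self.strain))
        if self.N < 0:
            raise ValueError(f"nutrient iron N must be >= 0, got {self.N}")


CANONICAL_N_GRID = (1.0, 2.0, 11.0, 41.0)


def canonical_conditions(strains: Iterable[str] = STRAINS) -> list[Condition]:
    """The 8 canonical strain x N conditions of the reference dataset."""
    return [Condition(s, n) for s in strains for n in CANONICAL_N_GRID]


def _load_canonical_yaml() -> dict:
    text = resources.files("yeastiron.data").joinpath("canonical_parameters.yaml").read_text()
    return yaml.safe_load(text)


def canonical_parameters(strain: str) -> StrainParameters:
    """Return the bundled optimized parameter set for ``strain`` (WT or DD).

    Shared parameters are identical across strains; the strains differ only in
    the whole-cell/cytosolic import Vmax (R_cell_max, R_cyt_max), the
    mitochondrial import rate constant (k_mit, and its three-compartment-tier
    value k_mit_c3), the vacuolar nanoparticle rate constant k_vp, and the
    growth half-saturation K_alpha.
    """
    strain = normalize_strain(strain)
    doc = _load_canonical_yaml()
    values = dict(doc["shared"])
    values.update(doc["strains"][strain])
    return StrainParameters(strain=strain, **values)
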