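"""Assembly of the C1/C3/C4/C9 ODE systems and tier-collapse maps.

Tier state vectors (all uM):

* C1: ``Fe_cell`` — all cell iron as one species.
* C3: ``Fe_cyt, Fe_mit, Fe_vac`` — one species per compartment.
* C4: ``C, CIA, Fe_mit, Fe_vac`` — cytosolic iron split into labile Fe(II)
  (``C``) and cytosolic/nuclear ISC + low-spin heme iron (``CIA``).
* C9: ``C, CIA, FM, FS, MP, F2, F3, VP, O2`` — adds mitochondrial labile
  Fe(II) (FM), ISC/heme centers (FS), nanoparticles (MP), vacuolar Fe(II)/
  Fe(III) (F2/F3), vacuolar nanoparticles (VP) and matrix oxygen (O2).

Every component equation carries the growth-dilution term ``-alpha*[X]``.
Transfer into an organelle is scaled by the volume ratio f_cyt/f_organelle so
that moles are conserved when material changes compartment; efflux terms from
the cytosol carry no factor.

In the C3 tier the substrate of the mitochondrial and vacuolar import laws is
the labile cytosolic pool, which at that tier *is* the whole cytosolic pool
(no CIA component exists), so the rate constants keep their meaning unchanged
across tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .params import CompartmentGeometry, Condition, StrainParameters
from .rate_laws import RateVector, growth_rate, hill_rate, mass_action_rate, reg_fs

__all__ = [
    "TIER_COMPONENTS",
    "CellState",
    "OdeSystem",
    "build_system",
    "collapse_state",
    "whole_cell_total",
    "DEFAULT_INITIAL_IRON",
]

TIERS = ("C1", "C3", "C4", "C9")

TIER_COMPONENTS: dict[str, tuple[str, ...]] = {
    "C1": ("Fe_cell",),
    "C3": ("Fe_cyt", "Fe_mit", "Fe_vac"),
    "C4": ("C", "CIA", "Fe_mit", "Fe_vac"),
    "C9": ("C", "CIA", "FM", "FS", "MP", "F2", "F3", "VP", "O2"),
}

#: canonical initial condition: 10 uM for every iron component, 0 uM for O2
DEFAULT_INITIAL_IRON = 10.0


@dataclass(frozen=True)
class CellState:
    """Tier-tagged vector of component concentrations (uM)."""

    tier: str
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.tier not in TIER_COMPONENTS:
            raise ValueError(f"unknown tier {self.tier!r}")
        expected = TIER_COMPONENTS[self.tier]
        got = tuple(self.components)
        if set(got) != set(expected):
            raise ValueError(
                f"tier {self.tier} expects components {expected}, got {got}"
            )
        for name, v in self.components.items():
            if v < 0:
                raise ValueError(f"concentration {name} must be >= 0, got {v}")
        object.__setattr__(
            self, "components", {k: float(self.components[k]) for k in expected}
        )

    def __getitem__(self, name: str) -> float:
        return self.components[name]

    def to_array(self) -> np.ndarray:
        return np.array([self.components[c] for c in TIER_COMPONENTS[self.tier]])

    @classmethod
    def from_array(cls, tier: str, y: np.ndarray) -> "CellState":
        names = TIER_COMPONENTS[tier]
        if len(y) != len(names):
            raise ValueError(f"tier {tier} needs {len(names)} components, got {len(y)}")
        return cls(tier, dict(zip(names, np.maximum(np.asarray(y, float), 0.0))))


@dataclass(frozen=True)
class OdeSystem:
    """One assembled model: tier, condition, parameters and right-hand side."""

    tier: str
    condition: Condition
    params: StrainParameters
    geometry: CompartmentGeometry
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        if self.tier not in TIER_COMPONENTS:
            raise ValueError(f"unknown tier {self.tier!r}")
        object.__setattr__(
            self,
            "alpha",
            growth_rate(self.condition.N, self.params.alpha_max, self.params.K_alpha),
        )

    # -- state handling ---------------------------------------------------
    @property
    def components(self) -> tuple[str, ...]:
        return TIER_COMPONENTS[self.tier]

    @property
    def dim(self) -> int:
        return len(self.components)

    def initial_state(self, iron: float = DEFAULT_INITIAL_IRON) -> np.ndarray:
        y0 = np.full(self.dim, float(iron))
        if self.tier == "C9":
            y0[-1] = 0.0  # O2 starts at zero
        return y0

    # -- rates ------------------------------------------------------------
    def rates(self, y: np.ndarray) -> RateVector:
        """Instantaneous rates at state ``y`` (negative entries clipped)."""
        p, g = self.params, self.geometry
        N = self.condition.N
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        a = self.alpha
        if self.tier == "C1":
            return RateVector(alpha=a, R_cell=hill_rate(N, p.R_cell_max, p.K_N, p.sens))

        R_cyt = hill_rate(N, p.R_cyt_max, p.K_N, p.sens)
        if self.tier == "C3":
            C = y[0]  # labile cytosolic iron == whole cytosolic pool at C3
            k_mit = p.k_mit_c3
        else:
            C = y[0]
            k_mit = p.k_mit_c3 if self.tier == "C4" else p.k_mit
        R_mit = mass_action_rate(k_mit, C)
        R_vac = hill_rate(C, p.R_vac_max, p.K_vac, p.nvac)
        common = dict(alpha=a, R_cell=g.f_cyt * R_cyt, R_cyt=R_cyt, R_mit=R_mit, R_vac=R_vac)
        if self.tier == "C3":
            return RateVector(**common)
        R_cia = hill_rate(C, p.R_cia_max, p.K_cia, p.ncia)
        if self.tier == "C4":
            return RateVector(**common, R_cia=R_cia)
        _, _, FM, FS, MP, F2, F3, VP, O2 = y
        return RateVector(
            **common,
            R_cia=R_cia,
            R_isu=hill_rate(FM, p.R_isu_max, p.K_isu, p.nisu),
            R_23=p.k_23 * F2 * reg_fs(FS, p.FS_sp, p.n23),
            R_vp=mass_action_rate(p.k_vp, F3, p.nvp),
            R_mp=p.k_mp * FM * O2,
            R_res=p.k_res * FS * O2,
            R_O2=p.k_O2 * max(p.O2_cyt - O2, 0.0),
        )

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative (uM/hr) at state ``y``; defined for all y >= 0."""
        if len(y) != self.dim:
            raise ValueError(
                f"state dimension {len(y)} inconsistent with tier {self.tier}"
            )
        r = self.rates(y)
        a = self.alpha
        g = self.geometry
        yc = np.maximum(np.asarray(y, dtype=float), 0.0)
        if self.tier == "C1":
            return np.array([r.R_cell - a * yc[0]])
        if self.tier == "C3":
            Fe_cyt, Fe_mit, Fe_vac = yc
            return np.array(
                [
                    r.R_cyt - r.R_mit - r.R_vac - a * Fe_cyt,
                    r.R_mit / g.mit_over_cyt - a * Fe_mit,
                    r.R_vac / g.vac_over_cyt - a * Fe_vac,
                ]
            )
        if self.tier == "C4":
            C, CIA, Fe_mit, Fe_vac = yc
            return np.array(
                [
                    r.R_cyt - r.R_mit - r.R_vac - r.R_cia - a * C,
                    r.R_cia - a * CIA,
                    r.R_mit / g.mit_over_cyt - a * Fe_mit,
                    r.R_vac / g.vac_over_cyt - a * Fe_vac,
                ]
            )
        C, CIA, FM, FS, MP, F2, F3, VP, O2 = yc
        # R_O2 uses the raw (unclipped) O2 so that overshoot relaxes back
        R_O2 = self.params.k_O2 * (self.params.O2_cyt - y[-1])
        return np.array(
            [
                r.R_cyt - r.R_mit - r.R_vac - r.R_cia - a * C,
                r.R_cia - a * CIA,
                r.R_mit / g.mit_over_cyt - r.R_isu - r.R_mp - a * FM,
                r.R_isu - a * FS,
                r.R_mp - a * MP,
                r.R_vac / g.vac_over_cyt - r.R_23 - a * F2,
                r.R_23 - r.R_vp - a * F3,
                r.R_vp - a * VP,
                R_O2 - r.R_mp - r.R_res - a * y[-1],
            ]
        )

    def state(self, y: np.ndarray) -> CellState:
        return CellState.from_array(self.tier, y)


def build_system(
    tier: str,
    condition: Condition,
    p: StrainParameters,
    g: CompartmentGeometry | None = None,
) -> OdeSystem:
    """Assemble the ODE system for one tier at one growth condition."""
    if g is None:
        g = CompartmentGeometry()
    return OdeSystem(tier=tier, condition=condition, params=p, geometry=g)


def collapse_state(fine: CellState) -> CellState:
    """Collapse a C4 or C9 state onto the three-compartment (C3) pools.

    Fe_cyt = C + CIA;  Fe_mit = FM + FS + MP;  Fe_vac = F2 + F3 + VP.
    Oxygen is dropped (it is not an iron pool).
    """
    c = fine.components
    if fine.tier == "C9":
        pools = {
            "Fe_cyt": c["C"] + c["CIA"],
            "Fe_mit": c["FM"] + c["FS"] + c["MP"],
            "Fe_vac": c["F2"] + c["F3"] + c["VP"],
        }
    elif fine.tier == "C4":
        pools = {
            "Fe_cyt": c["C"] + c["CIA"],
            "Fe_mit": c["Fe_mit"],
            "Fe_vac": c["Fe_vac"],
        }
    else:
        raise ValueError(f"collapse_state needs a C4 or C9 state, got {fine.tier}")
    return CellState("C3", pools)


def whole_cell_total(state: CellState, g: CompartmentGeometry) -> float:
    """Volume-fraction-weighted whole-cell iron concentration (uM)."""
    if state.tier == "C1":
        raise ValueError("whole_cell_total needs a compartmentalized (>= C3) state")
    s = state if state.tier == "C3" else collapse_state(state)
    c = s.components
    return g.f_cyt * c["Fe_cyt"] + g.f_mit * c["Fe_mit"] + g.f_vac * c["Fe_vac"]
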