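"""Expanding-steady-state solving and steady-state algebra checks.

The steady state is found by integrate-and-check: the stiff C9 system couples
slow growth dilution (~0.05/hr) to fast oxygen relaxation (k_O2 = 25/hr plus a
respiration term k_res*[FS] that can exceed 1e4/hr), so an implicit/LSODA
integrator is run over expanding horizons until the relative rate of change
falls below tolerance, after which the algebraic system is root-polished.
Integrating from the canonical initial conditions (rather than root-finding
blindly) matters: the C9 mitochondrial subsystem can be bistable in
iron-starved mutant cells, and the physically reached branch is the one the
trajectory selects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .ode_models import CellState, OdeSystem
from .params import Condition
from .rate_laws import RateVector

__all__ = ["SteadyStateResult", "solve_steady", "steady_residuals", "attractor_probe"]

DEFAULT_TOL = 1e-9
DEFAULT_T_MAX = 1e4


@dataclass(frozen=True)
class SteadyStateResult:
    """A converged (or honestly flagged non-converged) steady state."""

    condition: Condition
    state: CellState
    rates: RateVector
    residuals: np.ndarray  # rhs at the state, uM/hr per component
    converged: bool
    t_final: float
    system: OdeSystem

    @property
    def max_relative_residual(self) -> float:
        y = self.state.to_array()
        scale = np.maximum(np.abs(y), 1.0)
        return float(np.max(np.abs(self.residuals) / scale))

    def component(self, name: str) -> float:
        return self.state[name]


def _relative_rate(system: OdeSystem, y: np.ndarray) -> float:
    dy = system.rhs(0.0, y)
    return float(np.max(np.abs(dy) / np.maximum(np.abs(y), 1.0)))


def solve_steady(
    system: OdeSystem,
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
    y0: np.ndarray | None = None,
    polish: bool = True,
) -> SteadyStateResult:
    """Integrate ``system`` from its canonical initial conditions to steady state.

    Convergence criterion: max_i |d[X_i]/dt| / max(|[X_i]|, 1 uM) < tol.  The
    integration runs over geometrically expanding horizons up to ``t_max`` hr;
    if the criterion is never met the result is returned with
    ``converged=False`` rather than raising.  When converged (and ``polish``),
    the algebraic steady-state system is root-polished to tighten residuals.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    y = system.initial_state() if y0 is None else np.asarray(y0, dtype=float)
    if len(y) != system.dim:
        raise ValueError("initial state dimension inconsistent with tier")
    t = 0.0
    horizon = 10.0
    converged = _relative_rate(system, y) < tol
    while not converged and t < t_max:
        t_next = min(t + horizon, t_max)
        sol = solve_ivp(
            system.rhs,
            (t, t_next),
            y,
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
            dense_output=False,
        )
        if not sol.success:  # fall back to BDF on a rare LSODA failure
            sol = solve_ivp(system.rhs, (t, t_next), y, method="BDF", rtol=1e-8, atol=1e-10)
        y = np.maximum(sol.y[:, -1], 0.0)
        t = t_next
        horizon *= 4.0
        converged = _relative_rate(system, y) < tol

    if converged and polish:
        y = _polish(system, y)

    residuals = system.rhs(0.0, y)
    return SteadyStateResult(
        condition=system.condition,
        state=system.state(y),
        rates=system.rates(y),
        residuals=residuals,
        converged=converged,
        t_final=t,
        system=system,
    )


def _polish(system: OdeSystem, y: np.ndarray) -> np.ndarray:
    """Root-polish the algebraic steady state; keep only a nearby valid root."""
    sol = root(lambda z: system.rhs(0.0, z), y, method="hybr", tol=1e-13)
    z = sol.x
    if not sol.success:
        return y
    if np.any(z < -1e-9 * np.maximum(np.abs(y), 1.0)):
        return y
    scale = np.maximum(np.abs(y), 1.0)
    if np.max(np.abs(z - y) / scale) > 1e-3:  # drifted to a different root
        return y
    return np.maximum(z, 0.0)


def steady_residuals(res: SteadyStateResult) -> dict[str, float]:
    """Per-equation imbalance (uM/hr) of the C9 steady-state algebra.

    Returns the left-minus-right imbalance of each steady balance: the
    cytosolic budget, the two organelle import budgets (volume-ratio scaled),
    the five production = dilution identities, and the oxygen balance.
    """
    if res.state.tier != "C9":
        raise ValueError("steady_residuals needs a C9 result")
    r = res.rates
    a = r.alpha
    g = res.system.geometry
    c = res.state.components
    return {
        "cytosol": r.R_cyt - (r.R_mit + r.R_vac + r.R_cia + a * c["C"]),
        "mito_import": r.R_mit - g.mit_over_cyt * (r.R_isu + r.R_mp + a * c["FM"]),
        "vac_import": r.R_vac - g.vac_over_cyt * (r.R_23 + a * c["F2"]),
        "cia": r.R_cia - a * c["CIA"],
        "isu": r.R_isu - a * c["FS"],
        "vp": r.R_vp - a * c["VP"],
        "f23": r.R_23 - (r.R_vp + a * c["F3"]),
        "mp": r.R_mp - a * c["MP"],
        "o2": r.R_O2 - (r.R_mp + r.R_res + a * c["O2"]),
    }


def attractor_probe(
    system: OdeSystem,
    scales: tuple[float, ...] = (0.1, 1.0, 10.0),
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
) -> list[SteadyStateResult]:
    """Steady states reached from initial conditions scaled by each factor.

    Used to probe whether a condition has a single global attractor; mutant
    cells under iron starvation are a known bistable case (diseased
    nanoparticle branch vs healthy ISC branch).
    """
    out = []
    for s in scales:
        y0 = system.initial_state() * s
        out.append(solve_steady(system, tol=tol, t_max=t_max, y0=y0))
    return out
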