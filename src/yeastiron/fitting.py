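"""ERR objective, coordinate-descent optimizer, tiered fitting, sensitivity.

The objective is the normalized mean relative error

    ERR = mean over datapoints of 2*|sim - dat| / (sim + dat),

which weighs every datapoint evenly regardless of magnitude (pools span four
orders of magnitude).  Optimization is derivative-free coordinate descent:
each parameter in turn is multiplied by (1 +/- step) and a candidate is kept
only if it strictly lowers ERR; the step schedule is +/-10%, then 5%, then 1%.
Within each step size full parameter sweeps are repeated until a sweep accepts
nothing, which keeps the procedure deterministic and strictly descending
while letting parameters travel more than one step from their start.

The tiers are fitted in order of increasing complexity, transferring the
optimized parameters of each stage to the next: growth/import constants from
the one-pool tier, organelle import constants from the three-pool tier, the
cytosolic ISC rate from the four-pool tier, and the remaining speciation,
regulation and oxygen constants from the full nine-component tier.  Between
the four- and nine-component stages the mitochondrial import constant is
rescaled (doubled for WT, divided by 1.3 for the deletion strain) before
refinement — the adjustment needed so that healthy mitochondria exclude
oxygen while ISC-assembly mutants still accumulate nanoparticles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .mb_data import ObservationRecord, POOL_NAMES
from .params import StrainParameters, STRAINS
from .rate_laws import growth_rate, hill_rate, mass_action_rate
from .ode_models import build_system
from .steady_state import solve_steady

__all__ = [
    "err_metric",
    "coordinate_descent",
    "fit_tiered",
    "fit_c1",
    "fit_c3",
    "fit_c4",
    "fit_c9",
    "sensitivity_scan",
    "FitResult",
    "SensitivityReport",
    "DEFAULT_SCHEDULE",
]

DEFAULT_SCHEDULE = (0.10, 0.05, 0.01)


def err_metric(sim: Sequence[float], dat: Sequence[float]) -> float:
    """Mean of 2|sim-dat|/(sim+dat) over paired values.

    Pairs with sim+dat == 0 carry no information for a relative error and are
    skipped with a warning.  Each term is bounded by 2 for positive values, so
    ERR <= 2.
    """
    sim = np.asarray(sim, dtype=float)
    dat = np.asarray(dat, dtype=float)
    if sim.shape != dat.shape:
        raise ValueError("sim and dat must have equal length")
    denom = sim + dat
    keep = denom != 0.0
    if not np.all(keep):
        warnings.warn(f"err_metric: skipped {int((~keep).sum())} zero-sum pair(s)")
    if not np.any(keep):
        raise ValueError("err_metric: no usable pairs")
    return float(np.mean(2.0 * np.abs(sim[keep] - dat[keep]) / denom[keep]))


@dataclass
class FitResult:
    """Optimized parameters and bookkeeping for one fitting stage."""

    tier: str
    parameters: dict[str, float]  # flat parameter vector (see key convention)
    err_value: float
    history: list[tuple[str, float, float, bool]] = field(default_factory=list)
    datapoints_used: list[tuple[str, float, str]] = field(default_factory=list)

    @property
    def accepted_moves(self) -> list[tuple[str, float, float, bool]]:
        return [h for h in self.history if h[3]]

    def moved_parameters(self) -> set[str]:
        return {h[0] for h in self.accepted_moves}


@dataclass(frozen=True)
class SensitivityReport:
    """One-at-a-time +/-1% sensitivity indices around an optimum."""

    err_opt: float
    indices: dict[str, float]

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.indices.items(), key=lambda kv: -kv[1])


def coordinate_descent(
    objective: Callable[[Mapping[str, float]], float],
    params: Mapping[str, float],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    max_sweeps: int = 60,
    max_passes: int = 8,
) -> FitResult:
    """Deterministic multiplicative coordinate descent.

    For each step size in ``schedule``, parameters are cycled in their given
    order; each is tried at value*(1+step) and value*(1-step) and a candidate
    is accepted only if it strictly lowers the objective (ties reject, for
    determinism).  Sweeps at one step size repeat until a sweep accepts no
    candidate (or ``max_sweeps`` is hit), and the whole coarse-to-fine
    schedule is re-run until a full pass accepts nothing (correlated
    parameters travel along shallow valleys this way).  The final objective
    never exceeds the initial one.
    """
    current = dict(params)
    err = objective(current)
    if not math.isfinite(err):
        raise ValueError("objective is not finite at the starting point")
    history: list[tuple[str, float, float, bool]] = []
    for _ in range(max_passes):
        pass_improved = False
        for step in schedule:
            for _ in range(max_sweeps):
                improved = False
                for name in current:
                    for sign in (+1.0, -1.0):
                        cand = current[name] * (1.0 + sign * step)
                        trial = dict(current)
                        trial[name] = cand
                        try:
                            e = objective(trial)
                        except (ValueError, FloatingPointError):
                            e = math.inf
                        if not math.isfinite(e):
                            history.append((name, cand, math.inf, False))
                            continue
                        accept = e < err
                        history.append((name, cand, e, accept))
                        if accept:
                            current[name] = cand
                            err = e
                            improved = True
                            pass_improved = True
                            break  # take the first improving direction, move on
                if not improved:
                    break
        if not pass_improved:
            break
    return FitResult(tier="", parameters=current, err_value=err, history=history)


# ---------------------------------------------------------------------------
# parameter-vector plumbing
#
# Flat fit vectors use plain names for strain-shared parameters and
# "name@WT" / "name@DD" for strain-specific ones.
# ---------------------------------------------------------------------------

def apply_flat(base: Mapping[str, StrainParameters], flat: Mapping[str, float]) -> dict[str, StrainParameters]:
    """Overlay a flat fit vector onto per-strain parameter sets."""
    out = {}
    for strain, p in base.items():
        changes = {}
        for key, v in flat.items():
            if "@" in key:
                name, s = key.split("@", 1)
                if s == strain:
                    changes[name] = v
            else:
                changes[key] = v
        out[strain] = p.replace(**changes)
    return out


def flat_from(base: Mapping[str, StrainParameters], shared: Iterable[str], per_strain: Iterable[str]) -> dict[str, float]:
    """Extract a flat starting vector from per-strain parameter sets."""
    any_strain = next(iter(base.values()))
    flat = {name: getattr(any_strain, name) for name in shared}
    for name in per_strain:
        for strain in base:
            flat[f"{name}@{strain}"] = getattr(base[strain], name)
    return flat


def _check_identifiability(tier: str, n_points: int, n_params: int) -> None:
    if n_points < n_params:
        warnings.warn(
            f"{tier} stage has {n_points} datapoints for {n_params} free "
            "parameters; the stage runs but is under-determined"
        )


def _records_by_strain(observations: Sequence[ObservationRecord]) -> dict[str, list[ObservationRecord]]:
    by = {s: [] for s in STRAINS}
    for rec in observations:
        by[rec.condition.strain].append(rec)
    for s, recs in by.items():
        if len({r.condition.N for r in recs}) < 2:
            warnings.warn(f"fewer than 2 nutrient levels for strain {s}")
    return by


# -- scalar steady-state helpers (cytosolic budget at the C3/C4 tiers) ------

def _c3_cyt_steady(p: StrainParameters, N: float, alpha: float, with_cia: bool) -> float:
    """Labile cytosolic iron at the C3 (or C4, with_cia=True) steady state."""
    R_cyt = hill_rate(N, p.R_cyt_max, p.K_N, p.sens)

    def f(x: float) -> float:
        out = R_cyt - mass_action_rate(p.k_mit_c3, x) - hill_rate(x, p.R_vac_max, p.K_vac, p.nvac) - alpha * x
        if with_cia:
            out -= hill_rate(x, p.R_cia_max, p.K_cia, p.ncia)
        return out

    hi = R_cyt / alpha if alpha > 0 else 1e9
    return brentq(f, 0.0, max(hi, 1.0), xtol=1e-12, rtol=1e-14)


# ---------------------------------------------------------------------------
# fitting stages
# ---------------------------------------------------------------------------

def _c1_data_driven_start(by: dict[str, list[ObservationRecord]]) -> dict[str, float]:
    """Linearized starting guesses for the stage-1 laws.

    Growth: double-reciprocal regression 1/alpha = 1/a_max + (K/a_max)/N per
    strain.  Import: logit regression ln(R/(Vmax-R)) = n*ln(N) - n*ln(K) with
    Vmax set just above the largest observed rate.  These closed forms put the
    descent inside the right valley; the schedule does the polishing.
    """
    flat: dict[str, float] = {}
    amax_est, kn_est, sens_est = [], [], []
    for s, recs in by.items():
        N = np.array([r.condition.N for r in recs], float)
        al = np.array([r.alpha_dat for r in recs], float)
        R = np.array([r.fluxes_dat.R_cell for r in recs], float)
        keep = (al > 0) & (N > 0)
        b, a = np.polyfit(1.0 / N[keep], 1.0 / al[keep], 1)  # slope, intercept
        a = max(a, 1e-12)
        amax_est.append(1.0 / a)
        flat[f"K_alpha@{s}"] = max(b / a, 1e-6)
        vmax0 = 1.25 * float(R.max())
        keep = (R > 0) & (R < vmax0)
        n, c = np.polyfit(np.log(N[keep]), np.log(R[keep] / (vmax0 - R[keep])), 1)
        n = min(max(n, 1.0), 6.0)
        flat[f"R_cell_max@{s}"] = vmax0
        sens_est.append(n)
        kn_est.append(float(np.exp(-c / n)))
    flat["alpha_max"] = float(np.mean(amax_est))
    flat["sens"] = float(np.mean(sens_est))
    flat["K_N"] = float(np.mean(kn_est))
    return flat


def fit_c1(
    observations: Sequence[ObservationRecord],
    base: Mapping[str, StrainParameters],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    init_from_data: bool = False,
) -> FitResult:
    """Stage 1: growth law and whole-cell import law against alpha and R_cell."""
    by = _records_by_strain(observations)
    flat0 = flat_from(base, shared=["alpha_max", "K_N", "sens"], per_strain=["K_alpha", "R_cell_max"])
    if init_from_data:
        flat0.update(_c1_data_driven_start(by))
    used = [(q, r.condition.N, r.condition.strain) for q in ("alpha", "R_cell")
            for s in STRAINS for r in by[s]]

    def objective(flat: Mapping[str, float]) -> float:
        ps = apply_flat(base, flat)
        sim, dat = [], []
        for s in STRAINS:
            p = ps[s]
            for r in by[s]:
                sim.append(growth_rate(r.condition.N, p.alpha_max, p.K_alpha))
                dat.append(r.alpha_dat)
                sim.append(hill_rate(r.condition.N, p.R_cell_max, p.K_N, p.sens))
                dat.append(r.fluxes_dat.R_cell)
        return err_metric(sim, dat)

    _check_identifiability("C1", len(used), len(flat0))
    res = coordinate_descent(objective, flat0, schedule)
    res.tier = "C1"
    res.datapoints_used = used
    return res


def fit_c3(
    observations: Sequence[ObservationRecord],
    base: Mapping[str, StrainParameters],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> FitResult:
    """Stage 2: organelle import laws against the compartment fluxes.

    The cytosolic import Vmax is initialized from the stage-1 whole-cell value
    (R_cyt_max = R_cell_max / f_cyt) and then re-optimized.
    """
    g = observations[0].geometry
    by = _records_by_strain(observations)
    base = {s: p.replace(R_cyt_max=p.R_cell_max / g.f_cyt) for s, p in base.items()}
    flat0 = flat_from(base, shared=["R_vac_max", "K_vac", "nvac"], per_strain=["k_mit_c3", "R_cyt_max"])
    used = [(q, r.condition.N, r.condition.strain) for q in ("R_mit", "R_vac", "R_cyt_only")
            for s in STRAINS for r in by[s]]

    def objective(flat: Mapping[str, float]) -> float:
        ps = apply_flat(base, flat)
        sim, dat = [], []
        for s in STRAINS:
            p = ps[s]
            for r in by[s]:
                alpha = r.alpha_dat
                x = _c3_cyt_steady(p, r.condition.N, alpha, with_cia=False)
                sim.extend([
                    mass_action_rate(p.k_mit_c3, x),
                    hill_rate(x, p.R_vac_max, p.K_vac, p.nvac),
                    alpha * x,
                ])
                f = r.fluxes_dat
                dat.extend([f.R_mit, f.R_vac, alpha * r.compartments_dat["Fe_cyt"]])
        return err_metric(sim, dat)

    _check_identifiability("C3", len(used), len(flat0))
    res = coordinate_descent(objective, flat0, schedule)
    res.tier = "C3"
    res.datapoints_used = used
    return res


def fit_c4(
    observations: Sequence[ObservationRecord],
    base: Mapping[str, StrainParameters],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> FitResult:
    """Stage 3: cytosolic ISC assembly rate law against R_cia."""
    by = _records_by_strain(observations)
    flat0 = flat_from(base, shared=["R_cia_max", "K_cia", "ncia"], per_strain=[])
    used = [("R_cia", r.condition.N, r.condition.strain) for s in STRAINS for r in by[s]]

    def objective(flat: Mapping[str, float]) -> float:
        ps = apply_flat(base, flat)
        sim, dat = [], []
        for s in STRAINS:
            p = ps[s]
            for r in by[s]:
                x = _c3_cyt_steady(p, r.condition.N, r.alpha_dat, with_cia=True)
                sim.append(hill_rate(x, p.R_cia_max, p.K_cia, p.ncia))
                dat.append(r.fluxes_dat.R_cia)
        return err_metric(sim, dat)

    _check_identifiability("C4", len(used), len(flat0))
    res = coordinate_descent(objective, flat0, schedule)
    res.tier = "C4"
    res.datapoints_used = used
    return res


K_MIT_RESCALE = {"WT": 2.0, "DD": 1.0 / 1.3}

C9_RATE_KEYS = ("R_cia", "R_isu", "R_vp", "R_23", "R_mp")


def _c9_objective_pairs(p: StrainParameters, rec: ObservationRecord):
    cond = rec.condition
    system = build_system("C9", cond, p, rec.geometry)
    res = solve_steady(system, tol=1e-7, t_max=2000.0)
    sim, dat, keys = [], [], []
    for q in POOL_NAMES:
        sim.append(res.state[q])
        dat.append(rec.pools_dat[q])
        keys.append((q, cond.N, cond.strain))
    r = res.rates
    f = rec.fluxes_dat
    for q in C9_RATE_KEYS:
        sim.append(getattr(r, q))
        dat.append(getattr(f, q))
        keys.append((q, cond.N, cond.strain))
    return sim, dat, keys


def fit_c9(
    observations: Sequence[ObservationRecord],
    base: Mapping[str, StrainParameters],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    rescale_k_mit: bool = True,
    max_sweeps: int = 60,
) -> FitResult:
    """Stage 4: full-model stage against all pools and formation rates.

    Before refinement the mitochondrial import constant inherited from the
    three-compartment stage is rescaled: doubled for WT and divided by 1.3
    for the deletion strain.
    """
    by = _records_by_strain(observations)
    if rescale_k_mit:
        base = {s: p.replace(k_mit=p.k_mit_c3 * K_MIT_RESCALE[s]) for s, p in base.items()}
    flat0 = flat_from(
        base,
        shared=["R_isu_max", "K_isu", "nisu", "nvp", "k_23", "FS_sp", "n23", "k_mp", "k_O2", "k_res"],
        per_strain=["k_vp", "k_mit"],
    )
    used: list[tuple[str, float, str]] = []

    def objective(flat: Mapping[str, float]) -> float:
        ps = apply_flat(base, flat)
        sim, dat = [], []
        for s in STRAINS:
            for r in by[s]:
                si, da, _ = _c9_objective_pairs(ps[s], r)
                sim.extend(si)
                dat.extend(da)
        return err_metric(sim, dat)

    for s in STRAINS:
        for r in by[s]:
            _, _, keys = _c9_objective_pairs(base[s], r)
            used.extend(keys)
    _check_identifiability("C9", len(used), len(flat0))
    res = coordinate_descent(objective, flat0, schedule, max_sweeps=max_sweeps)
    res.tier = "C9"
    res.datapoints_used = used
    return res


def fit_tiered(
    observations: Sequence[ObservationRecord],
    base: Mapping[str, StrainParameters],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    tiers: Sequence[str] = ("C1", "C3", "C4", "C9"),
    final_joint: bool = True,
    max_sweeps: int = 60,
) -> dict[str, FitResult]:
    """Run the multi-tier pipeline, transferring parameters between stages.

    Returns one FitResult per tier (plus a ``"joint"`` entry when the final
    all-parameter re-optimization pass is run).  Earlier-stage parameters are
    held fixed in later stages except for the prescribed mitochondrial-import
    rescale and the final joint pass.
    """
    current = dict(base)
    out: dict[str, FitResult] = {}
    stage_funcs = {"C1": fit_c1, "C3": fit_c3, "C4": fit_c4, "C9": fit_c9}
    for tier in tiers:
        res = stage_funcs[tier](observations, current, schedule)
        out[tier] = res
        current = apply_flat(current, res.parameters)
        if tier == "C3":
            # the C9 value starts from the C3 one until the C9 stage rescales it
            current = {s: p.replace(k_mit=p.k_mit_c3) for s, p in current.items()}
    if final_joint and "C9" in tiers:
        flat0 = flat_from(
            current,
            shared=["alpha_max", "K_N", "sens", "R_vac_max", "K_vac", "nvac",
                    "R_cia_max", "K_cia", "ncia", "R_isu_max", "K_isu", "nisu",
                    "nvp", "k_23", "FS_sp", "n23", "k_mp", "k_O2", "k_res"],
            per_strain=["K_alpha", "R_cell_max", "R_cyt_max", "k_mit_c3", "k_mit", "k_vp"],
        )
        by = _records_by_strain(observations)

        def joint_objective(flat: Mapping[str, float]) -> float:
            ps = apply_flat(current, flat)
            sim, dat = [], []
            for s in STRAINS:
                p = ps[s]
                for r in by[s]:
                    sim.append(growth_rate(r.condition.N, p.alpha_max, p.K_alpha))
                    dat.append(r.alpha_dat)
                    si, da, _ = _c9_objective_pairs(p, r)
                    sim.extend(si)
                    dat.extend(da)
            return err_metric(sim, dat)

        res = coordinate_descent(joint_objective, flat0, schedule, max_sweeps=max_sweeps)
        res.tier = "joint"
        out["joint"] = res
        current = apply_flat(current, res.parameters)
    out["final_parameters"] = current  # type: ignore[assignment]
    return out


def sensitivity_scan(
    objective: Callable[[Mapping[str, float]], float],
    params_opt: Mapping[str, float],
    delta: float = 0.01,
) -> SensitivityReport:
    """One-at-a-time sensitivity: S = (ERR(+d) + ERR(-d)) / (2 * ERR(opt)).

    S = 1 for a parameter the objective ignores; larger S means the fit
    degrades faster when that parameter is displaced from the optimum.
    """
    err_opt = objective(dict(params_opt))
    if err_opt == 0:
        raise ValueError("sensitivity index undefined at ERR(opt) = 0")
    indices = {}
    for name, v in params_opt.items():
        up = dict(params_opt)
        up[name] = v * (1.0 + delta)
        dn = dict(params_opt)
        dn[name] = v * (1.0 - delta)
        indices[name] = (objective(up) + objective(dn)) / (2.0 * err_opt)
    return SensitivityReport(err_opt=err_opt, indices=indices)
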