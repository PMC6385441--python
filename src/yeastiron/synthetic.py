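"""Synthetic observation tables generated from known ground-truth parameters.

The generator emulates the measurement structure of the real observation
tables: for each strain x nutrient-iron condition it solves the model to its
expanding steady state, converts the component pools into the Mössbauer
observables that are actually measured (whole-cell and mitochondrial
spectral-group concentrations, growth rate, whole-cell iron), applies
independent multiplicative lognormal noise to every observable, and then runs
the same pool-inversion and flux algebra a spectroscopist would apply to real
spectra.  Because all observables are positive and span four orders of
magnitude, multiplicative (lognormal, unit-mean) noise parameterized by a
coefficient of variation is the natural error model; the printed tables'
2-significant-figure rounding corresponds to an implicit CV of roughly
5-10%.

Noise is applied to the *observables* (groups, alpha, totals), not to the
inferred pools, mirroring what is measured; ground truth is recorded
alongside so recovery studies can score themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mb_data import MbGroups, ObservationRecord, POOL_NAMES, groups_from_pools, pools_from_groups
from .ode_models import build_system, whole_cell_total
from .params import CompartmentGeometry, Condition, StrainParameters
from .rate_laws import growth_rate
from .steady_state import solve_steady

__all__ = ["SyntheticConfig", "generate_observations", "noiseless_truth"]

DEFAULT_N_VALUES = (1.0, 2.0, 11.0, 41.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic dataset.

    ``source_tier`` selects which model tier generates the underlying truth
    (pool resolution degrades gracefully below C9: pools the tier does not
    resolve are zero).  ``noise_cv`` is the coefficient of variation of the
    unit-mean lognormal factor applied independently to every observable;
    ``seed`` fixes the entire output.
    """

    true_parameters: Mapping[str, StrainParameters]
    N_values: Sequence[float] = DEFAULT_N_VALUES
    noise_cv: float = 0.0
    seed: int = 0
    source_tier: str = "C9"
    geometry: CompartmentGeometry = field(default_factory=CompartmentGeometry)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.source_tier not in ("C1", "C3", "C4", "C9"):
            raise ValueError(f"unknown source tier {self.source_tier!r}")


def _pools_from_state(tier: str, state) -> dict[str, float]:
    """Map a steady state of any tier onto the nine-pool layout (zeros fill)."""
    c = state.components
    pools = dict.fromkeys(POOL_NAMES, 0.0)
    if tier == "C9":
        pools.update({k: c[k] for k in POOL_NAMES})
    elif tier == "C4":
        pools.update({"C": c["C"], "CIA": c["CIA"], "FM": c["Fe_mit"], "F2": c["Fe_vac"]})
    elif tier == "C3":
        pools.update({"C": c["Fe_cyt"], "FM": c["Fe_mit"], "F2": c["Fe_vac"]})
    return pools


def noiseless_truth(cfg: SyntheticConfig) -> list[dict]:
    """Solve the source tier at every condition; returns per-condition truth.

    Each entry carries the condition, alpha, whole-cell iron, the nine pools
    and the spectral groups, all noise-free.  Conditions whose steady-state
    solve does not converge are skipped with a warning.
    """
    out = []
    for strain, p in cfg.true_parameters.items():
        for N in cfg.N_values:
            cond = Condition(strain, N)
            system = build_system(cfg.source_tier, cond, p, cfg.geometry)
            res = solve_steady(system)
            if not res.converged:
                warnings.warn(f"steady state did not converge for {strain} N={N}; skipped")
                continue
            alpha = growth_rate(N, p.alpha_max, p.K_alpha)
            if cfg.source_tier == "C1":
                Fe_cell = res.state["Fe_cell"]
                pools = dict.fromkeys(POOL_NAMES, 0.0)
                pools["C"] = Fe_cell / cfg.geometry.f_cyt  # all iron nominally cytosolic
            else:
                Fe_cell = whole_cell_total(res.state, cfg.geometry)
                pools = _pools_from_state(cfg.source_tier, res.state)
            out.append(
                dict(
                    condition=cond,
                    alpha=alpha,
                    Fe_cell=Fe_cell,
                    pools=pools,
                    groups=groups_from_pools(pools, cfg.geometry),
                )
            )
    return out


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n)


#: observables receiving independent noise, in draw order (determinism contract)
OBSERVABLES = (
    "alpha", "Fe_cell", "C_assumed",
    "FeII_cell", "CD_cell", "NP_cell", "FeIII_cell",
    "FeII_mit", "CD_mit", "NPplusFeIII_mit",
)


def generate_observations(
    cfg: SyntheticConfig,
    truth: list[dict] | None = None,
) -> tuple[list[ObservationRecord], list[dict]]:
    """Generate noisy observation records plus the ground-truth table.

    ``truth`` may be passed to reuse a previously computed noiseless solution
    (the expensive part) when only the noise seed differs.
    """
    if truth is None:
        truth = noiseless_truth(cfg)
    rng = np.random.default_rng(cfg.seed)
    records, ground = [], []
    g = cfg.geometry
    for entry in truth:
        f = dict(zip(OBSERVABLES, _lognormal_factors(rng, cfg.noise_cv, len(OBSERVABLES))))
        gr = entry["groups"]
        noisy = MbGroups(
            FeII_cell=gr.FeII_cell * f["FeII_cell"],
            CD_cell=gr.CD_cell * f["CD_cell"],
            NP_cell=gr.NP_cell * f["NP_cell"],
            FeIII_cell=gr.FeIII_cell * f["FeIII_cell"],
            FeII_mit=gr.FeII_mit * f["FeII_mit"],
            CD_mit=gr.CD_mit * f["CD_mit"],
            NPplusFeIII_mit=gr.NPplusFeIII_mit * f["NPplusFeIII_mit"],
        )
        C_assumed = entry["pools"]["C"] * f["C_assumed"]
        try:
            pools = pools_from_groups(noisy, C_assumed, g)
        except ValueError:
            # noise pushed an inferred pool negative; clip the subtraction
            pools = _clipped_pools(noisy, C_assumed, g)
        rec = ObservationRecord(
            condition=entry["condition"],
            alpha_dat=entry["alpha"] * f["alpha"],
            Fe_cell_dat=entry["Fe_cell"] * f["Fe_cell"],
            pools_dat=pools,
            geometry=g,
        )
        records.append(rec)
        ground.append(dict(condition=entry["condition"], alpha=entry["alpha"],
                           Fe_cell=entry["Fe_cell"], pools=dict(entry["pools"])))
    return records, ground


def _clipped_pools(groups: MbGroups, C_assumed: float, g: CompartmentGeometry) -> dict[str, float]:
    return {
        "C": C_assumed,
        "FM": groups.FeII_mit,
        "FS": groups.CD_mit,
        "MP": groups.NPplusFeIII_mit,
        "F2": max((groups.FeII_cell - g.f_cyt * C_assumed - g.f_mit * groups.FeII_mit) / g.f_vac, 0.0),
        "CIA": max((groups.CD_cell - g.f_mit * groups.CD_mit) / g.f_cyt, 0.0),
        "VP": max((groups.NP_cell - g.f_mit * groups.NPplusFeIII_mit) / g.f_vac, 0.0),
        "F3": groups.FeIII_cell / g.f_vac,
    }


def effective_c1_truth(cfg: SyntheticConfig) -> dict[str, dict[str, float]]:
    """Observable-level truth for the whole-cell (C1) import parameters.

    When observations come from the compartmental model, the recoverable
    whole-cell import Vmax is f_cyt * R_cyt_max (total-iron balance:
    alpha*[Fe_cell] = f_cyt*R_cyt at steady state); for a C1 source it is
    R_cell_max itself.  alpha_max and K_alpha are observable directly.
    """
    out = {}
    for strain, p in cfg.true_parameters.items():
        if cfg.source_tier == "C1":
            vmax = p.R_cell_max
        else:
            vmax = cfg.geometry.f_cyt * p.R_cyt_max
        out[strain] = {"alpha_max": p.alpha_max, "K_alpha": p.K_alpha, "R_cell_max": vmax}
    return out
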