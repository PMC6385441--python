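"""Pure rate-law kernels shared by every model tier.

Every law maps non-negative concentrations to non-negative rates and is
monotone in its substrate.  Non-integer exponents (nisu=2.3, nvp=2.4, n23=1.6)
are evaluated as real powers of non-negative arguments; callers inside ODE
right-hand sides clip transient solver undershoot to zero before calling in.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "growth_rate",
    "hill_rate",
    "mass_action_rate",
    "reg_fs",
    "o2_matrix_steady",
    "RateVector",
]


def growth_rate(N: float, alpha_max: float, K_alpha: float) -> float:
    """Cell growth rate alpha(N) = alpha_max * N / (K_alpha + N), in 1/hr.

    Michaelis-Menten saturation of the exponential growth rate with nutrient
    iron: zero at N=0, approaching alpha_max as N -> infinity.
    """
    if N < 0:
        raise ValueError(f"nutrient iron N must be >= 0, got {N}")
    if alpha_max <= 0 or K_alpha <= 0:
        raise ValueError("alpha_max and K_alpha must be strictly positive")
    return alpha_max * N / (K_alpha + N)


def hill_rate(x: float, Vmax: float, K: float, n: float) -> float:
    """Hill rate Vmax * x^n / (K^n + x^n), in uM/hr.

    With n=1 this is the Michaelis-Menten form used for the growth rate;
    n>1 models cooperative (sigmoidal) transport or assembly.
    """
    if x < 0:
        raise ValueError(f"substrate must be >= 0, got {x}")
    if Vmax <= 0 or K <= 0:
        raise ValueError("Vmax and K must be strictly positive")
    if n < 1:
        raise ValueError(f"Hill exponent must be >= 1, got {n}")
    if x == 0.0:
        return 0.0
    xn = x**n
    return Vmax * xn / (K**n + xn)


def mass_action_rate(k: float, x: float, n: float = 1.0) -> float:
    """Mass-action rate k * x^n, in uM/hr (k may carry uM^(1-n)/hr units)."""
    if x < 0:
        raise ValueError(f"substrate must be >= 0, got {x}")
    if k < 0:
        raise ValueError(f"rate constant must be >= 0, got {k}")
    if n < 1:
        raise ValueError(f"exponent must be >= 1, got {n}")
    if x == 0.0:
        return 0.0
    return k * x**n


def reg_fs(FS: float, FS_sp: float, n23: float) -> float:
    """Iron-regulon valve 1 / (1 + (FS_sp/FS)^n23), dimensionless in [0, 1).

    Gates the vacuolar Fe(II)->Fe(III) conversion on iron-sulfur-cluster
    sufficiency: nearly closed (-> 0) when the mitochondrial ISC pool FS is far
    below its set point FS_sp, nearly open (-> 1) far above it, and exactly 1/2
    at the set point.  The FS=0 value is the continuous limit 0.
    """
    if FS < 0:
        raise ValueError(f"FS must be >= 0, got {FS}")
    if FS_sp <= 0:
        raise ValueError("FS_sp must be strictly positive")
    if n23 < 1:
        raise ValueError(f"n23 must be >= 1, got {n23}")
    if FS == 0.0:
        return 0.0
    try:
        ratio = (FS_sp / FS) ** n23
    except OverflowError:  # FS astronomically below set point: valve shut
        return 0.0
    return 1.0 / (1.0 + ratio)


def o2_matrix_steady(FM: float, FS: float, alpha: float, p) -> float:
    """Closed-form steady mitochondrial-matrix [O2] (uM).

    Balancing diffusion in, nanoparticle formation, respiration and dilution:

        [O2] = O2_cyt * k_O2 / (k_O2 + k_mp*FM + k_res*FS + alpha)

    Strictly decreasing in FM and FS, bounded above by the cytosolic
    concentration O2_cyt.  ``p`` is a StrainParameters-like object.
    """
    if FM < 0 or FS < 0 or alpha < 0:
        raise ValueError("FM, FS and alpha must be >= 0")
    return p.O2_cyt * p.k_O2 / (p.k_O2 + p.k_mp * FM + p.k_res * FS + alpha)


@dataclass(frozen=True)
class RateVector:
    """Instantaneous rates (uM/hr) and growth rate (1/hr) at one state.

    Fields not meaningful at a given tier are zero.
    """

    alpha: float = 0.0
    R_cell: float = 0.0
    R_cyt: float = 0.0
    R_mit: float = 0.0
    R_vac: float = 0.0
    R_cia: float = 0.0
    R_isu: float = 0.0
    R_23: float = 0.0
    R_vp: float = 0.0
    R_mp: float = 0.0
    R_res: float = 0.0
    R_O2: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate {f.name} must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
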