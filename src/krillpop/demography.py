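"""Closed-form demographic estimators and their inversions.

All quantities are scalars under a molecular-clock / mutation-drift-equilibrium
model: divergence time from synonymous divergence, effective population size
from Watterson's theta, scaled and absolute split times from genome-wide FST,
and the per-generation recombination rate from the population-scaled rate rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class SplitModelParams:
    """Scalar parameters of the split/divergence model.

    Units: ``D`` substitutions per site (synonymous), ``g`` years per
    generation, ``u`` mutations per site per generation, ``theta_w`` per base,
    ``fst`` dimensionless in [0, 1), ``T`` dimensionless (Reynolds-scaled
    time), ``t`` generations, ``ne`` individuals, ``rho`` per base,
    ``r`` per base per generation, ``locus_bp`` bases.
    """

    D: float | None = None
    g: float = 1.0
    u: float | None = None
    theta_w: float | None = None
    fst: float | None = None
    ne: float | None = None
    rho: float | None = None
    locus_bp: int | None = None
    derived: dict = field(default_factory=dict)


def divergence_time_years(D: float, g: float, u: float) -> float:
    """Split time in years under a constant clock: D * g / (2 u)."""
    if u <= 0:
        raise ValueError("mutation rate must be positive")
    return D * g / (2.0 * u)


def ne_from_theta(theta_w: float, u: float) -> float:
    """Long-term effective population size theta_W / (4 u)."""
    if u <= 0:
        raise ValueError("mutation rate must be positive")
    return theta_w / (4.0 * u)


def split_time_from_fst(fst: float) -> float:
    """Scaled split time T = -ln(1 - FST) / 2."""
    if not 0.0 <= fst < 1.0:
        raise ValueError("FST must be in [0, 1)")
    return -math.log(1.0 - fst) / 2.0


def fst_from_split_time(T: float) -> float:
    """Inverse of :func:`split_time_from_fst`: FST = 1 - exp(-2 T)."""
    return 1.0 - math.exp(-2.0 * T)


def generations(T: float, ne: float) -> float:
    """Generations since the split: t = T * 4 * Ne."""
    if ne <= 0:
        raise ValueError("Ne must be positive")
    return T * 4.0 * ne


def rec_rate_from_rho(rho: float, ne: float):
    """Invert rho = 4 * Ne * r; returns (r per bp per generation, cM/Mb)."""
    if ne <= 0:
        raise ValueError("Ne must be positive")
    r = rho / (4.0 * ne)
    return r, r * 1e8


def rho_from_rec_rate(r: float, ne: float) -> float:
    return 4.0 * ne * r


def theta_per_locus(theta_w: float, locus_bp: int) -> float:
    """Population mutation rate per simulation locus."""
    if locus_bp < 1:
        raise ValueError("locus length must be >= 1 bp")
    return theta_w * locus_bp


def report(params: SplitModelParams) -> dict[str, float]:
    """Evaluate every estimator whose inputs are present."""
    out: dict[str, float] = {}
    if params.D is not None and params.u is not None:
        out["divergence_time_years"] = divergence_time_years(params.D, params.g, params.u)
    if params.theta_w is not None and params.u is not None:
        out["ne"] = ne_from_theta(params.theta_w, params.u)
    ne = params.ne if params.ne is not None else out.get("ne")
    if params.fst is not None:
        out["T"] = split_time_from_fst(params.fst)
        if ne is not None:
            out["t_generations"] = generations(out["T"], ne)
    if params.rho is not None and ne is not None:
        out["r_per_bp"], out["r_cM_per_Mb"] = rec_rate_from_rho(params.rho, ne)
    if params.theta_w is not None and params.locus_bp is not None:
        out["theta_locus"] = theta_per_locus(params.theta_w, params.locus_bp)
    params.derived = out
    return out
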