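"""Rate-constant inference and flux classification from paired BafA assays.

Bafilomycin A (BafA) blocks lysosomal acidification, which in the kinetic
model acts as a multiplicative reduction of the AP->AL conversion rate
``beta`` and the AL degradation rate ``gamma`` while leaving the influx ``J``
unchanged (AP and AL pools are scored in animals of the same genotype and age,
so isolation-membrane supply is assumed constant across arms).

Because the steady-state pools are ``AP = J/beta`` and ``AL = J/gamma``, the
rate fold-changes are inversely related to the pool fold-changes: a threefold
increase in APs and a twofold increase in ALs under BafA implies a threefold
decrease in ``beta`` and a twofold decrease in ``gamma``.

The flux-assay decision logic: no significant change in either pool after
BafA indicates blocked autophagy; a change in either pool indicates active
autophagy, sub-labelled by the response pattern (AP up / AL down = complete
inhibition of acidification; AP up / AL up = partial inhibition, where
sluggish lysosomal enzymes let ALs accumulate too).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .kinetics import (
    KineticParameters,
    PoolState,
    closed_form_timecourse,
    steady_state_pools,
)

__all__ = [
    "UndefinedRatioError",
    "Perturbation",
    "ChangeCall",
    "FluxClass",
    "infer_rate_fold_changes",
    "apply_perturbation",
    "classify_flux",
    "equilibration_fraction",
    "is_equilibrated",
]

Direction = Literal["increase", "decrease", "none"]


class UndefinedRatioError(ValueError):
    """Raised when a pool ratio is undefined because a pool is zero."""


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative factors applied to beta and gamma; control is (1, 1)."""

    f_beta: float
    f_gamma: float

    def __post_init__(self) -> None:
        if not (self.f_beta > 0 and self.f_gamma > 0):
            raise ValueError(
                f"perturbation factors must be > 0, got ({self.f_beta}, {self.f_gamma})"
            )


@dataclass(frozen=True)
class ChangeCall:
    """Direction call for one pool's control-vs-treatment comparison."""

    direction: Direction
    p_value: float
    rate_ratio: float


@dataclass(frozen=True)
class FluxClass:
    """Flux status plus the BafA response pattern for active autophagy."""

    status: Literal["active", "blocked"]
    inhibition_pattern: Literal["complete", "partial", "other", "not_applicable"]


def infer_rate_fold_changes(control: PoolState, bafa: PoolState) -> Perturbation:
    """Infer (f_beta, f_gamma) from paired control/BafA steady-state pools.

    Assumes influx ``J`` is unchanged by treatment and both arms are at steady
    state, so ``f_beta = AP_control / AP_bafa`` and
    ``f_gamma = AL_control / AL_bafa``.
    """
    if control.ap <= 0 or control.al <= 0 or bafa.ap <= 0 or bafa.al <= 0:
        raise UndefinedRatioError(
            "all pools must be > 0 to infer rate fold-changes; got "
            f"control=({control.ap}, {control.al}), bafa=({bafa.ap}, {bafa.al})"
        )
    return Perturbation(f_beta=control.ap / bafa.ap, f_gamma=control.al / bafa.al)


def apply_perturbation(
    params: KineticParameters, pert: Perturbation
) -> KineticParameters:
    """Scale beta and gamma by the perturbation factors; influx unchanged."""
    return KineticParameters(
        influx_J=params.influx_J,
        beta=params.beta * pert.f_beta,
        gamma=params.gamma * pert.f_gamma,
        time_unit=params.time_unit,
    )


def classify_flux(ap_call: ChangeCall, al_call: ChangeCall) -> FluxClass:
    """Classify flux status from the AP and AL direction calls.

    (none, none) -> blocked.  Any other combination -> active, with pattern
    complete for (increase, decrease), partial for (increase, increase), and
    other for the remaining active combinations.  Total over the 3x3 grid.
    """
    pair = (ap_call.direction, al_call.direction)
    if pair == ("none", "none"):
        return FluxClass(status="blocked", inhibition_pattern="not_applicable")
    if pair == ("increase", "decrease"):
        return FluxClass(status="active", inhibition_pattern="complete")
    if pair == ("increase", "increase"):
        return FluxClass(status="active", inhibition_pattern="partial")
    return FluxClass(status="active", inhibition_pattern="other")


def equilibration_fraction(
    params: KineticParameters, pert: Perturbation, t: float = 2.0
) -> float:
    """Fraction of the way to the new steady state ``t`` hours after perturbation.

    The assay scores pools two hours after BafA injection on the premise that
    the perturbed system has re-equilibrated; that premise fails for slow rate
    constants.  Returns ``1 - ||x(t) - x_new|| / ||x(0) - x_new||`` (sup norm
    relative to each pool's total excursion), which is 1 at full equilibration.
    A system already at its new steady state returns 1.0.
    """
    base = steady_state_pools(params)
    new_params = apply_perturbation(params, pert)
    new_ss = steady_state_pools(new_params)
    traj = closed_form_timecourse(new_params, base, [0.0, t])
    gaps0 = (abs(base.ap - new_ss.ap), abs(base.al - new_ss.al))
    gaps_t = (abs(traj.ap[-1] - new_ss.ap), abs(traj.al[-1] - new_ss.al))
    rel = max(
        (gt / g0 if g0 > 0 else 0.0) for gt, g0 in zip(gaps_t, gaps0)
    )
    return 1.0 - rel


def is_equilibrated(
    params: KineticParameters,
    pert: Perturbation,
    t: float = 2.0,
    threshold: float = 0.95,
) -> bool:
    """Flag whether the perturbed system is >= ``threshold`` of the way to its
    new steady state at time ``t`` (default the assay's 2-hour read-out)."""
    frac = equilibration_fraction(params, pert, t)
    return bool(frac >= threshold or math.isclose(frac, threshold))
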