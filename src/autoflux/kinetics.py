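"""Deterministic core of the three-step autophagy model.

Material from the isolation membrane enters the autophagosome (AP) pool at a
constant influx ``J`` (vesicles per hour, the isolation-membrane concentration
lumped with its maturation rate constant), APs fuse with lysosomes to become
autolysosomes (ALs) at rate constant ``beta`` (per hour), and ALs are degraded
at rate constant ``gamma`` (per hour):

.. math::

    dAP/dt = J - \\beta\\,AP \\qquad dAL/dt = \\beta\\,AP - \\gamma\\,AL

At steady state the pools are ``AP = J/beta`` and ``AL = J/gamma``, and the
autophagic flux through every step equals ``J``.  The AP:AL pool ratio at
steady state equals ``gamma/beta``, so an AP pool smaller than the AL pool
implies ``gamma < beta`` (AL turnover rate-limiting).

The chain is linear, so the full time course has a closed form; a numerical
integrator is provided alongside it and the two are cross-checked in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InvalidParameterError",
    "NotAtSteadyStateError",
    "KineticParameters",
    "PoolState",
    "Trajectory",
    "steady_state_pools",
    "steady_state_flux",
    "pool_ratio",
    "simulate_timecourse",
    "closed_form_timecourse",
]


class InvalidParameterError(ValueError):
    """Raised when kinetic parameters violate their positivity constraints."""


class NotAtSteadyStateError(ValueError):
    """Raised when pools are inconsistent with the steady state of the parameters."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate parameters of the IM -> AP -> AL -> degradation chain.

    Parameters
    ----------
    influx_J
        Constant AP-formation rate, vesicles per ``time_unit``.  This is the
        lumped product of the isolation-membrane pool and its maturation rate
        constant; the two factors are never separately identifiable here.
    beta
        AP -> AL conversion rate constant, per ``time_unit``.
    gamma
        AL degradation rate constant, per ``time_unit``.
    time_unit
        Label only; defaults to ``"hour"``.
    """

    influx_J: float
    beta: float
    gamma: float
    time_unit: str = "hour"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.influx_J) and self.influx_J >= 0):
            raise InvalidParameterError(f"influx_J must be >= 0, got {self.influx_J}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise InvalidParameterError(f"gamma must be > 0, got {self.gamma}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "influx_J": self.influx_J,
                "beta": self.beta,
                "gamma": self.gamma,
                "time_unit": self.time_unit,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "KineticParameters":
        d = json.loads(s)
        return cls(
            influx_J=d["influx_J"],
            beta=d["beta"],
            gamma=d["gamma"],
            time_unit=d.get("time_unit", "hour"),
        )


@dataclass(frozen=True)
class PoolState:
    """AP and AL pool sizes (expected vesicle counts per observation unit)."""

    ap: float
    al: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ap) and self.ap >= 0):
            raise InvalidParameterError(f"ap must be >= 0, got {self.ap}")
        if not (np.isfinite(self.al) and self.al >= 0):
            raise InvalidParameterError(f"al must be >= 0, got {self.al}")

    def to_json(self) -> str:
        return json.dumps({"ap": self.ap, "al": self.al})

    @classmethod
    def from_json(cls, s: str) -> "PoolState":
        d = json.loads(s)
        return cls(ap=d["ap"], al=d["al"])


@dataclass(frozen=True)
class Trajectory:
    """Pool sizes over time; ``times`` strictly increasing, arrays aligned."""

    times: np.ndarray
    ap: np.ndarray
    al: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        al = np.asarray(self.al, dtype=float)
        if not (len(times) == len(ap) == len(al)):
            raise ValueError("times, ap and al must have equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "al", al)

    @property
    def states(self) -> list[PoolState]:
        return [PoolState(a, l) for a, l in zip(self.ap, self.al)]


def steady_state_pools(params: KineticParameters) -> PoolState:
    """Closed-form steady-state pools ``AP = J/beta``, ``AL = J/gamma``."""
    return PoolState(ap=params.influx_J / params.beta, al=params.influx_J / params.gamma)


def steady_state_flux(
    pools: PoolState, params: KineticParameters, rtol: float = 1e-9
) -> float:
    """Autophagic flux at steady state.

    At steady state the influx, the AP->AL conversion rate ``AP*beta`` and the
    AL degradation rate ``AL*gamma`` are all equal; their common value is the
    flux.  Raises :class:`NotAtSteadyStateError` if the supplied pools are not
    the steady state of ``params`` within relative tolerance ``rtol``.
    """
    j = params.influx_J
    scale = max(1.0, j)
    if abs(j - pools.ap * params.beta) > rtol * scale or abs(
        pools.ap * params.beta - pools.al * params.gamma
    ) > rtol * scale:
        raise NotAtSteadyStateError(
            f"pools (ap={pools.ap}, al={pools.al}) are not the steady state of "
            f"(J={j}, beta={params.beta}, gamma={params.gamma})"
        )
    return j


def pool_ratio(params: KineticParameters) -> float:
    """Steady-state AP:AL ratio; equals ``gamma/beta`` exactly.

    The ratio is inversely related to the ratio of the rate constants, so an
    observed AP pool smaller than the AL pool implies ``gamma < beta``.
    """
    return params.gamma / params.beta


def _validate_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if times[0] != 0:
        raise ValueError("times must start at 0")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def closed_form_timecourse(
    params: KineticParameters, init: PoolState, times
) -> Trajectory:
    """Analytic solution of the linear chain from ``init`` at the given times.

    AP relaxes exponentially to ``J/beta`` at rate ``beta``; AL is driven by AP
    and relaxes at rate ``gamma``.  The repeated-eigenvalue case ``beta ==
    gamma`` is handled by its own limit form (a ``t * exp(-beta t)`` secular
    term) rather than by perturbing parameters.
    """
    times = _validate_times(times)
    j, b, g = params.influx_J, params.beta, params.gamma
    ap_ss = j / b
    al_ss = j / g
    d = init.ap - ap_ss
    ap = ap_ss + d * np.exp(-b * times)
    if b == g:
        al = al_ss + (b * d * times + (init.al - al_ss)) * np.exp(-b * times)
    else:
        coef = b * d / (g - b)
        al = al_ss + coef * np.exp(-b * times) + (init.al - al_ss - coef) * np.exp(
            -g * times
        )
    # exact solution is non-negative for non-negative init; clip rounding dust
    return Trajectory(times=times, ap=np.maximum(ap, 0.0), al=np.maximum(al, 0.0))


def simulate_timecourse(
    params: KineticParameters,
    init: PoolState,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Numerically integrate the pool ODEs from ``init`` at the given times."""
    times = _validate_times(times)
    if len(times) == 1:
        return Trajectory(times=times, ap=np.array([init.ap]), al=np.array([init.al]))

    def rhs(_t, y):
        ap, al = y
        return [params.influx_J - params.beta * ap, params.beta * ap - params.gamma * al]

    sol = solve_ivp(
        rhs,
        t_span=(times[0], times[-1]),
        y0=[init.ap, init.al],
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(
        times=times, ap=np.maximum(sol.y[0], 0.0), al=np.maximum(sol.y[1], 0.0)
    )
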