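"""Trajectory integration and summary statistics.

The community ODE is stiff once grazer or parasite populations explode, so
integration uses SciPy's LSODA with a tight relative tolerance (1e-8) and
per-variable absolute tolerances scaled to the initial magnitudes.  States
are clamped to be non-negative at output times; inside the right-hand side
response functions already evaluate on ``max(state, 0)`` so transient
negative excursions of the adaptive stepper cannot flip signs in the
quotient terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    STATE_VARS,
    CommunityMask,
    CommunityState,
    ModelOptions,
    ParameterSet,
    _flux_tuple,
)

__all__ = [
    "Trajectory",
    "TrajectorySummary",
    "IntegrationError",
    "integrate_community",
    "prevalence_series",
    "summarize",
]


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:.4g} d)")
        self.last_time = last_time


@dataclass
class Trajectory:
    """States sampled on a uniform output grid.

    ``states`` has shape ``(n_times, 8)`` with columns in ``STATE_VARS``
    order, clamped to be non-negative.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 8):
            raise ValueError("times must be 1-D and states (n_times, 8)")
        if self.times.size and (self.times[0] != 0.0
                                or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must start at 0 and strictly increase")

    def series(self, var: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(var)]

    @property
    def prevalence(self) -> np.ndarray:
        return prevalence_series(self)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "time_d", self.times)
        df["prevalence_pct"] = self.prevalence
        return df


@dataclass
class TrajectorySummary:
    """Peak values, peak times (earliest attainment) and final values."""

    maxima: Dict[str, float]
    time_of_max: Dict[str, float]
    finals: Dict[str, float]
    max_prevalence: float
    day_of_max_prevalence: int
    time_of_max_prevalence: float

    def to_dict(self) -> dict:
        return {
            "maxima": dict(self.maxima),
            "time_of_max": dict(self.time_of_max),
            "finals": dict(self.finals),
            "max_prevalence_pct": self.max_prevalence,
            "day_of_max_prevalence": self.day_of_max_prevalence,
            "time_of_max_prevalence": self.time_of_max_prevalence,
        }


def integrate_community(
    initial: CommunityState,
    params: ParameterSet,
    mask: CommunityMask = CommunityMask(),
    horizon: float = 30.0,
    output_step: float = 0.1,
    options: ModelOptions = ModelOptions(),
    rtol: float = 1e-8,
    method: str = "LSODA",
    max_step: Optional[float] = None,
) -> Trajectory:
    """Integrate the community ODE over ``[0, horizon]`` days.

    Deterministic for fixed inputs.  Absolute tolerances are
    ``rtol * max(|y0_i|, 1)`` per variable so that state variables spanning
    eight orders of magnitude are resolved comparably.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if output_step <= 0:
        raise ValueError("output_step must be > 0")
    initial.validate(mask)

    active = mask.active_states()
    frozen = tuple(v in mask.frozen for v in STATE_VARS)
    p = params
    opt = options

    def rhs(t, y):
        terms = _flux_tuple(y, p, active, frozen, opt)
        return [sum(tv) for tv in terms]

    y0 = initial.to_array()
    n_out = int(round(horizon / output_step))
    t_eval = np.linspace(0.0, n_out * output_step, n_out + 1)
    t_eval = t_eval[t_eval <= horizon + 1e-12]
    atol = np.maximum(np.abs(y0), 1.0) * rtol
    sol = solve_ivp(
        rhs, (0.0, float(horizon)), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol,
        **({"max_step": max_step} if max_step else {}),
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(sol.message, last)
    return Trajectory(times=sol.t, states=np.maximum(sol.y.T, 0.0))


def prevalence_series(traj: Trajectory) -> np.ndarray:
    """Infection prevalence ``100 * I / (H + I)`` in percent, 0 where H+I=0."""
    H = traj.series("H")
    I = traj.series("I")
    tot = H + I
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(tot > 0.0, 100.0 * I / np.where(tot > 0, tot, 1.0), 0.0)
    return prev


def _first_peak_index(s: np.ndarray, rel: float = 1e-8) -> int:
    """Earliest index attaining the series maximum.

    Values within a relative tolerance of the maximum count as ties: on
    saturating series the floating-point argmax wanders along the plateau
    with integrator round-off, so ties are resolved at the accuracy the
    integration actually delivers (default 1e-8, matching ``rtol``).
    """
    mx = float(np.max(s))
    if mx <= 0.0:
        return int(np.argmax(s))
    return int(np.argmax(s >= mx * (1.0 - rel)))


def summarize(traj: Trajectory) -> TrajectorySummary:
    """Peaks, peak times and finals on the output grid.

    Peak times use the earliest attainment of the maximum (ties resolved
    at integrator accuracy); the prevalence peak day is additionally
    reported rounded to the nearest integer day.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    maxima, tmax, finals = {}, {}, {}
    for var in STATE_VARS:
        s = traj.series(var)
        i = _first_peak_index(s)
        maxima[var] = float(np.max(s))
        tmax[var] = float(traj.times[i])
        finals[var] = float(s[-1])
    prev = traj.prevalence
    ip = _first_peak_index(prev)
    return TrajectorySummary(
        maxima=maxima,
        time_of_max=tmax,
        finals=finals,
        max_prevalence=float(np.max(prev)),
        day_of_max_prevalence=int(round(float(traj.times[ip]))),
        time_of_max_prevalence=float(traj.times[ip]),
    )
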