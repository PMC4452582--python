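"""Cause-specific loss attribution and removal-effect intensities.

Two complementary measures quantify how community members suppress hosts
and parasites:

* integrated loss shares — each loss term of a state equation is
  re-evaluated along a simulated trajectory and integrated (trapezoid rule
  on the output grid) over a window, typically the *demise phase* from the
  variable's earliest peak to the end of the run; shares are percentages of
  the summed integrated losses.
* removal-effect intensity — the relative increase of a variable's maximum
  when a community member is excluded, ``100 * (max_without - max_with) /
  max_without``; a positive intensity marks the removed member as
  growth-limiting for that variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .model import (
    STATE_VARS,
    CommunityMask,
    CommunityState,
    FLUX_TERMS,
    ModelOptions,
    ParameterSet,
    decompose_fluxes,
)
from .simulate import Trajectory, _first_peak_index

__all__ = [
    "LossLedger",
    "RemovalEffect",
    "flux_series",
    "integrated_loss_shares",
    "demise_window",
    "removal_effect_intensity",
]

#: Loss (negative-signed) terms per state equation.
LOSS_TERMS: Dict[str, Tuple[str, ...]] = {
    "H": ("infection_loss", "ciliate_grazing"),
    "I": ("maturation_loss", "ciliate_grazing"),
    "P": ("infection_attachment_loss", "natural_mortality", "rotifer_grazing"),
    "D": ("ciliate_grazing",),
    "A": ("rotifer_grazing",),
    "N": ("uptake_h", "uptake_d", "uptake_a"),
}


class UndefinedShareError(ZeroDivisionError):
    """Total integrated loss is zero; shares are undefined."""


@dataclass
class LossLedger:
    """Integrated losses of one variable over a window, with shares."""

    variable: str
    window: Tuple[float, float]
    integrated: Dict[str, float]   # term -> time-integrated loss (state units)
    shares: Dict[str, float]       # term -> percent of total loss

    @property
    def total(self) -> float:
        return sum(self.integrated.values())


@dataclass
class RemovalEffect:
    """Effect of excluding one community member on one variable's maximum."""

    variable: str
    removed: str
    intensity: float          # percent; 0 when removal does not raise the max
    below_reporting_threshold: bool   # intensities < 1% are reported but flagged
    max_with: float
    max_without: float

    @property
    def phase(self) -> str:
        return "growth-limiting" if self.intensity > 0 else "none"


def flux_series(
    traj: Trajectory,
    params: ParameterSet,
    mask: CommunityMask = CommunityMask(),
    options: ModelOptions = ModelOptions(),
) -> Dict[str, Dict[str, np.ndarray]]:
    """Re-evaluate every named flux term along a trajectory's output grid."""
    out: Dict[str, Dict[str, np.ndarray]] = {
        var: {name: np.empty(traj.times.size) for name in FLUX_TERMS[var]}
        for var in STATE_VARS
    }
    for i in range(traj.times.size):
        fb = decompose_fluxes(
            CommunityState.from_array(traj.states[i]), params, mask, options
        )
        for var in STATE_VARS:
            for name, val in fb.terms[var].items():
                out[var][name][i] = val
    return out


def demise_window(traj: Trajectory, variable: str) -> Tuple[float, float]:
    """Window from a variable's earliest maximum to the end of the run."""
    s = traj.series(variable)
    if s.size == 0:
        raise ValueError("empty trajectory")
    i = _first_peak_index(s)
    return float(traj.times[i]), float(traj.times[-1])


def integrated_loss_shares(
    traj: Trajectory,
    params: ParameterSet,
    variable: str,
    window: Optional[Tuple[float, float]] = None,
    mask: CommunityMask = CommunityMask(),
    options: ModelOptions = ModelOptions(),
    terms: Optional[Sequence[str]] = None,
) -> LossLedger:
    """Integrate each loss term of ``variable`` over ``window``.

    ``window`` defaults to the whole run; pass ``demise_window(traj, var)``
    for post-peak attribution.  ``terms`` restricts the denominator (e.g.
    to exclude infection attachment from a "mortality" ledger); by default
    every loss term of the equation is counted.
    """
    if variable not in LOSS_TERMS:
        raise ValueError(f"{variable!r} has no loss terms")
    chosen = tuple(terms) if terms is not None else LOSS_TERMS[variable]
    unknown = set(chosen) - set(LOSS_TERMS[variable])
    if unknown:
        raise ValueError(f"unknown loss terms for {variable}: {sorted(unknown)}")
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    t0, t1 = window
    sel = (traj.times >= t0 - 1e-12) & (traj.times <= t1 + 1e-12)
    if not np.any(sel):
        raise ValueError("window does not overlap the trajectory")

    series = flux_series(traj, params, mask, options)[variable]
    t = traj.times[sel]
    integ = {}
    for name in chosen:
        loss = np.maximum(-series[name][sel], 0.0)
        integ[name] = float(np.trapezoid(loss, t)) if t.size > 1 else 0.0
    total = sum(integ.values())
    if total <= 0.0:
        raise UndefinedShareError(
            f"total integrated loss of {variable} over {window} is zero"
        )
    shares = {k: 100.0 * v / total for k, v in integ.items()}
    return LossLedger(variable=variable, window=(t0, t1),
                      integrated=integ, shares=shares)


def removal_effect_intensity(
    baseline: Trajectory,
    removed: Trajectory,
    variable: str,
    removed_member: str = "",
) -> RemovalEffect:
    """Intensity of a member's negative effect on one variable's maximum.

    ``baseline`` is the full-community run, ``removed`` the run without the
    tested member.  A maximum that increases upon removal marks the member
    as growth-limiting; the intensity is the relative increase in percent.
    Intensities below 1% are reported but flagged.
    """
    max_with = float(np.max(baseline.series(variable)))
    max_without = float(np.max(removed.series(variable)))
    if max_without <= 0.0:
        raise ValueError("maximum without the member is zero; intensity undefined")
    intensity = 100.0 * (max_without - max_with) / max_without
    intensity = max(intensity, 0.0)
    return RemovalEffect(
        variable=variable,
        removed=removed_member,
        intensity=intensity,
        below_reporting_threshold=intensity < 1.0,
        max_with=max_with,
        max_without=max_without,
    )
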