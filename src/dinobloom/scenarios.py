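"""Experiment designs: community configurations and initial conditions.

This module is the package's input generator.  Every experiment is built
programmatically from the published parameter table and the stated designs:
the three community-complexity scenarios at two trophic states, the
nitrate x competitor grid, the component-removal designs, and the rotifer
grazing assays.  No external data are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

from .model import (
    CommunityMask,
    CommunityState,
    ConfigurationError,
    MEMBERS,
    ParameterSet,
)

__all__ = [
    "ScenarioSpec",
    "GridSpec",
    "table1_defaults",
    "build_scenario",
    "nutrient_competition_grid",
    "removal_designs",
    "grazing_assay_design",
    "TROPHIC_NITRATE",
]

#: Nitrate forcing (uM) for the two trophic conditions: the values measured
#: before and after the experimental nutrient pulse in the source mesocosm.
TROPHIC_NITRATE: Dict[str, float] = {"oligo": 1.0, "eutro": 36.0}


@dataclass
class ScenarioSpec:
    """A fully specified simulation: who is present, where they start."""

    label: str
    mask: CommunityMask
    initial: CommunityState
    horizon: float = 30.0
    notes: str = ""

    def __post_init__(self) -> None:
        self.initial.validate(self.mask)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mask"]["frozen"] = sorted(self.mask.frozen)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        m = dict(d["mask"])
        m["frozen"] = frozenset(m.get("frozen", ()))
        return cls(
            label=d["label"],
            mask=CommunityMask(**m),
            initial=CommunityState(**d["initial"]),
            horizon=d.get("horizon", 30.0),
            notes=d.get("notes", ""),
        )


@dataclass
class GridSpec:
    """The nitrate x other-phytoplankton factorial design.

    The competitor total is split between nanophytoplankton and diatoms at
    the stated 99:1 ratio; each cell is run with and without parasites by
    default.
    """

    totals: Sequence[float] = (1e4, 1e5, 1e6, 1e7, 1e8, 1e9)
    nitrate: Sequence[float] = (0.5, 1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    nano_ratio: Tuple[float, float] = (99.0, 1.0)
    parasites: Sequence[bool] = (True, False)

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.totals) or any(n <= 0 for n in self.nitrate):
            raise ConfigurationError("grid levels must be > 0")
        if min(self.nano_ratio) < 0 or sum(self.nano_ratio) <= 0:
            raise ConfigurationError("invalid nano:diatom ratio")

    def split(self, total: float) -> Tuple[float, float]:
        """(nanophytoplankton, diatom) abundances summing to ``total``."""
        w = sum(self.nano_ratio)
        return total * self.nano_ratio[0] / w, total * self.nano_ratio[1] / w


def table1_defaults() -> Tuple[ParameterSet, CommunityState]:
    """The published parameter values and initial community composition.

    The initial abundances describe the eukaryotic plankton community at
    the start of a *Prorocentrum triestinum* bloom following an
    experimental nutrient pulse (Thau Lagoon mesocosm, autumn 2009).
    Nitrate defaults to the post-pulse (eutrophic) 36 uM and is overridden
    per scenario.
    """
    params = ParameterSet()
    initial = CommunityState(
        H=1.48e5, I=3e3, P=1.16e5, D=2.5e4, A=1.9e6, C=3.2e3, R=20.0, N=36.0,
    )
    return params, initial


def _masked_initial(base: CommunityState, mask: CommunityMask,
                    nitrate: float) -> CommunityState:
    """Zero out the states of inactive members and set the nitrate forcing."""
    from .model import STATE_VARS

    vals = base.to_dict()
    vals["N"] = float(nitrate)
    for var, active in zip(STATE_VARS, mask.active_states()):
        if not active:
            vals[var] = 0.0
    return CommunityState(**vals)


def build_scenario(level: int, trophic: str) -> ScenarioSpec:
    """One of the three community-complexity scenarios.

    Level 1: hosts and parasites only.  Level 2: adds both grazer guilds.
    Level 3: the full community including diatoms and nanophytoplankton.
    ``trophic`` selects the nitrate forcing: ``"oligo"`` (1 uM) or
    ``"eutro"`` (36 uM).
    """
    if trophic not in TROPHIC_NITRATE:
        raise ConfigurationError(f"unknown trophic condition {trophic!r}")
    if level == 1:
        mask = CommunityMask(diatoms=False, nanophytoplankton=False,
                             microciliates=False, rotifers=False)
    elif level == 2:
        mask = CommunityMask(diatoms=False, nanophytoplankton=False)
    elif level == 3:
        mask = CommunityMask()
    else:
        raise ConfigurationError(f"scenario level must be 1, 2 or 3, got {level!r}")
    _, base = table1_defaults()
    initial = _masked_initial(base, mask, TROPHIC_NITRATE[trophic])
    return ScenarioSpec(
        label=f"scenario-{level}-{trophic}",
        mask=mask,
        initial=initial,
        horizon=30.0,
        notes=f"community complexity level {level}, "
              f"{TROPHIC_NITRATE[trophic]:g} uM nitrate",
    )


def _grid_initial(nano: float, diatom: float, nitrate: float,
                  parasites: bool) -> CommunityState:
    return CommunityState(
        H=2.5e5, I=0.0, P=1.25e5 if parasites else 0.0,
        D=diatom, A=nano, C=3.2e3, R=20.0, N=float(nitrate),
    )


def nutrient_competition_grid(grid: GridSpec = GridSpec()) -> List[ScenarioSpec]:
    """All runs of the nitrate x competitor factorial (default 6x8x2 = 96).

    Dinoflagellates start at 250,000 cells/L with no infections; runs with
    parasites start with 125,000 dinospores/L.
    """
    specs = []
    for total in grid.totals:
        nano, diatom = grid.split(total)
        for nitrate in grid.nitrate:
            for par in grid.parasites:
                mask = CommunityMask(parasites=bool(par))
                specs.append(ScenarioSpec(
                    label=f"grid-other{total:.0e}-N{nitrate:g}-"
                          f"{'par' if par else 'nopar'}",
                    mask=mask,
                    initial=_grid_initial(nano, diatom, nitrate, par),
                    horizon=30.0,
                    notes="nutrient x competitor grid cell",
                ))
    return specs


def removal_designs(other_phyto_total: float,
                    nitrate: float = 36.0) -> List[ScenarioSpec]:
    """Full-community baseline plus one design per excluded member.

    Used at a low (1e4) and a high (1e8 cells/L) competitor abundance under
    eutrophic forcing to attribute growth-limiting versus demise-driving
    effects.
    """
    if other_phyto_total not in (1e4, 1e8):
        raise ConfigurationError(
            "removal designs are defined for totals 1e4 and 1e8 cells/L"
        )
    grid = GridSpec()
    nano, diatom = grid.split(other_phyto_total)

    def spec(mask: CommunityMask, tag: str, note: str) -> ScenarioSpec:
        init = _masked_initial(
            _grid_initial(nano, diatom, nitrate, mask.parasites), mask, nitrate
        )
        return ScenarioSpec(
            label=f"removal-other{other_phyto_total:.0e}-{tag}",
            mask=mask, initial=init, horizon=30.0, notes=note,
        )

    specs = [spec(CommunityMask(), "baseline", "all members present")]
    for member in MEMBERS:
        if member == "dinoflagellates":
            # hosts removed: parasites cannot persist either
            mask = CommunityMask(dinoflagellates=False, parasites=False)
        else:
            mask = CommunityMask().without(member)
        specs.append(spec(mask, f"minus-{member}", f"{member} excluded"))
    return specs


def grazing_assay_design(nano_level: float, mode: str) -> ScenarioSpec:
    """Rotifer grazing-on-dinospores assay.

    ``mode="24h"``: hosts absent, nanophytoplankton frozen at ``nano_level``
    (no growth, removing interference from both dinospore release and prey
    growth), 125,000 dinospores/L and 20 rotifers/L for one day.
    ``mode="30d"``: the full community under eutrophic forcing with
    29,000 diatoms/L and the grid-experiment initials, run for 30 days.
    """
    if nano_level <= 0:
        raise ConfigurationError("nano_level must be > 0")
    if mode == "24h":
        mask = CommunityMask(
            dinoflagellates=False, diatoms=False, microciliates=False,
            frozen=frozenset({"H", "I", "A", "N"}),
        )
        initial = CommunityState(H=0.0, I=0.0, P=1.25e5, D=0.0,
                                 A=float(nano_level), C=0.0, R=20.0, N=36.0)
        return ScenarioSpec(
            label=f"assay24h-nano{nano_level:.0e}", mask=mask,
            initial=initial, horizon=1.0,
            notes="24-h rotifer grazing assay; hosts absent, "
                  "nanophytoplankton frozen",
        )
    if mode == "30d":
        initial = CommunityState(H=2.5e5, I=0.0, P=1.25e5, D=2.9e4,
                                 A=float(nano_level), C=3.2e3, R=20.0, N=36.0)
        return ScenarioSpec(
            label=f"assay30d-nano{nano_level:.0e}", mask=CommunityMask(),
            initial=initial, horizon=30.0,
            notes="30-d dinospore consumption assay, eutrophic",
        )
    raise ConfigurationError(f"assay mode must be '24h' or '30d', got {mode!r}")
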