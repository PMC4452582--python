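"""Core plankton community model.

Eight coupled state variables describe a simplified eukaryotic plankton
community during a nutrient pulse: uninfected (``H``) and infected (``I``)
dinoflagellates, free-living parasite dinospores (``P``), diatoms (``D``),
nanophytoplankton (``A``), microciliates (``C``), rotifers (``R``) and
nitrate (``N``).  Phytoplankton growth is Monod-limited by nitrate;
infection of hosts by dinospores follows a Holling type-II attack; each
infection matures over ``h`` days and releases ``epsilon`` new dinospores;
microciliates graze dinoflagellates and diatoms, rotifers graze
nanophytoplankton and dinospores, both with saturating functional responses
and threshold-type numerical responses.

The right-hand side is assembled from named flux terms so that loss
attribution (see :mod:`dinobloom.attribution`) decomposes the derivative
exactly: per equation, the signed terms sum bitwise-identically to the
value returned by :func:`community_rhs`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, FrozenSet, Tuple

import numpy as np

__all__ = [
    "STATE_VARS",
    "ParameterSet",
    "CommunityState",
    "CommunityMask",
    "ModelOptions",
    "FluxBreakdown",
    "monod_limitation",
    "infection_attack_rate",
    "ciliate_growth_rate",
    "ciliate_ingestion_rate",
    "rotifer_growth_rate",
    "rotifer_ingestion_rate",
    "temperature_factor",
    "community_rhs",
    "decompose_fluxes",
]

#: State-variable order used throughout the package.
STATE_VARS: Tuple[str, ...] = ("H", "I", "P", "D", "A", "C", "R", "N")

#: Community members that can be switched off in experiments.
MEMBERS: Tuple[str, ...] = (
    "dinoflagellates",
    "parasites",
    "diatoms",
    "nanophytoplankton",
    "microciliates",
    "rotifers",
)


class ConfigurationError(ValueError):
    """Raised for invalid parameter values or inconsistent masks."""


class NumericalModelError(ArithmeticError):
    """Raised when a flux term evaluates to NaN or infinity."""


@dataclass(frozen=True)
class ParameterSet:
    """All rate, affinity, quota and threshold constants of the model.

    Defaults are the literature-derived values used for the Thau Lagoon
    community template (a *Prorocentrum triestinum* bloom infected by
    *Amoebophrya* spp.).  Units are per day, micromolar, and cells (or
    individuals) per litre; ``T`` is the water temperature in deg C.

    ``h`` is the parasite handling/maturation time in days: it appears both
    in the Holling type-II denominator of the attack rate and as the mean
    residence time of an infection (loss ``I/h``, release ``epsilon*I/h``).
    """

    # dinoflagellates (hosts)
    r_h: float = 0.7          # maximal growth rate, 1/d
    K_h: float = 2.3          # half-saturation for N uptake, uM
    Q_h: float = 7.12e-7      # N cell quota, uM/cell
    # parasites
    epsilon: float = 150.0    # dinospores released per infected host
    m: float = 0.26           # dinospore mortality, 1/d
    a: float = 1.34e-8        # dinospore search rate, L/dinospore/d
    h: float = 2.46           # handling/maturation time, d
    # diatoms
    r_d: float = 1.5
    K_d: float = 1.2
    Q_d: float = 6.12e-7
    # nanophytoplankton
    r_a: float = 0.7
    K_a: float = 0.5
    Q_a: float = 4.33e-9
    # microciliates
    r_cmax: float = 0.32      # maximal growth rate, 1/d
    K_rc: float = 1.8e6       # half-saturation for growth, prey/L
    x_c: float = 7.24e5       # prey threshold for growth, prey/L
    G_cmax: float = 168.0     # maximal ingestion, prey/ciliate/d
    K_Gc: float = 3.26e7      # half-saturation for ingestion, prey/L
    # rotifers
    r_rmax: float = 1.03
    K_rr: float = 4.74e6
    x_r: float = 2.52e6
    G_rmax: float = 2.7e3     # maximal ingestion, prey/rotifer/h
    K_Gr: float = 1.59e8
    # environment
    T: float = 20.0           # temperature, deg C

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigurationError(f"parameter {f.name} is not finite")
            if f.name in ("x_c", "x_r"):
                if v < 0:
                    raise ConfigurationError(f"threshold {f.name} must be >= 0")
            elif f.name == "T":
                if v <= 0:
                    raise ConfigurationError("temperature T must be > 0 (deg C)")
            elif v <= 0:
                raise ConfigurationError(f"parameter {f.name} must be > 0")
        # guarantees the numerical-response denominators K + (prey - x')
        # stay positive for all prey >= 0
        if self.K_rc <= self.x_c:
            raise ConfigurationError("K_rc must exceed x_c")
        if self.K_rr <= self.x_r:
            raise ConfigurationError("K_rr must exceed x_r")

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, **overrides)

    def to_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CommunityState:
    """Abundances (cells or ind per litre) and nitrate (uM) at one instant."""

    H: float = 0.0
    I: float = 0.0
    P: float = 0.0
    D: float = 0.0
    A: float = 0.0
    C: float = 0.0
    R: float = 0.0
    N: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y) -> "CommunityState":
        return cls(**{v: float(y[i]) for i, v in enumerate(STATE_VARS)})

    def to_dict(self) -> Dict[str, float]:
        return {v: getattr(self, v) for v in STATE_VARS}

    def validate(self, mask: "CommunityMask | None" = None) -> None:
        for v in STATE_VARS:
            x = getattr(self, v)
            if not math.isfinite(x) or x < 0:
                raise ConfigurationError(f"state {v} must be finite and >= 0")
        if mask is not None:
            for v, active in zip(STATE_VARS, mask.active_states()):
                if not active and getattr(self, v) != 0.0:
                    raise ConfigurationError(
                        f"state {v} must be 0 for an inactive community member"
                    )


@dataclass(frozen=True)
class CommunityMask:
    """Which community members participate, and which states are frozen.

    Inactive members contribute nothing to any term and their derivatives
    are identically zero.  ``frozen`` states keep their value fixed
    (derivative forced to zero) while still feeding cross terms; freezing
    ``"N"`` turns nitrate into a constant forcing (a test hook), freezing
    ``"A"`` realizes the 24-h grazing assay's no-growth nanophytoplankton.
    """

    dinoflagellates: bool = True
    parasites: bool = True
    diatoms: bool = True
    nanophytoplankton: bool = True
    microciliates: bool = True
    rotifers: bool = True
    frozen: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.frozen) - set(STATE_VARS)
        if bad:
            raise ConfigurationError(f"unknown frozen states: {sorted(bad)}")
        if self.parasites and not self.dinoflagellates:
            # allowed only for host-free assay designs that freeze the
            # (empty) host pools explicitly
            if not {"H", "I"} <= set(self.frozen):
                raise ConfigurationError(
                    "parasites without dinoflagellates requires frozen H and I"
                )

    def active_states(self) -> Tuple[bool, ...]:
        """Activity flag per state variable, in ``STATE_VARS`` order."""
        return (
            self.dinoflagellates,
            self.dinoflagellates and self.parasites,
            self.parasites,
            self.diatoms,
            self.nanophytoplankton,
            self.microciliates,
            self.rotifers,
            True,
        )

    def member_active(self, member: str) -> bool:
        if member not in MEMBERS:
            raise ConfigurationError(f"unknown member {member!r}")
        return getattr(self, member)

    def without(self, member: str) -> "CommunityMask":
        if member not in MEMBERS:
            raise ConfigurationError(f"unknown member {member!r}")
        return replace(self, **{member: False})


@dataclass(frozen=True)
class ModelOptions:
    """Equation-variant switches.

    The published equation table carries two apparent typesetting defects;
    the corrected forms are the defaults and the printed forms remain
    available for comparison:

    * ``strict_nitrate_uptake`` — printed nitrate equation multiplies every
      uptake term by the dinoflagellate abundance ``H`` instead of each
      group's own abundance.
    * ``strict_rotifer_growth`` — printed rotifer equation reads
      ``dR/dt = r_r * C`` (microciliate abundance) instead of ``r_r * R``.
    """

    strict_nitrate_uptake: bool = False
    strict_rotifer_growth: bool = False


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

def monod_limitation(N, K):
    """Michaelis–Menten–Monod nutrient limitation ``N / (K + N)``.

    Dimensionless, in ``[0, 1)``; 0 at zero nutrient, 1/2 at ``N = K``.
    """
    N = np.asarray(N, dtype=float) if np.ndim(N) else float(N)
    if np.any(np.asarray(N) < 0):
        raise ValueError("nitrate concentration must be >= 0")
    if K <= 0:
        raise ValueError("half-saturation constant must be > 0")
    return N / (K + N)


def infection_attack_rate(H, a, h):
    """Holling type-II per-dinospore infection rate ``a*H / (1 + a*h*H)``.

    ``a`` is the search rate (L per dinospore per day), ``h`` the handling
    time in days; the rate saturates at ``1/h`` for abundant hosts.
    """
    H = np.asarray(H, dtype=float) if np.ndim(H) else float(H)
    if np.any(np.asarray(H) < 0):
        raise ValueError("host abundance must be >= 0")
    return a * H / (1.0 + a * h * H)


def ciliate_growth_rate(prey, params: ParameterSet):
    """Microciliate numerical response on prey ``H + I + D``.

    Threshold form ``r_cmax * (prey - x_c) / (K_rc + (prey - x_c))``:
    zero exactly at the prey threshold, negative (starvation) below it,
    approaching ``r_cmax`` for abundant prey.
    """
    prey = np.asarray(prey, dtype=float) if np.ndim(prey) else float(prey)
    if np.any(np.asarray(prey) < 0):
        raise ValueError("prey abundance must be >= 0")
    excess = prey - params.x_c
    denom = params.K_rc + excess
    if np.any(np.asarray(denom) <= 0):
        raise ConfigurationError("ciliate numerical-response denominator <= 0")
    return params.r_cmax * excess / denom


def ciliate_ingestion_rate(prey, params: ParameterSet):
    """Microciliate functional response, prey per ciliate per day."""
    prey = np.asarray(prey, dtype=float) if np.ndim(prey) else float(prey)
    if np.any(np.asarray(prey) < 0):
        raise ValueError("prey abundance must be >= 0")
    return params.G_cmax * prey / (params.K_Gc + prey)


def rotifer_growth_rate(prey, params: ParameterSet):
    """Rotifer numerical response on prey ``A + P`` (may be negative)."""
    prey = np.asarray(prey, dtype=float) if np.ndim(prey) else float(prey)
    if np.any(np.asarray(prey) < 0):
        raise ValueError("prey abundance must be >= 0")
    excess = prey - params.x_r
    denom = params.K_rr + excess
    if np.any(np.asarray(denom) <= 0):
        raise ConfigurationError("rotifer numerical-response denominator <= 0")
    return params.r_rmax * excess / denom


def temperature_factor(T) -> float:
    """Temperature scaling of rotifer ingestion, ``0.94/(1+219000*T^-4.35)``."""
    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be > 0 deg C")
    return 0.94 / (1.0 + 219000.0 * T ** -4.35)


def rotifer_ingestion_rate(prey, T, params: ParameterSet):
    """Rotifer functional response, prey per rotifer per day.

    The saturating hourly ingestion ``G_rmax * prey / (K_Gr + prey)`` is
    temperature-scaled and converted to a daily rate (x 24); at 20 deg C
    the combined multiplier is about 15.25.
    """
    prey = np.asarray(prey, dtype=float) if np.ndim(prey) else float(prey)
    if np.any(np.asarray(prey) < 0):
        raise ValueError("prey abundance must be >= 0")
    return params.G_rmax * prey / (params.K_Gr + prey) * temperature_factor(T) * 24.0


# ---------------------------------------------------------------------------
# flux decomposition and RHS
# ---------------------------------------------------------------------------

#: Named signed flux terms per state equation, in evaluation order.
FLUX_TERMS: Dict[str, Tuple[str, ...]] = {
    "H": ("growth", "infection_loss", "ciliate_grazing"),
    "I": ("infection_gain", "maturation_loss", "ciliate_grazing"),
    "P": ("release_gain", "infection_attachment_loss", "natural_mortality",
          "rotifer_grazing"),
    "D": ("growth", "ciliate_grazing"),
    "A": ("growth", "rotifer_grazing"),
    "C": ("net_growth",),
    "R": ("net_growth",),
    "N": ("uptake_h", "uptake_d", "uptake_a"),
}


def _flux_tuple(y, p: ParameterSet, active, frozen_mask, opt: ModelOptions):
    """All signed flux terms as a flat tuple, fast scalar path.

    ``y`` is the raw 8-vector (may contain transient negatives from an
    adaptive stepper: responses are evaluated on ``max(y, 0)``), ``active``
    the per-state activity flags, ``frozen_mask`` per-state frozen flags.
    """
    H, I, P, D, A, C, R, N = (float(v) for v in y)
    H = H if H > 0.0 else 0.0
    I = I if I > 0.0 else 0.0
    P = P if P > 0.0 else 0.0
    D = D if D > 0.0 else 0.0
    A = A if A > 0.0 else 0.0
    C = C if C > 0.0 else 0.0
    R = R if R > 0.0 else 0.0
    N = N if N > 0.0 else 0.0
    if not active[0]:
        H = I = 0.0
    if not active[2]:
        P = I = 0.0
    if not active[3]:
        D = 0.0
    if not active[4]:
        A = 0.0
    if not active[5]:
        C = 0.0
    if not active[6]:
        R = 0.0

    f_h = N / (p.K_h + N)
    f_d = N / (p.K_d + N)
    f_a = N / (p.K_a + N)
    phi = p.a * H / (1.0 + p.a * p.h * H)

    prey_c = H + I + D
    prey_r = A + P
    if prey_c > 0.0:
        g_c = C * p.G_cmax * prey_c / (p.K_Gc + prey_c) / prey_c
    else:
        g_c = 0.0  # grazing-partition quotient defined as 0 at zero prey
    if prey_r > 0.0:
        g_r = (R * p.G_rmax * prey_r / (p.K_Gr + prey_r)
               * _FT_CACHE.get(p) / prey_r)
    else:
        g_r = 0.0
    r_c = p.r_cmax * (prey_c - p.x_c) / (p.K_rc + (prey_c - p.x_c))
    r_r = p.r_rmax * (prey_r - p.x_r) / (p.K_rr + (prey_r - p.x_r))

    mat = I / p.h

    # H
    tH = (p.r_h * H * f_h, -phi * P, -g_c * H)
    # I
    tI = (phi * P, -mat, -g_c * I)
    # P
    tP = (p.epsilon * mat, -phi * P, -p.m * P, -g_r * P)
    # D
    tD = (p.r_d * D * f_d, -g_c * D)
    # A
    tA = (p.r_a * A * f_a, -g_r * A)
    # C, R
    tC = (r_c * C,)
    tR = (r_r * (C if opt.strict_rotifer_growth else R),)
    # N
    if opt.strict_nitrate_uptake:
        tN = (-H * p.r_h * f_h * p.Q_h,
              -H * p.r_d * f_d * p.Q_d,
              -H * p.r_a * f_a * p.Q_a)
    else:
        tN = (-H * p.r_h * f_h * p.Q_h,
              -D * p.r_d * f_d * p.Q_d,
              -A * p.r_a * f_a * p.Q_a)

    terms = (tH, tI, tP, tD, tA, tC, tR, tN)
    if any(frozen_mask) or not all(active):
        zero = {i for i in range(8) if frozen_mask[i] or not active[i]}
        terms = tuple(
            tuple(0.0 for _ in t) if i in zero else t
            for i, t in enumerate(terms)
        )
    return terms


class _FTCache:
    """Memoize the temperature multiplier per ParameterSet instance."""

    def __init__(self) -> None:
        self._key = None
        self._val = 0.0

    def get(self, p: ParameterSet) -> float:
        if self._key is not p:
            self._val = temperature_factor(p.T) * 24.0
            self._key = p
        return self._val


_FT_CACHE = _FTCache()


@dataclass
class FluxBreakdown:
    """Signed per-term rates for every state equation.

    ``terms[var][name]`` is the signed rate (units of that state per day);
    per equation the terms sum bitwise-identically to the RHS because
    :func:`community_rhs` sums exactly these values in the same order.
    """

    terms: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def rhs(self) -> CommunityState:
        vals = {}
        for var in STATE_VARS:
            acc = 0.0
            for name in FLUX_TERMS[var]:
                acc += self.terms[var][name]
            vals[var] = acc
        return CommunityState(**vals)

    def losses(self, var: str) -> Dict[str, float]:
        """Magnitudes of the negative (loss) terms of one equation."""
        return {k: -v for k, v in self.terms[var].items() if v < 0}


def _check_finite(terms) -> None:
    for var, names in zip(STATE_VARS, (FLUX_TERMS[v] for v in STATE_VARS)):
        t = terms[STATE_VARS.index(var)]
        for name, val in zip(names, t):
            if not math.isfinite(val):
                raise NumericalModelError(
                    f"non-finite flux term {var}.{name} = {val!r}"
                )


def decompose_fluxes(
    state: CommunityState,
    params: ParameterSet,
    mask: CommunityMask = CommunityMask(),
    options: ModelOptions = ModelOptions(),
) -> FluxBreakdown:
    """Evaluate every named flux term at one state."""
    active = mask.active_states()
    frozen = tuple(v in mask.frozen for v in STATE_VARS)
    terms = _flux_tuple(state.to_array(), params, active, frozen, options)
    _check_finite(terms)
    return FluxBreakdown(
        terms={
            var: dict(zip(FLUX_TERMS[var], terms[i]))
            for i, var in enumerate(STATE_VARS)
        }
    )


def community_rhs(
    state: CommunityState,
    params: ParameterSet,
    mask: CommunityMask = CommunityMask(),
    options: ModelOptions = ModelOptions(),
) -> CommunityState:
    """Time derivative of the community state (per day)."""
    active = mask.active_states()
    frozen = tuple(v in mask.frozen for v in STATE_VARS)
    terms = _flux_tuple(state.to_array(), params, active, frozen, options)
    _check_finite(terms)
    vals = {}
    for i, var in enumerate(STATE_VARS):
        acc = 0.0
        for val in terms[i]:
            acc += val
        vals[var] = acc
    return CommunityState(**vals)
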