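"""Unit and property tests for the response functions and the ODE RHS."""

import pytest
from hypothesis import given, settings, strategies as st

from dinobloom import (
    CommunityMask,
    CommunityState,
    ConfigurationError,
    ModelOptions,
    NumericalModelError,
    ParameterSet,
    STATE_VARS,
    ciliate_growth_rate,
    ciliate_ingestion_rate,
    community_rhs,
    decompose_fluxes,
    infection_attack_rate,
    monod_limitation,
    rotifer_growth_rate,
    rotifer_ingestion_rate,
    temperature_factor,
)

P = ParameterSet()


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("N,K,expected", [
    (0.0, 2.3, 0.0),                 # zero nutrient
    (2.3, 2.3, 0.5),                 # half-saturation definition
    (36.0, 2.3, 36.0 / (2.3 + 36.0)),  # independently coded expression
])
def test_monod_limitation_values(N, K, expected):
    assert monod_limitation(N, K) == pytest.approx(expected, rel=1e-12)


def test_monod_limitation_domain_errors():
    with pytest.raises(ValueError):
        monod_limitation(-1.0, 2.3)
    with pytest.raises(ValueError):
        monod_limitation(1.0, 0.0)


def test_infection_attack_rate_values():
    assert infection_attack_rate(0.0, P.a, P.h) == 0.0
    # saturation at 1/h for abundant hosts
    assert infection_attack_rate(1e15, P.a, P.h) == pytest.approx(
        1.0 / P.h, rel=1e-6)
    # directly coded arithmetic at the nominal host abundance
    H = 1.48e5
    expected = (1.34e-8 * H) / (1.0 + 1.34e-8 * 2.46 * H)
    assert infection_attack_rate(H, P.a, P.h) == pytest.approx(
        expected, rel=1e-12)


def test_ciliate_numerical_response():
    # exactly zero at the prey threshold
    assert ciliate_growth_rate(P.x_c, P) == 0.0
    # approaches the maximal growth rate
    assert ciliate_growth_rate(1e15, P) == pytest.approx(P.r_cmax, rel=1e-6)
    # starvation below threshold: directly coded expression
    expected = 0.32 * (-7.24e5) / (1.8e6 - 7.24e5)
    assert ciliate_growth_rate(0.0, P) == pytest.approx(expected, rel=1e-12)


def test_ciliate_functional_response():
    assert ciliate_ingestion_rate(0.0, P) == 0.0
    assert ciliate_ingestion_rate(P.K_Gc, P) == pytest.approx(P.G_cmax / 2)
    assert ciliate_ingestion_rate(1e18, P) == pytest.approx(
        P.G_cmax, rel=1e-6)


def test_rotifer_numerical_response():
    assert rotifer_growth_rate(P.x_r, P) == 0.0
    assert rotifer_growth_rate(1e15, P) == pytest.approx(P.r_rmax, rel=1e-6)
    expected = 1.03 * (-2.52e6) / (4.74e6 - 2.52e6)
    assert rotifer_growth_rate(0.0, P) == pytest.approx(expected, rel=1e-12)


def test_rotifer_ingestion_temperature_scaling():
    # hourly -> daily conversion with the temperature factor at 20 C
    ft = 0.94 / (1.0 + 219000.0 * 20.0 ** -4.35)
    assert temperature_factor(20.0) == pytest.approx(ft, rel=1e-12)
    assert rotifer_ingestion_rate(0.0, 20.0, P) == 0.0
    expected = 2.7e3 * 0.5 * ft * 24.0
    assert rotifer_ingestion_rate(P.K_Gr, 20.0, P) == pytest.approx(
        expected, rel=1e-12)
    with pytest.raises(ValueError):
        rotifer_ingestion_rate(1e6, -5.0, P)


# ---------------------------------------------------------------------------
# parameter / state invariants
# ---------------------------------------------------------------------------

def test_parameter_invariants_enforced():
    with pytest.raises(ConfigurationError):
        ParameterSet(r_h=-0.1)
    with pytest.raises(ConfigurationError):
        ParameterSet(K_rc=1e5)   # K_rc <= x_c
    with pytest.raises(ConfigurationError):
        ParameterSet(x_r=5e6)    # K_rr <= x_r
    with pytest.raises(ConfigurationError):
        ParameterSet().with_overrides(bogus=1.0)


def test_state_validation_against_mask():
    s = CommunityState(H=1.0, D=5.0)
    with pytest.raises(ConfigurationError):
        s.validate(CommunityMask(diatoms=False))
    s2 = CommunityState(H=1.0)
    s2.validate(CommunityMask(diatoms=False))  # consistent: no error


def test_mask_requires_frozen_hosts_for_hostfree_parasites():
    with pytest.raises(ConfigurationError):
        CommunityMask(dinoflagellates=False)
    CommunityMask(dinoflagellates=False, frozen=frozenset({"H", "I"}))


# ---------------------------------------------------------------------------
# RHS structure
# ---------------------------------------------------------------------------

def test_extinction_fixed_point():
    rhs = community_rhs(CommunityState(N=5.0), P)
    for v in STATE_VARS:
        if v != "N":
            assert getattr(rhs, v) == 0.0
    assert rhs.N == 0.0  # nothing left to take nutrients up


def test_monod_growth_limit_without_enemies():
    # no parasites, grazers or competitors: pure Monod-limited growth
    s = CommunityState(H=1e5, N=36.0)
    rhs = community_rhs(s, P)
    assert rhs.H == pytest.approx(0.7 * (36.0 / 38.3) * 1e5, rel=1e-12)
    assert rhs.I == rhs.P == rhs.D == rhs.A == 0.0
    assert rhs.N == pytest.approx(-1e5 * 0.7 * (36.0 / 38.3) * 7.12e-7,
                                  rel=1e-12)


def test_nonfinite_term_raises_named_error():
    with pytest.raises(NumericalModelError, match="flux term"):
        community_rhs(CommunityState(H=float("inf"), N=1.0), P)


state_strategy = st.builds(
    CommunityState,
    H=st.floats(0, 1e9), I=st.floats(0, 1e8), P=st.floats(0, 1e10),
    D=st.floats(0, 1e9), A=st.floats(0, 1e10), C=st.floats(0, 1e7),
    R=st.floats(0, 1e7), N=st.floats(0, 50),
)


@settings(max_examples=200, deadline=None)
@given(state=state_strategy)
def test_flux_decomposition_matches_rhs_exactly(state):
    """Per equation, the signed flux terms sum bitwise to the RHS."""
    fb = decompose_fluxes(state, P)
    rhs = community_rhs(state, P)
    for v in STATE_VARS:
        assert getattr(fb.rhs(), v) == getattr(rhs, v)


@settings(max_examples=200, deadline=None)
@given(state=state_strategy)
def test_structural_invariants(state):
    fb = decompose_fluxes(state, P)
    rhs = community_rhs(state, P)
    # no nutrient recycling
    assert rhs.N <= 0.0
    # saturation bounds of the responses
    phi = infection_attack_rate(state.H, P.a, P.h)
    assert 0.0 <= phi <= 1.0 / P.h + 1e-15
    prey_c = state.H + state.I + state.D
    assert 0.0 <= ciliate_ingestion_rate(prey_c, P) <= P.G_cmax
    assert ciliate_growth_rate(prey_c, P) <= P.r_cmax
    assert rotifer_growth_rate(state.A + state.P, P) <= P.r_rmax
    # grazing partition closure: per-prey grazing losses sum to C*Gc
    if prey_c > 1e-12 and state.C > 1e-12:
        total = (-fb.terms["H"]["ciliate_grazing"]
                 - fb.terms["I"]["ciliate_grazing"]
                 - fb.terms["D"]["ciliate_grazing"])
        assert total == pytest.approx(
            state.C * ciliate_ingestion_rate(prey_c, P), rel=1e-9)
    prey_r = state.A + state.P
    if prey_r > 1e-12 and state.R > 1e-12:
        total = (-fb.terms["P"]["rotifer_grazing"]
                 - fb.terms["A"]["rotifer_grazing"])
        assert total == pytest.approx(
            state.R * rotifer_ingestion_rate(prey_r, P.T, P), rel=1e-9)


@settings(max_examples=50, deadline=None)
@given(state=state_strategy)
def test_masked_members_have_zero_dynamics(state):
    mask = CommunityMask(diatoms=False, rotifers=False)
    s = CommunityState(**{**state.to_dict(), "D": 0.0, "R": 0.0})
    fb = decompose_fluxes(s, P, mask)
    assert all(v == 0.0 for v in fb.terms["D"].values())
    assert all(v == 0.0 for v in fb.terms["R"].values())
    # masked members contribute nothing to cross terms
    assert fb.terms["N"]["uptake_d"] == 0.0
    assert fb.terms["P"]["rotifer_grazing"] == 0.0
    assert fb.terms["A"]["rotifer_grazing"] == 0.0


def test_frozen_variable_has_zero_derivative_but_feeds_cross_terms():
    mask = CommunityMask(frozen=frozenset({"A", "N"}))
    s = CommunityState(H=1e5, P=1e5, A=1e7, R=20.0, N=36.0)
    fb = decompose_fluxes(s, P, mask)
    assert all(v == 0.0 for v in fb.terms["A"].values())
    assert all(v == 0.0 for v in fb.terms["N"].values())
    # frozen nanophytoplankton still dilute and feed rotifer grazing
    assert fb.terms["P"]["rotifer_grazing"] < 0.0


def test_zero_prey_grazing_quotients_defined_as_zero():
    s = CommunityState(C=1e4, R=100.0, N=10.0)  # grazers without any prey
    fb = decompose_fluxes(s, P)
    assert fb.terms["H"]["ciliate_grazing"] == 0.0
    assert fb.terms["P"]["rotifer_grazing"] == 0.0


def test_strict_equation_variants():
    s = CommunityState(H=1e5, I=1e3, P=1e5, D=1e4, A=1e6, C=3e3, R=20, N=36)
    base = community_rhs(s, P)
    strict_n = community_rhs(s, P, options=ModelOptions(
        strict_nitrate_uptake=True))
    strict_r = community_rhs(s, P, options=ModelOptions(
        strict_rotifer_growth=True))
    # printed nitrate equation scales all uptake with H
    fh, fd, fa = (36 / (K + 36) for K in (P.K_h, P.K_d, P.K_a))
    assert strict_n.N == pytest.approx(
        -1e5 * (P.r_h * fh * P.Q_h + P.r_d * fd * P.Q_d + P.r_a * fa * P.Q_a),
        rel=1e-12)
    assert strict_n.N != base.N
    # printed rotifer equation reproduces from microciliate abundance
    prey_r = 1e6 + 1e5
    rr = rotifer_growth_rate(prey_r, P)
    assert strict_r.R == pytest.approx(rr * 3e3, rel=1e-12)
    assert strict_r.R != base.R
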