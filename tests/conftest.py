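import pytest

from dinobloom import (
    ParameterSet,
    build_scenario,
    integrate_community,
    removal_designs,
    table1_defaults,
)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return table1_defaults()[0]


def _run(spec, params, **kw):
    return integrate_community(spec.initial, params, spec.mask,
                               horizon=spec.horizon, **kw)


@pytest.fixture(scope="session")
def traj_s1_eutro(params):
    return _run(build_scenario(1, "eutro"), params)


@pytest.fixture(scope="session")
def traj_s1_oligo(params):
    return _run(build_scenario(1, "oligo"), params)


@pytest.fixture(scope="session")
def traj_s2_eutro(params):
    return _run(build_scenario(2, "eutro"), params)


@pytest.fixture(scope="session")
def traj_s3_eutro(params):
    return _run(build_scenario(3, "eutro"), params)


@pytest.fixture(scope="session")
def traj_s3_oligo(params):
    return _run(build_scenario(3, "oligo"), params)


@pytest.fixture(scope="session")
def removal_trajectories(params):
    """Baseline and single-exclusion runs for both competitor levels."""
    out = {}
    for total in (1e4, 1e8):
        runs = {}
        for spec in removal_designs(total):
            tag = ("baseline" if "minus" not in spec.label
                   else spec.label.split("minus-")[-1])
            runs[tag] = _run(spec, params)
        out[total] = runs
    return out
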