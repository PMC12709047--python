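import numpy as np
import pytest

from mutrescue import (
    effective_growth,
    fixation_profile,
    mutator_advantage,
    mutator_fixation_profile,
    preexistence_advantage_limit,
    rescue_prob,
    rescue_result,
    total_rescue,
)
from mutrescue.experiments_cli import make_params
from mutrescue.growth_model import LineageType

from conftest import constant_growth_trajectory


def test_effective_growth_definition(ref_traj_n2, ref_params_n2):
    traj, p = ref_traj_n2, ref_params_n2
    t = 600.0
    comp = np.interp(t, traj.times, traj.competition)
    f = p.growth(t, LineageType.RW)
    assert effective_growth(t, LineageType.RW, traj, p) == pytest.approx(f * comp)
    # full competition -> 0 (uses a synthetic saturated trajectory)
    params, crowded = constant_growth_trajectory(0.9, crowd=1.0, T=100.0, m=101)
    assert effective_growth(50.0, LineageType.RW, crowded, params) == 0.0
    with pytest.raises(ValueError):
        effective_growth(traj.t_end + 1.0, LineageType.RW, traj, p)


@pytest.mark.parametrize("f", [0.2, 0.5, 1.0])
def test_constant_growth_closed_form(f):
    params, traj = constant_growth_trajectory(f)
    prof = fixation_profile(traj, params, background="W")
    # away from t=0 the rising Hill equals 1 to machine precision
    assert prof.pfix[100] == pytest.approx(1 - 0.1 / f, abs=1e-9)


def test_subcritical_lineage_never_fixes():
    # crowding pushes f_eff = 0.9 * 0.05 below g = 0.1
    params, traj = constant_growth_trajectory(0.9, crowd=0.95, T=500.0, m=501)
    prof = fixation_profile(traj, params, background="W")
    assert np.all(prof.pfix == 0.0)


def test_fixation_profile_monotone_and_bounded(ref_traj_n2, ref_params_n2):
    prof = fixation_profile(ref_traj_n2, ref_params_n2, background="W")
    assert np.all((prof.pfix >= 0) & (prof.pfix <= 1))
    # in a deteriorating-then-recovering environment the later a rescue
    # lineage is founded, the less subcritical time it must survive
    assert np.all(np.diff(prof.pfix) >= -1e-12)


def test_backward_system_reproduces_rescue_profile(ref_traj_n2, ref_params_n2):
    """The RM component of the two-type backward system must agree with the
    single-type integral formula."""
    pM, pR = mutator_fixation_profile(ref_traj_n2, ref_params_n2)
    ref = fixation_profile(ref_traj_n2, ref_params_n2, background="M")
    sel = ref.pfix > 1e-8
    assert np.allclose(pR.pfix[sel], ref.pfix[sel], rtol=1e-3)


def test_mutator_lineage_fixation_degenerate_cases():
    from mutrescue import integrate_de_novo

    # sterile mutator: nu' >= nu_c means fM == 0 and PfixM == 0 everywhere
    p = make_params(nu=0.25, F=5.0, n=2.0, theta=100.0, E=500.0)
    pM, _ = mutator_fixation_profile(integrate_de_novo(p), p)
    assert np.all(pM.pfix == 0.0)
    # mu' = 0: a mutator lineage that cannot generate rescue never fixes
    p2 = make_params(nu=0.0, F=5.0, n=2.0, theta=100.0, E=0.0)
    pM2, _ = mutator_fixation_profile(integrate_de_novo(p2), p2)
    assert np.all(pM2.pfix == 0.0)


def test_rescue_prob_zero_channels(ref_params_n2):
    from mutrescue import integrate_de_novo, integrate_preexisting

    p = ref_params_n2.with_(E=0.0)
    traj = integrate_de_novo(p)
    assert rescue_prob(traj, p, "M") == 0.0  # mu_M = 0
    p2 = ref_params_n2.with_(alpha=0.0, E=0.0)
    traj2 = integrate_preexisting(p2)
    assert rescue_prob(traj2, p2, "M") == 0.0  # no mutators present


def test_total_rescue_and_advantage_arithmetic():
    assert total_rescue(0.1, 0.2) == pytest.approx(0.28)
    assert total_rescue(0.37, 0.0) == 0.37
    assert total_rescue(1.0, 0.5) == 1.0
    with pytest.raises(ValueError):
        total_rescue(1.2, 0.0)
    assert mutator_advantage(0.14, 0.1) == pytest.approx(0.4)
    assert mutator_advantage(0.1, 0.1) == 0.0
    with pytest.raises(ZeroDivisionError):
        mutator_advantage(0.1, 0.0)


@pytest.mark.parametrize(
    "F,alpha,expected", [(5.0, 0.05, 0.20), (1.0, 0.3, 0.0), (2.0, 0.05, 0.05)]
)
def test_preexistence_advantage_limit(F, alpha, expected):
    assert preexistence_advantage_limit(F, alpha) == pytest.approx(expected)


def test_rescue_result_identity_and_baseline():
    p = make_params(nu=2e-3, F=5.0, n=4.0, theta=200.0, E=500.0, alpha=0.05)
    for scenario in ("de_novo", "preexisting"):
        res = rescue_result(p, scenario)
        assert res.Prall == pytest.approx(
            res.PrW + (1 - res.PrW) * res.PrM, abs=1e-15
        )
        assert 0 <= res.PrM <= 1 and 0 <= res.PrW <= res.PrW0 <= 1


def test_de_novo_baseline_equals_preexisting_baseline():
    p = make_params(nu=2e-3, F=5.0, n=4.0, theta=200.0)
    PrW0_d = rescue_result(p.with_(E=0.0), "de_novo").PrW0
    PrW0_p = rescue_result(p.with_(alpha=0.0), "preexisting").PrW0
    assert PrW0_d == pytest.approx(PrW0_p, rel=1e-8)


def test_emergence_reduces_wildtype_rescue():
    """Mutator emergence diverts wildtype births: PrW < PrW0 for E > 0."""
    for nu in (1e-3, 5e-3, 2e-2):
        res = rescue_result(
            make_params(nu=nu, F=5.0, n=10.0, theta=500.0, E=2000.0), "de_novo"
        )
        assert res.PrW <= res.PrW0
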