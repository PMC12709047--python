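import numpy as np
import pytest
from scipy import stats

from mutrescue import (
    SimState,
    branching_oracle_pfix,
    event_rates,
    run_ensemble,
    simulate_replicate,
)
from mutrescue.experiments_cli import make_params
from mutrescue.stochastic_sim import initial_counts

from conftest import constant_growth_trajectory


def small_params(**kw):
    base = dict(nu=1e-3, F=5.0, n=4.0, theta=50.0, E=500.0, K=200.0, r=2e-3)
    base.update(kw)
    return make_params(**base)


def test_event_rate_table_conservation_and_limits():
    p = small_params()
    state = SimState(W=100, M=10, RW=5, RM=2)
    rates = event_rates(state, 25.0, p)
    comp = 1 - state.total / p.dem.K
    fW = p.growth(25.0, __import__("mutrescue").LineageType.W)
    assert rates["birth_W"] == pytest.approx(fW * comp * 100)
    assert rates["death_M"] == pytest.approx(p.dem.g * 10)
    assert len(rates) == 8 and all(v >= 0 for v in rates.values())
    # at carrying capacity all births stop, deaths continue
    full = SimState(W=200, M=0, RW=0, RM=0)
    r_full = event_rates(full, 25.0, p)
    assert all(r_full[f"birth_{x}"] == 0.0 for x in "W M RW RM".split())
    assert r_full["death_W"] == pytest.approx(p.dem.g * 200)
    empty = SimState(W=0, M=0, RW=0, RM=0)
    assert all(v == 0.0 for v in event_rates(empty, 0.0, p).values())


def test_initial_counts_split():
    p = small_params(alpha=0.05, K=1e4)
    w0, m0 = initial_counts(p, "preexisting")
    N0 = p.dem.K * (1 - p.dem.g / p.fW0)
    assert w0 + m0 == pytest.approx(N0, abs=1.0)
    assert m0 == round(0.05 * N0)
    # alpha > 0 always seeds at least one mutator
    p_tiny = small_params(alpha=1e-5, K=1e3)
    assert initial_counts(p_tiny, "preexisting")[1] == 1


def test_ensemble_reproducible_bit_identical():
    p = small_params()
    chk = np.linspace(5.0, 100.0, 8)
    a, nw_a = run_ensemble(p, 50, master_seed=123, scenario="de_novo", checkpoints=chk)
    b, nw_b = run_ensemble(p, 50, master_seed=123, scenario="de_novo", checkpoints=chk)
    assert np.array_equal(a.outcomes, b.outcomes)
    assert np.array_equal(a.mutator_fixed, b.mutator_fixed)
    assert np.array_equal(nw_a, nw_b)
    c, nw_c = run_ensemble(p, 50, master_seed=124, scenario="de_novo", checkpoints=chk)
    assert not np.array_equal(nw_a, nw_c)


def test_no_rescue_channel_means_certain_extinction():
    # mu = mu_M = 0 in a deteriorating environment: all replicates die
    p = make_params(nu=0.0, F=1.0, n=4.0, theta=50.0, E=0.0, K=200.0)
    s = run_ensemble(p, 200, master_seed=9, scenario="de_novo")
    assert s.counts["extinct"] == 200
    assert s.n_mutator_fixed == 0


def test_single_founder_constant_rate_fixation_frequency():
    """One rescue founder at constant effective growth f=1, g=0.1: the
    branching fixation probability is 1 - g/f = 0.9."""
    params, traj = constant_growth_trajectory(1.0, T=500.0, m=501)
    freq, se = branching_oracle_pfix(5.0, traj, params, "W", 10000, seed=21)
    assert freq == pytest.approx(0.9, abs=3 * max(se, 3e-3))


def test_subcritical_constant_rates_never_fix():
    # crowding makes b = 0.9*0.05 < g: 0 survivors expected
    params, traj = constant_growth_trajectory(0.9, crowd=0.95, T=500.0, m=501)
    freq, _ = branching_oracle_pfix(5.0, traj, params, "W", 10000, seed=22)
    assert freq == 0.0


def test_thinning_inter_event_times_are_exact():
    """With frozen (constant) rates the waits between accepted events must
    be exponential with the state-dependent total rate: rescaling each
    wait by that rate gives iid Exp(1) samples (KS test, fixed seed)."""
    p = make_params(
        nu=0.05, F=5.0, n=2.0, theta=100.0, E=500.0, K=500.0, r=2e-3,
        mode="constant",
    )
    rec = simulate_replicate(
        p, seed=77, scenario="de_novo", record_events=4000, t_end=80.0,
        rescue_threshold=10**9, cap=10**6,
    )
    codes = rec.event_codes
    assert len(codes) == 4000
    # reconstruct the state sequence to compute each step's total rate
    w, m, rw, rm = initial_counts(p, "de_novo") + (0, 0)
    cfW, cfM = p.mut.cost_factor_wildtype, p.mut.cost_factor_mutator
    g, K = p.dem.g, p.dem.K
    rates = np.empty(len(codes))
    for i, code in enumerate(codes):
        N = w + m + rw + rm
        comp = max(0.0, 1 - N / K)
        # frozen environment: rescue types have zero birth rate
        rates[i] = comp * (cfW * w + cfM * m) + g * N
        delta = 1 if code < 4 else -1
        which = code % 4
        if which == 0:
            w += delta
        elif which == 1:
            m += delta
        elif which == 2:
            rw += delta
        else:
            rm += delta
    times = np.concatenate([[0.0], rec.event_times])
    scaled = np.diff(times) * rates
    ks = stats.kstest(scaled, "expon")
    assert ks.pvalue > 0.01


def test_mean_field_convergence_to_deterministic_trajectory():
    from mutrescue import integrate_de_novo

    p = make_params(nu=1e-3, F=5.0, n=10.0, E=0.0, theta=200.0, K=1e3, r=2e-3)
    chk = np.linspace(20.0, 320.0, 10)
    s, nw = run_ensemble(p, 300, master_seed=5, scenario="de_novo", checkpoints=chk)
    traj = integrate_de_novo(p)
    det = np.interp(chk, traj.times, traj.N_total)
    mean = nw.mean(axis=0)
    se = nw.std(axis=0, ddof=1) / np.sqrt(nw.shape[0])
    assert np.all(np.abs(mean - det) < 3 * se + 1e-9)


def test_replicate_classification_fields():
    p = small_params(nu=2e-2, E=2000.0)
    rec = simulate_replicate(p, seed=5, scenario="de_novo")
    assert rec.outcome in (
        "extinct",
        "rescued_by_wildtype",
        "rescued_by_mutator",
        "persisted",
    )
    w, m, rw, rm = rec.final_counts
    if rec.outcome == "extinct":
        assert w + m + rw + rm == 0
    if rec.mutator_fixed:
        assert w == 0 and rw == 0 and m + rm > 0
    if rec.outcome == "rescued_by_mutator":
        assert rm > rw


def test_classify_outcome_rules():
    from mutrescue import classify_outcome

    assert classify_outcome(
        SimState(W=0, M=0, RW=0, RM=0, t=50.0), t_end=600.0, rescue_threshold=100
    ) == ("extinct", False)
    out, fixed = classify_outcome(
        SimState(W=0, M=0, RW=0, RM=1200, t=300.0), t_end=600.0, rescue_threshold=1000
    )
    assert out == "rescued_by_mutator" and fixed
    out, fixed = classify_outcome(
        SimState(W=3, M=0, RW=900, RM=300, t=300.0), t_end=600.0, rescue_threshold=1000
    )
    assert out == "rescued_by_wildtype" and not fixed
    # alive at t_end with any rescue carriers counts as rescued
    out, _ = classify_outcome(
        SimState(W=50, M=0, RW=2, RM=0, t=600.0), t_end=600.0, rescue_threshold=1000
    )
    assert out == "rescued_by_wildtype"
    out, _ = classify_outcome(
        SimState(W=50, M=5, RW=0, RM=0, t=600.0), t_end=600.0, rescue_threshold=1000
    )
    assert out == "persisted"
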