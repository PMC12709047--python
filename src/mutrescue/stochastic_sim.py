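"""Exact Gillespie-type simulation of the four-type rescue process.

Individuals of types W, M, RW, RM are born at rate
``f_type(t) * max(0, 1 - N/K)`` and die at rate ``g``; at birth the
offspring of a wildtype is a mutator with probability ``mu_M`` or a
rescue mutant with probability ``mu``, and the offspring of a mutator
carries the rescue allele with probability ``mu'`` (rescue types breed
true).  Time-dependence is handled by Poisson thinning against a global
bound, so sampling is exact in distribution; see :mod:`mutrescue._kernels`.

A replicate terminates at extinction, at a declared rescue (rescue types
reaching a threshold, default 0.1 K), or at ``t_end`` (default 6 theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .deterministic_dynamics import ModelParams, Trajectory, equilibrium_size
from .growth_model import LineageType, growth_rate, hill_rise

__all__ = [
    "SimState",
    "ReplicateRecord",
    "EnsembleSummary",
    "OUTCOMES",
    "event_rates",
    "classify_outcome",
    "initial_counts",
    "simulate_replicate",
    "run_ensemble",
    "branching_oracle_pfix",
]

OUTCOMES = ("extinct", "rescued_by_wildtype", "rescued_by_mutator", "persisted")

_SCENARIOS = ("de_novo", "preexisting", "constant_env")


@dataclass
class SimState:
    """Integer counts per lineage type at a point in time."""

    W: int
    M: int
    RW: int
    RM: int
    t: float = 0.0

    @property
    def total(self) -> int:
        return self.W + self.M + self.RW + self.RM

    def count(self, lineage: LineageType) -> int:
        return getattr(self, lineage.name)


@dataclass
class ReplicateRecord:
    """Classified outcome of a single simulation replicate."""

    outcome: str
    mutator_fixed: bool
    t_final: float
    final_counts: tuple[int, int, int, int]
    seed: int
    event_times: np.ndarray | None = None
    event_codes: np.ndarray | None = None


@dataclass
class EnsembleSummary:
    """Outcome statistics over seeded independent replicates."""

    n_replicates: int
    counts: dict[str, int]
    n_mutator_fixed: int
    master_seed: int
    scenario: str
    outcomes: np.ndarray = field(repr=False)
    mutator_fixed: np.ndarray = field(repr=False)

    @property
    def n_rescued(self) -> int:
        return self.counts["rescued_by_wildtype"] + self.counts["rescued_by_mutator"]

    @property
    def rescue_freq(self) -> float:
        return self.n_rescued / self.n_replicates

    @property
    def rescue_se(self) -> float:
        p = self.rescue_freq
        return math.sqrt(p * (1.0 - p) / self.n_replicates)

    def freq(self, outcome: str) -> float:
        return self.counts[outcome] / self.n_replicates

    def freq_se(self, outcome: str) -> float:
        p = self.freq(outcome)
        return math.sqrt(p * (1.0 - p) / self.n_replicates)

    @property
    def mutator_rescue_fraction(self) -> float:
        """Fraction of rescued populations rescued by the mutator."""
        if self.n_rescued == 0:
            return float("nan")
        return self.counts["rescued_by_mutator"] / self.n_rescued

    @property
    def mutator_rescue_fraction_se(self) -> float:
        if self.n_rescued == 0:
            return float("nan")
        p = self.mutator_rescue_fraction
        return math.sqrt(p * (1.0 - p) / self.n_rescued)

    def to_dict(self) -> dict:
        d = {
            "n_replicates": self.n_replicates,
            "master_seed": self.master_seed,
            "scenario": self.scenario,
            "n_mutator_fixed": self.n_mutator_fixed,
            "rescue_freq": self.rescue_freq,
            "rescue_se": self.rescue_se,
        }
        d.update({f"n_{k}": v for k, v in self.counts.items()})
        return d


def event_rates(state: SimState, t: float, params: ModelParams) -> dict[str, float]:
    """Per-event rate table at time ``t`` (introspection; not the hot path)."""
    K, g = params.dem.K, params.dem.g
    comp = max(0.0, 1.0 - state.total / K)
    rates: dict[str, float] = {}
    for lt in LineageType:
        f = float(growth_rate(t, lt, params.env, params.mut))
        rates[f"birth_{lt.name}"] = f * comp * state.count(lt)
        rates[f"death_{lt.name}"] = g * state.count(lt)
    return rates


def classify_outcome(
    state: SimState,
    *,
    t_end: float,
    rescue_threshold: int,
) -> tuple[str, bool]:
    """Classify a terminated replicate; returns (outcome, mutator_fixed).

    Extinct if the population is empty; rescued once rescue types reach
    ``rescue_threshold`` (or are present at all at ``t_end``), attributed
    to the mutator when RM holds the majority of rescue types; otherwise
    the population persisted.  ``mutator_fixed`` marks states where every
    survivor carries the mutator background.
    """
    rescued = state.RW + state.RM
    mut_fixed = state.W == 0 and state.RW == 0 and (state.M + state.RM) > 0
    if state.total == 0:
        return "extinct", False
    if rescued >= rescue_threshold or (state.t >= t_end and rescued > 0):
        outcome = "rescued_by_mutator" if state.RM > state.RW else "rescued_by_wildtype"
        return outcome, mut_fixed
    return "persisted", mut_fixed


def initial_counts(params: ModelParams, scenario: str) -> tuple[int, int]:
    """Rounded equilibrium (W, M) counts for a scenario's initial state."""
    N0 = equilibrium_size(params.dem, params.fW0)
    if scenario == "preexisting":
        m0 = int(round(params.dem.alpha * N0))
        if params.dem.alpha > 0:
            m0 = max(m0, 1)
        return int(round((1.0 - params.dem.alpha) * N0)), m0
    return int(round(N0)), 0


def _kernel_args(params: ModelParams, scenario: str):
    env, mut, dem = params.env, params.mut, params.dem
    frozen = env.constant or scenario == "constant_env"
    split_scenario = "preexisting" if scenario == "preexisting" else "de_novo"
    w0, m0 = initial_counts(params, split_scenario)
    return {
        "w0": w0,
        "m0": m0,
        "K": float(dem.K),
        "g": dem.g,
        "cfW": mut.cost_factor_wildtype,
        "cfM": mut.cost_factor_mutator,
        "theta": env.theta,
        "n": env.n,
        "n_rise": env.rise_exponent,
        "mu": mut.mu,
        "mu_p": mut.mu_prime,
        "mu_M": mut.mu_M if split_scenario == "de_novo" else 0.0,
        "frozen": frozen,
    }


def _resolve_run_params(params: ModelParams, t_end, rescue_threshold, cap):
    if t_end is None:
        t_end = 6.0 * params.env.theta
    if rescue_threshold is None:
        rescue_threshold = math.ceil(0.1 * params.dem.K)
    if cap is None:
        cap = int(2 * params.dem.K)
    return float(t_end), int(rescue_threshold), int(cap)


def simulate_replicate(
    params: ModelParams,
    seed: int,
    scenario: str = "de_novo",
    *,
    t_end: float | None = None,
    rescue_threshold: int | None = None,
    cap: int | None = None,
    record_events: int = 0,
) -> ReplicateRecord:
    """Simulate one replicate; ``record_events`` caps an optional event log."""
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    t_end, rescue_threshold, cap = _resolve_run_params(
        params, t_end, rescue_threshold, cap
    )
    ka = _kernel_args(params, scenario)
    ev_t = np.zeros(int(record_events), dtype=np.float64)
    ev_c = np.zeros(int(record_events), dtype=np.int64)
    chk_t = np.zeros(0, dtype=np.float64)
    chk_c = np.zeros((0, 4), dtype=np.int64)
    out, mf, t, w, m, rw, rm, n_ev = _kernels.replicate_kernel(
        int(seed) & 0x7FFFFFFF,
        ka["w0"],
        ka["m0"],
        0,
        0,
        ka["K"],
        ka["g"],
        ka["cfW"],
        ka["cfM"],
        ka["theta"],
        ka["n"],
        ka["n_rise"],
        ka["mu"],
        ka["mu_p"],
        ka["mu_M"],
        ka["frozen"],
        t_end,
        rescue_threshold,
        cap,
        chk_t,
        chk_c,
        ev_t,
        ev_c,
    )
    if out == 4:
        raise RuntimeError(
            f"population exceeded the hard cap {cap}; raise `cap` for this run"
        )
    kept = min(n_ev, int(record_events))
    return ReplicateRecord(
        outcome=OUTCOMES[out],
        mutator_fixed=bool(mf),
        t_final=t,
        final_counts=(w, m, rw, rm),
        seed=int(seed),
        event_times=ev_t[:kept] if record_events else None,
        event_codes=ev_c[:kept] if record_events else None,
    )


def _substream_seeds(master_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n) & 0x7FFFFFFF).astype(np.int64)


def run_ensemble(
    params: ModelParams,
    n_replicates: int,
    master_seed: int,
    scenario: str = "de_novo",
    *,
    t_end: float | None = None,
    rescue_threshold: int | None = None,
    cap: int | None = None,
    checkpoints: np.ndarray | None = None,
):
    """Run a seeded ensemble; deterministic given ``master_seed``.

    Returns an :class:`EnsembleSummary`; if ``checkpoints`` is given,
    returns ``(summary, chk_NW)`` where ``chk_NW[i, j]`` is replicate i's
    non-rescue population size at checkpoint j.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    t_end, rescue_threshold, cap = _resolve_run_params(
        params, t_end, rescue_threshold, cap
    )
    ka = _kernel_args(params, scenario)
    seeds = _substream_seeds(master_seed, n_replicates)
    chk = (
        np.asarray(checkpoints, dtype=np.float64)
        if checkpoints is not None
        else np.zeros(0, dtype=np.float64)
    )
    outcomes, fixed, t_final, finals, chk_NW = _kernels.ensemble_kernel(
        seeds,
        ka["w0"],
        ka["m0"],
        ka["K"],
        ka["g"],
        ka["cfW"],
        ka["cfM"],
        ka["theta"],
        ka["n"],
        ka["n_rise"],
        ka["mu"],
        ka["mu_p"],
        ka["mu_M"],
        ka["frozen"],
        t_end,
        rescue_threshold,
        cap,
        chk,
    )
    if np.any(outcomes == 4):
        raise RuntimeError(f"population exceeded the hard cap {cap} in some replicates")
    counts = {name: int(np.sum(outcomes == i)) for i, name in enumerate(OUTCOMES)}
    summary = EnsembleSummary(
        n_replicates=n_replicates,
        counts=counts,
        n_mutator_fixed=int(fixed.sum()),
        master_seed=master_seed,
        scenario=scenario,
        outcomes=outcomes,
        mutator_fixed=fixed.astype(bool),
    )
    if checkpoints is not None:
        return summary, chk_NW
    return summary


def branching_oracle_pfix(
    t0: float,
    traj: Trajectory,
    params: ModelParams,
    background: str,
    n_lineages: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo fixation frequency of single founder lineages.

    Background ``"W"``/``"M"``: a single rescue mutant (RW / RM) founded
    at ``t0``.  Background ``"M_lineage"``: a single non-rescue mutator
    whose births yield rescue mutants with probability mu'.  Rates are
    read from the resident trajectory with no feedback.  Returns
    ``(frequency, binomial SE)``.
    """
    if background not in ("W", "M", "M_lineage"):
        raise ValueError(f"unknown background {background!r}")
    env, mut, dem = params.env, params.mut, params.dem
    if env.constant:
        raise ValueError("the branching oracle reads a deteriorating trajectory")
    two_type = background == "M_lineage"
    cfR = mut.cost_factor_wildtype if background == "W" else mut.cost_factor_mutator
    cfA = mut.cost_factor_mutator
    comp = traj.competition
    t_max = float(traj.times[-1])
    b_end = cfR * hill_rise(t_max, env.theta, env.rise_exponent) * comp[-1]
    supercrit_end = b_end > dem.g
    seeds = _substream_seeds(seed, n_lineages)
    wins = _kernels.oracle_ensemble_kernel(
        seeds,
        float(t0),
        traj.times,
        comp,
        env.theta,
        env.n,
        env.rise_exponent,
        cfA,
        cfR,
        dem.g,
        mut.mu_prime,
        two_type,
        supercrit_end,
        t_max,
    )
    p = wins / n_lineages
    se = math.sqrt(max(p * (1.0 - p), 1.0 / n_lineages) / n_lineages)
    return p, se
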