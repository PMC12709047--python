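"""Fixation probabilities and rescue-probability integrals.

A rescue mutant founded as a single copy at time ``t0`` survives drift
with probability

    Pfix(t0) = 1 / (1 + g * int_{t0}^inf exp(rho(t)) dt),
    rho(t)   = int_{t0}^t [g - f_eff(u)] du,

where ``f_eff`` is the rescue lineage's growth rate damped by logistic
competition with the resident populations.  The probability that the
population is rescued through a given mutational channel is the founding
rate integrated against this fixation probability, e.g. for the wildtype
channel

    PrW = mu * int_0^inf PfixW(u) NW(u) fW(u) [1 - N(u)/K] du.

For a de-novo mutator the founder is not itself a rescue mutant: its
lineage must first produce a rescue mutation that then fixes.  That
fixation probability, PfixM(t0), is obtained by integrating the backward
extinction-probability equations of the two-type (mutator, rescued-mutator)
time-inhomogeneous branching process, written in terms of success
probabilities for numerical conditioning.

All outer integrals share the trajectory's dense time grid; the integral
in Pfix is evaluated in log space with an analytic constant-rate tail
beyond the trajectory horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .deterministic_dynamics import ModelParams, Trajectory, integrate
from .growth_model import LineageType, growth_rate

__all__ = [
    "FixationProfile",
    "RescueResult",
    "effective_growth",
    "fixation_profile",
    "fixation_prob_rescue",
    "mutator_fixation_profile",
    "fixation_prob_mutator_lineage",
    "rescue_prob",
    "total_rescue",
    "mutator_advantage",
    "preexistence_advantage_limit",
    "rescue_result",
]

#: probabilities below this are reported as exactly 0 (quadrature noise floor)
PROB_FLOOR = 1e-30

_BACKGROUND_LINEAGE = {"W": LineageType.RW, "M": LineageType.RM}


@dataclass
class FixationProfile:
    """Fixation probability of a single founder vs. founding time."""

    times: np.ndarray
    pfix: np.ndarray
    background: str  # "W_rescue", "M_rescue" or "M_lineage"

    def at(self, t0) -> np.ndarray | float:
        """Interpolate the profile at founding time(s) ``t0``."""
        out = np.interp(t0, self.times, self.pfix)
        return float(out) if np.ndim(t0) == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t0": self.times, "pfix": self.pfix})


@dataclass
class RescueResult:
    """Rescue probabilities and mutator advantage for one parameter set."""

    PrW0: float
    PrW: float
    PrM: float
    Prall: float
    scenario: str
    params: ModelParams = field(repr=False)

    @property
    def advantage_defined(self) -> bool:
        return self.PrW0 > 0.0

    @property
    def advantage(self) -> float:
        """Relative mutator advantage (Prall - PrW0)/PrW0; NaN if undefined."""
        if not self.advantage_defined:
            return float("nan")
        return (self.Prall - self.PrW0) / self.PrW0

    @property
    def absolute_gain(self) -> float:
        return self.Prall - self.PrW0

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "PrW0": self.PrW0,
            "PrW": self.PrW,
            "PrM": self.PrM,
            "Prall": self.Prall,
            "advantage": self.advantage if self.advantage_defined else None,
            "advantage_defined": self.advantage_defined,
            "absolute_gain": self.absolute_gain,
        }


def effective_growth(t, lineage: LineageType, traj: Trajectory, params: ModelParams):
    """Growth rate of ``lineage`` damped by competition, f * (1 - N/K)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < traj.times[0]) or np.any(t_arr > traj.times[-1]):
        raise ValueError("t outside the trajectory grid")
    comp = np.interp(t_arr, traj.times, traj.competition)
    out = growth_rate(t_arr, lineage, params.env, params.mut) * comp
    return float(out) if t_arr.ndim == 0 else out


def _rescue_effective_profile(traj: Trajectory, params: ModelParams, background: str):
    lineage = _BACKGROUND_LINEAGE[background]
    f = growth_rate(traj.times, lineage, params.env, params.mut)
    return np.asarray(f) * traj.competition


def fixation_profile(
    traj: Trajectory, params: ModelParams, background: str = "W"
) -> FixationProfile:
    """Pfix(t0) of a single rescue mutant, on the trajectory grid.

    ``background`` selects the rescue lineage: ``"W"`` (RW, cost of nu) or
    ``"M"`` (RM, cost of nu').  Evaluated simultaneously for every grid
    point via a reverse log-sum-exp accumulation of the exponent integral;
    the tail beyond the trajectory horizon is added in closed form with
    the end-of-grid rates held constant.  If the lineage is subcritical at
    the horizon the tail integral diverges and Pfix is identically 0.
    """
    if background not in _BACKGROUND_LINEAGE:
        raise ValueError(f"background must be 'W' or 'M', got {background!r}")
    t = traj.times
    g = params.dem.g
    f_eff = _rescue_effective_profile(traj, params, background)
    label = f"{background}_rescue"

    f_end = f_eff[-1]
    if f_end <= g:
        # never recovers above the death rate: certain loss
        return FixationProfile(times=t, pfix=np.zeros_like(t), background=label)

    # R(t) = int_0^t (g - f_eff); rho(t; t0) = R(t) - R(t0)
    R = cumulative_trapezoid(g - f_eff, t, initial=0.0)
    dt = np.diff(t)
    # per-segment integral of e^R with R piecewise linear:
    #   int = dt * e^{R_i} * (e^d - 1)/d,  d = R_{i+1} - R_i
    # (exact for linear R; trapezoid would need steps << 1/(f-g))
    d = np.diff(R)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(
            np.abs(d) < 1e-8,
            d / 2.0,
            np.where(
                d > 30.0,
                d - np.log(np.abs(d) + 1e-300),
                np.log(np.abs(np.expm1(np.minimum(d, 30.0))) / (np.abs(d) + 1e-300)),
            ),
        )
    seg = np.log(dt) + R[:-1] + log_ratio
    # logW[j] = log int_{t_j}^{T} e^{R}
    rev = np.logaddexp.accumulate(seg[::-1])[::-1]
    log_tail = R[-1] - np.log(f_end - g)
    logW = np.empty_like(R)
    logW[:-1] = np.logaddexp(rev, log_tail)
    logW[-1] = log_tail
    # Pfix = 1/(1 + g e^{logW - R}) computed as a stable sigmoid
    x = np.log(g) + logW - R
    pfix = np.exp(-np.logaddexp(0.0, x))
    pfix[pfix < PROB_FLOOR] = 0.0
    return FixationProfile(times=t, pfix=pfix, background=label)


def fixation_prob_rescue(
    t0: float, traj: Trajectory, params: ModelParams, background: str = "W"
) -> float:
    """Pfix of a single rescue mutant founded at ``t0`` (scalar helper)."""
    return fixation_profile(traj, params, background).at(t0)


def mutator_fixation_profile(
    traj: Trajectory, params: ModelParams
) -> tuple[FixationProfile, FixationProfile]:
    """PfixM(t0): a single de-novo mutator founds a fixing rescue lineage.

    Solves the backward equations of the two-type branching process in
    which a mutator individual gives birth at rate fM(t)(1 - N/K), dies at
    rate g, and each offspring carries the rescue allele with probability
    mu'; rescued mutators (RM) breed true at rate fRM(t)(1 - N/K).  In
    terms of the success probabilities pM(t0) = PfixM and pR(t0) =
    Pfix of a single RM founder, the backward system is

        dpM/dt = -[(bM - g - bM mu') pM + bM mu' pR
                   - bM (1 - mu') pM^2 - bM mu' pM pR]
        dpR/dt = -[(bR - g) pR - bR pR^2]

    integrated from the horizon (pM = 0; pR from the constant-rate closed
    form) back to t=0.  Returns ``(PfixM profile, RM-rescue profile)``;
    the second must agree with :func:`fixation_profile` on background "M"
    and serves as an internal consistency check.
    """
    t = traj.times
    g = params.dem.g
    mu_p = params.mu_prime
    comp_grid = traj.competition
    env, mut = params.env, params.mut

    def bM(ti):
        return growth_rate(ti, LineageType.M, env, mut) * np.interp(
            ti, t, comp_grid
        )

    def bR(ti):
        return growth_rate(ti, LineageType.RM, env, mut) * np.interp(
            ti, t, comp_grid
        )

    T = t[-1]
    if bM(T) > g:
        raise RuntimeError(
            "horizon too short: the mutator lineage is still supercritical "
            f"at the trajectory end (b_M({T:g}) = {bM(T):.3g} > g = {g:g})"
        )
    bR_end = bR(T)
    pR_T = max(0.0, 1.0 - g / bR_end) if bR_end > g else 0.0

    def rhs(ti, y):
        pM, pR = y
        bm, br = bM(ti), bR(ti)
        dpM = (bm - g - bm * mu_p) * pM + bm * mu_p * pR
        dpM -= bm * (1.0 - mu_p) * pM * pM + bm * mu_p * pM * pR
        dpR = (br - g) * pR - br * pR * pR
        return [-dpM, -dpR]

    sol = solve_ivp(
        rhs,
        (T, 0.0),
        [0.0, pR_T],
        method="LSODA",
        rtol=1e-8,
        atol=1e-14,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"backward fixation system failed: {sol.message}")
    y = sol.sol(t)
    pM = np.clip(y[0], 0.0, 1.0)
    pR = np.clip(y[1], 0.0, 1.0)
    pM[pM < PROB_FLOOR] = 0.0
    return (
        FixationProfile(times=t, pfix=pM, background="M_lineage"),
        FixationProfile(times=t, pfix=pR, background="M_rescue"),
    )


def fixation_prob_mutator_lineage(
    t0: float, traj: Trajectory, params: ModelParams
) -> float:
    """PfixM at a single founding time (scalar helper)."""
    return mutator_fixation_profile(traj, params)[0].at(t0)


def rescue_prob(
    traj: Trajectory,
    params: ModelParams,
    source: str,
    scenario: str | None = None,
) -> float:
    """Probability of rescue through the ``source`` channel.

    ``source="W"``: rescue mutants seeded from wildtype births at rate mu.
    ``source="M"``: in the de novo scenario, mutator lineages seeded from
    wildtype births at rate mu_M, weighted by PfixM; in the pre-existing
    scenario, rescue mutants seeded from mutator births at rate mu'.
    """
    if source not in ("W", "M"):
        raise ValueError(f"source must be 'W' or 'M', got {source!r}")
    scenario = scenario or traj.scenario
    t = traj.times
    comp = traj.competition
    env, mut = params.env, params.mut

    if source == "W":
        prof = fixation_profile(traj, params, background="W")
        fW = np.asarray(growth_rate(t, LineageType.W, env, mut))
        integrand = params.mu * prof.pfix * traj.NW * fW * comp
    elif scenario == "de_novo":
        prof, _ = mutator_fixation_profile(traj, params)
        fW = np.asarray(growth_rate(t, LineageType.W, env, mut))
        integrand = params.mu_M * prof.pfix * traj.NW * fW * comp
    else:
        prof = fixation_profile(traj, params, background="M")
        fM = np.asarray(growth_rate(t, LineageType.M, env, mut))
        integrand = params.mu_prime * prof.pfix * traj.NM * fM * comp

    pr = float(np.trapezoid(integrand, t))
    pr = min(max(pr, 0.0), 1.0)
    return 0.0 if pr < PROB_FLOOR else pr


def total_rescue(PrW: float, PrM: float) -> float:
    """Overall rescue probability PrW + (1 - PrW) PrM.

    Rescue by one background excludes later rescue by the other.
    """
    for name, p in (("PrW", PrW), ("PrM", PrM)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    return PrW + (1.0 - PrW) * PrM


def mutator_advantage(Prall: float, PrW0: float) -> float:
    """Relative advantage (Prall - PrW0)/PrW0.

    Raises when PrW0 = 0, where the measure is undefined.
    """
    if PrW0 <= 0.0:
        raise ZeroDivisionError("mutator advantage undefined: PrW0 = 0")
    return (Prall - PrW0) / PrW0


def preexistence_advantage_limit(F: float, alpha: float) -> float:
    """Cost-free limit (F - 1) * alpha of the pre-existence advantage."""
    if F < 1:
        raise ValueError(f"F must be >= 1, got {F}")
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    return (F - 1.0) * alpha


def rescue_result(params: ModelParams, scenario: str) -> RescueResult:
    """End-to-end pipeline: integrate dynamics and assemble a RescueResult.

    ``PrW0`` is computed from the mutator-free baseline (``mu_M=0`` for
    de novo, ``alpha=0`` for pre-existing), which share the same
    single-population decline.
    """
    if scenario == "de_novo":
        baseline_params = params.with_(E=0.0)
    elif scenario == "preexisting":
        baseline_params = params.with_(alpha=0.0)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    traj = integrate(params, scenario)
    traj0 = integrate(baseline_params, scenario)
    PrW0 = rescue_prob(traj0, baseline_params, "W")
    PrW = rescue_prob(traj, params, "W")
    PrM = rescue_prob(traj, params, "M")
    return RescueResult(
        PrW0=PrW0,
        PrW=PrW,
        PrM=PrM,
        Prall=total_rescue(PrW, PrM),
        scenario=scenario,
        params=params,
    )
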