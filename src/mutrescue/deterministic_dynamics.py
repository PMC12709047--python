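"""Deterministic population dynamics under the deteriorating environment.

The wildtype (and, where applicable, the mutator) population declines
logistically as its growth rate falls below the death rate ``g``.  Two
scenarios are integrated:

* ``de_novo`` — mutators emerge stochastically from wildtype births at
  rate ``mu_M``; here ``NM`` is the deterministic approximation of the
  *expected* mutator population size, which competes with the wildtype in
  the shared carrying-capacity term.
* ``preexisting`` — a fraction ``alpha`` of the equilibrium population is
  mutator at t=0 and no further modifier mutation occurs; both populations
  decline deterministically.

Populations are treated as continuous densities; discreteness and
extinction are the business of :mod:`mutrescue.stochastic_sim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .growth_model import (
    EnvironmentParams,
    LineageType,
    MutationParams,
    growth_rate,
)

__all__ = [
    "DemographyParams",
    "ModelParams",
    "Trajectory",
    "equilibrium_size",
    "integrate_de_novo",
    "integrate_preexisting",
    "integrate",
]

#: adaptive integrator tolerances; populations span many orders of
#: magnitude on the way to extinction
RTOL = 1e-8
ATOL = 1e-10

#: truncation rule: stop once fW(t) < FW_CUTOFF*fW(0) and N_total <
#: POP_CUTOFF individuals, capped at HORIZON_CAP_THETA * theta
FW_CUTOFF = 1e-8
POP_CUTOFF = 1e-3
HORIZON_CAP_THETA = 50.0

#: grid refinement around the environmental transition
REFINE_POINTS = 2000
BASE_POINTS = 2000


@dataclass(frozen=True)
class DemographyParams:
    """Carrying capacity ``K``, per-capita death rate ``g`` and the
    pre-existing mutator fraction ``alpha``."""

    K: float
    g: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"carrying capacity K must be > 0, got {self.K}")
        if not 0 < self.g < 1:
            raise ValueError(f"death rate g must be in (0, 1), got {self.g}")
        if not 0 <= self.alpha < 1:
            raise ValueError(f"mutator fraction alpha must be in [0, 1), got {self.alpha}")


@dataclass(frozen=True)
class ModelParams:
    """Immutable bundle of environment, mutation and demography parameters."""

    env: EnvironmentParams
    mut: MutationParams
    dem: DemographyParams

    def __post_init__(self) -> None:
        fW0 = self.mut.cost_factor_wildtype
        if fW0 <= self.dem.g:
            raise ValueError(
                f"no viable equilibrium: fW(0) = {fW0} <= g = {self.dem.g}"
            )

    # convenience pass-throughs used throughout the package
    @property
    def mu(self) -> float:
        return self.mut.mu

    @property
    def mu_prime(self) -> float:
        return self.mut.mu_prime

    @property
    def mu_M(self) -> float:
        return self.mut.mu_M

    @property
    def fW0(self) -> float:
        """Wildtype growth rate at t=0 (Hill factor is 1)."""
        return self.mut.cost_factor_wildtype

    def growth(self, t, lineage: LineageType):
        return growth_rate(t, lineage, self.env, self.mut)

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with selected nested fields replaced.

        Accepts any field name of the nested parameter dataclasses, e.g.
        ``params.with_(E=0.0, alpha=0.0)``.
        """
        env_f = {f for f in EnvironmentParams.__dataclass_fields__}
        mut_f = {f for f in MutationParams.__dataclass_fields__}
        dem_f = {f for f in DemographyParams.__dataclass_fields__}
        env_kw = {k: v for k, v in kw.items() if k in env_f}
        mut_kw = {k: v for k, v in kw.items() if k in mut_f}
        dem_kw = {k: v for k, v in kw.items() if k in dem_f}
        unknown = set(kw) - env_f - mut_f - dem_f
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return ModelParams(
            env=replace(self.env, **env_kw) if env_kw else self.env,
            mut=replace(self.mut, **mut_kw) if mut_kw else self.mut,
            dem=replace(self.dem, **dem_kw) if dem_kw else self.dem,
        )


@dataclass
class Trajectory:
    """Deterministic population sizes on a dense time grid.

    ``NM`` holds E[NM] in the de novo scenario and the deterministic
    mutator population in the pre-existing scenario.
    """

    times: np.ndarray
    NW: np.ndarray
    NM: np.ndarray
    scenario: str
    params: ModelParams = field(repr=False)

    @property
    def N_total(self) -> np.ndarray:
        return self.NW + self.NM

    @property
    def competition(self) -> np.ndarray:
        """Logistic competition factor 1 - (NW+NM)/K, clipped at 0."""
        return np.clip(1.0 - self.N_total / self.params.dem.K, 0.0, None)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "NW": self.NW, "NM": self.NM})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def equilibrium_size(dem: DemographyParams, fW0: float) -> float:
    """Pre-change equilibrium population size ``K(1 - g/fW(0))``."""
    if fW0 <= dem.g:
        raise ValueError(
            f"no viable equilibrium: initial growth rate {fW0} <= death rate {dem.g}"
        )
    return dem.K * (1.0 - dem.g / fW0)


def _horizon(params: ModelParams, t_end: float | None) -> float:
    if t_end is not None:
        return float(t_end)
    theta = params.env.theta
    if params.env.constant:
        return 6.0 * theta
    return HORIZON_CAP_THETA * theta


def _grid(params: ModelParams, T: float) -> np.ndarray:
    theta = params.env.theta
    base = np.linspace(0.0, T, BASE_POINTS + 1)
    hi = min(5.0 * theta, T)
    lo = min(0.2 * theta, hi)
    refine = np.linspace(lo, hi, REFINE_POINTS)
    return np.union1d(base, refine)


def integrate(
    params: ModelParams,
    scenario: str,
    *,
    t_end: float | None = None,
    initial: tuple[float, float] | None = None,
) -> Trajectory:
    """Integrate the coupled wildtype/mutator ODE system.

    Parameters
    ----------
    scenario : {"de_novo", "preexisting"}
    t_end : float, optional
        Override the truncation rule with a fixed horizon.
    initial : (NW0, NM0), optional
        Absolute initial sizes; defaults to the equilibrium split of the
        scenario (all-wildtype for de novo, ``(1-alpha)/alpha`` split for
        pre-existing).
    """
    if scenario not in ("de_novo", "preexisting"):
        raise ValueError(f"unknown scenario {scenario!r}")
    env, mut, dem = params.env, params.mut, params.dem
    K, g = dem.K, dem.g
    mu_M = mut.mu_M

    N0 = equilibrium_size(dem, params.fW0)
    if initial is None:
        if scenario == "preexisting":
            y0 = [(1.0 - dem.alpha) * N0, dem.alpha * N0]
        else:
            y0 = [N0, 0.0]
    else:
        y0 = [float(initial[0]), float(initial[1])]

    fW = lambda t: growth_rate(t, LineageType.W, env, mut)
    fM = lambda t: growth_rate(t, LineageType.M, env, mut)

    if scenario == "de_novo":

        def rhs(t, y):
            NW, NM = y
            comp = 1.0 - (NW + NM) / K
            bW = fW(t) * comp
            dNW = (bW * (1.0 - mu_M) - g) * NW
            dNM = mu_M * bW * NW + (fM(t) * comp - g) * NM
            return [dNW, dNM]

    else:

        def rhs(t, y):
            NW, NM = y
            comp = 1.0 - (NW + NM) / K
            return [(fW(t) * comp - g) * NW, (fM(t) * comp - g) * NM]

    T = _horizon(params, t_end)
    events = None
    if t_end is None and not env.constant:
        fW0 = params.fW0

        def done(t, y):
            # crosses zero (downwards) once both the environment and the
            # population are numerically gone
            return max(y[0] + y[1] - POP_CUTOFF, fW(t) - FW_CUTOFF * fW0)

        done.terminal = True
        done.direction = -1
        events = [done]

    sol = solve_ivp(
        rhs,
        (0.0, T),
        y0,
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        dense_output=True,
        events=events,
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    T_eff = float(sol.t[-1])
    times = _grid(params, T_eff)
    y = sol.sol(times)
    NW = np.clip(y[0], 0.0, None)
    NM = np.clip(y[1], 0.0, None)
    return Trajectory(times=times, NW=NW, NM=NM, scenario=scenario, params=params)


def integrate_de_novo(params: ModelParams, **kw) -> Trajectory:
    """Wildtype decline with expected de-novo mutator population."""
    return integrate(params, "de_novo", **kw)


def integrate_preexisting(params: ModelParams, **kw) -> Trajectory:
    """Coupled decline of wildtype and pre-existing mutator populations."""
    if params.dem.alpha == 0 and kw.get("initial") is None:
        # legal but degenerate: reduces to the single-population decline
        pass
    return integrate(params, "preexisting", **kw)
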