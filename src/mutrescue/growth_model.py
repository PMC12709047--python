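"""Time-dependent growth rates and mutation-rate bookkeeping.

The environment deteriorates along a Hill function centred at time ``theta``
with steepness ``n``: lineages without the rescue allele have a falling
relative growth rate, lineages carrying the rescue allele a rising one.
Every growth rate is additionally scaled by a linear mutation-load cost
``max(0, 1 - nu/nu_c)`` so that genomic mutation rates at or above the
critical rate ``nu_c`` are sterile (lethal mutagenesis).

Four lineage types are tracked throughout the package:

========  ====================================================
``W``     wildtype (mutation rate ``nu``, no rescue allele)
``M``     mutator (rate ``nu' = F*nu`` or ``nu + delta``)
``RW``    rescue allele on the wildtype background
``RM``    rescue allele on the mutator background
========  ====================================================
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "LineageType",
    "EnvironmentParams",
    "MutationParams",
    "cost_factor",
    "hill_decay",
    "hill_rise",
    "growth_rate",
    "mutator_rate",
    "derived_rates",
]

ArrayLike = Union[float, np.ndarray]


class LineageType(enum.Enum):
    """The four lineage types of the two-locus model."""

    W = "W"
    M = "M"
    RW = "RW"
    RM = "RM"

    @property
    def is_mutator(self) -> bool:
        return self in (LineageType.M, LineageType.RM)

    @property
    def is_rescued(self) -> bool:
        return self in (LineageType.RW, LineageType.RM)


@dataclass(frozen=True)
class EnvironmentParams:
    """Hill-function environment.

    Parameters
    ----------
    n : float
        Speed of the environmental change (Hill exponent), > 0.
    theta : float
        Time (generations) around which the change is centred, > 0.
    mode : str
        ``"deteriorating"`` (default) or ``"constant"``.  In constant mode
        every growth function is frozen at its t=0 value, i.e. non-rescue
        lineages keep their full cost-scaled growth rate and rescue
        lineages have growth rate zero.
    n_rise : float or None
        Optional separate Hill exponent for the rescue allele's rise;
        defaults to ``n``.
    """

    n: float
    theta: float
    mode: str = "deteriorating"
    n_rise: float | None = None

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError(f"Hill exponent n must be > 0, got {self.n}")
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.mode not in ("deteriorating", "constant"):
            raise ValueError(f"unknown environment mode {self.mode!r}")
        if self.n_rise is not None and not self.n_rise > 0:
            raise ValueError(f"n_rise must be > 0, got {self.n_rise}")

    @property
    def rise_exponent(self) -> float:
        return self.n if self.n_rise is None else self.n_rise

    @property
    def constant(self) -> bool:
        return self.mode == "constant"


@dataclass(frozen=True)
class MutationParams:
    """Genomic mutation rates and their partition over the two loci.

    ``nu`` is the wildtype genomic mutation rate per genome per generation;
    a fraction ``r`` of genomic mutations hits the rescue locus, so the
    per-generation rescue-mutation rates are ``mu = r*nu`` (wildtype) and
    ``mu' = r*nu'`` (mutator).  Mutators emerge from wildtype births at
    rate ``mu_M = E*r*nu`` where ``E`` is the emergence factor.  The
    mutator genomic rate is ``nu' = F*nu`` (multiplicative model) or
    ``nu + delta`` (additive model).
    """

    nu: float
    nu_c: float = 1.0
    F: float = 1.0
    delta: float = 0.0
    mutator_model: str = "multiplicative"
    r: float = 2e-4
    E: float = 0.0

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError(f"nu must be >= 0, got {self.nu}")
        if not self.nu_c > 0:
            raise ValueError(f"nu_c must be > 0, got {self.nu_c}")
        if self.mutator_model not in ("multiplicative", "additive"):
            raise ValueError(f"unknown mutator_model {self.mutator_model!r}")
        if self.mutator_model == "multiplicative" and self.F < 1:
            raise ValueError(f"mutator strength F must be >= 1, got {self.F}")
        if self.mutator_model == "additive" and self.delta < 0:
            raise ValueError(f"additive increment delta must be >= 0, got {self.delta}")
        if not 0 < self.r <= 1:
            raise ValueError(f"rescue-locus fraction r must be in (0, 1], got {self.r}")
        if self.E < 0:
            raise ValueError(f"emergence factor E must be >= 0, got {self.E}")
        mu, mu_prime, mu_M = derived_rates(self)
        if mu + mu_M > 1:
            raise ValueError(
                f"per-birth mutation probabilities mu + mu_M = {mu + mu_M} exceed 1"
            )
        if mu_prime > 1:
            raise ValueError(f"per-birth mutation probability mu' = {mu_prime} exceeds 1")

    @property
    def nu_prime(self) -> float:
        return mutator_rate(self)

    @property
    def mu(self) -> float:
        return self.r * self.nu

    @property
    def mu_prime(self) -> float:
        return self.r * self.nu_prime

    @property
    def mu_M(self) -> float:
        return self.E * self.r * self.nu

    @property
    def cost_factor_wildtype(self) -> float:
        return cost_factor(self.nu, self.nu_c)

    @property
    def cost_factor_mutator(self) -> float:
        return cost_factor(self.nu_prime, self.nu_c)


def cost_factor(nu: float, nu_c: float) -> float:
    """Growth-rate multiplier ``max(0, 1 - nu/nu_c)`` from mutation load.

    The linear cost hits zero at the critical rate ``nu_c`` (lethal
    mutagenesis) and is clamped there for higher rates.
    """
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    if not nu_c > 0:
        raise ValueError(f"nu_c must be > 0, got {nu_c}")
    return max(0.0, 1.0 - nu / nu_c)


def mutator_rate(mut: MutationParams) -> float:
    """Mutator genomic mutation rate nu' under the configured model."""
    if mut.mutator_model == "multiplicative":
        return mut.F * mut.nu
    return mut.nu + mut.delta


def derived_rates(mut: MutationParams) -> tuple[float, float, float]:
    """Per-locus per-generation rates ``(mu, mu', mu_M)``.

    ``mu = r*nu`` (wildtype -> rescue), ``mu' = r*nu'`` (mutator -> rescue),
    ``mu_M = E*r*nu`` (wildtype -> mutator).
    """
    nu_prime = mutator_rate(mut)
    return mut.r * mut.nu, mut.r * nu_prime, mut.E * mut.r * mut.nu


def hill_decay(t: ArrayLike, theta: float, n: float) -> ArrayLike:
    """Falling Hill factor 1/(1 + (t/theta)^n); equals 1 at t=0."""
    x = np.asarray(t, dtype=float) / theta
    out = 1.0 / (1.0 + x**n)
    return out if out.ndim else float(out)


def hill_rise(t: ArrayLike, theta: float, n: float) -> ArrayLike:
    """Rising Hill factor (t/theta)^n/(1 + (t/theta)^n); equals 0 at t=0."""
    x = np.asarray(t, dtype=float) / theta
    xn = x**n
    out = xn / (1.0 + xn)
    return out if out.ndim else float(out)


def growth_rate(
    t: ArrayLike,
    lineage: LineageType,
    env: EnvironmentParams,
    mut: MutationParams,
) -> ArrayLike:
    """Relative growth rate of ``lineage`` at time ``t``.

    Non-rescue lineages (W, M) follow the falling Hill function, rescue
    lineages (RW, RM) the rising one; each is scaled by the cost factor of
    its background (``nu`` for W/RW, ``nu'`` for M/RM).  In a constant
    environment all four are frozen at their t=0 values.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("time t must be >= 0")
    cf = mut.cost_factor_mutator if lineage.is_mutator else mut.cost_factor_wildtype
    if env.constant:
        val = cf if not lineage.is_rescued else 0.0
        arr = np.asarray(t, dtype=float)
        return val if arr.ndim == 0 else np.full_like(arr, val)
    if lineage.is_rescued:
        return cf * hill_rise(t, env.theta, env.rise_exponent)
    return cf * hill_decay(t, env.theta, env.n)
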