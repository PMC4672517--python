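"""Per-copy loss-rate (hazard) functions for duplicate-gene retention mechanisms.

Three retention mechanisms are modeled through the shape of the instantaneous
loss rate (hazard) of a duplicate copy as a function of time (time-dependent
model) or of the copy's own age (age-dependent model):

* **nonfunctionalization** — degenerative silencing of one copy; a constant
  hazard ``mu``.
* **neofunctionalization** — retention after a single beneficial change; a
  convexly decaying hazard ``alpha * exp(-age * alpha)`` with ``0 < alpha < 1``.
* **subfunctionalization** — retention after complementary degenerative
  changes partition the ancestral function; a sigmoidally decaying
  (reversed-logistic) hazard ``alpha * exp(gamma - age) / (1 + exp(gamma - age))``
  with scale ``0 < alpha < 1`` and a known location ``gamma > 0``.

Duplications occur at a constant per-copy rate ``lam`` in every mechanism.
All closed-form cumulative hazards needed by the reconstructed-process
quantities live here as well.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "Mechanism",
    "MechanismParams",
    "DEFAULT_GAMMA",
    "hazard",
    "cumulative_hazard",
    "rho",
    "HazardRate",
    "loss_rate",
    "standard_mechanisms",
]

#: Default logistic location for subfunctionalization. With gamma = 5 the
#: subfunctionalization hazard at age 0 is within 1% of alpha, so all three
#: mechanisms share (almost exactly) the same initial deletion rate.
DEFAULT_GAMMA = 5.0


class Mechanism(str, enum.Enum):
    """Duplicate-gene retention mechanism."""

    NONFUNCTIONALIZATION = "nonfunctionalization"
    NEOFUNCTIONALIZATION = "neofunctionalization"
    SUBFUNCTIONALIZATION = "subfunctionalization"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_MECHANISM_ALIASES = {
    "nonfunctionalization": Mechanism.NONFUNCTIONALIZATION,
    "nonfunc": Mechanism.NONFUNCTIONALIZATION,
    "non": Mechanism.NONFUNCTIONALIZATION,
    "neofunctionalization": Mechanism.NEOFUNCTIONALIZATION,
    "neofunc": Mechanism.NEOFUNCTIONALIZATION,
    "neo": Mechanism.NEOFUNCTIONALIZATION,
    "subfunctionalization": Mechanism.SUBFUNCTIONALIZATION,
    "subfunc": Mechanism.SUBFUNCTIONALIZATION,
    "sub": Mechanism.SUBFUNCTIONALIZATION,
}


def as_mechanism(mechanism: "Mechanism | str") -> Mechanism:
    """Coerce a mechanism name (full name or short alias) to :class:`Mechanism`."""
    if isinstance(mechanism, Mechanism):
        return mechanism
    try:
        return _MECHANISM_ALIASES[str(mechanism).lower()]
    except KeyError:
        raise ValueError(
            f"unknown mechanism {mechanism!r}; expected one of "
            f"{sorted(set(_MECHANISM_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class MechanismParams:
    """Rate parameters of one retention mechanism.

    Parameters
    ----------
    mechanism:
        Which retention mechanism the hazard describes.
    lam:
        Constant per-copy duplication rate (per unit time, > 0).
    mu:
        Constant loss rate; nonfunctionalization only.
    alpha:
        Hazard scale in (0, 1); neo- and subfunctionalization only.
    gamma:
        Logistic location (time units, > 0); subfunctionalization only.
        Treated as known and fixed, never estimated.
    """

    mechanism: Mechanism
    lam: float
    mu: Optional[float] = None
    alpha: Optional[float] = None
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", as_mechanism(self.mechanism))
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"duplication rate lam must be > 0, got {self.lam}")
        m = self.mechanism
        if m is Mechanism.NONFUNCTIONALIZATION:
            if self.mu is None or not (self.mu > 0 and math.isfinite(self.mu)):
                raise ValueError("nonfunctionalization requires mu > 0")
            if self.alpha is not None or self.gamma is not None:
                raise ValueError("nonfunctionalization takes only (lam, mu)")
        else:
            if self.mu is not None:
                raise ValueError(f"{m.value} does not take mu")
            if self.alpha is None or not (0.0 < self.alpha < 1.0):
                raise ValueError(f"{m.value} requires alpha in (0, 1)")
            if m is Mechanism.NEOFUNCTIONALIZATION:
                if self.gamma is not None:
                    raise ValueError("neofunctionalization does not take gamma")
            else:
                if self.gamma is None or not (self.gamma > 0):
                    raise ValueError("subfunctionalization requires gamma > 0")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def nonfunctionalization(cls, lam: float, mu: float) -> "MechanismParams":
        return cls(Mechanism.NONFUNCTIONALIZATION, lam=lam, mu=mu)

    @classmethod
    def neofunctionalization(cls, lam: float, alpha: float) -> "MechanismParams":
        return cls(Mechanism.NEOFUNCTIONALIZATION, lam=lam, alpha=alpha)

    @classmethod
    def subfunctionalization(
        cls, lam: float, alpha: float, gamma: float = DEFAULT_GAMMA
    ) -> "MechanismParams":
        return cls(Mechanism.SUBFUNCTIONALIZATION, lam=lam, alpha=alpha, gamma=gamma)

    @property
    def loss_param(self) -> float:
        """The single free loss parameter (``mu`` or ``alpha``)."""
        return self.mu if self.mechanism is Mechanism.NONFUNCTIONALIZATION else self.alpha

    @property
    def loss_param_name(self) -> str:
        return "mu" if self.mechanism is Mechanism.NONFUNCTIONALIZATION else "alpha"

    def with_rates(self, lam: float, loss: float) -> "MechanismParams":
        """Return a copy with new duplication and loss-parameter values."""
        if self.mechanism is Mechanism.NONFUNCTIONALIZATION:
            return replace(self, lam=lam, mu=loss)
        return replace(self, lam=lam, alpha=loss)


def standard_mechanisms(
    lam: float = 0.2, loss: float = 0.8, gamma: float = DEFAULT_GAMMA
) -> dict[Mechanism, MechanismParams]:
    """The matched-onset parameter trio used throughout the simulation studies.

    All three mechanisms share the duplication rate ``lam`` and (nearly) the
    same initial deletion rate ``loss``, so differences in simulated
    duplication times are attributable to hazard shape alone.
    """
    return {
        Mechanism.NONFUNCTIONALIZATION: MechanismParams.nonfunctionalization(lam, loss),
        Mechanism.NEOFUNCTIONALIZATION: MechanismParams.neofunctionalization(lam, loss),
        Mechanism.SUBFUNCTIONALIZATION: MechanismParams.subfunctionalization(
            lam, loss, gamma
        ),
    }


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe for large |x|
    return np.logaddexp(0.0, x)


def hazard(params: MechanismParams, age):
    """Instantaneous per-copy loss rate at a given age (or absolute time).

    In the time-dependent model the argument is absolute time since the root;
    in the age-dependent model it is the copy's age. The functional forms are
    identical.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    m = params.mechanism
    if m is Mechanism.NONFUNCTIONALIZATION:
        out = np.full_like(age, params.mu)
    elif m is Mechanism.NEOFUNCTIONALIZATION:
        out = params.alpha * np.exp(-age * params.alpha)
    else:
        out = params.alpha * expit(params.gamma - age)
    return out if out.ndim else float(out)


def cumulative_hazard(params: MechanismParams, a0, a1):
    """Exact integral of the hazard over the age interval ``[a0, a1]``.

    Closed forms: constant hazard ``mu * (a1 - a0)``; neofunctionalization
    ``exp(-a0*alpha) - exp(-a1*alpha)``; subfunctionalization
    ``alpha * log((1 + e^{gamma-a0}) / (1 + e^{gamma-a1}))`` (evaluated with
    softplus for overflow safety).
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    if np.any(a0 < 0):
        raise ValueError("interval endpoints must be non-negative")
    if np.any(a1 < a0):
        raise ValueError("requires a1 >= a0")
    m = params.mechanism
    if m is Mechanism.NONFUNCTIONALIZATION:
        out = params.mu * (a1 - a0)
    elif m is Mechanism.NEOFUNCTIONALIZATION:
        out = np.exp(-a0 * params.alpha) - np.exp(-a1 * params.alpha)
    else:
        out = params.alpha * (_softplus(params.gamma - a0) - _softplus(params.gamma - a1))
    return out if out.ndim else float(out)


class HazardRate:
    """A mechanism hazard viewed as a time-dependent loss rate.

    Exposes the small protocol the reconstructed-process machinery needs:
    ``rate(t)`` (vectorized), ``integral(a, b)`` (exact cumulative hazard),
    and ``max_rate`` (an upper bound on the rate, attained at age 0 since all
    three hazards are non-increasing).
    """

    def __init__(self, params: MechanismParams):
        self.params = params
        self.max_rate = float(hazard(params, 0.0))

    def rate(self, t):
        return hazard(self.params, t)

    def integral(self, a, b):
        return cumulative_hazard(self.params, a, b)

    def __repr__(self) -> str:  # pragma: no cover
        return f"HazardRate({self.params!r})"


def loss_rate(params: MechanismParams) -> HazardRate:
    """Wrap ``params`` as the time-dependent loss rate of the time model."""
    return HazardRate(params)


def rho(params: MechanismParams, lossrate, tau: float, t: float):
    """Net log-decline exponent ``rho(tau, t) = int_tau^t mu_s ds - lam*(t - tau)``.

    ``lossrate`` may be any object with an ``integral(a, b)`` method (a raw
    mechanism :class:`HazardRate`, which uses closed forms, or a mean-loss-rate
    cache from the age model, which integrates its interpolant).
    """
    tau = np.asarray(tau, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < tau):
        raise ValueError("requires t >= tau")
    out = np.asarray(lossrate.integral(tau, t)) - params.lam * (t - tau)
    return out if out.ndim else float(out)
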