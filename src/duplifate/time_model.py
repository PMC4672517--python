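"""Reconstructed-process quantities for the time-dependent birth-death model.

The observable data are the duplication times of the lineages that survive to
the present time ``T`` (the reconstructed process): extinct copies leave no
trace. Starting from ``n0`` copies at time 0 (``n0 = 2`` at a duplication
root, whose time ``t_2 = 0`` is fixed), the ordered duplication times
``t_{n0+1} < ... < t_{nT} < T`` of the ``nT`` surviving lineages have a
tractable joint density built from three ingredients:

* ``P(tau, T)`` — the probability that a single copy alive at ``tau`` has at
  least one surviving descendant at ``T``:
  ``P(tau, T) = [1 + int_tau^T mu_t e^{rho(tau,t)} dt]^{-1}`` with
  ``rho(tau, t) = int_tau^t (mu_s - lam) ds``.
* ``u_ij = 1 - P(t_i, t_j) e^{rho(t_i, t_j)}`` — the probability that a copy
  alive at ``t_i`` leaves more than one reconstructed lineage at ``t_j``.
* ``eta_ij = 1 - (1 - u_iT) / (1 - u_jT)`` — the parameter of the (negative
  binomial / geometric) distribution of the number of surviving lineages.

Everything is computed in log space. The log of ``1 - u_{tau,T}``,
``L(tau) = log P(tau, T) + rho(tau, T)``, is the workhorse: powers of
``1 - eta`` telescope into differences of ``L``.

The same formulas serve the age-dependent model by passing a mean-loss-rate
cache (:class:`~duplifate.age_model.PhiCache`) as the ``lossrate`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import gammaln

from .hazards import HazardRate, MechanismParams, loss_rate

__all__ = [
    "Timeline",
    "survival_prob",
    "u_prob",
    "eta",
    "lineage_count_prob",
    "conditional_density",
    "conditional_log_density",
    "joint_log_density",
]

# 12-point Gauss-Legendre panel rule: exact to ~1e-14 for the smooth
# exponential-type integrands here once panels are narrower than about one
# e-folding of the integrand.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(12)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Timeline:
    """Ordered duplication times of one reconstructed gene family.

    ``times`` holds the ``nT - n0`` duplication times in ``(0, T)``, strictly
    increasing; the origin time (``t_2 = 0`` when ``n0 = 2``) is implicit.
    """

    T: float
    n0: int
    nT: int
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError("present time T must be > 0")
        if not (1 <= self.n0 <= self.nT):
            raise ValueError("requires 1 <= n0 <= nT")
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size != self.nT - self.n0:
            raise ValueError(
                f"expected {self.nT - self.n0} duplication times, got {times.size}"
            )
        if times.size:
            if np.any(times <= 0) or np.any(times >= self.T):
                raise ValueError("duplication times must lie strictly inside (0, T)")
            if np.any(np.diff(times) <= 0):
                raise ValueError("duplication times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def to_dataframe(self, replicate_id: int = 0) -> pd.DataFrame:
        """Long-form table with one row per duplication event."""
        return pd.DataFrame(
            {
                "replicate_id": replicate_id,
                "event_index": np.arange(self.n0 + 1, self.nT + 1),
                "time": self.times,
            }
        )

    @classmethod
    def from_times(
        cls, times: Sequence[float], T: float, n0: int = 2
    ) -> "Timeline":
        times = np.sort(np.asarray(times, dtype=float))
        return cls(T=T, n0=n0, nT=n0 + times.size, times=times)


# ---------------------------------------------------------------------------
# vectorized reconstructed-process core
# ---------------------------------------------------------------------------
def _panel_nodes(edges: np.ndarray, per_unit: float):
    """Split each interval between consecutive edges into GL panels.

    Returns flat node positions, matching quadrature weights, and the index
    of the first node of each interval (for segment sums via ``reduceat``).
    """
    widths = np.diff(edges)
    n_panels = np.maximum(1, np.ceil(widths * per_unit).astype(int))
    offsets = np.concatenate(([0], np.cumsum(n_panels)))
    total = offsets[-1]
    seg_of_panel = np.repeat(np.arange(len(widths)), n_panels)
    within = np.arange(total) - offsets[seg_of_panel]
    h = (widths / n_panels)[seg_of_panel]
    left = edges[:-1][seg_of_panel] + within * h
    nodes = left[:, None] + (h[:, None] / 2.0) * (1.0 + _GL_X[None, :])
    weights = (h[:, None] / 2.0) * _GL_W[None, :]
    starts = offsets[:-1] * _GL_X.size
    return nodes.ravel(), weights.ravel(), starts


def _reconstructed_quantities(lam: float, lossrate, taus: np.ndarray, T: float):
    """Return ``(log P(tau, T), L(tau))`` for a vector of times ``tau``.

    ``L(tau) = log P(tau, T) + rho(tau, T) = log(1 - u_{tau,T})``. The
    survival integral ``I(tau) = int_tau^T mu_t e^{rho(tau,t)} dt`` factors as
    ``e^{-E(tau)} * int_tau^T mu_t e^{E(t)} dt`` with
    ``E(t) = int_0^t mu - lam*t``, so one pass of panel quadrature over the
    segments between the sorted taus serves every query point.
    """
    taus = np.asarray(taus, dtype=float)
    if np.any(taus < 0) or np.any(taus > T):
        raise ValueError("requires 0 <= tau <= T")
    edges = np.unique(np.append(taus, T))
    per_unit = max(4.0, 1.5 * (lam + lossrate.max_rate))
    n_seg = len(edges) - 1

    if n_seg:
        nodes, weights, starts = _panel_nodes(edges, per_unit)
        rate_n = np.asarray(lossrate.rate(nodes), dtype=float)
        expo_n = np.asarray(lossrate.integral(0.0, nodes), dtype=float) - lam * nodes
        shift = expo_n.max()
        contrib = weights * rate_n * np.exp(expo_n - shift)
        seg_sums = np.add.reduceat(contrib, starts)
        with np.errstate(divide="ignore"):
            seg_logs = np.log(seg_sums) + shift
        # suffix logsumexp over segments
        suffix = np.logaddexp.accumulate(seg_logs[::-1])[::-1]
        suffix = np.append(suffix, -np.inf)  # tau = T: empty integral
    else:
        suffix = np.array([-np.inf])

    expo_e = np.asarray(lossrate.integral(0.0, edges), dtype=float) - lam * edges
    idx = np.searchsorted(edges, taus)
    log_integral = suffix[idx] - expo_e[idx]
    log_p = -np.logaddexp(0.0, log_integral)  # -log(1 + I)
    rho_T = (expo_e[-1] - expo_e[idx])  # rho(tau, T)
    return log_p, log_p + rho_T


def _log_u_from_L(L: np.ndarray) -> np.ndarray:
    """log(u) = log(1 - e^L) for L <= 0, -inf at L = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(L < 0, np.log(-np.expm1(np.minimum(L, -0.0))), -np.inf)
    return out


def _resolve_loss(params: MechanismParams, lossrate):
    return loss_rate(params) if lossrate is None else lossrate


# ---------------------------------------------------------------------------
# public scalar API
# ---------------------------------------------------------------------------
def survival_prob(
    params: MechanismParams,
    lossrate=None,
    tau: float = 0.0,
    T: float = 1.0,
    method: str = "quadrature",
    rng: Optional[np.random.Generator] = None,
    n_mc: int = 200_000,
) -> float:
    """Probability ``P(tau, T)`` that a copy alive at ``tau`` survives to ``T``.

    The default evaluates the integral by deterministic adaptive quadrature;
    ``method="monte-carlo"`` uses the crude Monte Carlo estimator (seed it via
    ``rng``), retained as a cross-check.
    """
    if tau > T:
        raise ValueError("requires tau <= T")
    if tau == T:
        return 1.0
    loss = _resolve_loss(params, lossrate)
    lam = params.lam

    if method == "quadrature":
        a_tau = float(np.asarray(loss.integral(0.0, tau)))

        def integrand(t):
            e = float(np.asarray(loss.integral(0.0, t))) - a_tau - lam * (t - tau)
            return float(np.asarray(loss.rate(t))) * np.exp(e)

        import warnings

        with warnings.catch_warnings():
            # roundoff chatter is handled by the explicit error check below
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(
                integrand, tau, T, epsabs=1e-12, epsrel=1e-10, limit=200
            )
        if not np.isfinite(val) or (val > 0 and err > 1e-6 * max(val, 1.0)):
            raise ArithmeticError(
                f"survival integral did not converge (value={val}, err={err})"
            )
    elif method == "monte-carlo":
        if rng is None:
            rng = np.random.default_rng()
        t = rng.uniform(tau, T, size=n_mc)
        e = np.asarray(loss.integral(tau, t)) - lam * (t - tau)
        val = (T - tau) * float(np.mean(np.asarray(loss.rate(t)) * np.exp(e)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return 1.0 / (1.0 + val)


def u_prob(params: MechanismParams, lossrate=None, ti: float = 0.0, tj: float = 1.0) -> float:
    """Probability that a copy at ``ti`` leaves >1 reconstructed lineage at ``tj``.

    ``u_ij = 1 - P(t_i, t_j) e^{rho(t_i, t_j)}``; computed as ``-expm1(L)``
    so values near 0 keep full precision.
    """
    if ti > tj:
        raise ValueError("requires ti <= tj")
    loss = _resolve_loss(params, lossrate)
    _, L = _reconstructed_quantities(params.lam, loss, np.array([ti]), tj)
    return float(-np.expm1(L[0]))


def eta(
    params: MechanismParams, lossrate=None, ti: float = 0.0, tj: float = 1.0, T: float = 1.0
) -> float:
    """Geometric parameter ``eta_ij = 1 - (1 - u_iT) / (1 - u_jT)`` for ti <= tj <= T."""
    if not (ti <= tj <= T):
        raise ValueError("requires ti <= tj <= T")
    loss = _resolve_loss(params, lossrate)
    _, L = _reconstructed_quantities(params.lam, loss, np.array([ti, tj]), T)
    return float(-np.expm1(L[0] - L[1]))


def lineage_count_prob(m: int, n: int, eta_val: float) -> float:
    """P(n_T = n | n_tau = m) = C(n-1, m-1) (1-eta)^m eta^{n-m}.

    The number of surviving lineages descending from ``m`` reconstructed
    lineages is negative-binomial with geometric parameter ``eta``.
    """
    if not (1 <= m <= n):
        raise ValueError("requires 1 <= m <= n")
    if not (0.0 <= eta_val < 1.0):
        raise ValueError("requires eta in [0, 1)")
    if n > m and eta_val == 0.0:
        return 0.0
    log_c = gammaln(n) - gammaln(m) - gammaln(n - m + 1)
    log_p = log_c + m * np.log1p(-eta_val)
    if n > m:
        log_p += (n - m) * np.log(eta_val)
    return float(np.exp(log_p))


# ---------------------------------------------------------------------------
# duplication-time densities
# ---------------------------------------------------------------------------
def conditional_log_density(
    params: MechanismParams,
    lossrate,
    ti,
    t_prev: float,
    i: int,
    nT: int,
    T: float,
):
    """Log of the conditional density of the i-th duplication time (vectorized).

    The density of ``t_i`` given the previous duplication time ``t_{i-1}``,
    the present time ``T`` and the final count ``nT`` is

    ``f(t_i | t_{i-1}, nT, T) = f(t_i | t_{i-1}) P(nT | n_{t_i}, T) / P(nT | n_{t_{i-1}}, T)``

    with ``f(t_i | t_{i-1}) = (i-1) lam P(t_i, T) (1 - eta_{t_{i-1}, t_i})^{i-1}``
    and ``n_{t_i} = i``. After cancellation this reduces to

    ``lam (nT - i + 1) P(t, T) e^{L(t)} u(t)^{nT-i} / u(t_prev)^{nT-i+1}``

    where ``u(t) = u_{t,T}`` and ``L = log(1 - u)``; that form is evaluated
    here in log space.
    """
    ti_arr = np.atleast_1d(np.asarray(ti, dtype=float))
    if np.any(ti_arr <= t_prev) or np.any(ti_arr >= T):
        raise ValueError("requires t_prev < ti < T")
    if not (2 <= i <= nT):
        raise ValueError("event index i must satisfy 2 <= i <= nT")
    loss = _resolve_loss(params, lossrate)
    log_p, L = _reconstructed_quantities(
        params.lam, loss, np.append(ti_arr, t_prev), T
    )
    log_p_t, L_t = log_p[:-1], L[:-1]
    L_prev = L[-1]
    log_u_t = _log_u_from_L(L_t)
    log_u_prev = float(_log_u_from_L(np.array([L_prev]))[0])
    k = nT - i  # remaining events after this one
    out = (
        np.log(params.lam)
        + np.log(k + 1)
        + log_p_t
        + L_t
        - (k + 1) * log_u_prev
    )
    if k > 0:
        out = out + k * log_u_t
    return out if np.ndim(ti) else float(out[0])


def conditional_density(params, lossrate, ti, t_prev, i, nT, T):
    """Conditional density of the i-th duplication time (natural scale)."""
    return np.exp(conditional_log_density(params, lossrate, ti, t_prev, i, nT, T))


def joint_log_density(params: MechanismParams, lossrate, timeline: Timeline) -> float:
    """Log joint density of a timeline's duplication times given ``(n0, nT, T)``.

    The reconstructed-process joint density

    ``f(t | nT, n0, T) = prod_{i=n0+1}^{nT} (i-1) lam P(t_i, T) (1-eta_{t_{i-1},t_i})^{i-1}
    * (1 - eta_{t_{nT}, T})^{nT}
    / [C(nT-1, n0-1) (1-eta_{0,T})^{n0} eta_{0,T}^{nT-n0}]``

    computed entirely in log space. The trailing ``(1-eta_{t_{nT},T})^{nT}``
    factor is the probability that none of the ``nT`` lineages duplicates
    again between the last observed event and the present; with it the joint
    density telescopes exactly into the product of the per-event conditional
    densities and integrates to 1 over the ordered times. This is the
    likelihood maximized to estimate ``(lam, mu)`` or ``(lam, alpha)``.
    """
    loss = _resolve_loss(params, lossrate)
    T, n0, nT = timeline.T, timeline.n0, timeline.nT
    ts = timeline.times
    if nT == n0:
        return 0.0  # no free duplication times; the conditional density is 1
    log_p, L = _reconstructed_quantities(
        params.lam, loss, np.concatenate(([0.0], ts)), T
    )
    L0 = L[0]
    # denominator: negative-binomial probability of nT given n0 at time 0
    log_c = gammaln(nT) - gammaln(n0) - gammaln(nT - n0 + 1)
    denom = log_c + n0 * L0 + (nT - n0) * float(_log_u_from_L(np.array([L0]))[0])
    i = np.arange(n0 + 1, nT + 1)
    L_t = L[1:]
    L_prev = L[:-1]  # previous duplication time (t_{n0} = 0 first)
    numer = np.sum(
        np.log(i - 1) + np.log(params.lam) + log_p[1:] + (i - 1) * (L_prev - L_t)
    )
    tail = nT * L_t[-1]  # no further duplications in (t_nT, T)
    return float(numer + tail - denom)
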