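"""Sequential simulation of duplication times conditional on ``(T, nT)``.

Timelines are generated recursively in forward direction: with ``t_2 = 0``
fixed at the root, each subsequent duplication time is drawn from its
conditional density given the previous one, the present time ``T`` and the
final copy number ``nT``, by rejection sampling under a flat envelope. The
envelope height is the numerically located maximum of the conditional
density times a safety factor; if a proposal ever exceeds the envelope it is
rebuilt with a larger factor and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .age_model import PhiCache, build_phi_cache
from .hazards import Mechanism, MechanismParams, loss_rate
from .time_model import Timeline, conditional_log_density

__all__ = [
    "SimConfig",
    "RejectionError",
    "sample_conditional_times",
    "sample_next_time",
    "simulate_timeline",
    "replicate_study",
    "ReplicateSet",
    "resolve_loss_rate",
]

logger = logging.getLogger(__name__)

#: proposals per event before the sampler gives up
MAX_REJECTIONS = 10**6
_ENVELOPE_SAFETY = 1.05
_ENVELOPE_REBUILD = 1.5
_BATCH = 256


class RejectionError(RuntimeError):
    """Raised when the rejection sampler exceeds its proposal budget."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one conditional-simulation study."""

    params: MechanismParams
    model: str = "time"  # "time" or "age"
    T: float = 10.0
    n0: int = 2
    nT: int = 32
    n_reps: int = 100
    seed: int = 0
    phi_grid_size: int = 256

    def __post_init__(self) -> None:
        if self.model not in ("time", "age"):
            raise ValueError("model must be 'time' or 'age'")
        if not (self.T > 0):
            raise ValueError("T must be > 0")
        if not (1 <= self.n0 <= self.nT):
            raise ValueError("requires 1 <= n0 <= nT")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def resolve_loss_rate(params: MechanismParams, model: str, T: float, grid_size: int = 256):
    """The loss-rate object a model kind implies: raw hazard or a phi cache.

    Under nonfunctionalization the age model coincides with the time model,
    so the exact constant hazard is used directly.
    """
    if model == "time" or params.mechanism is Mechanism.NONFUNCTIONALIZATION:
        return loss_rate(params)
    return build_phi_cache(params, T, grid_size)


def _build_envelope(params, lossrate, t_prev, i, nT, T, safety, coarse=128, fine=64):
    """Flat log-envelope over (t_prev, T): grid-located density max * safety."""
    width = T - t_prev
    grid = t_prev + width * (np.arange(1, coarse + 1) - 0.5) / coarse
    logf = conditional_log_density(params, lossrate, grid, t_prev, i, nT, T)
    log_max = float(np.max(logf))
    # local refinement sweeps around the running argmax; the bracket extends
    # to the open interval ends since the density can peak at a boundary
    eps = 1e-9 * width
    for _ in range(2):
        k = int(np.argmax(logf))
        lo = grid[k - 1] if k > 0 else t_prev + eps
        hi = grid[k + 1] if k < grid.size - 1 else T - eps
        grid = np.linspace(lo, hi, fine)
        logf = conditional_log_density(params, lossrate, grid, t_prev, i, nT, T)
        log_max = max(log_max, float(np.max(logf)))
    if not np.isfinite(log_max):
        raise RejectionError(
            f"envelope search failed at event i={i}: conditional density is "
            f"degenerate on ({t_prev}, {T})"
        )
    return log_max + np.log(safety)


def sample_conditional_times(
    params: MechanismParams,
    lossrate,
    t_prev: float,
    i: int,
    nT: int,
    T: float,
    rng: np.random.Generator,
    size: int = 1,
    max_rejections: int = MAX_REJECTIONS,
) -> np.ndarray:
    """Draw ``size`` variates from the i-th conditional duplication-time density.

    Rejection sampling with uniform proposals on ``(t_prev, T)`` under a flat
    envelope built once per call. Deterministic given ``rng`` state.
    """
    if not (t_prev < T):
        raise ValueError("requires t_prev < T")
    safety = _ENVELOPE_SAFETY
    log_env = _build_envelope(params, lossrate, t_prev, i, nT, T, safety)
    out: List[float] = []
    n_proposed = 0
    budget = max_rejections * size
    batch = min(max(_BATCH, 4 * size), 200_000)
    while len(out) < size and n_proposed < budget:
        props = rng.uniform(t_prev, T, size=batch)
        logu = np.log(rng.uniform(size=batch))
        logf = conditional_log_density(params, lossrate, props, t_prev, i, nT, T)
        n_proposed += batch
        if np.any(logf > log_env):
            safety *= _ENVELOPE_REBUILD
            logger.warning(
                "envelope exceeded at event i=%d; rebuilding with safety %.3g",
                i,
                safety,
            )
            log_env = _build_envelope(params, lossrate, t_prev, i, nT, T, safety)
            continue
        out.extend(props[logu <= logf - log_env][: size - len(out)])
    if len(out) < size:
        raise RejectionError(
            f"no acceptance after {n_proposed} proposals at event i={i} "
            f"(t_prev={t_prev:.4g}, envelope exp={log_env:.4g})"
        )
    return np.asarray(out)


def sample_next_time(
    params: MechanismParams,
    lossrate,
    t_prev: float,
    i: int,
    nT: int,
    T: float,
    rng: np.random.Generator,
    max_rejections: int = MAX_REJECTIONS,
) -> float:
    """Draw the i-th duplication time from its conditional density."""
    return float(
        sample_conditional_times(
            params, lossrate, t_prev, i, nT, T, rng, size=1,
            max_rejections=max_rejections,
        )[0]
    )


def simulate_timeline(
    config: SimConfig,
    rng: np.random.Generator,
    lossrate=None,
) -> Timeline:
    """Simulate one timeline of ``nT - n0`` duplication times sequentially.

    ``lossrate`` may be passed to reuse a prebuilt phi cache across
    replicates; otherwise it is derived from the config.
    """
    if lossrate is None:
        lossrate = resolve_loss_rate(
            config.params, config.model, config.T, config.phi_grid_size
        )
    times = []
    t_prev = 0.0
    for i in range(config.n0 + 1, config.nT + 1):
        t_prev = sample_next_time(
            config.params, lossrate, t_prev, i, config.nT, config.T, rng
        )
        times.append(t_prev)
    return Timeline(T=config.T, n0=config.n0, nT=config.nT, times=np.array(times))


@dataclass
class ReplicateSet:
    """A collection of independently simulated timelines plus their config."""

    config: SimConfig
    timelines: List[Timeline]

    def __len__(self) -> int:
        return len(self.timelines)

    def __iter__(self):
        return iter(self.timelines)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table of all replicates (replicate_id, event_index, time)."""
        return pd.concat(
            [tl.to_dataframe(replicate_id=k) for k, tl in enumerate(self.timelines)],
            ignore_index=True,
        )

    def mean_times(self) -> pd.Series:
        """Mean duplication time at each event index across replicates."""
        stacked = np.vstack([tl.times for tl in self.timelines])
        idx = np.arange(self.config.n0 + 1, self.config.nT + 1)
        return pd.Series(stacked.mean(axis=0), index=pd.Index(idx, name="event_index"))

    def plot_mean_times(self, ax=None, **kwargs):
        """Plot the mean duplication-time curve (event index vs mean time)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.mean_times()
        label = kwargs.pop("label", self.config.params.mechanism.value)
        ax.plot(m.index, m.values, label=label, **kwargs)
        ax.set_xlabel("event index")
        ax.set_ylabel("mean duplication time")
        return ax


def replicate_study(config: SimConfig) -> ReplicateSet:
    """Simulate ``n_reps`` independent timelines with reproducible child seeds.

    The master seed spawns one child stream per replicate via
    ``numpy.random.SeedSequence(seed).spawn``, so replicate ``k`` can be
    regenerated in isolation. Under the age model the phi cache is built once
    and shared across replicates.
    """
    lossrate = resolve_loss_rate(
        config.params, config.model, config.T, config.phi_grid_size
    )
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    timelines = [
        simulate_timeline(config, np.random.default_rng(child), lossrate=lossrate)
        for child in children
    ]
    return ReplicateSet(config=config, timelines=timelines)
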