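"""Maximum-likelihood fitting, AIC mechanism selection, and simulation studies.

The central objects follow the model/results idiom: a
:class:`DuplicateRetentionModel` is built from a :class:`~duplifate.time_model.Timeline`
and a candidate mechanism, and ``fit()`` returns a
:class:`DuplicateRetentionResults` carrying the estimates ``(lam_hat, mu_hat)``
or ``(lam_hat, alpha_hat)``, their observed-information standard errors, the
log-likelihood, the AIC (``2k - 2 logL`` with ``k = 2``; the subfunctionalization
location ``gamma`` is fixed, never estimated), and a ``summary()`` table.

:func:`model_select` fits all three mechanisms to the same timeline and picks
the lowest AIC; :func:`identification_study` and :func:`se_study` run the two
replicate simulation studies (percent of datasets recovering the true
mechanism; standard error of the estimates versus sample size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .hazards import (
    DEFAULT_GAMMA,
    Mechanism,
    MechanismParams,
    as_mechanism,
    standard_mechanisms,
)
from .simulate import ReplicateSet, SimConfig, replicate_study, resolve_loss_rate
from .time_model import Timeline, joint_log_density

__all__ = [
    "DuplicateRetentionModel",
    "DuplicateRetentionResults",
    "FitResult",
    "SelectionResult",
    "IdentificationStudy",
    "SEStudy",
    "log_likelihood",
    "fit_mle",
    "model_select",
    "identification_study",
    "se_study",
    "MECHANISM_ORDER",
]

#: fixed mechanism order; also the AIC tie-break order
MECHANISM_ORDER = (
    Mechanism.NONFUNCTIONALIZATION,
    Mechanism.NEOFUNCTIONALIZATION,
    Mechanism.SUBFUNCTIONALIZATION,
)

# multistart points on the natural scale (lam, loss parameter), spread over
# the admissible box; deterministic
_STARTS = [(0.2, 0.5), (0.05, 0.1), (0.05, 0.9), (1.0, 0.1), (1.0, 0.9)]

_LOG_LAM_BOUNDS = (np.log(1e-4), np.log(20.0))
_LOG_MU_BOUNDS = (np.log(1e-4), np.log(20.0))
_LOGIT_ALPHA_BOUNDS = (-12.0, 12.0)


def log_likelihood(
    timeline: Timeline,
    params: MechanismParams,
    model: str = "time",
    phi_grid_size: int = 256,
) -> float:
    """Log-likelihood of a timeline under one mechanism and model kind.

    For the time model this is the joint log density of the duplication
    times; for the age model the mean loss rate ``phi_t`` (tabulated per
    parameter set) replaces the hazard throughout.
    """
    lossrate = resolve_loss_rate(params, model, timeline.T, phi_grid_size)
    return joint_log_density(params, lossrate, timeline)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------
class DuplicateRetentionModel:
    """ML model of duplication times under one retention mechanism.

    Parameters
    ----------
    timeline:
        Observed (or simulated) duplication times with ``(T, n0, nT)``.
    mechanism:
        Candidate retention mechanism (name or :class:`Mechanism`).
    kind:
        ``"time"`` for the root-clock model, ``"age"`` for the
        age-dependent (mean-loss-rate) model.
    gamma:
        Fixed logistic location for subfunctionalization.
    """

    def __init__(
        self,
        timeline: Timeline,
        mechanism,
        kind: str = "time",
        gamma: float = DEFAULT_GAMMA,
        phi_grid_size: int = 256,
    ):
        if kind not in ("time", "age"):
            raise ValueError("kind must be 'time' or 'age'")
        self.timeline = timeline
        self.mechanism = as_mechanism(mechanism)
        self.kind = kind
        self.gamma = gamma
        self.phi_grid_size = phi_grid_size
        self._nfev = 0

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, T: float, n0: int = 2, **kwargs
    ) -> "DuplicateRetentionModel":
        """Build from a long-form table with a ``time`` column."""
        times = np.sort(np.asarray(data["time"], dtype=float))
        return cls(Timeline.from_times(times, T=T, n0=n0), **kwargs)

    # -- parameterization ---------------------------------------------------
    def _make_params(self, lam: float, loss: float) -> MechanismParams:
        m = self.mechanism
        if m is Mechanism.NONFUNCTIONALIZATION:
            return MechanismParams.nonfunctionalization(lam, loss)
        if m is Mechanism.NEOFUNCTIONALIZATION:
            return MechanismParams.neofunctionalization(lam, loss)
        return MechanismParams.subfunctionalization(lam, loss, self.gamma)

    def _transform(self, lam: float, loss: float) -> np.ndarray:
        """Natural -> unconstrained optimizer scale."""
        if self.mechanism is Mechanism.NONFUNCTIONALIZATION:
            return np.array([np.log(lam), np.log(loss)])
        return np.array([np.log(lam), logit(loss)])

    def _untransform(self, x: np.ndarray) -> tuple:
        lam = float(np.exp(np.clip(x[0], *_LOG_LAM_BOUNDS)))
        if self.mechanism is Mechanism.NONFUNCTIONALIZATION:
            loss = float(np.exp(np.clip(x[1], *_LOG_MU_BOUNDS)))
        else:
            loss = float(expit(np.clip(x[1], *_LOGIT_ALPHA_BOUNDS)))
        return lam, loss

    # -- likelihood ---------------------------------------------------------
    def loglike(self, params) -> float:
        """Log-likelihood at ``params`` (a MechanismParams or ``[lam, loss]``)."""
        if not isinstance(params, MechanismParams):
            params = self._make_params(float(params[0]), float(params[1]))
        return log_likelihood(
            self.timeline, params, model=self.kind, phi_grid_size=self.phi_grid_size
        )

    def _neg_loglike_x(self, x: np.ndarray) -> float:
        self._nfev += 1
        lam, loss = self._untransform(x)
        try:
            ll = self.loglike((lam, loss))
        except (ValueError, ArithmeticError, FloatingPointError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        start_params: Optional[Sequence[float]] = None,
        refine: Optional[str] = None,
        mh_steps: int = 2000,
        mh_scale: float = 0.1,
        seed: int = 0,
        xatol: float = 1e-6,
        fatol: float = 1e-8,
        maxiter: int = 400,
    ) -> "DuplicateRetentionResults":
        """Maximize the likelihood over ``(lam, loss parameter)``.

        Deterministic bounded Nelder-Mead local searches from five fixed
        multistart points on the (log lam, log mu / logit alpha) scale; the
        best optimum wins. ``refine="mh"`` appends a seeded random-walk
        Metropolis-Hastings refinement pass that keeps the best visited
        point (the stochastic search used in the original study).
        """
        if self.timeline.n_events < 1:
            raise ValueError("timeline must contain at least one duplication time")
        self._nfev = 0
        starts = [_STARTS[0] if start_params is None else tuple(start_params)]
        if start_params is None:
            starts = list(_STARTS)
        best = None
        converged = False
        for s in starts:
            x0 = self._transform(*s)
            res = optimize.minimize(
                self._neg_loglike_x,
                x0,
                method="Nelder-Mead",
                options=dict(
                    xatol=xatol, fatol=fatol, maxiter=maxiter, maxfev=2 * maxiter
                ),
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        x_hat = np.asarray(best.x, dtype=float)
        nll = float(best.fun)

        if refine == "mh":
            x_hat, nll = self._mh_refine(x_hat, nll, mh_steps, mh_scale, seed)
        elif refine is not None:
            raise ValueError(f"unknown refinement {refine!r}")

        lam_hat, loss_hat = self._untransform(x_hat)
        llf = -nll
        bse = self._observed_info_bse(lam_hat, loss_hat)
        names = ["lambda", self._make_params(lam_hat, loss_hat).loss_param_name]
        return DuplicateRetentionResults(
            model=self,
            params=pd.Series([lam_hat, loss_hat], index=names),
            llf=llf,
            converged=converged,
            nfev=self._nfev,
            bse=pd.Series(bse, index=names),
        )

    def _mh_refine(self, x0, nll0, n_steps, scale, seed):
        """Random-walk MH on the transformed scale; returns the best point seen."""
        rng = np.random.default_rng(seed)
        x, nll = np.array(x0), nll0
        best_x, best_nll = np.array(x0), nll0
        for _ in range(n_steps):
            prop = x + scale * rng.standard_normal(2)
            nll_p = self._neg_loglike_x(prop)
            if np.log(rng.uniform()) < nll - nll_p:
                x, nll = prop, nll_p
                if nll < best_nll:
                    best_x, best_nll = np.array(x), nll
        return best_x, best_nll

    def _observed_info_bse(self, lam: float, loss: float) -> np.ndarray:
        """Standard errors from the finite-difference observed information."""
        theta = np.array([lam, loss])
        h = 1e-4 * np.maximum(np.abs(theta), 1e-2)

        def nll(v):
            try:
                val = -self.loglike(v)
            except (ValueError, ArithmeticError):
                return np.nan
            return val

        H = np.full((2, 2), np.nan)
        f0 = nll(theta)
        for a in range(2):
            for b in range(a, 2):
                ea = np.eye(2)[a] * h[a]
                eb = np.eye(2)[b] * h[b]
                if a == b:
                    H[a, a] = (nll(theta + ea) - 2 * f0 + nll(theta - ea)) / h[a] ** 2
                else:
                    H[a, b] = H[b, a] = (
                        nll(theta + ea + eb)
                        - nll(theta + ea - eb)
                        - nll(theta - ea + eb)
                        + nll(theta - ea - eb)
                    ) / (4 * h[a] * h[b])
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            return np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
        except np.linalg.LinAlgError:
            return np.array([np.nan, np.nan])

    def simulate(
        self, params: MechanismParams, n_reps: int = 1, seed: int = 0
    ) -> "ReplicateSet":
        """Simulate replicate timelines at ``params`` under this model's shape."""
        cfg = SimConfig(
            params=params,
            model=self.kind,
            T=self.timeline.T,
            n0=self.timeline.n0,
            nT=self.timeline.nT,
            n_reps=n_reps,
            seed=seed,
            phi_grid_size=self.phi_grid_size,
        )
        return replicate_study(cfg)


@dataclass
class DuplicateRetentionResults:
    """MLE results for one mechanism: estimates, uncertainty, fit quality."""

    model: DuplicateRetentionModel
    params: pd.Series
    llf: float
    converged: bool
    nfev: int
    bse: pd.Series

    #: number of free parameters (lam plus one loss parameter; gamma fixed)
    k_params: int = 2

    @property
    def mechanism(self) -> Mechanism:
        return self.model.mechanism

    @property
    def kind(self) -> str:
        return self.model.kind

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def mechanism_params(self) -> MechanismParams:
        return self.model._make_params(*self.params.values)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Duplicate retention model fit",
            "=" * 46,
            f"mechanism:       {self.mechanism.value}",
            f"model kind:      {self.kind}-dependent",
            f"n events:        {self.model.timeline.n_events}"
            f"  (n0={self.model.timeline.n0}, nT={self.model.timeline.nT}, "
            f"T={self.model.timeline.T:g})",
            f"log-likelihood:  {self.llf:.4f}",
            f"AIC (k=2):       {self.aic:.4f}",
            f"converged:       {self.converged}   (nfev={self.nfev})",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<10}{self.params[name]:>12.5f}{self.bse[name]:>12.5f}"
            )
        if self.mechanism is Mechanism.SUBFUNCTIONALIZATION:
            lines.append(f"{'gamma':<10}{self.model.gamma:>12.5f}{'(fixed)':>12}")
        lines.append("=" * 46)
        return "\n".join(lines)


#: short alias
FitResult = DuplicateRetentionResults


# ---------------------------------------------------------------------------
# functional wrappers and selection
# ---------------------------------------------------------------------------
def fit_mle(
    timeline: Timeline,
    mechanism,
    model: str = "time",
    gamma: float = DEFAULT_GAMMA,
    **fit_kwargs,
) -> DuplicateRetentionResults:
    """Fit one mechanism by maximum likelihood (see ``DuplicateRetentionModel.fit``)."""
    return DuplicateRetentionModel(
        timeline, mechanism, kind=model, gamma=gamma
    ).fit(**fit_kwargs)


@dataclass
class SelectionResult:
    """All three per-mechanism fits plus the lowest-AIC pick."""

    fits: Dict[Mechanism, DuplicateRetentionResults]
    best: Mechanism

    @property
    def aic(self) -> pd.Series:
        return pd.Series(
            {m.value: f.aic for m, f in self.fits.items()}, name="aic"
        )

    def summary(self) -> str:
        rows = [f"selected mechanism: {self.best.value}", "-" * 46]
        for m in MECHANISM_ORDER:
            if m in self.fits:
                f = self.fits[m]
                flag = "" if f.converged else "  [not converged]"
                rows.append(f"{m.value:<24} AIC = {f.aic:10.3f}{flag}")
        return "\n".join(rows)


def model_select(
    timeline: Timeline,
    model: str = "time",
    gamma: float = DEFAULT_GAMMA,
    **fit_kwargs,
) -> SelectionResult:
    """Fit all three mechanisms and select the lowest AIC.

    Ties (and the ordering of candidates) follow the fixed order
    nonfunctionalization < neofunctionalization < subfunctionalization.
    Non-convergent fits are excluded from selection (but still reported)
    unless no fit converged.
    """
    fits: Dict[Mechanism, DuplicateRetentionResults] = {}
    for m in MECHANISM_ORDER:
        fits[m] = fit_mle(timeline, m, model=model, gamma=gamma, **fit_kwargs)
    eligible = [m for m in MECHANISM_ORDER if fits[m].converged]
    if not eligible:
        eligible = list(MECHANISM_ORDER)
    best = eligible[0]
    for m in eligible[1:]:
        if fits[m].aic < fits[best].aic:
            best = m
    return SelectionResult(fits=fits, best=best)


# ---------------------------------------------------------------------------
# simulation studies
# ---------------------------------------------------------------------------
@dataclass
class IdentificationStudy:
    """Percent of simulated datasets whose true mechanism wins on AIC."""

    selections: pd.DataFrame  # columns: truth, selected, replicate
    percent_correct: pd.Series  # per generating mechanism
    overall_percent: float  # mean over generating mechanisms

    def summary(self) -> str:
        lines = ["AIC mechanism-identification study", "-" * 46]
        for name, pct in self.percent_correct.items():
            lines.append(f"{name:<26}{pct:6.1f} % correct")
        lines.append(f"{'overall average':<26}{self.overall_percent:6.1f} %")
        return "\n".join(lines)


def identification_study(
    mechanisms: Optional[Dict[Mechanism, MechanismParams]] = None,
    n_reps: int = 100,
    model: str = "time",
    T: float = 10.0,
    n0: int = 2,
    nT: int = 32,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    **fit_kwargs,
) -> IdentificationStudy:
    """Simulate under each mechanism, select by AIC, report percent correct.

    Defaults follow the matched-onset study design: ``T = 10``, ``nT = 32``,
    ``lam = 0.2`` and loss parameter 0.8 for each generating mechanism,
    ``n_reps`` replicates per mechanism.
    """
    if mechanisms is None:
        mechanisms = standard_mechanisms(gamma=gamma)
    records = []
    ss = np.random.SeedSequence(seed)
    sub_seeds = ss.generate_state(len(mechanisms))
    for (truth, params), mseed in zip(mechanisms.items(), sub_seeds):
        reps = replicate_study(
            SimConfig(
                params=params, model=model, T=T, n0=n0, nT=nT,
                n_reps=n_reps, seed=int(mseed) % 2**31,
            )
        )
        for k, tl in enumerate(reps):
            sel = model_select(tl, model=model, gamma=gamma, **fit_kwargs)
            records.append(
                {"truth": truth.value, "replicate": k, "selected": sel.best.value}
            )
    selections = pd.DataFrame.from_records(records)
    pct = (
        selections.assign(correct=lambda d: d.truth == d.selected)
        .groupby("truth", sort=False)["correct"]
        .mean()
        * 100.0
    )
    return IdentificationStudy(
        selections=selections,
        percent_correct=pct,
        overall_percent=float(pct.mean()),
    )


@dataclass
class SEStudy:
    """Replicate-ensemble standard errors of the MLEs versus sample size."""

    estimates: pd.DataFrame  # long form: sample_size, replicate, parameter, estimate
    se: pd.DataFrame  # index sample_size, one column per parameter
    means: pd.DataFrame  # index sample_size, one column per parameter

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col in self.se.columns:
            ax.plot(self.se.index, self.se[col], marker="o", label=col, **kwargs)
        ax.set_xlabel("sample size (number of duplication times)")
        ax.set_ylabel("standard error of MLE")
        ax.legend()
        return ax


def se_study(
    sample_sizes: Sequence[int],
    n_reps: int = 30,
    mechanism=Mechanism.NONFUNCTIONALIZATION,
    params: Optional[MechanismParams] = None,
    model: str = "time",
    T: float = 10.0,
    n0: int = 2,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    **fit_kwargs,
) -> SEStudy:
    """Standard error of each MLE as the number of duplication times grows.

    ``sample_sizes`` are the per-replicate event counts (``nT = n0 + size``).
    The SE is the standard deviation of the MLEs across replicates; with
    ``n_reps = 1`` it is undefined and reported missing with a warning.
    """
    sizes = list(sample_sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sample_sizes must be strictly ascending")
    mechanism = as_mechanism(mechanism)
    if params is None:
        params = standard_mechanisms(gamma=gamma)[mechanism]
    if n_reps == 1:
        warnings.warn(
            "n_reps=1: ensemble standard errors are undefined and reported as NaN"
        )
    rows = []
    ss = np.random.SeedSequence(seed)
    size_seeds = ss.generate_state(len(sizes))
    for size, sseed in zip(sizes, size_seeds):
        reps = replicate_study(
            SimConfig(
                params=params, model=model, T=T, n0=n0, nT=n0 + int(size),
                n_reps=n_reps, seed=int(sseed) % 2**31,
            )
        )
        for k, tl in enumerate(reps):
            fit = fit_mle(tl, mechanism, model=model, gamma=gamma, **fit_kwargs)
            for name, val in fit.params.items():
                rows.append(
                    {
                        "sample_size": size,
                        "replicate": k,
                        "parameter": name,
                        "estimate": val,
                    }
                )
    estimates = pd.DataFrame.from_records(rows)
    grouped = estimates.groupby(["sample_size", "parameter"], sort=True)["estimate"]
    se = grouped.std(ddof=1).unstack("parameter")
    means = grouped.mean().unstack("parameter")
    return SEStudy(estimates=estimates, se=se, means=means)
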