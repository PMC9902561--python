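"""Survival curves, single-exponential fitting, replicate aggregation.

The force clamp turns each tether into a one-shot first-order decay, so a
run of n tethers yields an empirical survival ("decay") curve: the fraction
of tethers remaining versus time on the saved-frame grid.  The curve is fit
with

    y(t) = y0 + A * exp(-k * t)

where k is the off-rate at the applied force, A the dissociating fraction
(typically ~1) and the offset y0 >= 0 absorbs the small population of stuck
beads that never dissociate.  Off-rates per condition are aggregated as the
unweighted mean +/- sample standard deviation across replicate experiments
(each replicate fit separately).

Note the fit target is the full empirical survival function, not the binned
event histogram — the histogram (``histogram_dissociation``) is retained
for display/QC only, with bin widths scaled to keep roughly the same number
of bins regardless of the experiment's time span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dataset import DissociationDataset

__all__ = [
    "SurvivalCurve",
    "ExponentialFit",
    "OffRateEstimate",
    "build_survival_curve",
    "fit_single_exponential",
    "histogram_dissociation",
    "aggregate_replicates",
    "censored_mle_off_rate",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Fraction of tethers remaining on the saved-frame time grid."""

    times: np.ndarray
    fraction_remaining: np.ndarray
    n_total: int
    n_censored: int

    def __post_init__(self) -> None:
        f = self.fraction_remaining
        if len(f) != len(self.times):
            raise ValueError("times and fraction_remaining must align")
        if abs(f[0] - 1.0) > 1e-12:
            raise ValueError("fraction_remaining must start at 1")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("fraction_remaining must be non-increasing")


@dataclass(frozen=True)
class ExponentialFit:
    """One replicate's y0 + A*exp(-k t) fit."""

    k: float
    A: float
    y0: float
    r_squared: float
    n: int
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class OffRateEstimate:
    """Across-replicate off-rate: mean +/- sample sd of the replicate k's."""

    k_mean: float
    k_sd: float
    n_replicates: int
    n_tethers_total: int
    construct: str = ""
    force: float = float("nan")
    low_replicate: bool = False


def build_survival_curve(
    dataset: DissociationDataset, frame_interval: float | None = None
) -> SurvivalCurve:
    """Empirical survival curve of a dissociation dataset.

    Evaluated at every saved-frame time from 0 to the experiment end;
    censored tethers count as remaining throughout.  For datasets without a
    frame grid (continuous synthetic draws) a ~512-point grid spanning the
    experiment is used.
    """
    if dataset.n_total < 1:
        raise ValueError("dataset is empty")
    dt = frame_interval if frame_interval is not None else dataset.frame_interval
    t_end = dataset.end_time()
    if t_end <= 0:
        raise ValueError("experiment end time must be > 0")
    if dt is None:
        dt = t_end / 512.0
    grid = np.arange(0.0, t_end + dt / 2.0, dt)
    events = dataset.event_times
    remaining = dataset.n_total - np.searchsorted(events, grid, side="right")
    return SurvivalCurve(
        times=grid,
        fraction_remaining=remaining / dataset.n_total,
        n_total=dataset.n_total,
        n_censored=dataset.n_censored,
    )


def _model(t: np.ndarray, y0: float, A: float, k: float) -> np.ndarray:
    return y0 + A * np.exp(-k * t)


def fit_single_exponential(
    curve: SurvivalCurve, max_restarts: int = 5
) -> ExponentialFit:
    """Bounded nonlinear least squares of y = y0 + A*exp(-k t).

    Bounds: y0 in [0, 1] (the offset is allowed above zero for stuck beads),
    A in (0, 1.5], k > 0.  Initial guesses: y0 = censored fraction,
    A = 1 - censored fraction, k from the empirical 1/e crossing; perturbed
    restarts on failure.  R^2 is computed against the empirical curve.

    The time axis is normalised internally by the final grid time, so a
    common rescaling of all times rescales the fitted k by exactly the
    inverse factor.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.fraction_remaining, dtype=float)
    if len(t) < 5:
        raise ValueError("curve needs >= 5 points")
    if curve.n_censored >= curve.n_total:
        raise ValueError("curve needs at least one dissociation event")

    T = t[-1]
    tau = t / T

    cf = curve.n_censored / curve.n_total
    y0_0 = min(max(cf, 0.0), 1.0)
    A0 = min(max(1.0 - cf, 1e-3), 1.5)
    # 1/e crossing of the decaying component as the rate guess
    target = y0_0 + A0 / np.e
    idx = np.nonzero(y <= target)[0]
    kappa0 = 1.0 / max(tau[idx[0]], 1e-6) if len(idx) else 1.0

    lower = [0.0, 1e-12, 1e-12]
    upper = [1.0, 1.5, np.inf]
    rng = np.random.default_rng(12345)
    p0 = np.array([y0_0, A0, kappa0])
    last_err = ""
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(
                _model, tau, y, p0=np.clip(p0, lower, upper),
                bounds=(lower, upper), maxfev=20000,
            )
            y0_f, A_f, kappa_f = popt
            yhat = _model(tau, *popt)
            ss_res = float(np.sum((y - yhat) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
            return ExponentialFit(
                k=kappa_f / T, A=A_f, y0=y0_f, r_squared=r2,
                n=curve.n_total, converged=True,
            )
        except RuntimeError as err:  # no convergence: perturb and retry
            last_err = str(err)
            p0 = np.array([y0_0, A0, kappa0]) * rng.uniform(0.3, 3.0, size=3)
            p0[0] = min(p0[0], 1.0)
    return ExponentialFit(
        k=float("nan"), A=float("nan"), y0=float("nan"), r_squared=float("nan"),
        n=curve.n_total, converged=False,
        message=f"no convergence after {max_restarts} restarts: {last_err}",
    )


def histogram_dissociation(
    dataset: DissociationDataset, target_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Event-time histogram with span-scaled bin width (display/QC only).

    The bin width is span/target_bins rounded to a whole number of
    saved-frame intervals (at least one frame), so experiments whose time
    spans differ by orders of magnitude still get comparable bin counts.
    Returns (counts, bin_edges).  Never used in fitting.
    """
    events = dataset.event_times
    if len(events) == 0:
        raise ValueError("dataset has no dissociation events")
    dt = dataset.frame_interval or 1.0
    span = max(events.max(), dt)
    width = max(round(span / target_bins / dt), 1) * dt
    edges = np.arange(0.0, np.ceil(span / width) * width + width / 2.0 + width, width)
    counts, edges = np.histogram(events, bins=edges)
    return counts, edges


def censored_mle_off_rate(dataset: DissociationDataset) -> float:
    """Closed-form censored-exponential MLE  k = d / (sum t_i + sum c_j).

    The maximum-likelihood off-rate for exponential lifetimes with
    right-censoring: events d over total observed tether-time.  Used as an
    independent cross-check of the survival-curve fit (exact when y0 = 0
    and there is no slow phase).
    """
    d = dataset.n_events
    if d == 0:
        raise ValueError("no events")
    total_time = dataset.event_times.sum() + dataset.censoring_times.sum()
    return d / float(total_time)


def aggregate_replicates(
    fits: list[ExponentialFit],
    construct: str = "",
    force: float = float("nan"),
) -> OffRateEstimate:
    """Mean +/- sample standard deviation of replicate off-rates.

    Only converged fits contribute.  Fewer than three replicates triggers a
    warning (conditions are normally run at least in triplicate); a single
    replicate yields sd = 0 with the low-replicate flag set.
    """
    ks = np.array([f.k for f in fits if f.converged])
    if len(ks) == 0:
        raise ValueError("no converged fits to aggregate")
    low = len(ks) < 3
    if low:
        warnings.warn(
            f"only {len(ks)} converged replicate(s); off-rate sd unreliable",
            stacklevel=2,
        )
    return OffRateEstimate(
        k_mean=float(ks.mean()),
        k_sd=float(ks.std(ddof=1)) if len(ks) > 1 else 0.0,
        n_replicates=len(ks),
        n_tethers_total=int(sum(f.n for f in fits if f.converged)),
        construct=construct,
        force=force,
        low_replicate=low,
    )
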