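"""Dwell-time kinetics of two-state force-extension traces.

A constant-force recording of a protein binding and releasing a short ssDNA
probe is a telegraph signal: long extensions mark the unbound state, short
extensions the bound state.  This module segments such traces into states,
extracts dwell times, fits exponential rates, and locates the critical force
F_c where the observed binding and unbinding rates cross.

Conventions
-----------
* state 0 = bound (short extension), state 1 = unbound (long extension);
* an *unbound* dwell ends with a binding event, so the binding rate is
  estimated from unbound dwells and vice versa;
* boundary (first/last) dwells are censored: they contribute observation
  time but not events to the exponential MLE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.mixture import GaussianMixture

__all__ = [
    "ForceExtensionTrace",
    "SegmentationSettings",
    "SegmentationResult",
    "DwellSet",
    "RateEstimate",
    "KineticFit",
    "CriticalForce",
    "NoCrossoverError",
    "InsufficientDataError",
    "segment_trace",
    "dwell_times",
    "fit_rate",
    "critical_force",
]


class InsufficientDataError(ValueError):
    """Raised when too few events are available for a fit."""


class NoCrossoverError(RuntimeError):
    """Raised when rate-force lines are parallel and never cross."""


@dataclass
class ForceExtensionTrace:
    """One constant-force extension recording."""

    time: np.ndarray  # s, uniform grid
    extension: np.ndarray  # nm
    force: float  # pN, constant over the trace
    sampling_rate: float  # Hz
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.shape != self.extension.shape:
            raise ValueError("time and extension must have equal length")
        if self.force <= 0:
            raise ValueError("force must be > 0")
        dt = np.diff(self.time)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be a strictly increasing uniform grid")


@dataclass
class SegmentationSettings:
    """Knobs for two-state segmentation.

    The extension is boxcar-filtered over ``filter_width_s`` before level
    estimation, then labelled with dual-threshold hysteresis at
    ``mu_low + 0.3 * delta`` and ``mu_low + 0.7 * delta``.

    With ``adaptive=True`` the filter is widened until the filtered noise SD
    is at most ``target_noise_fraction`` of the level separation, so poorly
    separated traces do not sprout noise-induced events.
    """

    filter_width_s: float = 0.1
    low_fraction: float = 0.3
    high_fraction: float = 0.7
    min_separation_sd: float = 2.0
    max_fit_samples: int = 20000
    adaptive: bool = True
    target_noise_fraction: float = 1.0 / 6.0
    seed: int = 0


@dataclass
class SegmentationResult:
    states: np.ndarray | None  # int8 per-sample labels, or None
    transitions_detected: bool
    level_bound: float = np.nan
    level_unbound: float = np.nan
    noise_sd: float = np.nan

    @property
    def separation(self) -> float:
        return self.level_unbound - self.level_bound


@dataclass
class DwellSet:
    """Dwell times at one force, with censoring flags for boundary dwells."""

    bound_dwells: np.ndarray = field(default_factory=lambda: np.empty(0))
    unbound_dwells: np.ndarray = field(default_factory=lambda: np.empty(0))
    bound_censored: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    unbound_censored: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    force: float = np.nan


@dataclass
class RateEstimate:
    rate: float  # 1/s
    se: float  # 1/s
    n_events: int  # uncensored events


@dataclass
class KineticFit:
    """Observed rates at one force (pooled over traces)."""

    force: float
    k_bind_obs: RateEstimate
    k_unbind: RateEstimate


@dataclass
class CriticalForce:
    f_c: float  # pN
    se: float  # pN
    slope_bind: float  # d ln k_bind / dF, 1/pN
    slope_unbind: float  # 1/pN
    intercept_bind: float
    intercept_unbind: float
    n_forces_used: int
    extrapolated: bool = False


def segment_trace(
    trace: ForceExtensionTrace, settings: SegmentationSettings | None = None
) -> SegmentationResult:
    """Label each sample bound (0) / unbound (1).

    A two-component Gaussian level fit on the filtered extension locates the
    two levels; hysteresis thresholding then assigns states.  If the filtered
    histogram is effectively unimodal (levels closer than
    ``min_separation_sd`` pooled noise SDs) the trace is reported as having
    no transitions rather than raising.
    """
    settings = settings or SegmentationSettings()
    y = trace.extension
    if np.ptp(y) == 0.0:
        return SegmentationResult(None, False)
    width = max(1, int(round(settings.filter_width_s * trace.sampling_rate)))
    mu_lo, mu_hi, pooled_sd, delta = _fit_levels(y, width, settings)
    if settings.adaptive and delta > 0:
        # raw per-sample noise from the high-frequency differences; the
        # median absolute deviation is insensitive to the level jumps
        if y.size > 1:
            d = np.diff(y)
            sigma_raw = float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))
        else:
            sigma_raw = 0.0
        if sigma_raw > 0:
            needed = int(np.ceil((sigma_raw / (settings.target_noise_fraction * delta)) ** 2))
            if needed > width:
                width = needed
                mu_lo, mu_hi, pooled_sd, delta = _fit_levels(y, width, settings)
    yf = uniform_filter1d(y, size=width, mode="nearest")
    if delta < settings.min_separation_sd * pooled_sd:
        return SegmentationResult(None, False, mu_lo, mu_hi, pooled_sd)

    t_lo = mu_lo + settings.low_fraction * delta
    t_hi = mu_lo + settings.high_fraction * delta
    states = _hysteresis(yf, t_lo, t_hi)
    if np.all(states == states[0]):
        return SegmentationResult(None, False, mu_lo, mu_hi, pooled_sd)
    return SegmentationResult(states, True, mu_lo, mu_hi, pooled_sd)


def _fit_levels(y: np.ndarray, width: int, settings: SegmentationSettings):
    """Two-component Gaussian level fit on the boxcar-filtered extension."""
    yf = uniform_filter1d(y, size=width, mode="nearest")
    sub = yf
    if sub.size > settings.max_fit_samples:
        stride = int(np.ceil(sub.size / settings.max_fit_samples))
        sub = sub[::stride]
    gmm = GaussianMixture(
        n_components=2, n_init=3, random_state=settings.seed, covariance_type="full"
    ).fit(sub.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    order = np.argsort(means)
    mu_lo, mu_hi = means[order]
    w = gmm.weights_[order]
    pooled_sd = float(np.sqrt(np.sum(w * sds[order] ** 2)))
    delta = mu_hi - mu_lo
    if min(w) < 1e-3:
        delta = 0.0
    return float(mu_lo), float(mu_hi), pooled_sd, float(delta)


def _hysteresis(y: np.ndarray, t_lo: float, t_hi: float) -> np.ndarray:
    states = np.empty(y.size, dtype=np.int8)
    mid = 0.5 * (t_lo + t_hi)
    state = 1 if y[0] > mid else 0
    for i in range(y.size):
        v = y[i]
        if state == 0 and v > t_hi:
            state = 1
        elif state == 1 and v < t_lo:
            state = 0
        states[i] = state
    return states


def dwell_times(states: np.ndarray, sampling_rate: float, force: float = np.nan) -> DwellSet:
    """Run-length encode a state sequence into censored dwell times."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state sequence")
    change = np.flatnonzero(np.diff(states)) + 1
    if change.size == 0:
        warnings.warn("no state change: empty dwell set", stacklevel=2)
        return DwellSet(force=force)
    edges = np.concatenate(([0], change, [states.size]))
    lengths = np.diff(edges)
    run_states = states[edges[:-1]]
    durations = lengths / sampling_rate
    censored = np.zeros(durations.size, dtype=bool)
    censored[0] = censored[-1] = True
    b = run_states == 0
    return DwellSet(
        bound_dwells=durations[b],
        unbound_dwells=durations[~b],
        bound_censored=censored[b],
        unbound_censored=censored[~b],
        force=force,
    )


def fit_rate(
    dwells: np.ndarray, censored: np.ndarray | None = None, min_events: int = 5
) -> RateEstimate:
    """Exponential MLE with right censoring.

    k = (uncensored events) / (total observed time, censored included);
    SE = k / sqrt(n_events).
    """
    dwells = np.asarray(dwells, dtype=float)
    if censored is None:
        censored = np.zeros(dwells.size, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    n_events = int(np.sum(~censored))
    if n_events < min_events:
        raise InsufficientDataError(
            f"{n_events} uncensored dwells < required {min_events}"
        )
    total = float(np.sum(dwells))
    k = n_events / total
    return RateEstimate(rate=k, se=k / np.sqrt(n_events), n_events=n_events)


def _weighted_line(x: np.ndarray, y: np.ndarray, sigma: np.ndarray):
    w = 1.0 / sigma**2
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (y - yb)) / sxx
    intercept = yb - slope * xb
    return intercept, slope


def critical_force(
    fits: list[KineticFit],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CriticalForce:
    """Crossover of Bell (log-linear) rate-force lines.

    Weighted least squares of ln k against F for both rates; F_c is where
    the lines intersect; its SE comes from a seeded parametric bootstrap of
    the per-force log-rates.
    """
    if len(fits) < 3:
        raise InsufficientDataError("need rates at >= 3 forces")
    f = np.array([kf.force for kf in fits], dtype=float)
    lkb = np.log([kf.k_bind_obs.rate for kf in fits])
    lku = np.log([kf.k_unbind.rate for kf in fits])
    # delta-method error of ln k given SE(k)
    skb = np.array([kf.k_bind_obs.se / kf.k_bind_obs.rate for kf in fits])
    sku = np.array([kf.k_unbind.se / kf.k_unbind.rate for kf in fits])
    skb = np.where(skb > 0, skb, 1e-6)
    sku = np.where(sku > 0, sku, 1e-6)

    a1, b1 = _weighted_line(f, lkb, skb)
    a2, b2 = _weighted_line(f, lku, sku)
    if abs(b2 - b1) < 1e-6:
        raise NoCrossoverError("rate-force lines are parallel")
    fc = (a1 - a2) / (b2 - b1)

    rng = np.random.default_rng(seed)
    samples = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        a1b, b1b = _weighted_line(f, lkb + skb * rng.standard_normal(f.size), skb)
        a2b, b2b = _weighted_line(f, lku + sku * rng.standard_normal(f.size), sku)
        d = b2b - b1b
        samples[i] = (a1b - a2b) / d if abs(d) > 1e-6 else np.nan
    se = float(np.nanstd(samples))

    extrapolated = not (f.min() <= fc <= f.max())
    if extrapolated:
        warnings.warn(
            f"critical force {fc:.2f} pN lies outside sampled range "
            f"[{f.min():.2f}, {f.max():.2f}] pN",
            stacklevel=2,
        )
    return CriticalForce(
        f_c=float(fc),
        se=se,
        slope_bind=float(b1),
        slope_unbind=float(b2),
        intercept_bind=float(a1),
        intercept_unbind=float(a2),
        n_forces_used=int(f.size),
        extrapolated=extrapolated,
    )
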