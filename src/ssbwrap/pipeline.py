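"""End-to-end analysis of constant-force trace bundles.

Single-mode conditions pool dwell times per force, fit Bell lines and report
the crossover.  A condition may instead host two interaction modes, with any
individual trace produced by one of them; the pipeline therefore

1. estimates both rates per trace,
2. converts each balanced-enough trace into a critical-force sample
   ``F_c,i = F_i - s_i / beta`` where ``s = ln(k_unbind/k_bind)`` and
   ``beta`` is a shared log-rate-ratio slope fitted across traces,
3. runs the Gaussian-mixture bimodality test on those samples, and
4. refits per-mode rate-force lines on the traces assigned to each mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    CriticalForce,
    ForceExtensionTrace,
    InsufficientDataError,
    KineticFit,
    RateEstimate,
    SegmentationSettings,
    critical_force,
    dwell_times,
    fit_rate,
    segment_trace,
)
from .polymer import WLCParams
from .thermo import BindingEnergyResult, ModeSplit, binding_free_energy, classify_modes

__all__ = [
    "TraceRecord",
    "ConditionReport",
    "per_trace_rates",
    "per_trace_critical_forces",
    "pooled_fits",
    "analyze_condition",
]


@dataclass
class TraceRecord:
    """Per-trace kinetic summary."""

    index: int
    force: float
    k_bind: RateEstimate | None
    k_unbind: RateEstimate | None
    bound_dwells: np.ndarray
    unbound_dwells: np.ndarray
    bound_censored: np.ndarray
    unbound_censored: np.ndarray
    usable: bool

    @property
    def log_ratio(self) -> float:
        """s = ln(k_unbind / k_bind); zero at the mode's critical force."""
        return float(np.log(self.k_unbind.rate / self.k_bind.rate))

    @property
    def log_ratio_var(self) -> float:
        return 1.0 / self.k_bind.n_events + 1.0 / self.k_unbind.n_events


@dataclass
class ConditionReport:
    condition_label: str
    salt_mM: float
    records: list[TraceRecord]
    mode_split: ModeSplit | None
    fc_samples: np.ndarray
    fc_sample_indices: np.ndarray
    shared_slope: float
    per_mode_crossover: list[CriticalForce | None]
    result: BindingEnergyResult

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "trace": r.index,
                "force_pN": r.force,
                "k_bind_per_s": r.k_bind.rate if r.k_bind else np.nan,
                "k_unbind_per_s": r.k_unbind.rate if r.k_unbind else np.nan,
                "usable": r.usable,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def per_trace_rates(
    traces: list[ForceExtensionTrace],
    settings: SegmentationSettings | None = None,
    min_events: int = 5,
) -> list[TraceRecord]:
    """Segment every trace and fit both rates where enough events exist."""
    records = []
    for i, tr in enumerate(traces):
        seg = segment_trace(tr, settings)
        if not seg.transitions_detected:
            records.append(
                TraceRecord(i, tr.force, None, None, np.empty(0), np.empty(0),
                            np.empty(0, bool), np.empty(0, bool), False)
            )
            continue
        ds = dwell_times(seg.states, tr.sampling_rate, force=tr.force)
        try:
            kb = fit_rate(ds.unbound_dwells, ds.unbound_censored, min_events)
            ku = fit_rate(ds.bound_dwells, ds.bound_censored, min_events)
            usable = True
        except InsufficientDataError:
            kb = ku = None
            usable = False
        records.append(
            TraceRecord(
                i, tr.force, kb, ku,
                ds.bound_dwells, ds.unbound_dwells,
                ds.bound_censored, ds.unbound_censored,
                usable,
            )
        )
    return records


def _shared_slope_wls(F, s, w, labels):
    """Shared slope, per-cluster intercept weighted least squares."""
    num = den = 0.0
    for g in np.unique(labels):
        m = labels == g
        W = np.sum(w[m])
        Fb = np.sum(w[m] * F[m]) / W
        sb = np.sum(w[m] * s[m]) / W
        num += np.sum(w[m] * (F[m] - Fb) * (s[m] - sb))
        den += np.sum(w[m] * (F[m] - Fb) ** 2)
    return num / den


def _two_means_1d(x, w):
    """Exact weighted 2-means in 1D by split-point search; returns labels, WSS."""
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    best = (np.inf, 1)
    for cut in range(1, x.size):
        wss = 0.0
        for seg in (slice(0, cut), slice(cut, None)):
            W = np.sum(ws[seg])
            mu = np.sum(ws[seg] * xs[seg]) / W
            wss += np.sum(ws[seg] * (xs[seg] - mu) ** 2)
        if wss < best[0]:
            best = (wss, cut)
    labels = np.zeros(x.size, dtype=int)
    labels[order[best[1]:]] = 1
    return labels, best[0]


def per_trace_critical_forces(
    records: list[TraceRecord],
    s_max: float = 2.5,
    beta_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Critical-force sample per balanced trace, via a shared Bell slope.

    Only traces with both rates measured and |ln(k_u/k_b)| <= ``s_max``
    enter (far-from-balance traces extrapolate poorly).  Returns
    (fc_samples, trace indices used, fitted slope beta in 1/pN).
    """
    usable = [r for r in records if r.usable and abs(r.log_ratio) <= s_max]
    if len(usable) < 10:
        raise InsufficientDataError(f"only {len(usable)} balanced traces")
    F = np.array([r.force for r in usable])
    s = np.array([r.log_ratio for r in usable])
    w = 1.0 / np.array([r.log_ratio_var for r in usable])
    if beta_grid is None:
        beta_grid = np.linspace(0.05, 1.5, 59)

    # grid-initialise the shared slope by minimising the 2-cluster spread of
    # the implied per-trace crossovers, then refine by EM-style WLS
    best = (np.inf, beta_grid[0], None)
    for beta in beta_grid:
        fc = F - s / beta
        labels, wss = _two_means_1d(fc, w)
        if wss < best[0]:
            best = (wss, beta, labels)
    beta, labels = best[1], best[2]
    for _ in range(4):
        beta_new = _shared_slope_wls(F, s, w, labels)
        if beta_new <= 0:
            break
        fc = F - s / beta_new
        labels, _ = _two_means_1d(fc, w)
        beta = beta_new
    fc = F - s / beta
    idx = np.array([r.index for r in usable])
    return fc, idx, float(beta)


def pooled_fits(
    records: list[TraceRecord], min_events: int = 5, min_traces: int = 1
) -> list[KineticFit]:
    """Pool dwells across traces at each force and fit both rates."""
    fits = []
    for force in sorted({r.force for r in records}):
        sel = [r for r in records if r.force == force and r.bound_dwells.size]
        if len(sel) < min_traces:
            continue
        bd = np.concatenate([r.bound_dwells for r in sel])
        bc = np.concatenate([r.bound_censored for r in sel])
        ud = np.concatenate([r.unbound_dwells for r in sel])
        uc = np.concatenate([r.unbound_censored for r in sel])
        try:
            kb = fit_rate(ud, uc, min_events)
            ku = fit_rate(bd, bc, min_events)
        except InsufficientDataError:
            continue
        fits.append(KineticFit(force=force, k_bind_obs=kb, k_unbind=ku))
    return fits


def analyze_condition(
    traces: list[ForceExtensionTrace],
    salt_mM: float = np.nan,
    condition_label: str = "",
    n_released_nt: int = 20,
    wlc: WLCParams | None = None,
    settings: SegmentationSettings | None = None,
    seed: int = 0,
) -> ConditionReport:
    """Full pipeline: traces -> rates -> F_c (per mode) -> dG0."""
    wlc = wlc or WLCParams()
    if not traces:
        raise ValueError("no traces")
    if not condition_label:
        condition_label = traces[0].condition_label
    records = per_trace_rates(traces, settings)

    fc_samples, idx, beta = per_trace_critical_forces(records)
    split = classify_modes(fc_samples, seed=seed)

    rec_by_index = {r.index: r for r in records}
    per_mode_cross: list[CriticalForce | None] = []
    mode_fc = np.empty(split.mode_count)
    mode_fc_se = np.empty(split.mode_count)
    for m in range(split.mode_count):
        if split.mode_count == 1:
            mode_records = [r for r in records if r.usable]
        else:
            mode_idx = idx[split.labels == m]
            mode_records = [rec_by_index[i] for i in mode_idx]
        fits = pooled_fits(mode_records)
        cross = None
        if len(fits) >= 3:
            try:
                cross = critical_force(fits, seed=seed)
            except Exception as exc:  # parallel lines etc.
                warnings.warn(f"mode {m}: crossover fit failed ({exc})", stacklevel=2)
        per_mode_cross.append(cross)
        if cross is not None:
            mode_fc[m] = cross.f_c
            mode_fc_se[m] = cross.se
        else:
            sel = split.labels == m
            mode_fc[m] = split.means[m]
            mode_fc_se[m] = split.sds[m] / max(1.0, np.sqrt(np.sum(sel)))

    mode_dg0 = np.array(
        [binding_free_energy(fc, n_released_nt, wlc) for fc in mode_fc]
    )
    # d|dG0|/dF_c for SE propagation, by central difference
    dg0_se = np.empty(split.mode_count)
    for m in range(split.mode_count):
        h = 0.05
        d = (
            binding_free_energy(mode_fc[m] + h, n_released_nt, wlc)
            - binding_free_energy(mode_fc[m] - h, n_released_nt, wlc)
        ) / (2 * h)
        dg0_se[m] = abs(d) * mode_fc_se[m]

    w = split.weights
    result = BindingEnergyResult(
        condition_label=condition_label,
        salt_mM=salt_mM,
        f_c=float(np.sum(w * mode_fc)),
        f_c_se=float(np.sqrt(np.sum(w**2 * mode_fc_se**2))),
        delta_g0=float(np.sum(w * mode_dg0)),
        delta_g0_se=float(np.sqrt(np.sum(w**2 * dg0_se**2))),
        mode_count=split.mode_count,
        mode_f_c=mode_fc,
        mode_delta_g0=mode_dg0,
    )
    return ConditionReport(
        condition_label=condition_label,
        salt_mM=salt_mM,
        records=records,
        mode_split=split,
        fc_samples=fc_samples,
        fc_sample_indices=idx,
        shared_slope=beta,
        per_mode_crossover=per_mode_cross,
        result=result,
    )
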