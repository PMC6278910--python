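"""Binding-event detection and dwell-time kinetics.

Binding events are maximal runs of frames above a FRET threshold; the
bound dwell times t_off follow a single-exponential survival law
f(t) = A exp(-k t) whose rate is the dissociation constant k_off, while
the waiting times between events (t_on) follow a double-exponential
f(t) = A1 exp(-k1 t) + A2 exp(-k2 t) giving the fast and slow observed
association rates k_on,fast and k_on,slow (pseudo-first-order at fixed
protein concentration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .traces import FretTrace

__all__ = [
    "BindingEvent",
    "UnboundGap",
    "DwellSet",
    "ExpFit",
    "detect_events",
    "collect_dwells",
    "survival_curve",
    "fit_single_exp",
    "fit_double_exp",
]


@dataclass
class BindingEvent:
    """One bound interval detected on a FRET trajectory (times in s)."""

    start: float
    end: float
    mean_fret: float
    censored: bool
    trace_id: str = ""
    start_frame: int = 0
    end_frame: int = 0  # exclusive

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class UnboundGap:
    start: float
    end: float
    censored: bool
    trace_id: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class DwellSet:
    durations: np.ndarray
    kind: str  # "bound" | "unbound"
    n_traces: int
    frame_time: float

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.kind not in ("bound", "unbound"):
            raise ValueError("kind must be 'bound' or 'unbound'")


@dataclass
class ExpFit:
    model: str  # "single" | "double"
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]  # double: fast first (k1 >= k2)
    standard_errors: tuple[float, ...]
    n: int
    converged: bool = True
    fallback_single: bool = False
    diagnostics: dict = field(default_factory=dict)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (exclusive) index pairs of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_events(
    fret: FretTrace,
    threshold: float = 0.25,
    min_frames: int = 2,
) -> tuple[list[BindingEvent], list[UnboundGap]]:
    """Threshold-based event detection with debouncing.

    Bound = maximal runs of E >= threshold of at least ``min_frames``
    frames; interior unbound gaps shorter than ``min_frames`` are merged
    into the surrounding bound state first.  Events or gaps touching the
    trace boundaries are flagged censored.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if len(fret) == 0:
        raise ValueError("empty trace")
    eff = np.asarray(fret.efficiency, dtype=float)
    above = np.where(np.isfinite(eff), eff >= threshold, False)

    # debounce: close interior sub-min_frames gaps, then drop short events
    for start, stop in _runs(~above):
        if start > 0 and stop < len(above) and (stop - start) < min_frames:
            above[start:stop] = True
    for start, stop in _runs(above):
        if (stop - start) < min_frames:
            above[start:stop] = False

    dt = fret.frame_time
    events = [
        BindingEvent(
            start=start * dt,
            end=stop * dt,
            mean_fret=float(np.nanmean(eff[start:stop])),
            censored=(start == 0 or stop == len(above)),
            trace_id=fret.trace_id,
            start_frame=int(start),
            end_frame=int(stop),
        )
        for start, stop in _runs(above)
    ]
    gaps = [
        UnboundGap(
            start=start * dt,
            end=stop * dt,
            censored=(start == 0 or stop == len(above)),
            trace_id=fret.trace_id,
        )
        for start, stop in _runs(~above)
    ]
    return events, gaps


def collect_dwells(
    per_trace: list[tuple[list[BindingEvent], list[UnboundGap]]],
    include_censored: bool = False,
    frame_time: float | None = None,
) -> tuple[DwellSet, DwellSet]:
    """Pool dwell durations from many traces into bound/unbound sets.

    Censored intervals (touching a trace boundary) are excluded by
    default, since their true duration is unknown.
    """
    if not per_trace:
        raise ValueError("no traces given")
    bound, unbound = [], []
    for events, gaps in per_trace:
        bound.extend(e.duration for e in events if include_censored or not e.censored)
        unbound.extend(g.duration for g in gaps if include_censored or not g.censored)
    if frame_time is None:
        frame_time = 0.0
        for events, gaps in per_trace:
            if events:
                frame_time = (events[0].end - events[0].start) / max(
                    events[0].end_frame - events[0].start_frame, 1
                )
                break
    if not bound and not unbound:
        raise ValueError(
            "no usable dwells: every detected interval is censored "
            "(set include_censored=True or supply longer traces)"
        )
    n = len(per_trace)
    return (
        DwellSet(np.asarray(bound), "bound", n, frame_time),
        DwellSet(np.asarray(unbound), "unbound", n, frame_time),
    )


def survival_curve(dwells: DwellSet) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival S(t) = #(duration > t)/n on the frame-time grid."""
    d = dwells.durations
    if d.size < 5:
        raise ValueError("need at least 5 dwells for a survival curve")
    dt = dwells.frame_time if dwells.frame_time > 0 else max(d.min(), 1e-3)
    t = np.arange(0.0, d.max() + dt, dt)
    surv = (d[None, :] > t[:, None]).mean(axis=1)
    return t, surv


def _single(t, a, k):
    return a * np.exp(-k * t)


def _double(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _prepare_curve(
    t: np.ndarray,
    s: np.ndarray,
    n_dwells: int | None,
    n_grid: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Condition an empirical survival curve for exponential fitting.

    Three standard adjustments: (1) drop the flat S == 1 head, which on
    dwell data only reflects the detection dead time (no dwell shorter
    than ``min_frames`` can be observed) and would otherwise bias the
    fast rate; (2) when the curve is dense, subsample it onto a
    log-spaced time grid so the long, highly redundant tail does not
    dominate the residuals of a multi-exponential fit; (3) when the
    number of underlying dwells is known, weight points by the binomial
    standard error of S(t) (with a continuity correction so S = 0 / 1
    points keep finite weight).
    """
    keep = s < 1.0
    if keep.sum() >= 5:
        t, s = t[keep], s[keep]
    if n_grid is not None and t.size > n_grid and t[0] > 0:
        target = np.geomspace(t[0], t[-1], n_grid)
        idx = np.unique(np.searchsorted(t, target).clip(0, t.size - 1))
        t, s = t[idx], s[idx]
    sigma = None
    if n_dwells is not None and n_dwells > 0:
        s_corr = (s * n_dwells + 0.5) / (n_dwells + 1)
        sigma = np.sqrt(s_corr * (1.0 - s_corr) / n_dwells)
    return t, s, sigma


def fit_single_exp(
    survival: tuple[np.ndarray, np.ndarray],
    n_dwells: int | None = None,
    n_grid: int | None = 200,
) -> ExpFit:
    """Nonlinear least squares of A exp(-k t) to an empirical survival curve.

    ``n_dwells`` (if known) enables binomial-variance weighting of the
    curve points; dense curves are fit on a log-spaced time subgrid of at
    most ``n_grid`` points.  The amplitude A is left free rather than
    pinned to 1 because the first grid point already reflects frame
    quantization.
    """
    t, s = map(np.asarray, survival)
    if t.size < 5:
        raise ValueError("need at least 5 support points")
    tf, sf, sigma = _prepare_curve(t, s, n_dwells, n_grid)
    k0 = 1.0 / max(np.trapezoid(s, t), 1e-9)  # area under S approximates mean dwell
    try:
        popt, pcov = curve_fit(
            _single, tf, sf, p0=[1.0, k0], sigma=sigma,
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"single-exponential fit did not converge: {exc}") from exc
    se = tuple(np.sqrt(np.diag(pcov)).tolist())
    return ExpFit(
        model="single",
        amplitudes=(float(popt[0]),),
        rates=(float(popt[1]),),
        standard_errors=se,
        n=tf.size,
    )


def fit_double_exp(
    survival: tuple[np.ndarray, np.ndarray],
    n_dwells: int | None = None,
    n_grid: int | None = 60,
) -> ExpFit:
    """Two-component exponential fit, components ordered fast-first.

    The optimizer is multi-started over a small ladder of rate
    initializations (anchored at the curve's overall 1/mean with the fast
    start at least 10x the slow start) and the lowest-residual solution
    wins.  If the two rate components collapse (within 5%) or every start
    fails, a single-exponential fit is returned with
    ``fallback_single=True`` and a warning.
    """
    t, s = map(np.asarray, survival)
    if t.size < 10:
        raise ValueError("need at least 10 support points")
    tf, sf, sigma = _prepare_curve(t, s, n_dwells, n_grid)
    k_mean = 1.0 / max(np.trapezoid(s, t), 1e-9)
    starts = []
    for mult_fast in (2.0, 10.0, 50.0):
        k2_0 = max(k_mean / 4.0, 1e-6)
        k1_0 = max(mult_fast * k_mean, 10.0 * k2_0)
        starts.append((k1_0, k2_0))

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for k1_0, k2_0 in starts:
        try:
            popt, pcov = curve_fit(
                _double, tf, sf, p0=[0.5, k1_0, 0.5, k2_0], sigma=sigma,
                bounds=([0.0, 1e-12, 0.0, 1e-12], [np.inf] * 4), maxfev=50000,
            )
        except RuntimeError:
            continue
        resid = _double(tf, *popt) - sf
        if sigma is not None:
            resid = resid / sigma
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)

    if best is not None:
        _, popt, pcov = best
        a1, k1, a2, k2 = popt
        se = np.sqrt(np.diag(pcov))
        if k1 < k2:  # reorder fast-first
            a1, k1, a2, k2 = a2, k2, a1, k1
            se = se[[2, 3, 0, 1]]
        amp_total = a1 + a2
        amp_ok = amp_total > 0 and min(a1, a2) / amp_total >= 0.01
        if k1 > 0 and abs(k1 - k2) / k1 >= 0.05 and amp_ok:
            return ExpFit(
                model="double",
                amplitudes=(float(a1), float(a2)),
                rates=(float(k1), float(k2)),
                standard_errors=(float(se[0]), float(se[2]), float(se[1]), float(se[3])),
                n=tf.size,
            )
    warnings.warn(
        "double-exponential components collapsed or fit failed; "
        "falling back to a single-exponential model"
    )
    single = fit_single_exp((t, s), n_dwells=n_dwells)
    single.fallback_single = True
    return single
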