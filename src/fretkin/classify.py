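"""Static/dynamic classification of binding events.

A binding event is dynamic if it shows at least one FRET change of 0.1
or more sustained for at least 50 ms, and static otherwise.  The
classifier realizes this as maximum-likelihood change-point detection:
recursive binary segmentation under a constant-mean Gaussian model, a
split being accepted when it lowers the Bayesian information criterion,
followed by merging of sub-threshold (< 0.1 FRET) and sub-duration
(< 50 ms) segments.  At an 80 ms frame time the 50 ms criterion is met
by any one-frame segment; the parameter matters at faster frame rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

__all__ = [
    "Segment",
    "EventClassification",
    "PopulationSummary",
    "segment_event",
    "classify_event",
    "summarize",
]


@dataclass
class Segment:
    start_frame: int
    end_frame: int  # exclusive
    mean: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class EventClassification:
    event_ref: str
    label: str  # "static" | "dynamic"
    n_segments: int
    max_delta: float
    evidence: float  # BIC improvement of the segmentation over one segment


@dataclass
class PopulationSummary:
    n_events: int
    n_dynamic: int
    n_static: int
    frac_dynamic: float
    binomial_ci95: tuple[float, float]


def _rss(x: np.ndarray) -> float:
    return float(np.sum((x - x.mean()) ** 2))


#: minimum frames on each side of a candidate change point; one-frame
#: provisional segments carry no variance information and turn single
#: noise outliers into spurious splits
MIN_SPLIT_FRAMES = 2


def _best_split(x: np.ndarray, min_seg: int = MIN_SPLIT_FRAMES) -> tuple[int, float] | tuple[None, None]:
    """Best single change point by residual sum of squares.

    Returns (split index k, RSS of the two-segment model), with at least
    ``min_seg`` frames on either side; (None, None) if no split fits.
    """
    n = x.size
    k = np.arange(min_seg, n - min_seg + 1)
    if k.size == 0:
        return None, None
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    rss_left = css[k - 1] - cs[k - 1] ** 2 / k
    rss_right = (css[-1] - css[k - 1]) - (cs[-1] - cs[k - 1]) ** 2 / (n - k)
    total = rss_left + rss_right
    i = int(np.argmin(total))
    return int(k[i]), float(total[i])


def _split_accepted(n: int, rss0: float, rss1: float, penalty_params: float = 2.0) -> bool:
    """BIC test: split if the likelihood gain beats the parameter penalty.

    With profiled Gaussian variance, -2 ln L = n log(RSS/n) + const; a
    split adds one mean and one change-point location (2 parameters).
    """
    eps = 1e-12 * max(rss0, 1.0)
    if rss0 <= eps:
        return False  # flat segment, nothing to gain
    gain = n * np.log(max(rss0, eps) / max(rss1, eps))
    return gain > penalty_params * np.log(n)


def _recursive_segments(
    x: np.ndarray, offset: int, out: list[tuple[int, int]], min_seg: int
) -> None:
    n = x.size
    if n < 2 * min_seg:
        out.append((offset, offset + n))
        return
    k, rss1 = _best_split(x, min_seg)
    if k is not None and _split_accepted(n, _rss(x), rss1):
        _recursive_segments(x[:k], offset, out, min_seg)
        _recursive_segments(x[k:], offset + k, out, min_seg)
    else:
        out.append((offset, offset + n))


def segment_event(
    event_fret: np.ndarray,
    frame_time: float,
    delta: float = 0.1,
    min_ms: float = 50.0,
) -> list[Segment]:
    """Segment one event's FRET series into constant-FRET levels.

    Recursive BIC-penalized change-point search, then (a) adjacent
    segments whose means differ by less than ``delta`` are merged and
    (b) segments shorter than ``min_ms`` are merged into the neighbor
    with the closer mean.  Degenerate events return one segment.
    """
    x = np.asarray(event_fret, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("event contains no finite FRET values")
    # decided once from the whole event: long events use two-frame
    # provisional segments to keep single-frame noise outliers from
    # becoming splits; events too short for that fall back to
    # single-frame splits, where the delta-merge below is the only
    # guard and the test reduces to the direct FRET-change criterion
    min_seg = MIN_SPLIT_FRAMES if x.size >= 7 else 1
    bounds: list[tuple[int, int]] = []
    _recursive_segments(x, 0, bounds, min_seg)
    bounds.sort()

    min_frames = int(np.ceil(min_ms / 1000.0 / frame_time - 1e-9))

    def _means(bds):
        return [float(x[a:b].mean()) for a, b in bds]

    # merge short segments into the neighbor with the closer mean
    changed = True
    while changed and len(bounds) > 1:
        changed = False
        means = _means(bounds)
        for i, (a, b) in enumerate(bounds):
            if (b - a) >= max(min_frames, 1):
                continue
            if i == 0:
                j = 1
            elif i == len(bounds) - 1:
                j = i - 1
            else:
                j = i - 1 if abs(means[i - 1] - means[i]) <= abs(means[i + 1] - means[i]) else i + 1
            lo, hi = min(i, j), max(i, j)
            bounds[lo:hi + 1] = [(bounds[lo][0], bounds[hi][1])]
            changed = True
            break

    # merge adjacent segments closer than delta, smallest difference first
    while len(bounds) > 1:
        means = _means(bounds)
        diffs = np.abs(np.diff(means))
        i = int(np.argmin(diffs))
        if diffs[i] >= delta:
            break
        bounds[i:i + 2] = [(bounds[i][0], bounds[i + 1][1])]

    return [Segment(a, b, float(x[a:b].mean())) for a, b in bounds]


def classify_event(
    segments: list[Segment],
    frame_time: float,
    delta: float = 0.1,
    min_ms: float = 50.0,
    event_ref: str = "",
    event_fret: np.ndarray | None = None,
) -> EventClassification:
    """Label an event dynamic iff it has >= 2 segments, a sustained FRET
    change >= ``delta`` between adjacent segments, and every segment at
    least ``min_ms`` long."""
    if not segments:
        raise ValueError("no segments")
    means = [s.mean for s in segments]
    max_delta = float(np.max(np.abs(np.diff(means)))) if len(means) > 1 else 0.0
    min_frames = int(np.ceil(min_ms / 1000.0 / frame_time - 1e-9))
    durations_ok = all(s.n_frames >= max(min_frames, 1) for s in segments)
    dynamic = len(segments) >= 2 and max_delta >= delta and durations_ok
    evidence = 0.0
    if event_fret is not None and len(segments) > 1:
        x = np.asarray(event_fret, dtype=float)
        x = x[np.isfinite(x)]
        n = x.size
        rss0 = _rss(x)
        rss1 = sum(_rss(x[s.start_frame:s.end_frame]) for s in segments)
        p0, p1 = 1, 2 * len(segments) - 1
        eps = 1e-12 * max(rss0, 1.0)
        bic0 = n * np.log(max(rss0, eps) / n) + p0 * np.log(n)
        bic1 = n * np.log(max(rss1, eps) / n) + p1 * np.log(n)
        evidence = float(bic0 - bic1)
    return EventClassification(
        event_ref=event_ref,
        label="dynamic" if dynamic else "static",
        n_segments=len(segments),
        max_delta=max_delta,
        evidence=evidence,
    )


def classify_trace_events(
    fret, events, delta: float = 0.1, min_ms: float = 50.0, edge_trim: int = 1
) -> list[EventClassification]:
    """Segment and classify every detected event of one FRET trace.

    Runs on the unsmoothed FRET series inside each event; smoothing would
    blur genuine sub-second transitions.  ``edge_trim`` frames are removed
    from each end of events long enough to afford it: the camera
    integrates over the frame, so the first and last frame of a binding
    event average bound and unbound signal and would register as a
    spurious FRET change.
    """
    out = []
    eff = np.asarray(fret.efficiency)
    for i, ev in enumerate(events):
        a, b = ev.start_frame, ev.end_frame
        if (b - a) >= 2 * edge_trim + 2:
            a, b = a + edge_trim, b - edge_trim
        x = eff[a:b]
        if x[np.isfinite(x)].size < 2:
            continue
        segs = segment_event(x, fret.frame_time, delta=delta, min_ms=min_ms)
        out.append(classify_event(
            segs, fret.frame_time, delta=delta, min_ms=min_ms,
            event_ref=f"{fret.trace_id}:{i}", event_fret=x,
        ))
    return out


def summarize(classifications: list[EventClassification]) -> PopulationSummary:
    """Counts, dynamic fraction and exact (Clopper-Pearson) 95% CI."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    n = len(classifications)
    n_dyn = sum(1 for c in classifications if c.label == "dynamic")
    ci = binomtest(n_dyn, n).proportion_ci(confidence_level=0.95, method="exact")
    return PopulationSummary(
        n_events=n,
        n_dynamic=n_dyn,
        n_static=n - n_dyn,
        frac_dynamic=n_dyn / n,
        binomial_ci95=(float(ci.low), float(ci.high)),
    )
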