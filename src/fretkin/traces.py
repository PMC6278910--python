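"""Intensity-trajectory I/O and conversion to apparent FRET.

Apparent FRET efficiency is E = I_A / (I_D + I_A) computed from raw
channel intensities after subtracting donor spectral leakage from the
acceptor channel.  Seven-point moving-average smoothing and pooled FRET
histograms with a single-Gaussian summary (center X0, width sigma)
follow standard smFRET practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "IntensityTrace",
    "FretTrace",
    "FretHistogram",
    "correct_leakage",
    "compute_fret",
    "smooth",
    "build_histogram",
    "read_trace",
    "write_fret_trace",
]


@dataclass
class IntensityTrace:
    """Two-channel intensity trajectory on a uniform frame grid."""

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_time: float
    trace_id: str = ""
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("time, donor, acceptor must have equal length")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time must be strictly increasing with constant step")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class FretTrace:
    """Apparent-FRET series with a record of the processing applied."""

    time: np.ndarray
    efficiency: np.ndarray
    frame_time: float
    trace_id: str = ""
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    gaussian_center: float | None = None  # X0
    gaussian_width: float | None = None   # sigma


def correct_leakage(trace: IntensityTrace, leakage: float = 0.10) -> IntensityTrace:
    """Subtract donor bleed-through from the acceptor channel.

    acceptor' = acceptor - leakage * donor, floored at zero; the donor is
    unchanged.  This is the exact inverse of the simulator's leakage step.
    """
    if leakage < 0:
        raise ValueError("leakage must be nonnegative")
    if leakage >= 1:
        raise ValueError("leakage must be < 1")
    acceptor = np.clip(trace.acceptor - leakage * trace.donor, 0.0, None)
    return IntensityTrace(
        time=trace.time.copy(),
        donor=trace.donor.copy(),
        acceptor=acceptor,
        frame_time=trace.frame_time,
        trace_id=trace.trace_id,
        provenance=trace.provenance + [{"step": "correct_leakage", "leakage": leakage}],
    )


def compute_fret(trace: IntensityTrace) -> FretTrace:
    """E_t = I_A / (I_D + I_A); frames with zero total intensity become NaN.

    Warns if leakage correction is not recorded in the trace provenance.
    """
    if not any(p.get("step") == "correct_leakage" for p in trace.provenance):
        warnings.warn(
            "computing FRET on a trace without recorded leakage correction",
            stacklevel=2,
        )
    total = trace.donor + trace.acceptor
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(total > 0, trace.acceptor / total, np.nan)
    return FretTrace(
        time=trace.time.copy(),
        efficiency=eff,
        frame_time=trace.frame_time,
        trace_id=trace.trace_id,
        provenance=trace.provenance + [{"step": "compute_fret"}],
    )


def smooth(fret: FretTrace, window: int = 7) -> FretTrace:
    """Centered moving average with shrinking windows at the edges.

    Missing frames (NaN) are excluded from each window's mean rather than
    interpolated.  The first frame of a 7-point smooth therefore averages
    frames 1-4; no frames are dropped, preserving dwell boundaries.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    sm = (
        pd.Series(fret.efficiency)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    # all-NaN windows stay NaN (rolling mean already does this)
    return FretTrace(
        time=fret.time.copy(),
        efficiency=sm,
        frame_time=fret.frame_time,
        trace_id=fret.trace_id,
        provenance=fret.provenance + [{"step": "smooth", "window": window}],
    )


def _gaussian(x, amp, x0, sigma):
    return amp * np.exp(-0.5 * ((x - x0) / sigma) ** 2)


def build_histogram(
    fret_traces: list[FretTrace],
    bins: int = 40,
    range: tuple[float, float] = (0.0, 1.0),
) -> FretHistogram:
    """Pool frames from all traces, bin, and fit a single Gaussian.

    The Gaussian center X0 and width sigma summarize the population; a
    failed fit leaves them as None with a warning.
    """
    if not fret_traces:
        raise ValueError("need at least one trace")
    pooled = np.concatenate([ft.efficiency for ft in fret_traces])
    pooled = pooled[np.isfinite(pooled)]
    pooled = pooled[(pooled >= range[0]) & (pooled <= range[1])]
    if pooled.size == 0:
        raise ValueError("no finite FRET values in range")
    counts, edges = np.histogram(pooled, bins=bins, range=range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = range[1] - range[0]
    x0 = sigma = None
    try:
        # moments of the histogram itself initialize the bounded fit
        w = counts / counts.sum()
        mu = float(np.sum(w * centers))
        sd = float(np.sqrt(np.sum(w * (centers - mu) ** 2)))
        p0 = [float(counts.max()), mu, max(sd, width / bins)]
        popt, _ = curve_fit(
            _gaussian, centers, counts.astype(float), p0=p0,
            bounds=([0.0, range[0], width / (2 * bins)], [np.inf, range[1], width]),
            maxfev=10000,
        )
        x0, sigma = float(popt[1]), abs(float(popt[2]))
    except Exception as exc:  # noqa: BLE001 - report and continue
        warnings.warn(f"Gaussian fit to FRET histogram failed: {exc}")
        x0 = sigma = None
    return FretHistogram(bin_edges=edges, counts=counts,
                         gaussian_center=x0, gaussian_width=sigma)


def read_trace(path: str | Path, legacy: bool = False, frame_time: float | None = None) -> IntensityTrace:
    """Read a tab-separated trace file.

    Default format: ``time_s  donor  acceptor`` with ``# key=value`` header
    lines (the simulator's output).  ``legacy=True`` reads three columns of
    frame-index, donor, acceptor and requires ``frame_time``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                continue  # column header
            rows.append(vals)
    arr = np.asarray(rows)
    if legacy:
        if frame_time is None:
            raise ValueError("legacy format requires frame_time")
        time = arr[:, 0] * frame_time
    else:
        time = arr[:, 0]
        if frame_time is None:
            frame_time = float(meta.get("frame_time", np.diff(time).mean() if len(time) > 1 else 0.08))
    return IntensityTrace(
        time=time,
        donor=arr[:, 1],
        acceptor=arr[:, 2],
        frame_time=frame_time,
        trace_id=meta.get("trace_id", path.stem),
    )


def read_fret_trace(path: str | Path) -> FretTrace:
    """Read a two-column FRET TSV written by :func:`write_fret_trace`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            try:
                rows.append([float(parts[0]), float(parts[1])])
            except ValueError:
                continue
    arr = np.asarray(rows)
    time = arr[:, 0]
    frame_time = float(meta.get("frame_time", np.diff(time).mean() if len(time) > 1 else 0.08))
    return FretTrace(
        time=time,
        efficiency=arr[:, 1],
        frame_time=frame_time,
        trace_id=meta.get("trace_id", path.stem),
    )


def write_fret_trace(fret: FretTrace, path: str | Path) -> None:
    """Write a FRET trajectory as TSV: time_s, fret."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frame_time={fret.frame_time}\n")
        fh.write(f"# trace_id={fret.trace_id}\n")
        for step in fret.provenance:
            fh.write(f"# step={step}\n")
        fh.write("time_s\tfret\n")
        for t, e in zip(fret.time, fret.efficiency):
            fh.write(f"{t:.6f}\t{e:.6f}\n")
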