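"""Gaussian-emission HMM idealization of long binding events.

Binding events longer than 60 s are pooled and fit with a shared
discrete-state hidden Markov model (default five states, one Gaussian
emission per state with free per-state variance), then each segment is
decoded to its most-likely (Viterbi) state path.  Only FRET values in
[0.05, 1.0] enter the fit; out-of-range frames are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that records the full log-likelihood trajectory."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)

from .kinetics import BindingEvent
from .traces import FretTrace

__all__ = [
    "HmmModel",
    "IdealizedPath",
    "select_segments",
    "fit_hmm",
    "viterbi",
]

FRET_RANGE = (0.05, 1.0)


@dataclass
class HmmModel:
    """Fitted HMM parameters, states sorted by ascending mean FRET."""

    n_states: int
    means: np.ndarray            # FRET per state, ascending
    sds: np.ndarray              # emission standard deviation per state
    trans: np.ndarray            # row-stochastic per-frame transition matrix
    initial: np.ndarray
    log_likelihood: float
    n_iter: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be positive")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("state means must be sorted ascending")

    def to_hmmlearn(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.n_states, covariance_type="diag",
                        init_params="", params="")
        m.startprob_ = self.initial.copy()
        m.transmat_ = self.trans.copy()
        m.means_ = self.means.reshape(-1, 1).copy()
        m.covars_ = (self.sds.reshape(-1, 1) ** 2).copy()
        return m


@dataclass
class IdealizedPath:
    """Viterbi decoding of one segment."""

    time: np.ndarray
    state_index: np.ndarray
    state_fret: np.ndarray
    source_trace: str = ""
    log_probability: float = 0.0


def select_segments(
    fret_traces: list[FretTrace],
    events_per_trace: list[list[BindingEvent]],
    min_duration: float = 60.0,
    fret_range: tuple[float, float] = FRET_RANGE,
) -> list[dict]:
    """Bound-event FRET segments longer than ``min_duration`` (strict).

    Frames with FRET outside ``fret_range`` (or missing) are dropped from
    each segment.  Returns dicts with keys ``fret``, ``time``, ``trace_id``,
    ``event`` for traceability; empty list if nothing qualifies.
    """
    segments = []
    for fret, events in zip(fret_traces, events_per_trace):
        eff = np.asarray(fret.efficiency)
        for ev in events:
            if ev.duration <= min_duration:
                continue
            chunk = eff[ev.start_frame:ev.end_frame]
            t = fret.time[ev.start_frame:ev.end_frame]
            keep = np.isfinite(chunk) & (chunk >= fret_range[0]) & (chunk <= fret_range[1])
            if keep.sum() == 0:
                continue
            segments.append({
                "fret": chunk[keep],
                "time": t[keep],
                "trace_id": fret.trace_id,
                "event": ev,
            })
    return segments


def _n_free_params(k: int) -> int:
    # k means + k variances + k(k-1) transition + (k-1) initial
    return k * 2 + k * (k - 1) + (k - 1)


def fit_hmm(
    segments: list[dict] | list[np.ndarray],
    n_states: int = 5,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol_per_frame: float = 1e-6,
    fret_range: tuple[float, float] = FRET_RANGE,
) -> HmmModel:
    """Pooled Baum-Welch fit over all segments with shared parameters.

    Multi-restart EM: means initialized evenly over the analysis range
    and jittered per restart, transitions start at 0.9 self-probability,
    initial distribution uniform.  A restart whose expected occupancy
    starves any state (< 1 frame) is discarded; the best surviving
    restart by log-likelihood wins.  States are relabeled so means ascend.
    """
    arrays = [
        np.asarray(s["fret"] if isinstance(s, dict) else s, dtype=float)
        for s in segments
    ]
    arrays = [a for a in arrays if a.size > 0]
    if not arrays:
        raise ValueError("no segments to fit")
    x = np.concatenate(arrays).reshape(-1, 1)
    lengths = [a.size for a in arrays]
    n_total = x.shape[0]
    if n_total < 10 * _n_free_params(n_states):
        raise ValueError(
            f"{n_total} pooled frames < 10 x {_n_free_params(n_states)} free "
            f"parameters; pool more segments or reduce n_states"
        )

    ss = np.random.SeedSequence(seed)
    base_means = np.linspace(fret_range[0], fret_range[1], n_states + 2)[1:-1]
    best: GaussianHMM | None = None
    best_hist: list[float] = []
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol_per_frame * n_total,
            init_params="",
            params="stmc",
            covars_prior=0.0,
            covars_weight=0.0,
            min_covar=1e-8,
            random_state=np.random.RandomState(int(rng.integers(2**31))),
        )
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        trans = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(trans, 0.9)
        model.transmat_ = trans / trans.sum(axis=1, keepdims=True)
        jitter = rng.normal(0.0, 0.02, n_states) if n_states > 1 else np.zeros(1)
        model.means_ = (base_means + jitter).reshape(-1, 1)
        model.covars_ = np.full((n_states, 1), 0.05**2)
        model.monitor_ = _HistoryMonitor(model.tol, model.n_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(x, lengths)
            except Exception:
                continue
        # expected state occupancy over the pooled data
        try:
            post = model.predict_proba(x, lengths)
        except Exception:
            continue
        if np.any(post.sum(axis=0) < 1.0):
            continue  # starved state
        hist = model.monitor_.full_history
        score = hist[-1] if hist else -np.inf
        if best is None or score > (best_hist[-1] if best_hist else -np.inf):
            best = model
            best_hist = list(hist)
    if best is None:
        raise RuntimeError(
            "all EM restarts left a starved state; try fewer states"
        )

    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(np.asarray(best.covars_).reshape(n_states, -1)[:, 0])[order]
    trans = best.transmat_[np.ix_(order, order)]
    trans = trans / trans.sum(axis=1, keepdims=True)
    initial = best.startprob_[order]
    initial = initial / initial.sum()
    return HmmModel(
        n_states=n_states,
        means=means,
        sds=np.clip(sds, 1e-6, None),
        trans=trans,
        initial=initial,
        log_likelihood=float(best_hist[-1]) if best_hist else float("nan"),
        n_iter=len(best_hist),
        loglik_history=np.asarray(best_hist),
    )


def viterbi(
    model: HmmModel,
    segment: dict | np.ndarray,
    fret_range: tuple[float, float] = FRET_RANGE,
) -> IdealizedPath:
    """Most-likely state path for one segment under a fitted model."""
    if isinstance(segment, dict):
        fret = np.asarray(segment["fret"], dtype=float)
        time = np.asarray(segment.get("time", np.arange(fret.size)), dtype=float)
        trace_id = str(segment.get("trace_id", ""))
    else:
        fret = np.asarray(segment, dtype=float)
        time = np.arange(fret.size, dtype=float)
        trace_id = ""
    keep = np.isfinite(fret) & (fret >= fret_range[0]) & (fret <= fret_range[1])
    if keep.sum() == 0:
        raise ValueError("segment has no frames inside the analysis FRET range")
    fret, time = fret[keep], time[keep]
    logprob, path = model.to_hmmlearn().decode(fret.reshape(-1, 1), algorithm="viterbi")
    return IdealizedPath(
        time=time,
        state_index=path.astype(int),
        state_fret=model.means[path],
        source_trace=trace_id,
        log_probability=float(logprob),
    )
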