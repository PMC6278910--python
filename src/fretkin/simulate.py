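"""Synthetic two-channel smFRET trajectory generator.

Emulates prism-TIRF recordings of a surface-immobilized DNA substrate
(Cy3 donor) visited by an acceptor-labelled polymerase: stochastic binding
with a biexponential waiting-time mixture, exponential bound dwells,
continuous-time Markov switching between FRET states during bound
intervals, donor->acceptor spectral leakage and additive Gaussian
detector noise.  Every trace carries a :class:`GroundTruth` record so
that downstream estimators (dwell-time fits, HMM idealization, the
static/dynamic classifier) can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .traces import IntensityTrace

__all__ = [
    "SimConfig",
    "StateSegment",
    "BoundInterval",
    "GroundTruth",
    "sample_dwells",
    "simulate_state_path",
    "render_trace",
    "render_cycles",
    "simulate_dataset",
    "write_trace",
    "write_ground_truth",
]


def _nearest_neighbour_rates(n: int, rate: float) -> np.ndarray:
    """Birth-death rate matrix: hops to adjacent states at a uniform rate."""
    q = np.zeros((n, n))
    for i in range(n - 1):
        q[i, i + 1] = rate
        q[i + 1, i] = rate
    return q


@dataclass
class SimConfig:
    """Generative parameters for one experimental condition.

    Defaults reproduce the wild-type polymerase/dideoxy-terminated
    substrate condition: 80 ms frames, k_off = 0.20 s^-1, biexponential
    binding with k_on,fast = 0.8 s^-1 and k_on,slow = 0.030 s^-1 in equal
    proportion, bound FRET states spanning 0.2-0.8, 10% donor leakage.
    ``noise_sd`` is per-channel Gaussian detector noise in intensity
    units; 70 on a total intensity of 1000 gives a per-frame FRET scatter
    of roughly 0.05, typical of EMCCD traces at this frame time.
    """

    frame_time: float = 0.08
    n_frames: int = 2500
    k_off: float = 0.20
    k_on_fast: float = 0.8
    k_on_slow: float = 0.030
    frac_fast: float = 0.5
    fret_states: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8)
    ctmc_rates: np.ndarray | None = None
    unbound_fret_mean: float = 0.0
    noise_sd: float = 70.0
    total_intensity: float = 1000.0
    leakage: float = 0.10
    p_dynamic: float = 0.49
    seed: int = 0
    initial_state: str = "stationary"  # or "uniform"
    ensure_dynamic_switch: bool = True
    #: minimum flanking-sojourn length (s) when conditioning dynamic bound
    #: intervals on an observable switch; None -> two frame times, the
    #: shortest level the camera can resolve as a distinct segment
    dynamic_min_sojourn: float | None = None

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        for name in ("k_off", "k_on_fast", "k_on_slow", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must be in [0, 1]")
        if not 0.0 <= self.p_dynamic <= 1.0:
            raise ValueError("p_dynamic must be in [0, 1]")
        if not all(0.0 <= e <= 1.0 for e in self.fret_states):
            raise ValueError("fret_states must lie in [0, 1]")
        if self.ctmc_rates is None:
            self.ctmc_rates = _nearest_neighbour_rates(len(self.fret_states), 0.5)
        self.ctmc_rates = np.asarray(self.ctmc_rates, dtype=float)
        if self.ctmc_rates.shape != (len(self.fret_states),) * 2:
            raise ValueError("ctmc_rates must be square with dim = len(fret_states)")
        off_diag = self.ctmc_rates[~np.eye(len(self.fret_states), dtype=bool)]
        if np.any(off_diag < 0):
            raise ValueError("off-diagonal ctmc_rates must be nonnegative")
        if self.initial_state not in ("stationary", "uniform"):
            raise ValueError("initial_state must be 'stationary' or 'uniform'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fret_states"] = list(self.fret_states)
        d["ctmc_rates"] = np.asarray(self.ctmc_rates).tolist()
        return d


@dataclass
class StateSegment:
    state: int
    start: float
    end: float


@dataclass
class BoundInterval:
    start: float
    end: float
    dynamic: bool
    segments: list[StateSegment] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    intervals: list[BoundInterval]
    dynamic: bool
    config: SimConfig

    def to_dict(self) -> dict:
        return {
            "dynamic": self.dynamic,
            "intervals": [
                {
                    "start": iv.start,
                    "end": iv.end,
                    "dynamic": iv.dynamic,
                    "segments": [
                        {"state": s.state, "start": s.start, "end": s.end}
                        for s in iv.segments
                    ],
                }
                for iv in self.intervals
            ],
            "config": self.config.to_dict(),
        }


def sample_dwells(
    cfg: SimConfig, n: int, kind: str, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` continuous-time dwell durations (seconds).

    Bound dwells are Exponential(k_off); unbound waits are the two-component
    mixture frac_fast * Exp(k_on_fast) + (1 - frac_fast) * Exp(k_on_slow).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if kind == "bound":
        if cfg.k_off <= 0:
            raise ValueError("k_off must be positive to sample bound dwells")
        return rng.exponential(1.0 / cfg.k_off, size=n)
    if kind == "unbound":
        if cfg.frac_fast > 0 and cfg.k_on_fast <= 0:
            raise ValueError("k_on_fast is zero but the fast population has weight")
        if cfg.frac_fast < 1 and cfg.k_on_slow <= 0:
            raise ValueError("k_on_slow is zero but the slow population has weight")
        fast = rng.random(n) < cfg.frac_fast
        out = np.empty(n)
        if fast.any():
            out[fast] = rng.exponential(1.0 / cfg.k_on_fast, size=int(fast.sum()))
        if (~fast).any():
            out[~fast] = rng.exponential(1.0 / cfg.k_on_slow, size=int((~fast).sum()))
        return out
    raise ValueError(f"kind must be 'bound' or 'unbound', got {kind!r}")


def stationary_distribution(rates: np.ndarray) -> np.ndarray:
    """Stationary distribution of the CTMC with off-diagonal rate matrix ``rates``."""
    n = rates.shape[0]
    q = np.array(rates, dtype=float)
    np.fill_diagonal(q, 0.0)
    gen = q - np.diag(q.sum(axis=1))
    if not np.any(q > 0):
        return np.full(n, 1.0 / n)
    # solve pi @ gen = 0 with sum(pi) = 1
    a = np.vstack([gen.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _has_observable_switch(
    segments: list[StateSegment],
    fret_states: tuple[float, ...],
    min_delta: float,
    min_sojourn: float,
) -> bool:
    """True if some state change of >= min_delta has both flanking sojourns
    lasting >= min_sojourn (the operational definition of a dynamic event)."""
    for a, b in zip(segments[:-1], segments[1:]):
        if (
            abs(fret_states[a.state] - fret_states[b.state]) >= min_delta - 1e-9
            and (a.end - a.start) >= min_sojourn
            and (b.end - b.start) >= min_sojourn
        ):
            return True
    return False


def simulate_state_path(
    cfg: SimConfig,
    duration: float,
    dynamic: bool,
    rng: np.random.Generator | int,
    require_jump: bool = False,
    min_delta: float = 0.1,
    min_sojourn: float = 0.05,
    max_tries: int = 500,
) -> list[StateSegment]:
    """Gillespie jump process over ``cfg.fret_states`` for one bound interval.

    Returns piecewise-constant segments with times relative to the interval
    start.  ``dynamic=False`` holds a single state for the whole interval.
    With ``require_jump`` the path is conditioned on actually being
    dynamic in the operational sense — it must contain a state change of
    at least ``min_delta`` FRET with both flanking sojourns lasting at
    least ``min_sojourn`` seconds — by drawing the first holding time from
    the truncated exponential and rejection-sampling up to ``max_tries``.
    Without this conditioning a fraction of nominally dynamic intervals
    would hold a single state throughout (no jump happens to fall inside
    the dwell) and the generated dynamic fraction would not mean what the
    per-event classification measures.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(cfg.fret_states)
    q = np.array(cfg.ctmc_rates, dtype=float)
    np.fill_diagonal(q, 0.0)
    if cfg.initial_state == "stationary":
        pi = stationary_distribution(q)
    else:
        pi = np.full(n, 1.0 / n)
    if dynamic and not np.any(q > 0):
        warnings.warn("all-zero rate matrix: dynamic interval rendered static")
        dynamic = False
    if not dynamic:
        state = int(rng.choice(n, p=pi))
        return [StateSegment(state, 0.0, duration)]

    def _one_path() -> list[StateSegment]:
        segments: list[StateSegment] = []
        state = int(rng.choice(n, p=pi))
        t = 0.0
        first = True
        while t < duration:
            total = q[state].sum()
            if total <= 0:  # absorbing state
                break
            if first and require_jump:
                # inverse-CDF draw from Exp(total) truncated to (0, duration)
                u = rng.random()
                hold = -np.log1p(-u * (1.0 - np.exp(-total * duration))) / total
            else:
                hold = rng.exponential(1.0 / total)
            first = False
            t_end = min(t + hold, duration)
            segments.append(StateSegment(state, t, t_end))
            t = t_end
            if t >= duration:
                break
            state = int(rng.choice(n, p=q[state] / total))
        if not segments or segments[-1].end < duration:
            start = segments[-1].end if segments else 0.0
            segments.append(StateSegment(state, start, duration))
        return segments

    if not require_jump:
        return _one_path()
    for _ in range(max_tries):
        segments = _one_path()
        if _has_observable_switch(segments, cfg.fret_states, min_delta, min_sojourn):
            return segments
    warnings.warn(
        "could not draw an observably dynamic path (interval too short "
        "or rates too extreme); returning the last draw"
    )
    return segments


def _frame_average(
    breaks: np.ndarray, values: np.ndarray, n_frames: int, dt: float
) -> np.ndarray:
    """Time-weighted mean of a piecewise-constant signal on the frame grid.

    ``breaks`` are segment boundaries (len = len(values)+1) covering
    [0, n_frames*dt].  An 80 ms camera frame integrates photons, so a state
    switch mid-frame produces an intermediate apparent FRET value.
    """
    edges = np.arange(n_frames + 1) * dt
    # cumulative integral of the signal at every segment boundary
    seg_int = np.concatenate([[0.0], np.cumsum(values * np.diff(breaks))])
    cum_at_edges = np.interp(edges, breaks, seg_int)
    return np.diff(cum_at_edges) / dt


def render_trace(
    cfg: SimConfig, rng: np.random.Generator | int | None = None, trace_id: str = "trace0"
) -> tuple[IntensityTrace, GroundTruth]:
    """Render one donor/acceptor intensity trace with its ground truth.

    The trace starts unbound; binding/unbinding alternates until
    ``n_frames`` are covered.  Noiseless channels during bound frames are
    I_D = T*(1-E), I_A = T*E for the frame-averaged FRET E; then leakage
    adds ``leakage * I_D`` to the acceptor, then i.i.d. Gaussian noise is
    added per channel and intensities are clipped at zero.
    """
    if cfg.n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(cfg.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    duration = cfg.n_frames * cfg.frame_time
    dynamic = bool(rng.random() < cfg.p_dynamic)

    intervals: list[BoundInterval] = []
    t = float(sample_dwells(cfg, 1, "unbound", rng)[0])
    while t < duration:
        dwell = float(sample_dwells(cfg, 1, "bound", rng)[0])
        end = min(t + dwell, duration)
        iv = BoundInterval(start=t, end=end, dynamic=dynamic)
        iv.segments = simulate_state_path(
            cfg, end - t, dynamic, rng,
            require_jump=dynamic and cfg.ensure_dynamic_switch,
            min_sojourn=(cfg.dynamic_min_sojourn
                         if cfg.dynamic_min_sojourn is not None
                         else 2.0 * cfg.frame_time),
        )
        intervals.append(iv)
        t = end + float(sample_dwells(cfg, 1, "unbound", rng)[0])

    truth = GroundTruth(intervals=intervals, dynamic=dynamic, config=cfg)
    trace = _render_from_truth(cfg, truth, rng, trace_id)
    return trace, truth


def _render_from_truth(
    cfg: SimConfig, truth: GroundTruth, rng: np.random.Generator, trace_id: str
) -> IntensityTrace:
    duration = cfg.n_frames * cfg.frame_time
    breaks = [0.0]
    values = []
    for iv in truth.intervals:
        if iv.start > breaks[-1]:
            values.append(cfg.unbound_fret_mean)
            breaks.append(iv.start)
        for seg in iv.segments:
            values.append(cfg.fret_states[seg.state])
            breaks.append(iv.start + seg.end)
    if breaks[-1] < duration:
        values.append(cfg.unbound_fret_mean)
        breaks.append(duration)
    efret = _frame_average(np.asarray(breaks), np.asarray(values), cfg.n_frames, cfg.frame_time)

    donor = cfg.total_intensity * (1.0 - efret)
    acceptor = cfg.total_intensity * efret
    acceptor = acceptor + cfg.leakage * donor
    if cfg.noise_sd > 0:
        donor = donor + rng.normal(0.0, cfg.noise_sd, cfg.n_frames)
        acceptor = acceptor + rng.normal(0.0, cfg.noise_sd, cfg.n_frames)
    donor = np.clip(donor, 0.0, None)
    acceptor = np.clip(acceptor, 0.0, None)
    time = np.arange(cfg.n_frames) * cfg.frame_time
    return IntensityTrace(
        time=time, donor=donor, acceptor=acceptor,
        frame_time=cfg.frame_time, trace_id=trace_id,
    )


def render_cycles(
    cfg: SimConfig,
    n_cycles: int,
    rng: np.random.Generator | int,
    trace_id: str = "trace0",
) -> tuple[IntensityTrace, GroundTruth]:
    """Render a trace containing exactly ``n_cycles`` complete binding events.

    The trace begins and ends unbound (the trailing gap is one further
    waiting-time draw), so every bound event is interior and uncensored.
    ``cfg.n_frames`` is ignored; the frame count is set by the dwell draws.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dynamic = bool(rng.random() < cfg.p_dynamic)
    waits = sample_dwells(cfg, n_cycles + 1, "unbound", rng)
    dwells = sample_dwells(cfg, n_cycles, "bound", rng)
    # an event must span at least one full frame to be detectable at all;
    # the generator is continuous-time, but a dwell shorter than ~1.5
    # frames can never be recovered, so keep draws honest and let the
    # detector miss what it misses
    intervals: list[BoundInterval] = []
    t = 0.0
    for i in range(n_cycles):
        t += float(waits[i])
        end = t + float(dwells[i])
        iv = BoundInterval(start=t, end=end, dynamic=dynamic)
        iv.segments = simulate_state_path(
            cfg, end - t, dynamic, rng,
            require_jump=dynamic and cfg.ensure_dynamic_switch,
            min_sojourn=(cfg.dynamic_min_sojourn
                         if cfg.dynamic_min_sojourn is not None
                         else 2.0 * cfg.frame_time),
        )
        intervals.append(iv)
        t = end
    total = t + float(waits[-1])
    n_frames = int(np.ceil(total / cfg.frame_time)) + 1
    cfg2 = dataclasses.replace(cfg, n_frames=n_frames)
    truth = GroundTruth(intervals=intervals, dynamic=dynamic, config=cfg2)
    trace = _render_from_truth(cfg2, truth, rng, trace_id)
    return trace, truth


def simulate_dataset(
    cfg: SimConfig,
    n_events: int,
    events_per_trace: int = 10,
    seed: int | None = None,
) -> tuple[list[IntensityTrace], list[GroundTruth]]:
    """Simulate a batch carrying exactly ``n_events`` bound events total.

    Events are packed ``events_per_trace`` per trace (last trace takes the
    remainder).  With ``events_per_trace=1`` each trace holds a single
    event, which makes the per-trace dynamic flag a per-event flag — the
    layout used for static/dynamic classification experiments.
    """
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    counts = [events_per_trace] * (n_events // events_per_trace)
    if n_events % events_per_trace:
        counts.append(n_events % events_per_trace)
    traces, truths = [], []
    for i, (count, child) in enumerate(zip(counts, ss.spawn(len(counts)))):
        rng = np.random.default_rng(child)
        tr, gt = render_cycles(cfg, count, rng, trace_id=f"trace{i:04d}")
        traces.append(tr)
        truths.append(gt)
    return traces, truths


def write_trace(trace: IntensityTrace, path: str | Path, **metadata) -> None:
    """Write a trace as tab-separated text: time_s, donor, acceptor."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frame_time={trace.frame_time}\n")
        fh.write(f"# trace_id={trace.trace_id}\n")
        for key, val in metadata.items():
            fh.write(f"# {key}={val}\n")
        fh.write("time_s\tdonor\tacceptor\n")
        for t, d, a in zip(trace.time, trace.donor, trace.acceptor):
            fh.write(f"{t:.6f}\t{d:.4f}\t{a:.4f}\n")


def write_ground_truth(truths: list[GroundTruth], path: str | Path) -> None:
    """Sidecar JSON for a batch of simulated traces."""
    payload = [gt.to_dict() for gt in truths]
    Path(path).write_text(json.dumps(payload, indent=1))
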