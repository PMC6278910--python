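"""File-based pipeline orchestration.

Runs simulate -> process -> kinetics -> hmm -> tdp -> classify as a
configured, logged sequence of stages, each reading the previous stage's
serialized outputs from disk (so any stage can be re-run standalone) and
writing a manifest with a hash of every numeric output for
reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import hmm as _hmm
from . import kinetics as _kinetics
from . import tdp as _tdp
from . import traces as _traces
from .simulate import SimConfig, simulate_dataset, write_ground_truth, write_trace

__all__ = ["RunConfig", "run"]

ALL_STAGES = ("simulate", "process", "kinetics", "hmm", "tdp", "classify")

log = logging.getLogger("fretkin.pipeline")


@dataclass
class RunConfig:
    out_dir: str
    sim: SimConfig | None = None
    input_dir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    n_traces: int = 10
    n_events: int | None = None
    events_per_trace: int = 10
    leakage: float = 0.10
    window: int = 7
    threshold: float = 0.25
    min_frames: int = 2
    n_states: int = 5
    min_segment_duration: float = 60.0
    tdp_bins: int = 50
    tdp_bandwidth: float = 0.02
    delta: float = 0.1
    min_ms: float = 50.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = doc.pop("sim", None)
        cfg = cls(**doc)
        if sim is not None:
            if "fret_states" in sim:
                sim["fret_states"] = tuple(sim["fret_states"])
            if "ctmc_rates" in sim and sim["ctmc_rates"] is not None:
                sim["ctmc_rates"] = np.asarray(sim["ctmc_rates"], dtype=float)
            cfg.sim = SimConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    A stage failure halts the run: partial outputs are kept, a FAILED
    marker naming the stage is written, and the error re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "stages": {},
        "numpy_version": np.__version__,
    }
    current = None
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            current = stage
            t0 = _time.time()
            log.info("stage %s: start", stage)
            outputs = _STAGE_FNS[stage](config, out)
            manifest["stages"][stage] = {
                "outputs": outputs,
                "hashes": {p: _hash_file(out / p) for p in outputs if (out / p).is_file()},
                "seconds": round(_time.time() - t0, 3),
            }
            log.info("stage %s: done (%d outputs)", stage, len(outputs))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current}\nerror={exc}\n")
        log.error("stage %s failed: %s", current, exc)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest["stages"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _stage_simulate(config: RunConfig, out: Path) -> list[str]:
    if config.sim is None:
        raise ValueError("simulate stage requires a sim config block")
    sim_dir = out / "traces"
    sim_dir.mkdir(exist_ok=True)
    n_events = config.n_events or config.n_traces * config.events_per_trace
    traces, truths = simulate_dataset(
        config.sim, n_events, config.events_per_trace, seed=config.seed
    )
    paths = []
    for tr in traces:
        p = sim_dir / f"{tr.trace_id}.tsv"
        write_trace(tr, p, seed=config.seed)
        paths.append(str(p.relative_to(out)))
    gt_path = sim_dir / "ground_truth.json"
    write_ground_truth(truths, gt_path)
    paths.append(str(gt_path.relative_to(out)))
    return paths


def _input_trace_files(config: RunConfig, out: Path) -> list[Path]:
    src = Path(config.input_dir) if config.input_dir else out / "traces"
    files = sorted(p for p in src.glob("*.tsv") if "ground_truth" not in p.name)
    if not files:
        raise FileNotFoundError(f"no trace files in {src}")
    return files


def _stage_process(config: RunConfig, out: Path) -> list[str]:
    proc = out / "fret"
    proc.mkdir(exist_ok=True)
    paths = []
    all_smoothed = []
    for f in _input_trace_files(config, out):
        tr = _traces.read_trace(f)
        ft = _traces.compute_fret(_traces.correct_leakage(tr, config.leakage))
        p = proc / f"{tr.trace_id}.fret.tsv"
        _traces.write_fret_trace(ft, p)
        paths.append(str(p.relative_to(out)))
        all_smoothed.append(_traces.smooth(ft, config.window))
    hist = _traces.build_histogram(all_smoothed)
    hist_path = proc / "histogram.json"
    hist_path.write_text(json.dumps({
        "bin_edges": hist.bin_edges.tolist(),
        "counts": hist.counts.tolist(),
        "X0": hist.gaussian_center,
        "sigma": hist.gaussian_width,
    }, indent=1))
    paths.append(str(hist_path.relative_to(out)))
    return paths


def _read_fret_dir(out: Path) -> list[_traces.FretTrace]:
    files = sorted((out / "fret").glob("*.fret.tsv"))
    if not files:
        raise FileNotFoundError("process stage outputs not found; run 'process' first")
    return [_traces.read_fret_trace(f) for f in files]


def _detect_all(config: RunConfig, fts):
    return [
        _kinetics.detect_events(ft, threshold=config.threshold, min_frames=config.min_frames)
        for ft in fts
    ]


def _stage_kinetics(config: RunConfig, out: Path) -> list[str]:
    fts = _read_fret_dir(out)
    per_trace = _detect_all(config, fts)
    bound, unbound = _kinetics.collect_dwells(per_trace)
    dwell_path = out / "dwells.tsv"
    with dwell_path.open("w") as fh:
        fh.write("trace_id\tkind\tduration_s\tcensored\n")
        for ft, (events, gaps) in zip(fts, per_trace):
            for e in events:
                fh.write(f"{ft.trace_id}\tbound\t{e.duration:.6f}\t{int(e.censored)}\n")
            for g in gaps:
                fh.write(f"{ft.trace_id}\tunbound\t{g.duration:.6f}\t{int(g.censored)}\n")
    report = {}
    if bound.durations.size >= 5:
        fit = _kinetics.fit_single_exp(_kinetics.survival_curve(bound))
        report["bound"] = _fit_to_dict(fit)
    if unbound.durations.size >= 10:
        fit = _kinetics.fit_double_exp(_kinetics.survival_curve(unbound))
        report["unbound"] = _fit_to_dict(fit)
    fit_path = out / "kinetics.json"
    fit_path.write_text(json.dumps(report, indent=1))
    return [str(dwell_path.relative_to(out)), str(fit_path.relative_to(out))]


def _fit_to_dict(fit: _kinetics.ExpFit) -> dict:
    return {
        "model": fit.model,
        "amplitudes": list(fit.amplitudes),
        "rates": list(fit.rates),
        "standard_errors": list(fit.standard_errors),
        "n": fit.n,
        "converged": fit.converged,
        "fallback_single": fit.fallback_single,
    }


def _stage_hmm(config: RunConfig, out: Path) -> list[str]:
    fts = _read_fret_dir(out)
    per_trace = _detect_all(config, fts)
    segments = _hmm.select_segments(
        fts, [ev for ev, _ in per_trace], min_duration=config.min_segment_duration
    )
    if not segments:
        (out / "hmm.json").write_text(json.dumps({"n_segments": 0}))
        return ["hmm.json"]
    model = _hmm.fit_hmm(segments, n_states=config.n_states, seed=config.seed)
    paths_out = out / "idealized"
    paths_out.mkdir(exist_ok=True)
    written = []
    for i, seg in enumerate(segments):
        path = _hmm.viterbi(model, seg)
        p = paths_out / f"segment{i:03d}.tsv"
        with p.open("w") as fh:
            fh.write("time_s\tstate\tstate_fret\n")
            for t, s, e in zip(path.time, path.state_index, path.state_fret):
                fh.write(f"{t:.6f}\t{s}\t{e:.6f}\n")
        written.append(str(p.relative_to(out)))
    (out / "hmm.json").write_text(json.dumps({
        "n_segments": len(segments),
        "n_states": model.n_states,
        "means": model.means.tolist(),
        "sds": model.sds.tolist(),
        "trans": model.trans.tolist(),
        "initial": model.initial.tolist(),
        "log_likelihood": model.log_likelihood,
        "n_iter": model.n_iter,
    }, indent=1))
    return written + ["hmm.json"]


def _read_idealized(out: Path) -> list[_hmm.IdealizedPath]:
    files = sorted((out / "idealized").glob("segment*.tsv"))
    paths = []
    for f in files:
        arr = np.loadtxt(f, skiprows=1)
        arr = np.atleast_2d(arr)
        paths.append(_hmm.IdealizedPath(
            time=arr[:, 0], state_index=arr[:, 1].astype(int),
            state_fret=arr[:, 2], source_trace=f.stem,
        ))
    return paths


def _stage_tdp(config: RunConfig, out: Path) -> list[str]:
    if not (out / "idealized").is_dir():
        (out / "tdp.meta.json").write_text(json.dumps({"n_transitions": 0}))
        return ["tdp.meta.json"]
    paths = _read_idealized(out)
    pairs = _tdp.extract_transitions(paths)
    if pairs.shape[0] == 0:
        (out / "tdp.meta.json").write_text(json.dumps({"n_transitions": 0}))
        return ["tdp.meta.json"]
    matrix = _tdp.build_tdp(pairs, bins=config.tdp_bins, bandwidth=config.tdp_bandwidth)
    _tdp.save_tdp(matrix, out / "tdp")
    _tdp.plot_tdp(matrix, out / "tdp.png")
    meta = json.loads((out / "tdp.meta.json").read_text())
    meta["symmetry_score"] = _tdp.tdp_symmetry_score(matrix)
    (out / "tdp.meta.json").write_text(json.dumps(meta, indent=1))
    return ["tdp.counts.tsv", "tdp.density.tsv", "tdp.meta.json", "tdp.png"]


def _stage_classify(config: RunConfig, out: Path) -> list[str]:
    fts = _read_fret_dir(out)
    per_trace = _detect_all(config, fts)
    cls = []
    for ft, (events, _) in zip(fts, per_trace):
        cls.extend(_classify.classify_trace_events(
            ft, events, delta=config.delta, min_ms=config.min_ms
        ))
    ev_path = out / "events.tsv"
    with ev_path.open("w") as fh:
        fh.write("event_ref\tlabel\tn_segments\tmax_delta\tevidence\n")
        for c in cls:
            fh.write(f"{c.event_ref}\t{c.label}\t{c.n_segments}\t{c.max_delta:.4f}\t{c.evidence:.3f}\n")
    if cls:
        summary = _classify.summarize(cls)
        (out / "classification.json").write_text(json.dumps({
            "n_events": summary.n_events,
            "n_dynamic": summary.n_dynamic,
            "n_static": summary.n_static,
            "frac_dynamic": summary.frac_dynamic,
            "binomial_ci95": list(summary.binomial_ci95),
        }, indent=1))
    else:
        (out / "classification.json").write_text(json.dumps({"n_events": 0}))
    return ["events.tsv", "classification.json"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "kinetics": _stage_kinetics,
    "hmm": _stage_hmm,
    "tdp": _stage_tdp,
    "classify": _stage_classify,
}
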