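"""Event detection and exponential dwell-time fitting."""

import numpy as np
import pytest

from fretkin.kinetics import (
    DwellSet,
    collect_dwells,
    detect_events,
    fit_double_exp,
    fit_single_exp,
    survival_curve,
)
from fretkin.simulate import SimConfig, simulate_dataset
from fretkin.traces import compute_fret, correct_leakage
from tests.conftest import make_fret


class TestDetectEvents:
    def test_hand_counted_event(self):
        ft = make_fret([0, 0, 0.5, 0.5, 0.5, 0, 0])
        events, gaps = detect_events(ft, threshold=0.25, min_frames=1)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(0.24)
        assert not events[0].censored
        assert len(gaps) == 2 and all(g.censored for g in gaps)

    def test_all_zero_trace_has_no_events(self):
        ft = make_fret([0.0] * 10)
        events, gaps = detect_events(ft)
        assert events == []
        assert len(gaps) == 1 and gaps[0].censored

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_events(make_fret([]))

    def test_short_gap_debounced(self):
        ft = make_fret([0.5] * 5 + [0.0] + [0.5] * 5)
        events, _ = detect_events(ft, min_frames=2)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(11 * 0.08)

    def test_short_event_suppressed(self):
        ft = make_fret([0.0] * 5 + [0.5] + [0.0] * 5)
        events, _ = detect_events(ft, min_frames=2)
        assert events == []

    def test_durations_match_ground_truth_at_zero_noise(self):
        cfg = SimConfig(
            noise_sd=0.0, leakage=0.0, fret_states=(0.5,),
            ctmc_rates=np.zeros((1, 1)), p_dynamic=0.0,
        )
        traces, truths = simulate_dataset(cfg, 30, events_per_trace=5, seed=8)
        dt = cfg.frame_time
        n_checked = 0
        for tr, gt in zip(traces, truths):
            ft = compute_fret(correct_leakage(tr, 0.0))
            events, _ = detect_events(ft, threshold=0.25, min_frames=1)
            got = [e for e in events if not e.censored]
            long_true = [iv for iv in gt.intervals if iv.duration > 2 * dt]
            assert len(got) >= len(long_true)
            for ev in got:
                # match by temporal overlap with the generating interval
                best = max(
                    gt.intervals,
                    key=lambda iv: min(iv.end, ev.end) - max(iv.start, ev.start),
                )
                assert min(best.end, ev.end) - max(best.start, ev.start) > 0
                assert abs(ev.duration - best.duration) <= dt + 1e-9
                n_checked += 1
        assert n_checked >= 25


class TestCollectDwells:
    def test_two_events_one_gap(self):
        ft = make_fret([0] * 3 + [0.5] * 4 + [0] * 4 + [0.5] * 4 + [0] * 3)
        pair = detect_events(ft, min_frames=2)
        bound, unbound = collect_dwells([pair])
        assert bound.durations.size == 2
        assert unbound.durations.size == 1

    def test_all_censored_is_error(self):
        ft = make_fret([0.5] * 10)  # one censored event, no gaps
        pair = detect_events(ft)
        with pytest.raises(ValueError, match="censored"):
            collect_dwells([pair])

    def test_censored_inclusion_flag(self):
        ft = make_fret([0.5] * 5 + [0.0] * 5)
        pair = detect_events(ft)
        bound, unbound = collect_dwells([pair], include_censored=True)
        assert bound.durations.size == 1
        assert unbound.durations.size == 1


class TestSurvival:
    def test_counting_example(self):
        ds = DwellSet(np.array([1.0, 2.0, 3.0, 1.5, 2.5]), "bound", 1, 1.0)
        t, s = survival_curve(ds)
        assert s[0] == 1.0
        assert np.interp(1.0, t, s) == pytest.approx(4 / 5)
        assert s[-1] == pytest.approx(0.0)

    def test_non_increasing_and_bounded(self, rng):
        ds = DwellSet(rng.exponential(5.0, 500), "bound", 1, 0.08)
        _, s = survival_curve(ds)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_exponential_survival_value(self, rng):
        ds = DwellSet(rng.exponential(5.0, 10_000), "bound", 1, 0.08)
        t, s = survival_curve(ds)
        assert np.interp(5.0, t, s) == pytest.approx(np.exp(-1), abs=0.02)

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            survival_curve(DwellSet(np.array([1.0]), "bound", 1, 0.08))


class TestSingleExp:
    def test_noiseless_curve_exact(self):
        t = np.arange(0, 30, 0.08)
        fit = fit_single_exp((t, np.exp(-0.2 * t)))
        assert fit.rates[0] == pytest.approx(0.2, rel=1e-3)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-3)

    def test_recovery_vs_mle_oracle(self, rng):
        d = rng.exponential(5.0, 10_000)
        ds = DwellSet(d, "bound", 1, 0.08)
        fit = fit_single_exp(survival_curve(ds), n_dwells=d.size)
        mle = 1.0 / np.mean(d)
        assert fit.rates[0] == pytest.approx(mle, rel=0.05)

    def test_time_rescaling_inverts_rate(self):
        t = np.arange(0, 30, 0.08)
        s = np.exp(-0.2 * t)
        k1 = fit_single_exp((t, s)).rates[0]
        k2 = fit_single_exp((t * 10, s)).rates[0]
        assert k2 == pytest.approx(k1 / 10, rel=1e-3)


class TestDoubleExp:
    def test_noiseless_curve_recovers_components(self):
        t = np.arange(0, 200, 0.08)
        s = 0.5 * np.exp(-0.8 * t) + 0.5 * np.exp(-0.03 * t)
        fit = fit_double_exp((t, s))
        assert fit.model == "double"
        assert fit.rates[0] == pytest.approx(0.8, rel=1e-3)
        assert fit.rates[1] == pytest.approx(0.03, rel=1e-3)

    def test_sampled_mixture_recovery(self):
        rng = np.random.default_rng(77)
        fast = rng.random(10_000) < 0.5
        d = np.where(
            fast, rng.exponential(1 / 0.8, 10_000), rng.exponential(1 / 0.03, 10_000)
        )
        ds = DwellSet(d, "unbound", 1, 0.08)
        fit = fit_double_exp(survival_curve(ds), n_dwells=d.size)
        assert fit.rates[0] == pytest.approx(0.8, rel=0.15)
        assert fit.rates[1] == pytest.approx(0.03, rel=0.15)

    def test_single_component_falls_back(self):
        t = np.arange(0, 60, 0.08)
        s = np.exp(-0.2 * t)
        with pytest.warns(UserWarning, match="single"):
            fit = fit_double_exp((t, s))
        assert fit.fallback_single
        assert fit.rates[0] == pytest.approx(0.2, rel=0.01)

    def test_rates_ordered_fast_first(self, rng):
        fast = rng.random(5000) < 0.5
        d = np.where(fast, rng.exponential(1 / 1.5, 5000), rng.exponential(1 / 0.05, 5000))
        fit = fit_double_exp(survival_curve(DwellSet(d, "unbound", 1, 0.08)), n_dwells=d.size)
        assert fit.rates[0] >= fit.rates[1]


def test_frame_quantization_bias_bounded():
    """Fitted k_off within 15% of truth when k*frame_time <= 0.03."""
    cfg = SimConfig(k_off=0.3, fret_states=(0.5, 0.6), ctmc_rates=np.full((2, 2), 0.3))
    all_bound = []
    for seed in (1, 2, 3):
        traces, _ = simulate_dataset(cfg, 100, events_per_trace=10, seed=seed)
        per = []
        for tr in traces:
            ft = compute_fret(correct_leakage(tr, cfg.leakage))
            per.append(detect_events(ft))
        bound, _ = collect_dwells(per)
        all_bound.append(bound.durations)
    d = np.concatenate(all_bound)
    fit = fit_single_exp(survival_curve(DwellSet(d, "bound", 3, 0.08)), n_dwells=d.size)
    assert fit.rates[0] == pytest.approx(0.3, rel=0.15)
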