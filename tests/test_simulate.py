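"""Generator statistics: dwell laws, state paths, rendering, determinism."""

import numpy as np
import pytest
from scipy import stats

from fretkin.simulate import (
    SimConfig,
    render_cycles,
    render_trace,
    sample_dwells,
    simulate_dataset,
    simulate_state_path,
    stationary_distribution,
)
from fretkin.traces import compute_fret, correct_leakage


class TestSampleDwells:
    def test_bound_mean_matches_rate(self):
        cfg = SimConfig(k_off=0.2)
        d = sample_dwells(cfg, 100_000, "bound", rng=1)
        assert np.mean(d) == pytest.approx(5.0, rel=0.02)

    def test_degenerate_mixture_is_pure_fast(self):
        cfg = SimConfig(frac_fast=1.0, k_on_fast=0.8)
        d = sample_dwells(cfg, 50_000, "unbound", rng=2)
        assert np.mean(d) == pytest.approx(1 / 0.8, rel=0.03)
        assert stats.kstest(d, lambda t: 1 - np.exp(-0.8 * t)).pvalue > 0.01

    def test_mixture_survival_closed_form(self):
        cfg = SimConfig(frac_fast=0.5, k_on_fast=0.8, k_on_slow=0.03)
        d = sample_dwells(cfg, 100_000, "unbound", rng=3)
        for t in (0.5, 2.0, 10.0, 50.0):
            expected = 0.5 * np.exp(-0.8 * t) + 0.5 * np.exp(-0.03 * t)
            assert np.mean(d > t) == pytest.approx(expected, abs=0.01)

    def test_bound_survival_ks(self):
        cfg = SimConfig(k_off=0.2)
        d = sample_dwells(cfg, 10_000, "bound", rng=4)
        assert stats.kstest(d, lambda t: 1 - np.exp(-0.2 * t)).pvalue > 0.01

    def test_zero_rate_with_weight_is_error(self):
        cfg = SimConfig(k_on_slow=0.0, frac_fast=0.5)
        with pytest.raises(ValueError, match="slow"):
            sample_dwells(cfg, 10, "unbound", rng=0)
        cfg2 = SimConfig(k_off=0.0)
        with pytest.raises(ValueError):
            sample_dwells(cfg2, 10, "bound", rng=0)


class TestStatePath:
    two_state = dict(
        fret_states=(0.3, 0.7),
        p_dynamic=1.0,
    )

    def test_static_path_is_single_segment(self):
        cfg = SimConfig(**self.two_state, ctmc_rates=np.array([[0, 1.0], [1.0, 0]]))
        segs = simulate_state_path(cfg, 10.0, dynamic=False, rng=0)
        assert len(segs) == 1
        assert segs[0].start == 0.0 and segs[0].end == 10.0

    def test_symmetric_rates_give_half_occupancy(self):
        cfg = SimConfig(**self.two_state, ctmc_rates=np.array([[0, 1.0], [1.0, 0]]))
        segs = simulate_state_path(cfg, 5_000.0, dynamic=True, rng=5)
        occ0 = sum(s.end - s.start for s in segs if s.state == 0) / 5_000.0
        assert occ0 == pytest.approx(0.5, abs=0.05)

    def test_asymmetric_occupancy_matches_stationary(self):
        # q01=1, q10=3 -> pi0 = 3/4
        q = np.array([[0.0, 1.0], [3.0, 0.0]])
        cfg = SimConfig(**self.two_state, ctmc_rates=q)
        segs = simulate_state_path(cfg, 10_000.0, dynamic=True, rng=6)
        occ0 = sum(s.end - s.start for s in segs if s.state == 0) / 10_000.0
        assert occ0 == pytest.approx(0.75, abs=0.03)
        assert stationary_distribution(q)[0] == pytest.approx(0.75)

    def test_all_zero_rates_warn_and_fall_back_to_static(self):
        cfg = SimConfig(**self.two_state, ctmc_rates=np.zeros((2, 2)))
        with pytest.warns(UserWarning, match="all-zero"):
            segs = simulate_state_path(cfg, 10.0, dynamic=True, rng=0)
        assert len(segs) == 1

    def test_conditioned_path_contains_observable_switch(self):
        cfg = SimConfig(**self.two_state, ctmc_rates=np.array([[0, 0.5], [0.5, 0]]))
        for seed in range(20):
            segs = simulate_state_path(
                cfg, 8.0, dynamic=True, rng=seed, require_jump=True, min_sojourn=0.16
            )
            long_enough = [s for s in segs if (s.end - s.start) >= 0.16]
            assert len(segs) >= 2
            assert len(long_enough) >= 2


class TestRenderTrace:
    def test_noiseless_channels_encode_fret(self, clean_cfg):
        trace, truth = render_trace(clean_cfg, rng=3)
        bound = np.zeros(len(trace), dtype=bool)
        dt = clean_cfg.frame_time
        for iv in truth.intervals:
            a = int(np.ceil(iv.start / dt))
            b = int(np.floor(iv.end / dt))
            bound[a:b] = True
        # frames fully inside a bound interval at E=0.5, T=1000 -> (500, 500)
        fully = bound.copy()
        fully[1:] &= bound[:-1]
        fully[:-1] &= bound[1:]
        if fully.any():
            assert np.allclose(trace.donor[fully], 500.0)
            assert np.allclose(trace.acceptor[fully], 500.0)

    def test_leakage_adds_tenth_of_donor(self, clean_cfg):
        import dataclasses

        cfg = dataclasses.replace(clean_cfg, leakage=0.10)
        t0, _ = render_trace(clean_cfg, rng=11)
        t1, _ = render_trace(cfg, rng=11)
        assert np.allclose(t1.donor, t0.donor)
        assert np.allclose(t1.acceptor, t0.acceptor + 0.10 * t0.donor)

    def test_roundtrip_fret_machine_precision(self, clean_cfg):
        """render -> leakage-correct -> FRET reproduces the generated
        frame-averaged efficiency exactly at zero noise."""
        import dataclasses

        cfg = dataclasses.replace(
            clean_cfg,
            leakage=0.10,
            fret_states=(0.3, 0.7),
            ctmc_rates=np.array([[0, 0.8], [0.8, 0]]),
            p_dynamic=1.0,
        )
        ref, _ = render_trace(dataclasses.replace(cfg, leakage=0.0), rng=21)
        expected = ref.acceptor / (ref.donor + ref.acceptor)
        leaky, _ = render_trace(cfg, rng=21)
        got = compute_fret(correct_leakage(leaky, 0.10)).efficiency
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)

    def test_same_seed_bit_identical_different_seed_not(self):
        cfg = SimConfig(n_frames=300)
        a, _ = render_trace(cfg, rng=9)
        b, _ = render_trace(cfg, rng=9)
        c, _ = render_trace(cfg, rng=10)
        assert np.array_equal(a.donor, b.donor)
        assert np.array_equal(a.acceptor, b.acceptor)
        assert not np.array_equal(a.acceptor, c.acceptor)

    def test_invalid_frames_rejected(self):
        with pytest.raises(ValueError):
            render_trace(SimConfig(n_frames=0), rng=0)

    def test_dynamic_fraction_within_binomial_ci(self):
        cfg = SimConfig(p_dynamic=0.49, n_frames=50)
        children = np.random.SeedSequence(99).spawn(600)
        flags = [
            render_trace(cfg, rng=np.random.default_rng(c))[1].dynamic
            for c in children
        ]
        p_hat = np.mean(flags)
        se = np.sqrt(0.49 * 0.51 / len(flags))
        assert abs(p_hat - 0.49) < 3 * se


class TestDatasets:
    def test_render_cycles_has_exact_event_count(self):
        cfg = SimConfig()
        trace, truth = render_cycles(cfg, 7, rng=2)
        assert len(truth.intervals) == 7
        assert truth.intervals[0].start > 0
        assert truth.intervals[-1].end < len(trace) * cfg.frame_time

    def test_intervals_ordered_nonoverlapping(self):
        cfg = SimConfig()
        _, truth = render_cycles(cfg, 20, rng=3)
        ivs = truth.intervals
        assert all(iv.end > iv.start for iv in ivs)
        assert all(b.start >= a.end for a, b in zip(ivs[:-1], ivs[1:]))

    def test_dataset_partitions_events_across_traces(self):
        cfg = SimConfig()
        traces, truths = simulate_dataset(cfg, 23, events_per_trace=10, seed=4)
        assert len(traces) == 3
        assert sum(len(t.intervals) for t in truths) == 23

    def test_trace_io_roundtrip(self, tmp_path):
        from fretkin.simulate import write_trace
        from fretkin.traces import read_trace

        cfg = SimConfig(n_frames=50)
        trace, _ = render_trace(cfg, rng=1, trace_id="abc")
        p = tmp_path / "abc.tsv"
        write_trace(trace, p)
        back = read_trace(p)
        assert back.trace_id == "abc"
        assert back.frame_time == pytest.approx(0.08)
        np.testing.assert_allclose(back.donor, trace.donor, atol=1e-4)
        np.testing.assert_allclose(back.acceptor, trace.acceptor, atol=1e-4)
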