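"""HMM fitting and Viterbi decoding, checked against closed forms and
exhaustive path enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretkin.hmm import HmmModel, fit_hmm, select_segments, viterbi
from fretkin.kinetics import BindingEvent
from tests.conftest import make_fret


def two_state_segments(rng, n_segments=6, length=1000, means=(0.3, 0.7), sd=0.05,
                       stay=0.95):
    """Markov-generated test segments with known parameters."""
    segs, paths = [], []
    for _ in range(n_segments):
        states = np.empty(length, dtype=int)
        states[0] = rng.integers(2)
        for i in range(1, length):
            states[i] = states[i - 1] if rng.random() < stay else 1 - states[i - 1]
        obs = np.array(means)[states] + rng.normal(0, sd, length)
        segs.append(np.clip(obs, 0.05, 1.0))
        paths.append(states)
    return segs, paths


def brute_force_viterbi(model: HmmModel, obs: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive argmax over all K^n state paths (oracle for short segments)."""
    from scipy.stats import norm

    n, k = obs.size, model.n_states
    paths = np.array(list(itertools.product(range(k), repeat=n)))  # (k^n, n)
    emis = norm.logpdf(obs[None, :], model.means[:, None], model.sds[:, None])  # (k, n)
    lp = np.log(model.initial)[paths[:, 0]] + emis[paths[:, 0], 0]
    for i in range(1, n):
        lp += np.log(model.trans)[paths[:, i - 1], paths[:, i]] + emis[paths[:, i], i]
    best = int(np.argmax(lp))
    return float(lp[best]), paths[best]


def random_model(rng, n_states):
    means = np.sort(rng.uniform(0.1, 0.9, n_states))
    means += np.arange(n_states) * 1e-3  # ensure strictly ascending
    trans = rng.uniform(0.05, 1.0, (n_states, n_states))
    trans /= trans.sum(axis=1, keepdims=True)
    initial = rng.uniform(0.05, 1.0, n_states)
    initial /= initial.sum()
    return HmmModel(
        n_states=n_states,
        means=means,
        sds=rng.uniform(0.02, 0.2, n_states),
        trans=trans,
        initial=initial,
        log_likelihood=0.0,
        n_iter=0,
    )


class TestSelectSegments:
    def _make(self, durations, dt=0.08):
        events, fts = [], []
        for d in durations:
            n = int(round(d / dt))
            fts.append(make_fret(np.full(n, 0.5), frame_time=dt))
            events.append([BindingEvent(0.0, n * dt, 0.5, False, "t", 0, n)])
        return fts, events

    def test_sixty_second_boundary_is_strict(self):
        fts, events = self._make([59.0, 60.0, 61.0])
        segs = select_segments(fts, events, min_duration=60.0)
        assert len(segs) == 1
        assert segs[0]["fret"].size == int(round(61.0 / 0.08))

    def test_out_of_range_frames_dropped(self):
        ft = make_fret([0.5] * 500 + [0.01] * 10 + [0.5] * 500)
        ev = [BindingEvent(0.0, 1010 * 0.08, 0.5, False, "t", 0, 1010)]
        segs = select_segments([ft], [ev], min_duration=60.0)
        assert segs[0]["fret"].size == 1000
        assert np.all(segs[0]["fret"] >= 0.05)

    def test_no_qualifying_segments_is_empty(self):
        fts, events = self._make([10.0, 20.0])
        assert select_segments(fts, events, min_duration=60.0) == []


class TestFitHmm:
    def test_two_state_recovery(self, rng):
        segs, _ = two_state_segments(rng)
        model = fit_hmm(segs, n_states=2, seed=0, n_restarts=3)
        assert model.means[0] == pytest.approx(0.3, abs=0.02)
        assert model.means[1] == pytest.approx(0.7, abs=0.02)
        assert np.all(model.sds < 0.1)

    def test_single_state_closed_form(self, rng):
        x = 0.45 + rng.normal(0, 0.04, 3000)
        model = fit_hmm([x], n_states=1, seed=0, n_restarts=1)
        assert model.means[0] == pytest.approx(np.mean(x), abs=1e-6)
        assert model.sds[0] == pytest.approx(np.std(x), rel=1e-3)

    def test_em_loglik_monotone(self, rng):
        segs, _ = two_state_segments(rng, n_segments=3, length=500)
        model = fit_hmm(segs, n_states=2, seed=1, n_restarts=1)
        hist = model.loglik_history
        assert hist.size >= 2
        assert np.all(np.diff(hist) >= -1e-6)

    def test_relabeling_invariance_across_restarts(self, rng):
        segs, _ = two_state_segments(rng)
        m1 = fit_hmm(segs, n_states=2, seed=3, n_restarts=2)
        m2 = fit_hmm(segs, n_states=2, seed=17, n_restarts=2)
        np.testing.assert_allclose(m1.means, m2.means, atol=0.01)
        assert np.all(np.diff(m1.means) > 0)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="free"):
            fit_hmm([rng.uniform(0.1, 0.9, 50)], n_states=5, seed=0)

    def test_transition_rows_stochastic(self, rng):
        segs, _ = two_state_segments(rng, n_segments=2, length=800)
        model = fit_hmm(segs, n_states=2, seed=0, n_restarts=2)
        np.testing.assert_allclose(model.trans.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.initial.sum(), 1.0, atol=1e-9)


class TestViterbi:
    def test_well_separated_states_decoded_exactly(self, rng):
        segs, paths = two_state_segments(rng, n_segments=1, length=400, sd=0.01)
        model = fit_hmm(segs, n_states=2, seed=0, n_restarts=2)
        out = viterbi(model, segs[0])
        np.testing.assert_array_equal(out.state_index, paths[0])
        assert np.allclose(out.state_fret, model.means[paths[0]])

    def test_matches_exhaustive_enumeration_small(self, rng):
        model = random_model(rng, 2)
        obs = rng.uniform(0.1, 0.9, 3)
        out = viterbi(model, obs)
        lp, path = brute_force_viterbi(model, obs)
        np.testing.assert_array_equal(out.state_index, path)
        assert out.log_probability == pytest.approx(lp, abs=1e-8)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_states=st.integers(2, 3),
        n_frames=st.integers(2, 10),
    )
    def test_matches_exhaustive_enumeration_property(self, seed, n_states, n_frames):
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_states)
        obs = rng.uniform(0.06, 0.99, n_frames)
        out = viterbi(model, obs)
        lp, path = brute_force_viterbi(model, obs)
        assert out.log_probability == pytest.approx(lp, abs=1e-8)
        np.testing.assert_array_equal(out.state_index, path)

    def test_path_logprob_bounded_by_total(self, rng):
        segs, _ = two_state_segments(rng, n_segments=1, length=200)
        model = fit_hmm(segs, n_states=2, seed=0, n_restarts=1)
        out = viterbi(model, segs[0])
        total = model.to_hmmlearn().score(np.asarray(segs[0]).reshape(-1, 1))
        assert out.log_probability <= total + 1e-8

    def test_all_out_of_range_segment_rejected(self, rng):
        model = random_model(rng, 2)
        with pytest.raises(ValueError, match="range"):
            viterbi(model, np.full(10, 0.01))
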