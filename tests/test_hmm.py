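"""Chromatin-state HMM: binarization, Baum-Welch, decoding, labels,
transition accounting."""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from epihet.hmm import (
    BinaryTrackSet,
    HMMModel,
    Segmentation,
    binarize_tracks,
    fit_hmm,
    forward_backward,
    label_states,
    posterior_decode,
    state_transition_table,
)
from epihet.intervals import make_genome_bins


def track_set(obs, marks=("m1",)):
    obs = np.atleast_2d(np.asarray(obs, dtype=np.int8))
    if obs.shape[1] != len(marks):
        obs = obs.T
    bins = make_genome_bins({"chr1": 200 * len(obs)}, 200)
    return BinaryTrackSet(bins, tuple(marks), obs)


def enumerate_posteriors(pi, A, B, obs):
    """Exhaustive-path posterior oracle for tiny sequences."""
    T, M = obs.shape
    K = len(pi)
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]]
        for t in range(T):
            for m in range(M):
                p *= B[path[t], m] if obs[t, m] == 1 else 1 - B[path[t], m]
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total, np.log(total)


class TestBinarize:
    def test_uniform_track_all_zero(self):
        bins = make_genome_bins({"chr1": 200 * 100}, 200)
        counts = np.full((100, 1), 5)
        ts = binarize_tracks(bins, counts, marks=("m",))
        assert ts.tracks.sum() == 0

    def test_single_hot_bin(self):
        bins = make_genome_bins({"chr1": 200 * 100}, 200)
        counts = np.zeros((100, 1), dtype=int)
        counts[42] = 500
        ts = binarize_tracks(bins, counts, marks=("m",))
        assert ts.tracks[:, 0].sum() == 1 and ts.tracks[42, 0] == 1

    def test_zero_signal_warns(self):
        bins = make_genome_bins({"chr1": 200 * 10}, 200)
        ts = binarize_tracks(bins, np.zeros((10, 1), dtype=int), marks=("m",))
        assert ts.tracks.sum() == 0 and np.isinf(ts.thresholds["m"])

    def test_recovers_planted_mark_presence(self, small_truth):
        from epihet.simulate import simulate_mark_counts

        cfg = small_truth.config
        counts = simulate_mark_counts(small_truth.mark_tracks["PRI"], seed=3,
                                      bg_rate=cfg.mark_bg_rate, signal_rate=cfg.mark_signal_rate)
        ts = binarize_tracks(small_truth.bins, counts, cfg.marks)
        acc = (ts.tracks == small_truth.mark_tracks["PRI"]).mean()
        assert acc >= 0.95


class TestFit:
    def test_single_state_closed_form(self):
        obs = np.array([[1], [1], [0], [1], [0], [0], [1], [1]])
        model = fit_hmm(track_set(obs), n_states=1)
        assert model.emissionprob[0, 0] == pytest.approx(obs.mean())
        assert model.transmat[0, 0] == 1.0

    def test_loglik_monotone(self):
        rng = np.random.default_rng(0)
        obs = (rng.random((400, 2)) < 0.3).astype(np.int8)
        model = fit_hmm(track_set(obs, marks=("a", "b")), n_states=2, seed=1, n_restarts=2)
        trace = np.asarray(model.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_degenerate_observations_warn(self):
        obs = np.ones((30, 1), dtype=np.int8)
        with pytest.warns(UserWarning, match="identical"):
            fit_hmm(track_set(obs), n_states=2, seed=0, n_restarts=1, max_iter=20)

    def test_fewer_bins_than_states(self):
        with pytest.raises(ValueError, match="fewer bins"):
            fit_hmm(track_set(np.array([[1], [0]])), n_states=5)

    def test_two_state_recovery(self):
        """Parameter recovery on a well-separated two-state chain."""
        from epihet.simulate import simulate_genome_states

        A = np.array([[0.95, 0.05], [0.10, 0.90]])
        B = np.array([[0.9, 0.1], [0.05, 0.85]])
        path, obs = simulate_genome_states(20_000, 2, A, B, seed=4)
        model = fit_hmm(track_set(obs, marks=("a", "b")), n_states=2, seed=5, n_restarts=4)
        # align states by emission similarity
        if np.abs(model.emissionprob[0] - B[0]).sum() > np.abs(model.emissionprob[1] - B[0]).sum():
            perm = [1, 0]
        else:
            perm = [0, 1]
        Bh = model.emissionprob[perm]
        Ah = model.transmat[perm][:, perm]
        assert np.abs(Bh - B).max() < 0.03
        assert np.abs(Ah - A).max() < 0.05


class TestPosterior:
    def test_single_state_posterior_is_one(self):
        obs = np.array([[1], [0], [1]])
        model = fit_hmm(track_set(obs), n_states=1)
        seg = posterior_decode(model, track_set(obs))
        np.testing.assert_allclose(seg.posterior, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("K,T,M", [(2, 3, 1), (2, 8, 2), (3, 12, 2)])
    def test_matches_exhaustive_enumeration(self, seed, K, T, M):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(K))
        A = rng.dirichlet(np.ones(K), size=K)
        B = rng.uniform(0.05, 0.95, size=(K, M))
        obs = (rng.random((T, M)) < 0.5).astype(float)
        model = HMMModel(pi, A, B, tuple(f"m{i}" for i in range(M)))
        gamma, _, ll = forward_backward(model, obs)
        expected, ll_exp = enumerate_posteriors(pi, A, B, obs)
        np.testing.assert_allclose(gamma, expected, atol=1e-10)
        assert ll == pytest.approx(ll_exp, abs=1e-10)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        obs = (rng.random((500, 2)) < 0.4).astype(np.int8)
        model = fit_hmm(track_set(obs, marks=("a", "b")), n_states=3, seed=0, n_restarts=2)
        seg = posterior_decode(model, track_set(obs, marks=("a", "b")))
        np.testing.assert_allclose(seg.posterior.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(seg.states, seg.posterior.argmax(axis=1))

    def test_deterministic_emissions_reproduce_observations(self):
        pi = np.array([0.5, 0.5])
        A = np.array([[0.5, 0.5], [0.5, 0.5]])
        B = np.array([[1.0], [0.0]])
        model = HMMModel(pi, A, B, ("m",))
        model.labels = {0: "on", 1: "off"}
        obs = np.array([[1], [0], [0], [1]], dtype=np.int8)
        seg = posterior_decode(model, track_set(obs))
        np.testing.assert_array_equal(seg.states, [0, 1, 1, 0])

    def test_agrees_with_hmmlearn(self):
        """Independent route: same posteriors as hmmlearn's categorical HMM
        on symbol-encoded observations."""
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(3)
        K, M, T = 3, 2, 300
        pi = rng.dirichlet(np.ones(K))
        A = rng.dirichlet(np.ones(K) * 5, size=K)
        B = rng.uniform(0.1, 0.9, size=(K, M))
        obs = (rng.random((T, M)) < 0.5).astype(np.int8)
        model = HMMModel(pi, A, B, ("a", "b"))
        gamma, _, ll = forward_backward(model, obs.astype(float))
        # encode the M binary marks as one categorical symbol
        symbols = obs[:, 0] * 2 + obs[:, 1]
        emis = np.zeros((K, 4))
        for s in range(4):
            bits = np.array([(s >> 1) & 1, s & 1])
            emis[:, s] = np.prod(B**bits * (1 - B) ** (1 - bits), axis=1)
        ref = CategoricalHMM(n_components=K)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = pi, A, emis
        post = ref.predict_proba(symbols.reshape(-1, 1))
        np.testing.assert_allclose(gamma, post, atol=1e-8)
        assert ll == pytest.approx(ref.score(symbols.reshape(-1, 1)), abs=1e-8)


class TestLabels:
    def test_canonical_patterns(self):
        B = np.array(
            [
                [0.9, 0.9, 0.05],   # E2
                [0.02, 0.03, 0.01], # E4
                [0.9, 0.1, 0.05],   # E1
                [0.05, 0.85, 0.02], # E3
                [0.02, 0.05, 0.95], # E5
            ]
        )
        model = HMMModel(np.full(5, 0.2), np.full((5, 5), 0.2), B, ("H3K4me3", "H3K27ac", "H3K27me3"))
        labels = label_states(model)
        assert [labels[i] for i in range(5)] == ["E2", "E4", "E1", "E3", "E5"]

    def test_duplicate_signature_disambiguated(self):
        B = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.02]])
        model = HMMModel(np.array([0.5, 0.5]), np.full((2, 2), 0.5), B, ("H3K4me3", "H3K27ac", "H3K27me3"))
        with pytest.warns(UserWarning, match="share emission signature"):
            labels = label_states(model)
        assert labels == {0: "E1", 1: "E1.2"}

    def test_noncanonical_signature_described(self):
        B = np.array([[0.9, 0.05, 0.9]])
        model = HMMModel(np.ones(1), np.ones((1, 1)), B, ("H3K4me3", "H3K27ac", "H3K27me3"))
        assert label_states(model)[0] == "H3K4me3+H3K27me3"


class TestTransitionTable:
    def seg_from_labels(self, labels):
        lut = {"E1": 0, "E2": 1, "E3": 2, "E4": 3, "E5": 4}
        states = np.array([lut[l] for l in labels])
        bins = make_genome_bins({"chr1": 200 * len(labels)}, 200)
        post = np.eye(5)[states]
        return Segmentation(bins, post, states, {v: k for k, v in lut.items()})

    def test_hand_enumerated_toy(self):
        a = self.seg_from_labels(["E1", "E2", "E4", "E4", "E3"])
        b = self.seg_from_labels(["E2", "E2", "E4", "E3", "E3"])
        res = state_transition_table(a, b)
        table = {(r["from"], r["to"]): r["n_bins"] for _, r in res["table"].iterrows()}
        assert table == {("E1", "E2"): 1, ("E2", "E2"): 1, ("E4", "E3"): 1, ("E3", "E3"): 1}
        assert res["n_excluded_stable_unmodified"] == 1

    def test_all_unmodified(self):
        a = self.seg_from_labels(["E4"] * 6)
        res = state_transition_table(a, a)
        assert len(res["table"]) == 0
        assert res["stable_unmodified_fraction"] == 1.0

    def test_conservation(self):
        rng = np.random.default_rng(2)
        la = rng.choice(["E1", "E2", "E3", "E4", "E5"], size=200)
        lb = rng.choice(["E1", "E2", "E3", "E4", "E5"], size=200)
        res = state_transition_table(self.seg_from_labels(la), self.seg_from_labels(lb))
        assert res["table"]["n_bins"].sum() + res["n_excluded_stable_unmodified"] == 200

    def test_mismatched_tilings_rejected(self):
        a = self.seg_from_labels(["E4"] * 5)
        b = self.seg_from_labels(["E4"] * 6)
        with pytest.raises(ValueError, match="tiling"):
            state_transition_table(a, b)
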