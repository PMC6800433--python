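"""Two-state ROH HMM: forward algorithm, Baum-Welch, decoding, tracts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rohkit.heterozygosity import HetWindowTrack
from rohkit.roh_hmm import (
    INBRED,
    OUTBRED,
    RohCallSet,
    RohHmmParams,
    decode,
    emission_loglik,
    extract_tracts,
    fit,
    forward_loglik,
    sample_track,
)
from rohkit.seqio import Interval


def make_track(k, n, scaffold="s1", w=100_000, missing_thresh=0.2):
    k = np.asarray(k)
    n = np.asarray(n)
    starts = np.arange(len(k)) * w
    df = pd.DataFrame(
        {"scaffold": scaffold, "start": starts, "end": starts + w, "het_count": k, "callable": n}
    )
    return HetWindowTrack(window_size=w, windows=df, min_callable_frac=missing_thresh, individual_id="t")


def enumerate_loglik(logB, params):
    """Brute-force sum over all state paths."""
    T = len(logB)
    lt = np.log(params.trans)
    li = np.log(params.init)
    total = -np.inf
    for path in itertools.product((0, 1), repeat=T):
        lp = li[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += lt[path[t - 1], path[t]] + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def enumerate_viterbi(logB, params):
    T = len(logB)
    lt = np.log(params.trans)
    li = np.log(params.init)
    best, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=T):
        lp = li[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += lt[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best:
            best, best_path = lp, path
    return best, np.array(best_path)


@pytest.fixture
def params():
    return RohHmmParams(
        lambda_in=5e-5,
        lambda_out=1e-3,
        trans=np.array([[0.95, 0.05], [0.02, 0.98]]),
        init=np.array([0.4, 0.6]),
    )


class TestForward:
    def test_single_window_closed_form(self):
        # pi=(1,0) puts all mass on the inbred state: log Poisson(2; 2)
        p = RohHmmParams(
            lambda_in=2e-5,
            lambda_out=1e-3,
            trans=np.array([[0.9, 0.1], [0.1, 0.9]]),
            init=np.array([1.0, 0.0]),
        )
        track = make_track([2], [100_000])
        mu = 2e-5 * 100_000
        expected = 2 * math.log(mu) - mu - math.log(2)
        assert forward_loglik(track, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("T", [2, 5, 12])
    def test_matches_path_enumeration(self, params, T):
        rng = np.random.default_rng(T)
        n = rng.integers(50_000, 100_000, size=T)
        k = rng.poisson(1e-3 * n)
        track = make_track(k, n)
        _, ktrack, ntrack, missing = next(track.per_scaffold())
        logB = emission_loglik(ktrack, ntrack, missing, params)
        assert forward_loglik(track, params) == pytest.approx(
            enumerate_loglik(logB, params), rel=1e-8
        )

    def test_invariant_to_state_relabeling(self, params):
        track = make_track([3, 0, 5], [100_000] * 3)
        swapped = RohHmmParams.__new__(RohHmmParams)
        # build the label-swapped model directly (bypass ordering check)
        swapped.lambda_in = params.lambda_out
        swapped.lambda_out = params.lambda_in
        swapped.trans = params.trans[::-1, ::-1].copy()
        swapped.init = params.init[::-1].copy()
        swapped.degenerate = True
        assert forward_loglik(track, params) == pytest.approx(
            forward_loglik(track, swapped), rel=1e-12
        )

    def test_missing_windows_contribute_likelihood_one(self, params):
        full = make_track([1, 7, 2], [100_000, 10_000, 100_000])
        # middle window is below the callable threshold -> missing
        assert full.missing.tolist() == [False, True, False]
        reduced = make_track([1, 0, 2], [100_000, 0, 100_000])
        assert forward_loglik(full, params) == pytest.approx(
            forward_loglik(reduced, params)
        )

    def test_nonpositive_rate_rejected(self, params):
        track = make_track([1], [100_000])
        bad = RohHmmParams(
            lambda_in=0.0, lambda_out=1e-3, trans=params.trans, init=params.init
        )
        with pytest.raises(ValueError, match="> 0"):
            forward_loglik(track, bad)


class TestDecode:
    def test_all_zero_counts_decode_inbred(self, params):
        track = make_track([0] * 50, [100_000] * 50)
        res = decode(track, params)
        assert (res.paths["s1"] == INBRED).all()

    def test_outbred_rate_counts_decode_outbred(self, params):
        track = make_track([100] * 50, [100_000] * 50)
        res = decode(track, params)
        assert (res.paths["s1"] == OUTBRED).all()

    def test_posteriors_sum_to_one(self, params):
        rng = np.random.default_rng(0)
        n = np.full(200, 100_000)
        k = rng.poisson(3e-4 * n)
        res = decode(make_track(k, n), params)
        assert np.allclose(res.posteriors["s1"].sum(axis=1), 1.0)

    @pytest.mark.parametrize("T", [3, 8, 12])
    def test_viterbi_matches_path_enumeration(self, params, T):
        rng = np.random.default_rng(100 + T)
        n = rng.integers(50_000, 100_000, size=T)
        k = rng.poisson(rng.choice([5e-5, 1e-3], size=T) * n)
        track = make_track(k, n)
        _, kk, nn, missing = next(track.per_scaffold())
        logB = emission_loglik(kk, nn, missing, params)
        res = decode(track, params)
        _, best = enumerate_viterbi(logB, params)
        assert (res.paths["s1"] == best).all()

    def test_viterbi_posterior_agreement_with_separated_states(self):
        p = RohHmmParams(
            lambda_in=1e-4,
            lambda_out=1e-3,
            trans=np.array([[0.99, 0.01], [0.01, 0.99]]),
            init=np.array([0.5, 0.5]),
        )
        track, _ = sample_track(p, 2000, 100_000, seed=8)
        res = decode(track, p)
        post_path = np.where(res.posteriors["sim"][:, INBRED] > 0.5, INBRED, OUTBRED)
        assert (res.paths["sim"] == post_path).mean() >= 0.95


class TestFit:
    def test_recovers_parameters_from_simulated_windows(self):
        true = RohHmmParams(
            lambda_in=5e-5,
            lambda_out=1e-3,
            trans=np.array([[0.99, 0.01], [0.005, 0.995]]),
            init=np.array([0.3, 0.7]),
        )
        track, _ = sample_track(true, 5000, 100_000, seed=42)
        fitted, history = fit(track, max_iter=100)
        assert abs(fitted.lambda_in - true.lambda_in) / true.lambda_in < 0.10
        assert abs(fitted.lambda_out - true.lambda_out) / true.lambda_out < 0.10
        diffs = np.diff(history)
        assert (diffs >= -1e-8 * np.abs(np.array(history[:-1]))).all()

    def test_infinite_tol_returns_init(self, params):
        track = make_track([1, 2, 0, 4], [100_000] * 4)
        fitted, history = fit(track, init=params, tol=float("inf"))
        assert fitted is params
        assert len(history) == 1

    def test_monotone_loglik_on_heterogeneous_input(self, params):
        rng = np.random.default_rng(9)
        n = rng.integers(20_000, 100_000, size=300)
        k = rng.poisson(rng.choice([5e-5, 1e-3], size=300) * n)
        _, history = fit(make_track(k, n), init=params, max_iter=30)
        diffs = np.diff(history)
        assert (diffs >= -1e-8 * np.abs(np.array(history[:-1]))).all()

    def test_degenerate_all_zero_input_flagged(self):
        track = make_track([0] * 100, [100_000] * 100)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fitted, _ = fit(track)
        assert fitted.degenerate
        assert fitted.lambda_in == fitted.lambda_out == 0.0

    def test_states_ordered_after_fit(self):
        true = RohHmmParams(
            lambda_in=1e-4,
            lambda_out=1e-3,
            trans=np.array([[0.98, 0.02], [0.02, 0.98]]),
            init=np.array([0.5, 0.5]),
        )
        track, _ = sample_track(true, 1000, 100_000, seed=3)
        # adversarial init with swapped magnitudes converges to ordered states
        init = RohHmmParams(
            lambda_in=9e-4,
            lambda_out=1.1e-3,
            trans=np.array([[0.9, 0.1], [0.1, 0.9]]),
            init=np.array([0.5, 0.5]),
        )
        fitted, _ = fit(track, init=init, max_iter=50)
        assert fitted.lambda_in < fitted.lambda_out


class TestExtractTracts:
    def test_inbred_block_becomes_tract(self, params):
        k = [100] * 10 + [0] * 30 + [100] * 10
        track = make_track(k, [100_000] * 50)
        res = decode(track, params)
        cs = extract_tracts(res, track, min_length=2_000_000)
        assert len(cs.tracts) == 1
        assert cs.tracts[0] == Interval("s1", 10 * 100_000, 40 * 100_000)
        assert cs.posteriors[0] > 0.99

    def test_short_block_dropped_at_threshold(self, params):
        k = [100] * 20 + [0] * 15 + [100] * 20
        track = make_track(k, [100_000] * 55)
        res = decode(track, params)
        cs = extract_tracts(res, track, min_length=2_000_000)
        assert cs.tracts == []

    def test_single_masked_window_does_not_split_tract(self, params):
        n = [100_000] * 50
        n[25] = 0  # masked desert inside the ROH
        k = [100] * 10 + [0] * 30 + [100] * 10
        k[25] = 0
        track = make_track(k, n)
        res = decode(track, params)
        cs = extract_tracts(res, track, min_length=2_000_000)
        assert len(cs.tracts) == 1
        assert cs.tracts[0].length == 3_000_000

    def test_callset_invariants_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            RohCallSet(
                individual_id="x",
                tracts=[Interval("s1", 0, 5_000_000), Interval("s1", 4_000_000, 9_000_000)],
                min_length=2_000_000,
            )
        with pytest.raises(ValueError, match="min_length"):
            RohCallSet(individual_id="x", tracts=[Interval("s1", 0, 10)], min_length=100)


class TestCallingQuality:
    def test_f1_against_truth_on_inbred_scenario(self, isolated_bundle):
        from conftest import bp_confusion
        from rohkit.heterozygosity import window_het

        b = isolated_bundle
        track = window_het(b.focal)
        fitted, _ = fit(track)
        cs = extract_tracts(decode(track, fitted), track)
        tp, fp, fn = bp_confusion(
            cs.tracts, b.truth.autozygous, b.pool.scaffold_lengths
        )
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.9
        assert recall >= 0.9
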