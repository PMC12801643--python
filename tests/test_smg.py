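"""Ultrasound decoders: corr2, the proportional signal, and both LDA
variants, checked against closed forms and brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonokin.pipeline import score_against_truth
from sonokin.smg import (
    DegenerateInputError,
    ReferenceFrames,
    build_reference_frames,
    corr2,
    decode_correlation,
    decode_lda_cv,
    decode_lda_endstate,
    proportional_samples,
)
from sonokin.streams import FrameStack

SMG_METHODS = ("smg_correlation", "smg_lda_endstate", "smg_lda_cv")


def _stack(frames, fps=5.0, roi=0):
    frames = np.asarray(frames)
    return FrameStack(frames=frames, times=np.arange(len(frames)) / fps,
                      pulse_roi_rows=roi)


def corr2_bruteforce(a, b):
    """Double-loop reference implementation of the 2-D correlation."""
    am, bm = a.mean(), b.mean()
    num = den_a = den_b = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            num += (a[i, j] - am) * (b[i, j] - bm)
            den_a += (a[i, j] - am) ** 2
            den_b += (b[i, j] - bm) ** 2
    return num / (np.sqrt(den_a) * np.sqrt(den_b))


class TestCorr2:
    def test_self_correlation_is_one(self, rng):
        a = rng.random((8, 8))
        assert corr2(a, a) == pytest.approx(1.0)

    def test_mirror_correlation_is_minus_one(self, rng):
        a = rng.random((8, 8))
        assert corr2(a, 2 * a.mean() - a) == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            a, b = rng.random((5, 5)), rng.random((5, 5))
            assert corr2(a, b) == pytest.approx(corr2_bruteforce(a, b),
                                                abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random((6, 4)), r.random((6, 4))
        assert corr2(a, b) == corr2(b, a)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            corr2(np.ones((4, 4)), np.arange(16.0).reshape(4, 4))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            corr2(rng.random((4, 4)), rng.random((5, 5)))


class TestReferenceFrames:
    def test_single_frame_stack_is_its_own_mean(self, rng):
        f = rng.random((1, 8, 8))
        refs = build_reference_frames(_stack(f), _stack(f + 0.1))
        assert np.array_equal(refs.mean_flexion_frame, f[0])

    def test_mean_matches_bruteforce_accumulation(self, rng):
        frames = rng.random((5, 6, 6))
        acc = np.zeros((6, 6))
        for f in frames:
            acc += f
        refs = build_reference_frames(_stack(frames), _stack(frames + 1.0))
        assert np.allclose(refs.mean_flexion_frame, acc / 5, atol=1e-12)

    def test_roi_rows_excluded(self, rng):
        frames = rng.random((3, 12, 8))
        refs = build_reference_frames(_stack(frames, roi=4),
                                      _stack(frames + 1.0, roi=4))
        assert refs.mean_flexion_frame.shape == (8, 8)

    def test_empty_stack_rejected(self, rng):
        empty = FrameStack(frames=np.empty((0, 4, 4)), times=np.empty(0))
        with pytest.raises(ValueError):
            build_reference_frames(empty, _stack(rng.random((2, 4, 4))))


class TestDecodeCorrelation:
    def test_proportional_ratio_definition(self, rng):
        """US = C_F/(C_F+C_E) holds on every valid frame; the prediction
        is its extension-oriented complement."""
        refs = ReferenceFrames(rng.random((8, 8)), rng.random((8, 8)))
        stack = _stack(rng.random((6, 8, 8)))
        samples = proportional_samples(stack, refs)
        pred = decode_correlation(stack, refs)
        for s, v in zip(samples, pred.values):
            assert s.us == pytest.approx(s.c_flexion / (s.c_flexion + s.c_extension))
            assert v == pytest.approx(1.0 - s.us)

    def test_brightness_invariance(self, rng):
        """US is invariant to global gain/offset of the current frame."""
        refs = ReferenceFrames(rng.random((8, 8)), rng.random((8, 8)))
        f = rng.random((1, 8, 8))
        base = decode_correlation(_stack(f), refs).values
        scaled = decode_correlation(_stack(3.0 * f + 0.7), refs).values
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_stateless_across_frames(self, rng):
        refs = ReferenceFrames(rng.random((8, 8)), rng.random((8, 8)))
        frames = rng.random((10, 8, 8))
        perm = rng.permutation(10)
        out = decode_correlation(_stack(frames), refs).values
        out_perm = decode_correlation(_stack(frames[perm]), refs).values
        assert np.allclose(out_perm, out[perm], atol=1e-15)

    def test_ill_conditioned_denominator_marked_invalid(self, rng):
        a = rng.random((8, 8))
        # C_F = +c, C_E = −c exactly: current frame correlates oppositely
        refs = ReferenceFrames(a, 2 * a.mean() - a)
        pred = decode_correlation(_stack(a[None]), refs)
        assert not pred.valid[0]
        assert np.isnan(pred.values[0])


class TestLdaEndstate:
    def test_training_anchors_map_to_zero_and_one(self, rng):
        flex = rng.random((1, 8, 8))
        ext = rng.random((1, 8, 8))
        stack = _stack(np.concatenate([flex, ext]))
        pred = decode_lda_endstate(stack, _stack(flex), _stack(ext))
        assert pred.values[0] == pytest.approx(0.0, abs=1e-9)
        assert pred.values[1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_projection(self, rng):
        flex = rng.random((3, 8, 8))
        ext = rng.random((3, 8, 8))
        frames = rng.random((5, 8, 8))
        pred = decode_lda_endstate(_stack(frames), _stack(flex), _stack(ext))
        mu_f, mu_e = flex.mean(0).ravel(), ext.mean(0).ravel()
        d = mu_e - mu_f
        expected = [(f.ravel() - mu_f) @ d / (d @ d) for f in frames]
        assert pred.values == pytest.approx(expected, abs=1e-12)

    def test_identical_training_frames_rejected(self, rng):
        f = rng.random((2, 8, 8))
        with pytest.raises(DegenerateInputError):
            decode_lda_endstate(_stack(f), _stack(f), _stack(f))


class TestLdaCv:
    def test_fold_sizes_and_single_prediction_per_frame(self, rng):
        frames = rng.random((450, 16, 16))
        labels = np.tile(np.linspace(0, 1, 45), 10)
        pred, fold = decode_lda_cv(_stack(frames), labels, k_folds=5)
        assert np.bincount(fold).tolist() == [90] * 5
        assert np.all(np.isfinite(pred.values))

    def test_outputs_are_convex_combinations_of_bin_centers(self, rng):
        frames = rng.random((100, 12, 12))
        labels = rng.random(100)
        pred, _ = decode_lda_cv(_stack(frames), labels, n_classes=10)
        assert np.all(pred.values >= 0.05 - 1e-9)
        assert np.all(pred.values <= 0.95 + 1e-9)

    def test_too_few_frames_rejected(self, rng):
        frames = rng.random((5, 8, 8))
        with pytest.raises(ValueError):
            decode_lda_cv(_stack(frames), np.linspace(0, 1, 5), n_classes=10)


class TestParameterRecovery:
    def test_noise_free_recovery_below_ten_percent(self, noise_free_trials):
        """All three decoders recover θ with normalized RMSE ≤ 0.10 on the
        noise-free fixed-seed suite."""
        for trial in noise_free_trials:
            scores = score_against_truth(trial, methods=SMG_METHODS)
            for method, s in scores.items():
                assert s["rmse"] <= 0.10, (trial.config.joint,
                                           trial.config.fes_condition, method)

    def test_default_trial_correlation_tracks_theta(self, default_trial):
        """Min-max-normalized proportional signal vs θ: Pearson r ≥ 0.95
        under the default study conditions."""
        s = score_against_truth(default_trial, methods=("smg_correlation",))
        assert s["smg_correlation"]["r"] >= 0.95

    def test_cv_lda_beats_endstate_lda(self, default_trial):
        """Training on the full movement sequence outperforms the two-frame
        end-state model on the same trial."""
        s = score_against_truth(
            default_trial, methods=("smg_lda_endstate", "smg_lda_cv"))
        assert s["smg_lda_cv"]["rmse"] <= s["smg_lda_endstate"]["rmse"]
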