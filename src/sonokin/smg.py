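"""Sonomyography decoders: correlation-based proportional signal and two
linear-discriminant variants.

All three estimate the motion-completion level of a joint from single
B-mode ultrasound frames, trained on 1-s end-state recordings (full flexion
and full extension) or, for the cross-validated variant, on the trial's own
frame sequence.  No temporal context is used: every output depends only on
the current frame.  The pulse-trace ROI rows are masked out of every
computation — they carry synchronization metadata, not anatomy.

Orientation convention: predictions increase toward full extension
(θ = 1 ≡ full extension), so the proportional decoder emits the
extension-completion ratio C_E/(C_F + C_E); the classical flexion-oriented
ratio C_F/(C_F + C_E) is retained on each :class:`ProportionalSample`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List

import warnings

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .streams import FrameStack, MethodPrediction

__all__ = [
    "ReferenceFrames",
    "ProportionalSample",
    "corr2",
    "build_reference_frames",
    "decode_correlation",
    "decode_lda_endstate",
    "decode_lda_cv",
]

#: frames whose correlation denominator |C_F + C_E| falls below this are
#: marked invalid (the ratio is ill-conditioned there)
DENOMINATOR_EPS = 1e-6


class DegenerateInputError(ValueError):
    """Raised for constant matrices or identical training classes."""


@dataclass
class ReferenceFrames:
    """Averaged end-state frames used to train the SMG decoders."""

    mean_flexion_frame: np.ndarray
    mean_extension_frame: np.ndarray

    def __post_init__(self):
        a, b = self.mean_flexion_frame, self.mean_extension_frame
        if a.shape != b.shape:
            raise ValueError("reference frames must share a shape")
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise DegenerateInputError("constant reference frame")


@dataclass(frozen=True)
class ProportionalSample:
    """Per-frame similarity measurements and the proportional signal."""

    c_flexion: float
    c_extension: float
    us: float          # C_F / (C_F + C_E), NaN when invalid
    valid: bool


def corr2(a: np.ndarray, b: np.ndarray) -> float:
    """2-D correlation coefficient between two equally shaped matrices.

    C = Σ(A−Ā)(B−B̄) / (√Σ(A−Ā)² · √Σ(B−B̄)²), in [−1, 1]; 1 is perfect
    positive correlation.  Raises :class:`DegenerateInputError` for a
    constant input (zero denominator).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum()) * np.sqrt((db * db).sum())
    if denom == 0:
        raise DegenerateInputError("corr2 undefined for a constant matrix")
    return float(np.clip((da * db).sum() / denom, -1.0, 1.0))


def _anatomy(stack: FrameStack) -> np.ndarray:
    return stack.anatomy().astype(float)


def build_reference_frames(
    flexion_stack: FrameStack, extension_stack: FrameStack
) -> ReferenceFrames:
    """Average each 1-s end-state stack into a single training frame.

    The pulse ROI is excluded before averaging.
    """
    for st in (flexion_stack, extension_stack):
        if len(st) == 0:
            raise ValueError("empty end-state stack")
    fa = _anatomy(flexion_stack)
    ea = _anatomy(extension_stack)
    if fa.shape[1:] != ea.shape[1:]:
        raise ValueError("end-state stacks have mismatched frame shapes")
    return ReferenceFrames(
        mean_flexion_frame=fa.mean(axis=0),
        mean_extension_frame=ea.mean(axis=0),
    )


def proportional_samples(
    stack: FrameStack, refs: ReferenceFrames
) -> List[ProportionalSample]:
    """Per-frame correlations to both references and the proportional ratio."""
    frames = _anatomy(stack)
    if frames.shape[1:] != refs.mean_flexion_frame.shape:
        raise ValueError("frame shape does not match references")
    out = []
    for f in frames:
        cf = corr2(f, refs.mean_flexion_frame)
        ce = corr2(f, refs.mean_extension_frame)
        denom = cf + ce
        if abs(denom) < DENOMINATOR_EPS:
            out.append(ProportionalSample(cf, ce, np.nan, False))
        else:
            out.append(ProportionalSample(cf, ce, cf / denom, True))
    return out


def decode_correlation(
    stack: FrameStack, refs: ReferenceFrames
) -> MethodPrediction:
    """Correlation-based proportional decoding of every frame.

    Output per frame is the extension-completion ratio C_E/(C_F + C_E)
    (one minus the flexion-oriented proportional signal), timestamped at
    the frame time; ill-conditioned frames carry NaN and are excluded from
    evaluation.  Deliberately not clamped to [0, 1]: per-trial min-max
    normalization happens at evaluation time.
    """
    samples = proportional_samples(stack, refs)
    values = np.array(
        [1.0 - s.us if s.valid else np.nan for s in samples], dtype=float
    )
    return MethodPrediction(times=stack.times.copy(), values=values,
                            method="smg_correlation")


def decode_lda_endstate(
    stack: FrameStack,
    flexion_stack: FrameStack,
    extension_stack: FrameStack,
) -> MethodPrediction:
    """LDA trained on the two averaged end-state frames only (Method 1).

    With one training sample per class the within-class scatter vanishes and
    the discriminant direction reduces to the class-mean difference
    d = μ_ext − μ_flex; the continuous output is the scalar projection
    ⟨f − μ_flex, d⟩ / ⟨d, d⟩, which maps the flexion anchor to 0 and the
    extension anchor to 1.  Not clamped.
    """
    refs = build_reference_frames(flexion_stack, extension_stack)
    mu_f = refs.mean_flexion_frame.ravel()
    mu_e = refs.mean_extension_frame.ravel()
    d = mu_e - mu_f
    dd = float(d @ d)
    if dd == 0:
        raise DegenerateInputError("identical end-state training frames")
    frames = _anatomy(stack).reshape(len(stack), -1)
    if frames.shape[1] != d.size:
        raise ValueError("frame shape does not match training frames")
    values = (frames - mu_f) @ d / dd
    return MethodPrediction(times=stack.times.copy(), values=values,
                            method="smg_lda_endstate")


def _pca_reduce(x_train, x_test, cap, variance_explained):
    """PCA via the n×n Gram matrix (n samples ≪ pixels), truncated to the
    fewest components explaining ``variance_explained`` of the variance and
    capped at ``cap``.  Returns (train scores, test scores, k)."""
    mean = x_train.mean(axis=0)
    xc = x_train - mean
    gram = xc @ xc.T
    evals, evecs = linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise DegenerateInputError("zero-variance training frames")
    k = int(np.searchsorted(np.cumsum(evals) / total, variance_explained) + 1)
    k = int(min(k, cap, np.count_nonzero(evals > 1e-10 * evals[0])))
    scale = np.sqrt(evals[:k])
    components = (xc.T @ evecs[:, :k]) / scale      # pixels × k, orthonormal
    z_train = evecs[:, :k] * scale
    z_test = (x_test - mean) @ components
    return z_train, z_test, k


def decode_lda_cv(
    stack: FrameStack,
    angle_labels: np.ndarray,
    k_folds: int = 5,
    n_classes: int = 10,
    variance_explained: float = 0.95,
    max_components: int = 40,
) -> tuple:
    """Cross-validated multiclass LDA over the trial's frame sequence
    (Method 2).

    Reference angles (one per frame, paired by nearest timestamp upstream)
    are quantized into ``n_classes`` equal-width bins over [0, 1].  Frames
    are PCA-reduced to the components explaining ``variance_explained`` of
    the variance, capped at n_train − n_classes and at ``max_components``
    (under speckle noise the raw variance criterion mostly counts isotropic
    noise directions, which dilute the discriminant); a
    shrinkage-regularized LDA is
    trained per fold on contiguous blocks covering (k−1)/k of the trial and
    predicts the held-out block, so each frame is predicted exactly once.
    The continuous output is the posterior-weighted mean of class-bin
    centers — a convex combination, hence bounded by the extreme bin
    centers.

    Returns ``(MethodPrediction, fold_assignment)``.
    """
    angle_labels = np.asarray(angle_labels, dtype=float)
    n = len(stack)
    if angle_labels.shape != (n,):
        raise ValueError("need one reference angle per frame")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if n < n_classes:
        raise ValueError("fewer frames than classes")

    edges = np.linspace(0.0, 1.0, n_classes + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    labels = np.clip(np.digitize(angle_labels, edges[1:-1]), 0, n_classes - 1)

    frames = _anatomy(stack).reshape(n, -1).astype(np.float32)
    fold = (np.arange(n) * k_folds) // n          # contiguous blocks
    values = np.full(n, np.nan)
    for f in range(k_folds):
        test = fold == f
        train = ~test
        x_train, y_train = frames[train], labels[train]
        n_train = int(train.sum())
        present = np.unique(y_train)
        cap = max(min(n_train - present.size, max_components), 1)

        z_train, z_test, _ = _pca_reduce(
            x_train, frames[test], cap, variance_explained
        )
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        with warnings.catch_warnings():
            # bins visited only once in a fold trigger a single-sample
            # covariance warning inside the shrinkage estimator; the pooled
            # within-class covariance is still well defined
            warnings.simplefilter("ignore", UserWarning)
            lda.fit(z_train, y_train)
            post = lda.predict_proba(z_test)
        values[test] = post @ centers[lda.classes_.astype(int)]

    pred = MethodPrediction(times=stack.times.copy(), values=values,
                            method="smg_lda_cv")
    return pred, fold
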