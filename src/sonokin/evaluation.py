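"""Decoder scoring and nonparametric statistical comparison.

Predictions and motion-capture references are min-max normalized per trial
(errors are then fractions of the range of motion) and compared by RMSE,
Pearson r and R².  Across trials, paired conditions (FES-ON vs FES-OFF) are
compared with the Wilcoxon signed-rank test and independent groups (EMG vs
SMG) with the Mann-Whitney U test, both at α = 0.01, with rank-biserial
correlation coefficients as effect sizes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalPair",
    "StatTestResult",
    "EvalReport",
    "rmse",
    "linear_fit",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "compile_report",
]

ALPHA = 0.01

#: switch to exact rank-test p-values at or below these sizes
WILCOXON_EXACT_MAX_N = 15
MANNWHITNEY_EXACT_MAX_PRODUCT = 400


class DegenerateSampleError(ValueError):
    pass


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi - lo <= 0:
        raise DegenerateSampleError("constant series cannot be normalized")
    return (v - lo) / (hi - lo)


@dataclass
class EvalPair:
    """Paired measured/predicted series, normalized to [0, 1].

    ``measured`` holds motion-capture motion-completion values M_1..M_N and
    ``predicted`` the decoder outputs P_1..P_N after timestamp pairing.
    Both series are min-max normalized at construction unless already so.
    """

    measured: np.ndarray
    predicted: np.ndarray
    pairing_mode: str = "nearest"
    normalize: bool = True

    def __post_init__(self):
        m = np.asarray(self.measured, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if m.shape != p.shape:
            raise ValueError("measured and predicted must have equal length")
        keep = np.isfinite(m) & np.isfinite(p)
        m, p = m[keep], p[keep]
        if m.size < 2:
            raise ValueError("need at least 2 finite pairs")
        if self.normalize:
            m = minmax_normalize(m)
            p = minmax_normalize(p)
        self.measured, self.predicted = m, p

    @property
    def n(self) -> int:
        return self.measured.size


@dataclass
class StatTestResult:
    test: str
    statistic: float
    p_value: float
    effect_size_r: float
    alpha: float = ALPHA
    n: Optional[int] = None
    exact: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect_size_r": self.effect_size_r,
            "alpha": self.alpha,
            "significant": self.significant,
            "n": self.n,
            "exact": self.exact,
        }


def rmse(pair: EvalPair) -> float:
    """Root mean squared error √(1/N Σ (M_i − P_i)²)."""
    d = pair.measured - pair.predicted
    return float(np.sqrt(np.mean(d * d)))


def linear_fit(pair: EvalPair) -> dict:
    """Ordinary least squares of predicted on measured.

    Returns Pearson r, R² (= r² for simple regression), slope, intercept
    and the two-sided p-value for r.
    """
    if pair.n < 3:
        raise ValueError("need at least 3 pairs for a linear fit")
    if np.ptp(pair.measured) == 0 or np.ptp(pair.predicted) == 0:
        raise DegenerateSampleError("zero variance in a series")
    res = stats.linregress(pair.measured, pair.predicted)
    return {
        "r": float(res.rvalue),
        "R2": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p_value": float(res.pvalue),
    }


def wilcoxon_signed_rank(x, y, alpha: float = ALPHA) -> StatTestResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied |differences| are mid-ranked.  The
    statistic is min(W+, W−); the matched-pairs rank-biserial effect size is
    (W+ − W−)/(W+ + W−), negative when x tends below y.  Exact p-values are
    used for n ≤ 15 untied differences, the normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatTestResult("wilcoxon_signed_rank", 0.0, 1.0, 0.0,
                              alpha=alpha, n=0, exact=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    effect = (w_plus - w_minus) / (w_plus + w_minus)

    has_ties = np.unique(np.abs(d)).size < n
    use_exact = n <= WILCOXON_EXACT_MAX_N and not has_ties
    method = "exact" if use_exact else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    return StatTestResult(
        "wilcoxon_signed_rank", statistic=min(w_plus, w_minus),
        p_value=float(res.pvalue), effect_size_r=float(effect),
        alpha=alpha, n=n, exact=use_exact,
    )


def mann_whitney_u(a, b, alpha: float = ALPHA) -> StatTestResult:
    """Mann-Whitney U test for independent groups.

    U is computed with tie correction; the rank-biserial effect size is
    2·U_a/(n_a·n_b) − 1 = (#{a>b} − #{a<b})/(n_a·n_b), oriented so negative
    values mean group ``a`` tends below group ``b``.  Exact p-values are
    used when n_a·n_b ≤ 400 and there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    use_exact = a.size * b.size <= MANNWHITNEY_EXACT_MAX_PRODUCT and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    effect = 2.0 * u_a / (a.size * b.size) - 1.0
    return StatTestResult(
        "mann_whitney_u", statistic=u_a, p_value=float(res.pvalue),
        effect_size_r=float(effect), alpha=alpha,
        n=int(a.size + b.size), exact=use_exact,
    )


SMG_METHODS = ("smg_correlation", "smg_lda_endstate", "smg_lda_cv")
EMG_METHODS = ("emg_tkeo", "emg_hilbert", "emg_rms")


@dataclass
class TrialScore:
    """Scores of one decoder on one trial."""

    joint: str
    condition: str              # FES "ON" / "OFF"
    method: str
    trial_index: int
    rmse: float
    r: float
    R2: float
    n_pairs: int

    @property
    def modality(self) -> str:
        return "SMG" if self.method in SMG_METHODS else "EMG"


@dataclass
class EvalReport:
    """Mean ± SD RMSE per joint × condition × method plus pooled tests."""

    scores: pd.DataFrame                      # one row per TrialScore
    rmse_table: pd.DataFrame                  # mean/sd/n grid
    tests: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    alpha: float = ALPHA

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "rmse_table": self.rmse_table.reset_index().to_dict("records"),
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
            "fits": self.fits,
        }


def compile_report(scores, alpha: float = ALPHA) -> EvalReport:
    """Aggregate per-trial decoder scores into the study-style report.

    Builds the mean ± SD RMSE grid (joint × FES condition × method), the
    pooled Mann-Whitney EMG-vs-SMG comparison (SMG as group a, so a
    negative effect size means SMG errors are lower), paired Wilcoxon
    FES-ON-vs-OFF comparisons within each modality, and per-cell linear
    fits are left to the caller (they require the raw pairs).  Cells with a
    single trial carry an undefined (NaN) SD.
    """
    rows = [s.__dict__ | {"modality": s.modality} for s in scores]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no scores to compile")

    table = (
        df.groupby(["joint", "condition", "method"])["rmse"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
             n="count")
    )

    tests = {}
    smg = df[df.modality == "SMG"]["rmse"].to_numpy()
    emg = df[df.modality == "EMG"]["rmse"].to_numpy()
    if smg.size and emg.size:
        tests["smg_vs_emg"] = mann_whitney_u(smg, emg, alpha=alpha)

    for modality in ("SMG", "EMG"):
        sub = df[df.modality == modality]
        on = sub[sub.condition == "ON"].set_index(
            ["joint", "method", "trial_index"])["rmse"]
        off = sub[sub.condition == "OFF"].set_index(
            ["joint", "method", "trial_index"])["rmse"]
        common = on.index.intersection(off.index)
        if len(common) >= 5:
            tests[f"fes_on_vs_off_{modality.lower()}"] = wilcoxon_signed_rank(
                on.loc[common].to_numpy(), off.loc[common].to_numpy(),
                alpha=alpha,
            )

    fits = {}
    for (joint, cond, method), grp in df[df.modality == "SMG"].groupby(
        ["joint", "condition", "method"]
    ):
        fits[f"{joint}/{cond}/{method}"] = {
            "r_mean": float(grp["r"].mean()),
            "R2_mean": float(grp["R2"].mean()),
            "n": int(len(grp)),
        }

    return EvalReport(scores=df, rmse_table=table, tests=tests, fits=fits,
                      alpha=alpha)
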