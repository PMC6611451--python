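"""Agreement and reliability statistics for repeated fascicle measurements.

Implements the battery used to validate automatic tracking against
manual digitisation:

* ICC(A,1) — single-measure, absolute-agreement intraclass correlation
  from the two-way ANOVA decomposition (targets x raters);
* CMC — the coefficient of multiple correlation, a waveform-level
  similarity statistic comparing frame-wise between-waveform variance to
  total variance;
* RMSE — root-mean-square error between paired series;
* Bland-Altman — bias, 95% limits of agreement, and a within-subject
  coefficient of variation, judged against an a-priori 10% threshold;
* a correlation-strength classification (poor / moderate / strong /
  very strong at 0.36 / 0.67 / 0.90).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "AgreementClass",
    "UndefinedStatisticError",
    "icc_a1",
    "cmc",
    "rmse",
    "bland_altman",
    "classify_r",
    "rmse_by_position",
    "CV_THRESHOLD_PERCENT",
]

#: a-priori acceptability threshold on the coefficient of variation
CV_THRESHOLD_PERCENT = 10.0


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given data
    (e.g. zero total variance)."""


class AgreementClass(enum.IntEnum):
    """Correlation-strength classes; ordered so comparisons follow strength."""

    POOR = 0  # [0, 0.36)
    MODERATE = 1  # [0.36, 0.67)
    STRONG = 2  # [0.67, 0.90)
    VERY_STRONG = 3  # [0.90, 1.0]


#: left-closed class boundaries
CLASS_BOUNDARIES = (0.36, 0.67, 0.90)


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,1) with the ANOVA mean squares it was computed from."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, 95% limits of agreement, and coefficient of variation (%)."""

    bias: float
    loa_low: float
    loa_high: float
    cv_percent: float
    n: int

    def within_cv_threshold(self, threshold: float = CV_THRESHOLD_PERCENT) -> bool:
        return self.cv_percent <= threshold


def icc_a1(matrix: np.ndarray) -> ICCResult:
    """Single-measure absolute-agreement intraclass correlation, ICC(A,1).

    Rows are measurement targets, columns raters (examiner-day sessions).
    The two-way ANOVA decomposition gives mean squares for rows (MS_R),
    columns (MS_C) and error (MS_E), and

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Absolute agreement: a constant bias in one rater's column lowers the
    coefficient, unlike consistency-type ICCs.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix contains missing/non-finite cells")

    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    )
    return ICCResult(icc=float(icc), ms_rows=ms_rows, ms_cols=ms_cols,
                     ms_error=ms_err, n=n, k=k)


def cmc(waves: np.ndarray) -> float:
    """Coefficient of multiple correlation of a set of waveforms.

    ``waves`` is a G x F matrix: G repeated waveforms sampled on a common
    grid of F frames.

        CMC = sqrt(1 - [sum_fg (Y_gf - Ybar_f)^2 / (F (G-1))]
                      / [sum_fg (Y_gf - Ybar)^2 / (G F - 1)])

    with Ybar_f the frame-wise mean and Ybar the grand mean.  When the
    waveforms differ more between repetitions than the waveform varies
    over time, the radicand is negative and NaN is returned (undefined;
    never silently clamped).
    """
    y = np.asarray(waves, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a G x F matrix with G >= 2, F >= 2")
    g, f = y.shape
    grand = y.mean()
    total = float(((y - grand) ** 2).sum())
    if total == 0:
        raise UndefinedStatisticError("zero total variance; CMC undefined")
    frame_means = y.mean(axis=0)
    within = float(((y - frame_means) ** 2).sum())
    radicand = 1.0 - (within / (f * (g - 1))) / (total / (g * f - 1))
    if radicand < 0:
        return float("nan")
    return float(np.sqrt(radicand))


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error between two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.size == 0:
        raise ValueError("series are empty")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def bland_altman(method1: np.ndarray, method2: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman method of differences for two measurement methods.

    bias = mean(d), limits of agreement = bias +/- 1.96 sd(d) (sample sd),
    with d = method1 - method2.  The coefficient of variation is the
    within-subject CV for paired methods, 100 (sd(d)/sqrt(2)) / grand mean
    of all paired values.
    """
    m1 = np.asarray(method1, dtype=float)
    m2 = np.asarray(method2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("paired series lengths differ")
    n = m1.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = m1 - m2
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    grand = float(np.concatenate([m1, m2]).mean())
    if grand == 0:
        raise UndefinedStatisticError("grand mean is zero; CV undefined")
    cv = 100.0 * (sd / np.sqrt(2.0)) / abs(grand)
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        cv_percent=cv, n=n,
    )


def classify_r(r: float) -> AgreementClass:
    """Correlation-strength class for r in [0, 1] (left-closed intervals)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    lo, mid, hi = CLASS_BOUNDARIES
    if r < lo:
        return AgreementClass.POOR
    if r < mid:
        return AgreementClass.MODERATE
    if r < hi:
        return AgreementClass.STRONG
    return AgreementClass.VERY_STRONG


def rmse_by_position(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]]
) -> dict[str, float]:
    """RMSE within each position label (e.g. the six ankle angles),
    preserving the given label order."""
    out: dict[str, float] = {}
    for label, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        if a.size == 0:
            raise ValueError(f"empty group for label {label!r}")
        out[label] = rmse(a, b)
    return out
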