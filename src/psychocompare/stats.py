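"""Comparison analytics for procedure agreement and learning.

Implements the statistical toolkit used to compare threshold (PSE) and
sensitivity (JND) estimates across procedures: the robust Sn scale
estimator with a criterion-of-3 outlier screen, normality-gated
Pearson/Spearman correlations, Bland-Altman agreement with t-based 95%
confidence intervals, a log transform for right-skewed JND distributions,
one-sample bias tests against the reference stimulus, and a one-way
repeated-measures ANOVA for block-wise (learning) effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "sn_scale",
    "screen_outliers",
    "OutlierScreen",
    "bland_altman",
    "AgreementReport",
    "correlation",
    "CorrelationResult",
    "transform_jnd",
    "block_analysis",
    "BlockAnalysis",
    "one_sample_bias",
]

# Rousseeuw & Croux finite-sample correction factors for Sn, n = 2..9;
# for n >= 10: n/(n - 0.9) when n is odd, 1 when even.
_SN_SMALL_N = {2: 0.743, 3: 1.851, 4: 0.954, 5: 1.351, 6: 0.993, 7: 1.198, 8: 1.005, 9: 1.131}


def _sn_correction(n: int) -> float:
    if n in _SN_SMALL_N:
        return _SN_SMALL_N[n]
    return n / (n - 0.9) if n % 2 == 1 else 1.0


def sn_scale(values: Sequence[float]) -> float:
    """Rousseeuw-Croux Sn robust scale estimate.

    Sn = c_n * 1.1926 * lomed_i { himed_j |x_i - x_j| }, with the high
    median the (floor(n/2)+1)-th order statistic over all j (including the
    zero at j = i), the low median the floor((n+1)/2)-th order statistic,
    the consistency constant 1.1926 (Gaussian), and the finite-sample
    factor c_n. Breakdown point ~50%; unlike the MAD it needs no symmetry.
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 2:
        raise ValueError("Sn needs at least 2 values")
    diffs = np.abs(x[:, None] - x[None, :])  # (n, n), zero diagonal
    h = n // 2 + 1  # high median rank, 1-based
    himeds = np.partition(diffs, h - 1, axis=1)[:, h - 1]
    k = (n + 1) // 2  # low median rank, 1-based
    lomed = np.partition(himeds, k - 1)[k - 1]
    return float(_sn_correction(n) * 1.1926 * lomed)


@dataclass
class OutlierScreen:
    values: np.ndarray
    sn: float
    criterion: float
    flags: np.ndarray
    degenerate_scale: bool = False


def screen_outliers(values: Sequence[float], criterion: float = 3.0) -> OutlierScreen:
    """Flag values whose distance from the median exceeds criterion x Sn.

    Single-pass screen (no iterative re-screening). A degenerate sample
    with Sn = 0 (massive ties) flags nothing and sets a warning flag.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("outlier screen needs at least 3 values")
    sn = sn_scale(x)
    if sn == 0:
        return OutlierScreen(x, sn, criterion, np.zeros(x.size, bool), degenerate_scale=True)
    flags = np.abs(x - np.median(x)) > criterion * sn
    return OutlierScreen(x, sn, criterion, flags)


@dataclass
class AgreementReport:
    """Bland-Altman agreement between two paired measurement procedures."""

    pair: tuple[str, str]
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    slope: float  # regression of differences on pair means
    slope_p: float

    @property
    def agreement_span(self) -> float:
        return self.loa_high - self.loa_low

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "n": self.n,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "ci_bias": list(self.ci_bias),
            "ci_loa_low": list(self.ci_loa_low),
            "ci_loa_high": list(self.ci_loa_high),
            "agreement_span": self.agreement_span,
            "slope": self.slope,
            "slope_p": self.slope_p,
        }


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    pair: tuple[str, str] = ("A", "B"),
) -> AgreementReport:
    """Bias and 95% limits of agreement (+-1.96 SD of the differences).

    Confidence intervals use the classical large-sample t approximations:
    bias +- t_{n-1} * SD/sqrt(n); each limit +- t_{n-1} * SD * sqrt(3/n).
    Also reports the slope of the differences regressed on the pair means
    (a proportional-bias check).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired measures must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    means = 0.5 * (a + b)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    t = float(sps.t.ppf(0.975, n - 1))
    half_bias = t * sd / np.sqrt(n)
    half_loa = t * sd * np.sqrt(3.0 / n)
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    if np.ptp(means) > 0:
        reg = sps.linregress(means, d)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    else:
        slope, slope_p = 0.0, 1.0
    return AgreementReport(
        pair=tuple(pair),
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_low=(loa_low - half_loa, loa_low + half_loa),
        ci_loa_high=(loa_high - half_loa, loa_high + half_loa),
        slope=slope,
        slope_p=slope_p,
    )


class CorrelationResult(NamedTuple):
    r: float
    p: float
    method: str  # "pearson" | "spearman"


def correlation(a: Sequence[float], b: Sequence[float], method: str = "auto") -> CorrelationResult:
    """Pairwise correlation with a Shapiro-Wilk normality gate.

    ``method="auto"``: Pearson when both margins pass Shapiro-Wilk at
    alpha = .05, Spearman otherwise (two-sided p either way).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "auto":
        normal = sps.shapiro(a).pvalue > 0.05 and sps.shapiro(b).pvalue > 0.05
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        res = sps.pearsonr(a, b)
    elif method == "spearman":
        res = sps.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method: {method}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), method)


def transform_jnd(jnds: Sequence[float], eps_fraction: float = 0.05):
    """Natural-log transform of JNDs, shifted when non-positive values occur.

    JND distributions are typically right-skewed, and a Box-Cox profile on
    simulated JND samples supports lambda ~ 0 (log). Negative-slope fits
    can produce non-positive JNDs; those samples are shifted by
    |min| + eps_fraction * range before the log, and the shift is returned
    so it can be reported.

    Returns (transformed, shift, shifted_flag).
    """
    x = np.asarray(jnds, float)
    if np.all(x > 0):
        return np.log(x), 0.0, False
    eps = eps_fraction * (np.ptp(x) if np.ptp(x) > 0 else 1.0)
    shift = float(abs(x.min()) + eps)
    warnings.warn(
        f"non-positive JNDs present; applying log(jnd + {shift:.6g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return np.log(x + shift), shift, True


@dataclass
class BlockAnalysis:
    """One-way repeated-measures ANOVA over the three session blocks."""

    n_observers: int
    block_means: np.ndarray
    block_cis: np.ndarray  # (3, 2) t-based 95% intervals
    F: float
    df: tuple[int, int]
    p: float
    pairwise: dict  # (i, j) -> {"diff": mean_i - mean_j, "p": paired t p}
    dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "n_observers": self.n_observers,
            "block_means": self.block_means.tolist(),
            "block_cis": self.block_cis.tolist(),
            "F": self.F,
            "df": list(self.df),
            "p": self.p,
            "pairwise": {f"{i}-{j}": v for (i, j), v in self.pairwise.items()},
            "dropped": self.dropped,
        }


def block_analysis(values: np.ndarray) -> BlockAnalysis:
    """Within-subject block effect on an (n_observers, 3) estimates table.

    Classical partition: SS_total = SS_subjects + SS_blocks + SS_error,
    F = MS_blocks / MS_error with (k-1, (n-1)(k-1)) df. Rows containing
    NaN (incomplete observers) are dropped with a count. Pairwise block
    mean differences come with uncorrected paired-t p values.
    """
    x = np.asarray(values, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("expected an (n_observers, n_blocks) array")
    complete = ~np.isnan(x).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} observers with missing blocks", RuntimeWarning)
    x = x[complete]
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 complete observers")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subj = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_block = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_block
    df_block, df_err = k - 1, (n - 1) * (k - 1)
    ms_block = ss_block / df_block
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    F = ms_block / ms_err if ms_err > 0 else 0.0
    p = float(sps.f.sf(F, df_block, df_err)) if ms_err > 0 else 1.0
    t = float(sps.t.ppf(0.975, n - 1))
    sem = x.std(axis=0, ddof=1) / np.sqrt(n)
    cis = np.stack([x.mean(axis=0) - t * sem, x.mean(axis=0) + t * sem], axis=1)
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = x[:, i] - x[:, j]
            if np.ptp(diff) == 0:
                tp = 1.0 if np.allclose(diff, 0) else 0.0
            else:
                tp = float(sps.ttest_rel(x[:, i], x[:, j]).pvalue)
            pairwise[(i + 1, j + 1)] = {"diff": float(diff.mean()), "p": tp}
    return BlockAnalysis(
        n_observers=n,
        block_means=x.mean(axis=0),
        block_cis=cis,
        F=float(F),
        df=(df_block, df_err),
        p=p,
        pairwise=pairwise,
        dropped=dropped,
    )


def one_sample_bias(values: Sequence[float], reference: float) -> dict:
    """Classical one-sample t test of the estimates against the reference."""
    x = np.asarray(values, float)
    res = sps.ttest_1samp(x, reference)
    return {
        "mean": float(x.mean()),
        "reference": float(reference),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(x.size),
    }
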