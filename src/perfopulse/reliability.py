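"""Agreement and reliability statistics for paired test-retest measurements.

Implements the Bland-Altman toolkit used to report test-retest reliability
of perforating-artery outcomes (N_detected, V_mean, vPI):

* limits of agreement  LoA = mean difference +/- 1.96 * SD(differences);
* coefficient of repeatability  CoR = 1.96 * SD(differences), also as a
  percentage of the mean measured value;
* coefficient of variation  CV = CoR / 1.96 (relative form);
* two-way mixed/random intraclass correlation (absolute agreement or
  consistency, single measurement) from the ANOVA mean squares;
* paired Student t-test;
* Dice overlap of two ROI masks for inter-rater agreement;
* a two-group sample-size calculation (normal approximation, with an exact
  t-based alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "DiceResult",
    "bland_altman",
    "agreement_from_summary",
    "compare_scans",
    "dice",
    "icc",
    "paired_ttest",
    "cv_from_cor",
    "sample_size_two_group",
    "bland_altman_plot",
]

LOA_MULTIPLIER = 1.96  # 95% limits under normality


@dataclass
class AgreementReport:
    """Paired-scan agreement statistics (Bland-Altman plus reliability)."""

    n_pairs: int
    mean_measurement: float  # mean of the pairwise averages
    mean_difference: float
    sd_difference: float  # sample SD, n-1 denominator
    loa_low: float
    loa_high: float
    cor: float
    cor_pct: float  # CoR as % of mean_measurement (nan when the mean is 0)
    cv_pct: float  # CV = CoR/1.96, in percent
    icc: float = float("nan")
    icc_model: str = ""
    t_statistic: float = float("nan")
    p_value: float = float("nan")

    @property
    def cor_pct_display(self) -> float:
        """CoR% rounded to integer percent, as conventionally reported."""
        return float(round(self.cor_pct))


@dataclass
class DiceResult:
    """Overlap of two binary masks."""

    dice: float
    size_a: int
    size_b: int
    intersection: int


def _loa_fields(mean_d: float, sd_d: float, mean_meas: float, n: int) -> AgreementReport:
    cor = LOA_MULTIPLIER * sd_d
    if mean_meas != 0:
        cor_pct = 100.0 * cor / mean_meas
    else:
        cor_pct = float("nan")
    return AgreementReport(
        n_pairs=n,
        mean_measurement=mean_meas,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - cor,
        loa_high=mean_d + cor,
        cor=cor,
        cor_pct=cor_pct,
        cv_pct=cor_pct / LOA_MULTIPLIER if np.isfinite(cor_pct) else float("nan"),
    )


def bland_altman(x, y) -> AgreementReport:
    """Bland-Altman agreement of two paired measurement series.

    Differences are ``x - y``; ``mean_measurement`` is the mean of the
    pairwise averages ``(x + y)/2``.  Requires at least two complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two complete pairs")
    d = x - y
    return _loa_fields(float(d.mean()), float(d.std(ddof=1)), float(((x + y) / 2.0).mean()), n)


def agreement_from_summary(
    mean_difference: float, sd_difference: float, mean_measurement: float, n_pairs: int = 0
) -> AgreementReport:
    """Agreement statistics recomputed from published summary values.

    Useful for checking reported limits of agreement / CoR% against their
    printed mean difference, SD of differences and mean measurement.
    """
    return _loa_fields(float(mean_difference), float(sd_difference), float(mean_measurement), n_pairs)


def compare_scans(x, y, icc_model: str = "absolute") -> AgreementReport:
    """Full agreement report for two scans: Bland-Altman + ICC + paired t."""
    report = bland_altman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) >= 3:
        report.icc = icc(x, y, model=icc_model)
        report.icc_model = {
            "absolute": "two-way random, absolute agreement, single measurement (ICC(2,1))",
            "consistency": "two-way mixed, consistency, single measurement (ICC(3,1))",
        }[icc_model]
    report.t_statistic, report.p_value = paired_ttest(x, y)
    return report


def dice(mask_a, mask_b) -> DiceResult:
    """Dice coefficient ``2|A n B| / (|A| + |B|)`` of two binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int((a & b).sum())
    return DiceResult(dice=2.0 * inter / (na + nb), size_a=na, size_b=nb, intersection=inter)


def icc(x, y, model: str = "absolute") -> float:
    """Single-measurement intraclass correlation of two paired ratings.

    ``model='absolute'`` gives the two-way random-effects absolute-agreement
    form ICC(2,1), the standard test-retest choice (a systematic offset
    between scans lowers it); ``model='consistency'`` gives ICC(3,1), which
    ignores such offsets.  Computed from the two-way ANOVA mean squares
    (subjects x scans, k=2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D data with n >= 3")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    msr = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((rater_means - grand) ** 2).sum() / (k - 1)
    sst = ((data - grand) ** 2).sum()
    sse = sst - k * ((subj_means - grand) ** 2).sum() - n * ((rater_means - grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    if model == "absolute":
        return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if model == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError("model must be 'absolute' or 'consistency'")


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired Student t-test; returns (t, p).

    Degenerate cases: identical pairs give ``(0, 1)``; a nonzero mean
    difference with zero SD gives ``(+/-inf, 0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return math.copysign(float("inf"), d.mean()), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def cv_from_cor(cor_pct: float) -> float:
    """Coefficient of variation (%) implied by a CoR percentage: CoR/1.96."""
    if cor_pct < 0:
        raise ValueError("cor_pct must be >= 0")
    return cor_pct / LOA_MULTIPLIER


def sample_size_two_group(
    baseline_mean: float,
    sd: float,
    pct_increase: float,
    power: float = 0.8,
    alpha: float = 0.05,
    method: str = "normal",
) -> int:
    """Total subjects to detect a relative group difference, two-sided.

    The detectable difference is ``delta = baseline_mean * pct_increase``.
    ``method='normal'`` uses the classic normal-approximation formula
    ``n/group = ceil(2 * ((z_{1-a/2} + z_{power}) * sd / delta)^2)``;
    ``method='t'`` solves the exact two-sample t-test power equation
    (slightly larger n).  Returns the total over both equal-sized groups.
    """
    if min(baseline_mean, sd, pct_increase) <= 0:
        raise ValueError("baseline_mean, sd and pct_increase must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    delta = baseline_mean * pct_increase
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
        n_per = math.ceil(2.0 * (z * sd / delta) ** 2)
    elif method == "t":
        from statsmodels.stats.power import TTestIndPower

        n_per = math.ceil(
            TTestIndPower().solve_power(
                effect_size=delta / sd, power=power, alpha=alpha, ratio=1.0
            )
        )
    else:
        raise ValueError("method must be 'normal' or 't'")
    return 2 * n_per


def bland_altman_plot(x, y, path, title: str = "") -> None:
    """Save a Bland-Altman scatter (pair means vs differences) with LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18)
    ax.axhline(report.mean_difference, color="k", lw=2)
    for v in (report.loa_low, report.loa_high):
        ax.axhline(v, color="k", ls="--", lw=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
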