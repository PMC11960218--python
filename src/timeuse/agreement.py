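"""Single-behaviour agreement between self-reported and device-measured time.

Three complementary views, each treating one behaviour at a time:

* ICC(2,1) — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation (children are rows, the two methods are columns),
  with the McGraw–Wong 95% confidence interval and F test;
* Bland–Altman — mean difference (self − device) with 1.96·SD limits of
  agreement;
* MAPE — mean absolute percentage error, self-report as the forecast and the
  device as the actual value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accel import BEHAVIOURS

logger = logging.getLogger(__name__)


def icc_strength(icc: float) -> str:
    """Conventional interpretation bands for ICC point estimates."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f: float
    df1: float
    df2: float
    p: float
    label: str


@dataclass
class BlandAltman:
    bias: float           # mean(self − device), min/day
    sd_diff: float        # sample SD of the differences (n − 1)
    loa_low: float
    loa_high: float
    points: pd.DataFrame  # per-pair (mean, diff) for plotting


@dataclass
class AgreementSummary:
    behaviour: str
    icc: ICCResult
    bland_altman: BlandAltman
    mape_pct: float
    mape_n_excluded: int = 0


def icc_2_1(x: np.ndarray, y: np.ndarray, *, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares with n subject rows and
    k = 2 method columns:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    The F statistic reported is MSR/MSE (test of ICC = 0) and the confidence
    interval follows the McGraw–Wong formulation with a Satterthwaite
    approximation for the denominator degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("icc_2_1 expects two 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in ICC input")

    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)          # rows (subjects)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)          # columns (methods)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr == 0 and msc == 0 and mse == 0):
        raise ValueError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom

    f = msr / mse if mse > 0 else np.inf
    df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)
    p = float(stats.f.sf(f, df1, df2))

    alpha = 1.0 - confidence
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den
    else:
        v = df2
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(icc=float(icc), ci_low=float(lower), ci_high=float(upper),
                     f=float(f), df1=df1, df2=df2, p=p, label=icc_strength(icc))


def icc_consistency(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(3,1) point estimate (consistency; offsets between methods ignored)."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))


def bland_altman(self_vals: np.ndarray, device_vals: np.ndarray) -> BlandAltman:
    """Bias and 1.96·SD limits of agreement for self − device differences."""
    s = np.asarray(self_vals, dtype=float)
    d = np.asarray(device_vals, dtype=float)
    if s.shape != d.shape or s.size < 1:
        raise ValueError("bland_altman expects equal-length arrays")
    diff = s - d
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if s.size > 1 else 0.0
    points = pd.DataFrame({"mean": (s + d) / 2.0, "diff": diff})
    return BlandAltman(bias=bias, sd_diff=sd,
                       loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                       points=points)


def mape(self_vals: np.ndarray, device_vals: np.ndarray) -> tuple[float, int]:
    """Mean absolute percentage error, in percent.

    Self-report is the forecast, the device the actual value.  Pairs with a
    zero device value are excluded with a warning; the exclusion count is
    returned alongside the estimate.
    """
    s = np.asarray(self_vals, dtype=float)
    d = np.asarray(device_vals, dtype=float)
    ok = d != 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("MAPE: excluded %d pair(s) with zero device value", n_excluded)
    if not ok.any():
        raise ValueError("MAPE undefined: all device values are zero")
    return float(np.mean(np.abs(s[ok] - d[ok]) / d[ok]) * 100.0), n_excluded


def mean_percent_difference(self_vals: np.ndarray, device_vals: np.ndarray) -> float:
    """Percent difference of the method means over the mean-of-methods.

    100 · (mean(self) − mean(device)) / ((mean(self) + mean(device)) / 2).
    """
    ms = float(np.mean(self_vals))
    md = float(np.mean(device_vals))
    return 100.0 * (ms - md) / ((ms + md) / 2.0)


def summarize_agreement(table: pd.DataFrame) -> dict[str, AgreementSummary]:
    """Per-behaviour agreement summaries from the participant analysis table.

    Expects ``device_<behaviour>`` and ``self_<behaviour>`` columns.
    """
    out = {}
    for b in BEHAVIOURS:
        d = table[f"device_{b}"].to_numpy()
        s = table[f"self_{b}"].to_numpy()
        m, n_exc = mape(s, d)
        out[b] = AgreementSummary(
            behaviour=b, icc=icc_2_1(s, d), bland_altman=bland_altman(s, d),
            mape_pct=m, mape_n_excluded=n_exc,
        )
    return out


def agreement_table(summaries: dict[str, AgreementSummary]) -> pd.DataFrame:
    """ICC/limits/MAPE report, one row per behaviour."""
    rows = []
    for b, s in summaries.items():
        rows.append({
            "behaviour": b, "icc": s.icc.icc, "icc_ci_low": s.icc.ci_low,
            "icc_ci_high": s.icc.ci_high, "icc_f": s.icc.f, "icc_p": s.icc.p,
            "icc_label": s.icc.label, "bias_min": s.bland_altman.bias,
            "sd_diff_min": s.bland_altman.sd_diff,
            "loa_low_min": s.bland_altman.loa_low,
            "loa_high_min": s.bland_altman.loa_high,
            "mape_pct": s.mape_pct,
        })
    return pd.DataFrame(rows)


def bland_altman_plot(summary: AgreementSummary, path) -> None:
    """Write a conventional Bland–Altman scatter for one behaviour."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = summary.bland_altman
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.points["mean"], ba.points["diff"], s=12, alpha=0.6)
    ax.axhline(ba.bias, color="tab:blue", label=f"bias {ba.bias:.0f}")
    for lim in (ba.loa_low, ba.loa_high):
        ax.axhline(lim, color="tab:red", linestyle="--")
    ax.set_xlabel("mean of methods (min/day)")
    ax.set_ylabel("self − device (min/day)")
    ax.set_title(summary.behaviour)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
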