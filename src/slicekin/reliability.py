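"""Test-retest reliability analysis for two-session displacement data.

Implements the full between-session analysis battery: per-trial coefficient
of variation (CV), paired and independent t-tests, ICC(2,1) with a 95%
confidence interval, Bland-Altman limits of agreement, heteroscedasticity
classification, and ratio limits of agreement.

Conventions, fixed for reproducibility:

* The SD of a two-value pair uses the n-1 denominator, so
  ``SD(x1, x2) = |x1 - x2| / sqrt(2)`` — the convention under which the
  worked pair (11.5, 10.8) yields a CV of 4.44%.
* Differences are ``session1 - session2`` and reported with sign.
* Heteroscedasticity is classified from the R^2 of an ordinary
  least-squares regression of |differences| on pair means, with values
  above 0.1 labelled heteroscedastic.
* ICC(2,1) is the Shrout-Fleiss two-way random-effects single-measure
  form, in which systematic between-session bias counts against
  agreement; its CI uses the McGraw & Wong F-based interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SessionPairData", "ICCResult", "BlandAltmanResult", "ReliabilityReport",
    "cv_between_sessions", "mean_cv", "icc_2_1", "bland_altman", "ratio_loa",
    "paired_t", "build_reliability_report", "bland_altman_plot",
]

HETEROSCEDASTICITY_R2 = 0.1


@dataclass(frozen=True)
class SessionPairData:
    """Paired measurements of the same trials from two sessions."""

    levels: np.ndarray  # nominal displacement level per trial (mm or deg)
    session1: np.ndarray
    session2: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, float).reshape(-1)
        s1 = np.asarray(self.session1, float).reshape(-1)
        s2 = np.asarray(self.session2, float).reshape(-1)
        if not (len(lv) == len(s1) == len(s2)):
            raise ValueError("levels, session1 and session2 must have equal length")
        if len(lv) == 0:
            raise ValueError("no trials")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "session1", s1)
        object.__setattr__(self, "session2", s2)

    @property
    def differences(self) -> np.ndarray:
        return self.session1 - self.session2

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.session1 + self.session2)

    @classmethod
    def from_csv(cls, path) -> "SessionPairData":
        df = pd.read_csv(path)
        return cls(df["level"].to_numpy(), df["session1"].to_numpy(),
                   df["session2"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "level": self.levels,
            "trial_id": np.arange(len(self.levels)),
            "session1": self.session1,
            "session2": self.session2,
        }).to_csv(path, index=False)


def cv_between_sessions(x1: float, x2: float) -> float:
    """Between-session CV of one trial, percent.

    Sample SD of the pair divided by the pair mean, times 100.  A pair
    mean of zero leaves the CV undefined and returns NaN; near-zero means
    (the 0-displacement level) naturally inflate the CV.
    """
    mean = (x1 + x2) / 2.0
    if mean == 0.0:
        return math.nan
    sd = abs(x1 - x2) / math.sqrt(2.0)
    return 100.0 * sd / mean


def mean_cv(data: SessionPairData, level: float) -> tuple[float, int]:
    """Mean of the per-trial CVs at one level; returns (percent, n_skipped).

    Trials with an undefined CV (zero pair mean) are skipped and counted.
    """
    sel = data.levels == level
    if not sel.any():
        raise ValueError(f"no trials at level {level}")
    cvs = np.array([cv_between_sessions(a, b)
                    for a, b in zip(data.session1[sel], data.session2[sel])])
    ok = ~np.isnan(cvs)
    skipped = int((~ok).sum())
    return (float(cvs[ok].mean()) if ok.any() else math.nan), skipped


# ---------------------------------------------------------------------------
# ICC(2,1)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "(2,1) two-way random, single measure"
    undefined: bool = False


def _two_way_mean_squares(mat: np.ndarray):
    n, k = mat.shape
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((mat - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(mat: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1) from two-way ANOVA mean squares, with an F-based 95% CI.

    ``mat`` is trials x sessions (>= 3 trials).  The two-way
    random-effects single-measure form is used because it is sensitive to
    systematic between-session bias.  Zero total variance leaves the ICC
    undefined (flagged).
    """
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a trials x sessions matrix with >= 2 sessions")
    n, k = mat.shape
    if n < 3:
        raise ValueError("need >= 3 trials")
    if np.allclose(mat, mat.flat[0]):
        return ICCResult(math.nan, math.nan, math.nan, undefined=True)
    msr, msc, mse = _two_way_mean_squares(mat)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICCResult(math.nan, math.nan, math.nan, undefined=True)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval
    alpha = 1.0 - confidence
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    if not math.isfinite(a) or mse == 0:
        return ICCResult(float(icc), float(icc), float(icc))
    v = ((a * msc + b * mse) ** 2 /
         ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = (n * (msr - f_low * mse) /
             (f_low * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_up * msr - mse) /
             (k * msc + (k * n - k - n) * mse + n * f_up * msr))
    return ICCResult(float(icc), float(lower), float(upper))


# ---------------------------------------------------------------------------
# Bland-Altman and ratio LOA


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float  # mean of session1 - session2
    sd_diff: float
    loa_low: float
    loa_high: float
    r_squared: float
    scedasticity: str  # "homo" | "hetero" | "degenerate"


def bland_altman(data: SessionPairData) -> BlandAltmanResult:
    """Bland-Altman agreement analysis with 95% (+/-1.96 SD) limits.

    R^2 comes from OLS of |differences| on pair means and classifies the
    error structure: homoscedastic for R^2 <= 0.1, heteroscedastic above.
    Constant differences or means make the regression degenerate; this is
    flagged rather than classified.
    """
    if len(data.levels) < 3:
        raise ValueError("need >= 3 pairs")
    d = data.differences
    m = data.means
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    abs_d = np.abs(d)
    if sd == 0.0 or m.std() == 0.0 or abs_d.std() == 0.0:
        return BlandAltmanResult(bias, sd, loa_low, loa_high, math.nan,
                                 "degenerate")
    r2 = float(stats.linregress(m, abs_d).rvalue ** 2)
    sced = "hetero" if r2 > HETEROSCEDASTICITY_R2 else "homo"
    return BlandAltmanResult(bias, sd, loa_low, loa_high, r2, sced)


def ratio_loa(data: SessionPairData) -> dict:
    """Ratio limits of agreement, percent of measurement magnitude.

    ``ratio LOA = [(SDdiffs / AVGmeans) x 1.96] x 100`` with SDdiffs the
    SD of the between-session differences and AVGmeans the average of the
    per-trial pair means.  The systematic-bias component (the mean
    difference) is reported separately from this random-error component.
    """
    d = data.differences
    avg_means = float(data.means.mean())
    if avg_means == 0.0:
        raise ValueError("AVGmeans is zero; ratio LOA undefined")
    sd_diffs = float(d.std(ddof=1))
    ratio = (sd_diffs / avg_means * 1.96) * 100.0
    return {
        "ratio_loa_percent": float(ratio),
        "systematic_bias": float(d.mean()),
        "random_error_percent": float(ratio),
        "sd_diffs": sd_diffs,
        "avg_means": avg_means,
    }


def paired_t(data: SessionPairData, mode: str = "paired") -> tuple[float, float]:
    """Two-tailed t-test between sessions: (t, p).

    ``paired`` compares trials matched across sessions; ``independent``
    treats the sessions as unrelated samples.  A zero-variance difference
    makes p degenerate (returned as NaN with t=0).
    """
    if len(data.levels) < 2:
        raise ValueError("need >= 2 trials")
    if mode == "paired":
        d = data.differences
        if d.std(ddof=0) == 0.0:  # zero SD of differences: p degenerate
            t0 = 0.0 if d[0] == 0.0 else math.copysign(math.inf, d[0])
            return t0, math.nan
        t, p = stats.ttest_rel(data.session1, data.session2)
    elif mode == "independent":
        t, p = stats.ttest_ind(data.session1, data.session2)
    else:
        raise ValueError("mode must be 'paired' or 'independent'")
    return float(t), float(p)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class ReliabilityReport:
    per_level: pd.DataFrame
    overall_mean_cv: float
    icc: ICCResult
    t_statistic: float
    p_value: float
    bland_altman: BlandAltmanResult
    ratio_loa: dict
    n_trials: int
    unit: str = "mm"
    extras: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"Test-retest reliability ({self.n_trials} trials)", ""]
        lines.append(self.per_level.to_string(index=False,
                                              float_format=lambda v: f"{v:.2f}"))
        lines.append("")
        lines.append(f"Overall mean CV: {self.overall_mean_cv:.2f} %")
        if self.icc.undefined:
            lines.append("ICC(2,1): undefined (zero total variance)")
        else:
            lines.append(f"ICC(2,1): {self.icc.icc:.2f} "
                         f"({self.icc.ci_low:.2f}-{self.icc.ci_high:.2f})")
        lines.append(f"Paired t-test: t = {self.t_statistic:.3f}, "
                     f"p = {self.p_value:.3f}")
        ba = self.bland_altman
        sced = {"homo": "homoscedastic", "hetero": "heteroscedastic",
                "degenerate": "degenerate"}[ba.scedasticity]
        lines.append(f"Bland-Altman: bias {ba.bias:.2f} {self.unit}, "
                     f"LOA [{ba.loa_low:.2f}, {ba.loa_high:.2f}] {self.unit}, "
                     f"R^2 = {ba.r_squared:.3f} ({sced})")
        rl = self.ratio_loa
        lines.append(f"Ratio LOA: bias {rl['systematic_bias']:.2f} {self.unit}, "
                     f"random error +/-{rl['ratio_loa_percent']:.2f} %")
        return "\n".join(lines) + "\n"

    def to_csv(self, path) -> None:
        self.per_level.to_csv(path, index=False)


def build_reliability_report(data: SessionPairData, unit: str = "mm") -> ReliabilityReport:
    """Assemble the full per-level + summary reliability record.

    One row per distinct level with the session means, SDs and mean CV;
    summary statistics (overall mean CV, ICC(2,1), paired t, Bland-Altman,
    ratio LOA) computed across all trials.
    """
    rows = []
    all_cvs = []
    for level in np.unique(data.levels):
        sel = data.levels == level
        cv, skipped = mean_cv(data, level)
        rows.append({
            "level": level,
            "n": int(sel.sum()),
            "mean_s1": data.session1[sel].mean(),
            "sd_s1": data.session1[sel].std(ddof=1) if sel.sum() > 1 else 0.0,
            "mean_s2": data.session2[sel].mean(),
            "sd_s2": data.session2[sel].std(ddof=1) if sel.sum() > 1 else 0.0,
            "mean_cv_percent": cv,
            "cv_undefined_skipped": skipped,
        })
        if not math.isnan(cv):
            all_cvs.append(cv)
    per_level = pd.DataFrame(rows)
    mat = np.column_stack([data.session1, data.session2])
    icc = icc_2_1(mat)
    t, p = paired_t(data)
    ba = bland_altman(data)
    rl = ratio_loa(data)
    return ReliabilityReport(
        per_level=per_level,
        overall_mean_cv=float(np.mean(all_cvs)) if all_cvs else math.nan,
        icc=icc, t_statistic=t, p_value=p, bland_altman=ba, ratio_loa=rl,
        n_trials=len(data.levels), unit=unit)


def bland_altman_plot(data: SessionPairData, path=None, unit: str = "mm"):
    """Bland-Altman scatter with bias and +/-1.96 SD limit lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(data)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data.means, data.differences, s=18, alpha=0.8)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.axhline(ba.bias, color="k", lw=1.2, label=f"bias {ba.bias:.2f}")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", ls="--", lw=1.0)
    ax.set_xlabel(f"pair mean ({unit})")
    ax.set_ylabel(f"session1 - session2 ({unit})")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig, ax
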