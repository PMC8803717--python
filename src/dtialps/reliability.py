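"""Reliability and agreement statistics for the ALPS index.

Test-retest agreement is judged with the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation ICC(2,1):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

from the two-way ANOVA mean squares (MSR rows/subjects, MSC columns/sessions,
MSE residual), with the standard F-based 95% confidence interval (McGraw &
Wong). Qualitative labels follow the Landis-Koch bands. Paired comparisons
use the two-sided paired t test and Pearson's r; condition effects across
>= 3 levels use a two-way repeated-measures ANOVA with subject as the random
block. All tests are two-sided at alpha = 0.05 with no multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MeasurementMatrix",
    "IccResult",
    "ReliabilityReport",
    "icc_absolute_agreement",
    "landis_koch_label",
    "paired_comparison",
    "rm_anova_two_way",
]

LANDIS_KOCH_BANDS = (
    (0.00, "slight"),
    (0.20, "fair"),
    (0.40, "moderate"),
    (0.60, "substantial"),
    (0.80, "almost perfect"),
)


@dataclass(frozen=True)
class MeasurementMatrix:
    """Subjects x sessions grid of index values (complete, no missing cells)."""

    values: np.ndarray
    subject_ids: tuple = ()
    session_ids: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need >= 2 subjects and >= 2 sessions")
        if not np.all(np.isfinite(v)):
            raise ValueError("missing or non-finite cells are not allowed")


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    label: str
    degenerate: bool = False
    note: str = ""
    mean_squares: dict = field(default_factory=dict)


@dataclass
class ReliabilityReport:
    """Bundle of the agreement statistics for one comparison."""

    icc: IccResult | None = None
    t_p: float | None = None
    t_stat: float | None = None
    pearson_r: float | None = None
    anova_table: list | None = None
    meta: dict = field(default_factory=dict)


def _two_way_mean_squares(x: np.ndarray) -> dict[str, float]:
    """Mean squares of the two-way (subject x session) layout, one obs/cell."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return {
        "msr": ss_rows / (n - 1),
        "msc": ss_cols / (k - 1),
        "mse": ss_err / ((n - 1) * (k - 1)),
        "n": n,
        "k": k,
    }


def icc_absolute_agreement(m: MeasurementMatrix, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns the point estimate, the McGraw-Wong F-based confidence interval,
    and the Landis-Koch label. A matrix with zero total variance has an
    undefined ICC and is reported as degenerate rather than raising.
    """
    x = m.values
    ms = _two_way_mean_squares(x)
    n, k = ms["n"], ms["k"]
    msr, msc, mse = ms["msr"], ms["msc"], ms["mse"]
    scale = max(np.abs(x).max() ** 2, np.finfo(float).tiny)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if np.var(x) <= 1e-24 * scale or denom <= 0:
        return IccResult(
            icc=float("nan"), ci95=(float("nan"), float("nan")), label="undefined",
            degenerate=True, note="zero total variance: ICC undefined", mean_squares=ms,
        )
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) interval for ICC(A,1)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci = (float(lower), float(upper))
    else:
        ci = (float("nan"), float("nan"))
    return IccResult(icc=float(icc), ci95=ci, label=landis_koch_label(icc), mean_squares=ms)


def landis_koch_label(icc: float) -> str:
    """Landis-Koch qualitative band for an agreement coefficient.

    Bands: poor < 0, slight 0-0.20, fair 0.21-0.40, moderate 0.41-0.60,
    substantial 0.61-0.80, almost perfect 0.81-1.00 (upper-inclusive edges).
    """
    if np.isnan(icc):
        return "undefined"
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.0:
        return "poor"
    label = "slight"
    for edge, name in LANDIS_KOCH_BANDS:
        if icc > edge:
            label = name
    if icc == 0.0:
        label = "slight"
    return label


def paired_comparison(a: np.ndarray, b: np.ndarray) -> ReliabilityReport:
    """Two-sided paired t test and Pearson correlation on subject-paired values.

    Callers comparing a multi-session mean against a single session must
    average the sessions first. Zero variance in the differences makes the t
    statistic undefined; this is flagged rather than raised.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length paired 1-D samples with n >= 3")
    d = a - b
    meta: dict = {}
    if np.allclose(d, d[0]):
        if np.isclose(d[0], 0.0):
            t_stat, t_p = 0.0, 1.0
            meta["note"] = "identical samples"
        else:
            t_stat, t_p = float("nan"), float("nan")
            meta["note"] = "zero variance in differences: t undefined"
    else:
        res = stats.ttest_rel(a, b)
        t_stat, t_p = float(res.statistic), float(res.pvalue)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r = float("nan")
        meta["note"] = meta.get("note", "") + " constant sample: r undefined"
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return ReliabilityReport(t_p=t_p, t_stat=t_stat, pearson_r=r, meta=meta)


def rm_anova_two_way(values: np.ndarray) -> list[dict]:
    """Two-way repeated-measures ANOVA (subjects x conditions, one obs/cell).

    The condition effect is tested against the subject-by-condition residual:
    F = MS_condition / MS_error with (k-1) and (n-1)(k-1) degrees of freedom.
    Requires a complete design with >= 3 condition levels.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3 or x.shape[0] < 2:
        raise ValueError("need a complete subjects x conditions design with >= 3 levels")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete design: non-finite cells")
    ms = _two_way_mean_squares(x)
    n, k = ms["n"], ms["k"]
    scale = max(np.abs(x).max() ** 2, np.finfo(float).tiny)
    if ms["mse"] <= 1e-24 * scale:
        degenerate_cond = ms["msc"] <= 1e-24 * scale
        f = 0.0 if degenerate_cond else float("inf")
        p = 1.0 if degenerate_cond else 0.0
    else:
        f = ms["msc"] / ms["mse"]
        p = float(stats.f.sf(f, k - 1, (n - 1) * (k - 1)))
    return [
        {"factor": "subject", "df": n - 1, "ms": ms["msr"], "f": None, "p": None},
        {"factor": "condition", "df": k - 1, "ms": ms["msc"], "f": float(f), "p": p},
        {"factor": "error", "df": (n - 1) * (k - 1), "ms": ms["mse"], "f": None, "p": None},
    ]
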