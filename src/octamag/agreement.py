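"""Method-comparison statistics: Bland-Altman, paired t, ICC, CR, relative change.

Conventions
-----------
Differences are always taken as (first method - second method), with the
first argument conventionally the estimate/uncorrected series and the
second the reference; reports state the direction explicitly.

The 95% limits of agreement are d_bar +/- 1.96*SD with the sample SD
(n-1 denominator).  Confidence intervals default to the classical
approximation SE(d_bar) = SD/sqrt(n) and SE(LoA) = SD*sqrt(3/n) with a
1.96 normal multiplier; an exact-t variant (t quantile, and
SE(LoA) = SD*sqrt(1/n + z^2/(2(n-1)))) is available via ``ci_method``.

The intraclass correlation is the two-way random-effects, absolute
agreement, single-measures variant — ICC(A,1) in McGraw & Wong's notation,
ICC(2,1) in Shrout & Fleiss's — with its confidence interval from the
standard F-distribution bounds.  Absolute-agreement ICCs penalise a
systematic offset between methods, which consistency ICCs would ignore.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidDenominatorError,
    PairingError,
    UndefinedStatisticError,
)

#: Coefficient of repeatability for FAZ area on the RTVue XR Avanti in
#: healthy eyes, mm^2 (Chen et al. repeatability study).
DEFAULT_FAZA_CR = 0.052


@dataclass(frozen=True)
class PairedSample:
    """Two methods' measurements on the same eyes, paired by label."""

    labels: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "labels", tuple(self.labels))
        if not (len(self.labels) == a.size == b.size):
            raise PairingError(
                f"labels/a/b lengths differ: {len(self.labels)}, {a.size}, {b.size}"
            )
        if a.size < 2:
            raise InsufficientDataError("need at least 2 pairs")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise PairingError("paired samples must not contain missing values")

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b

    def swapped(self) -> "PairedSample":
        return PairedSample(self.labels, self.b, self.a)


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    mean_diff_ci: Tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_lower_ci: Tuple[float, float]
    loa_upper_ci: Tuple[float, float]
    coverage_multiplier: float = 1.96

    @property
    def loa_width(self) -> float:
        return self.loa_upper - self.loa_lower


def loa_confidence_intervals(
    mean_diff: float,
    sd_diff: float,
    n: int,
    coverage: float = 1.96,
    ci_method: str = "approx",
    ci_z: float = 1.96,
):
    """95% confidence intervals for the lower and upper limits of agreement.

    ``approx`` uses SE(LoA) = SD*sqrt(3/n) with a fixed 1.96 multiplier;
    ``exact-t`` uses SE(LoA) = SD*sqrt(1/n + coverage^2/(2(n-1))) with the
    Student-t quantile.
    """
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    lower = mean_diff - coverage * sd_diff
    upper = mean_diff + coverage * sd_diff
    if ci_method == "approx":
        half = ci_z * sd_diff * math.sqrt(3.0 / n)
    elif ci_method == "exact-t":
        t = stats.t.ppf(0.975, n - 1)
        half = t * sd_diff * math.sqrt(1.0 / n + coverage ** 2 / (2.0 * (n - 1)))
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return (lower - half, lower + half), (upper - half, upper + half)


def bland_altman_from_summary(
    mean_diff: float,
    sd_diff: float,
    n: int,
    coverage: float = 1.96,
    ci_method: str = "approx",
) -> BlandAltmanResult:
    """Bland-Altman limits of agreement from summary statistics."""
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    se_mean = sd_diff / math.sqrt(n)
    z = 1.96 if ci_method == "approx" else stats.t.ppf(0.975, n - 1)
    lo_ci, up_ci = loa_confidence_intervals(
        mean_diff, sd_diff, n, coverage=coverage, ci_method=ci_method
    )
    return BlandAltmanResult(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        mean_diff_ci=(mean_diff - z * se_mean, mean_diff + z * se_mean),
        loa_lower=mean_diff - coverage * sd_diff,
        loa_upper=mean_diff + coverage * sd_diff,
        loa_lower_ci=lo_ci,
        loa_upper_ci=up_ci,
        coverage_multiplier=coverage,
    )


def bland_altman(
    sample: PairedSample, coverage: float = 1.96, ci_method: str = "approx"
) -> BlandAltmanResult:
    """Bland-Altman analysis of a paired sample (differences a - b)."""
    d = sample.differences
    return bland_altman_from_summary(
        float(np.mean(d)), float(np.std(d, ddof=1)), sample.n,
        coverage=coverage, ci_method=ci_method,
    )


def paired_t(
    sample: Optional[PairedSample] = None,
    *,
    mean_diff: Optional[float] = None,
    sd_diff: Optional[float] = None,
    n: Optional[int] = None,
):
    """Paired t test: t = d_bar / (SD/sqrt(n)), df = n-1, two-sided p.

    Accepts either a :class:`PairedSample` or the summary triple
    (mean_diff, sd_diff, n).
    """
    if sample is not None:
        d = sample.differences
        mean_diff = float(np.mean(d))
        sd_diff = float(np.std(d, ddof=1))
        n = sample.n
    if mean_diff is None or sd_diff is None or n is None:
        raise ValueError("provide a sample or all of mean_diff, sd_diff, n")
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    if sd_diff == 0:
        raise UndefinedStatisticError("paired t undefined for zero difference SD")
    t = mean_diff / (sd_diff / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def icc_absolute(sample: PairedSample, confidence: float = 0.95):
    """Single-measure absolute-agreement ICC from a two-way random model.

    Returns ``(icc, (ci_lower, ci_upper))``.  Computed from the two-way
    ANOVA mean squares,

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1)MSE + k(MSC - MSE)/n)

    with k = 2 raters (methods), and the F-distribution confidence bounds
    of McGraw & Wong.  Raises on zero total variance, where agreement is
    undefined.
    """
    if sample.n < 3:
        raise InsufficientDataError("ICC needs at least 3 subjects")
    x = np.column_stack([sample.a, sample.b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    sst = float(((x - grand) ** 2).sum())
    if sst <= 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: zero denominator")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0 or icc >= 1.0:
        return float(icc), (float(icc), float(icc))
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lower), float(upper))


def cr_exceedance(
    method: Sequence[float],
    reference: Sequence[float],
    cr: float = DEFAULT_FAZA_CR,
) -> float:
    """Percentage of pairs with |method - reference| strictly above CR.

    The coefficient of repeatability CR is the margin within which repeat
    measurements of the same eye are expected to agree; differences at
    exactly CR do not count as exceedances (strict inequality).
    """
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.size != r.size:
        raise PairingError(f"length mismatch: {m.size} vs {r.size}")
    if m.size < 1:
        raise InsufficientDataError("need at least 1 pair")
    if cr <= 0:
        raise ValueError("cr must be positive")
    return 100.0 * float(np.count_nonzero(np.abs(m - r) > cr)) / m.size


@dataclass(frozen=True)
class RelativeChangeResult:
    per_pair_pct: np.ndarray
    max_relative_pct: float
    max_absolute: float


def relative_change(reference, other) -> RelativeChangeResult:
    """Per-pair percentage change 100*|reference - other|/reference.

    Also reports the maximum relative (%) and maximum absolute change.
    Reference values must be strictly positive.
    """
    r = np.asarray(reference, dtype=float)
    o = np.asarray(other, dtype=float)
    if r.size != o.size:
        raise PairingError(f"length mismatch: {r.size} vs {o.size}")
    if np.any(r <= 0):
        raise InvalidDenominatorError("reference values must be > 0")
    abs_change = np.abs(r - o)
    pct = 100.0 * abs_change / r
    return RelativeChangeResult(
        per_pair_pct=pct,
        max_relative_pct=float(pct.max()),
        max_absolute=float(abs_change.max()),
    )


@dataclass(frozen=True)
class AgreementReport:
    """Full method-comparison report for one paired sample (a - b)."""

    bland_altman: BlandAltmanResult
    icc: float
    icc_ci: Tuple[float, float]
    t_stat: float
    df: int
    p_value: float
    direction: str = "a - b"
    cr: Optional[float] = None
    cr_exceedance_pct: Optional[float] = None
    relative: Optional[RelativeChangeResult] = None
    labels: tuple = field(default=(), repr=False)


def evaluate_agreement(
    sample: PairedSample,
    *,
    coverage: float = 1.96,
    ci_method: str = "approx",
    cr: Optional[float] = None,
    direction: str = "a - b",
) -> AgreementReport:
    """Run the full agreement battery on a paired sample.

    ``b`` is treated as the reference: CR exceedance and relative change
    (when requested via ``cr``/positive reference) are computed against it.
    """
    ba = bland_altman(sample, coverage=coverage, ci_method=ci_method)
    icc, icc_ci = icc_absolute(sample)
    try:
        t, df, p = paired_t(sample)
    except UndefinedStatisticError:
        t, df, p = 0.0, sample.n - 1, 1.0
    exceed = cr_exceedance(sample.a, sample.b, cr) if cr is not None else None
    rel = relative_change(sample.b, sample.a) if np.all(sample.b > 0) else None
    return AgreementReport(
        bland_altman=ba,
        icc=icc,
        icc_ci=icc_ci,
        t_stat=t,
        df=df,
        p_value=p,
        direction=direction,
        cr=cr,
        cr_exceedance_pct=exceed,
        relative=rel,
        labels=sample.labels,
    )


def format_p(p: float) -> str:
    """Display convention: 3 decimals, floored at '< 0.005'."""
    return "< 0.005" if p < 0.005 else f"{p:.3f}"


def report_to_dict(report: AgreementReport) -> dict:
    """Machine-readable report, full double precision."""
    ba = report.bland_altman
    d = {
        "direction": report.direction,
        "n": ba.n,
        "mean_diff": ba.mean_diff,
        "mean_diff_ci": list(ba.mean_diff_ci),
        "sd_diff": ba.sd_diff,
        "loa_lower": ba.loa_lower,
        "loa_lower_ci": list(ba.loa_lower_ci),
        "loa_upper": ba.loa_upper,
        "loa_upper_ci": list(ba.loa_upper_ci),
        "coverage_multiplier": ba.coverage_multiplier,
        "t_stat": report.t_stat,
        "df": report.df,
        "p_value": report.p_value,
        "icc": report.icc,
        "icc_ci": list(report.icc_ci),
    }
    if report.cr_exceedance_pct is not None:
        d["cr"] = report.cr
        d["cr_exceedance_pct"] = report.cr_exceedance_pct
    if report.relative is not None:
        d["relative_change_pct"] = report.relative.per_pair_pct.tolist()
        d["max_relative_change_pct"] = report.relative.max_relative_pct
        d["max_absolute_change"] = report.relative.max_absolute
    return d


def report_to_json(report: AgreementReport, indent: int = 2) -> str:
    return json.dumps(report_to_dict(report), indent=indent)


def format_report(report: AgreementReport, title: str = "Agreement") -> str:
    """Human-readable table with paper-style rounding."""
    ba = report.bland_altman
    lines = [
        title,
        f"  Direction of differences: {report.direction}   (n = {ba.n})",
        f"  Mean diff (95% CI): {ba.mean_diff:.3f} "
        f"({ba.mean_diff_ci[0]:.3f}, {ba.mean_diff_ci[1]:.3f})",
        f"  SD of differences:  {ba.sd_diff:.3f}",
        f"  Lower LoA (95% CI): {ba.loa_lower:.3f} "
        f"({ba.loa_lower_ci[0]:.3f}, {ba.loa_lower_ci[1]:.3f})",
        f"  Upper LoA (95% CI): {ba.loa_upper:.3f} "
        f"({ba.loa_upper_ci[0]:.3f}, {ba.loa_upper_ci[1]:.3f})",
        f"  t_stat (df): {report.t_stat:.3f} ({report.df})   "
        f"P = {format_p(report.p_value)}",
        f"  ICC (95% CI): {report.icc:.3f} "
        f"({report.icc_ci[0]:.3f}, {report.icc_ci[1]:.3f})",
    ]
    if report.cr_exceedance_pct is not None:
        lines.append(
            f"  CR exceedance (> {report.cr:g}): {report.cr_exceedance_pct:.1f}%"
        )
    if report.relative is not None:
        lines.append(
            f"  Max relative change: {report.relative.max_relative_pct:.1f}% "
            f"(max absolute {report.relative.max_absolute:.3f})"
        )
    return "\n".join(lines)
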