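"""Method-agreement statistics for paired volumetric measurements.

Implements the comparison toolkit for two automated packages measured on
the same cohort: two-way random-effects single-measures ICC with absolute
agreement and F-based confidence interval, Bland-Altman limits of
agreement with their confidence intervals, the paired Wilcoxon signed-rank
test (exact by enumeration for small samples), and triage-concordance
tabulation with 70-mL subgroups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDataError,
    ParameterError,
    SampleSizeError,
)
from .lesion import TriageDecision, VolumetricResult, mismatch_profile, triage_defuse3

#: Differences beyond this count switch the Wilcoxon test from exact
#: enumeration to the normal approximation.
WILCOXON_EXACT_MAX_N = 25

#: Subgroup boundary (mL) for triage-concordance tables.
SUBGROUP_ICV_ML = 70.0


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

def _anova_mean_squares(data: np.ndarray) -> Tuple[float, float, float]:
    """Row, column and error mean squares of an n-subjects x k-raters table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> Tuple[float, Tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Returns ``(icc, (ci_low, ci_high))``. The confidence interval uses the
    F-distribution method with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1D and of equal length")
    n = x.size
    if n < 5:
        raise SampleSizeError(f"ICC requires at least 5 pairs; got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("non-finite values in ICC input")
    data = np.column_stack([x, y])
    if np.ptp(data) == 0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    k = 2
    msr, msc, mse = _anova_mean_squares(data)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateDataError("degenerate ANOVA decomposition; ICC undefined")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        return float(icc), (float(icc), float(icc))

    alpha = 1.0 - ci_level
    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), (float(icc), float(icc))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else 1.0
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    return float(icc), (lower, upper)


ICC_BANDS = ("poor", "moderate", "good", "excellent")


def interpret_icc(value: float) -> str:
    """Band an ICC value: <0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good,
    >0.90 excellent."""
    if not -1.0 <= value <= 1.0:
        raise ParameterError(f"ICC must lie in [-1, 1]; got {value}")
    if value < 0.50:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.90:
        return "good"
    return "excellent"


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_diff_ci: Tuple[float, float]
    loa_low_ci: Tuple[float, float]
    loa_high_ci: Tuple[float, float]


def bland_altman(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements; differences are x - y.

    Limits of agreement are ``mean +- 1.96 sd`` (sd with n-1 denominator);
    each limit's CI uses the classic ``sd * sqrt(3/n)`` standard error with
    a t quantile.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n < 3:
        raise SampleSizeError(f"Bland-Altman requires at least 3 pairs; got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = mean - 1.96 * sd
    loa_high = mean + 1.96 * sd
    t = float(stats.t.ppf(0.5 + ci_level / 2, n - 1))
    se_mean = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    return BlandAltmanResult(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        mean_diff_ci=(mean - t * se_mean, mean + t * se_mean),
        loa_low_ci=(loa_low - t * se_loa, loa_low + t * se_loa),
        loa_high_ci=(loa_high - t * se_loa, loa_high + t * se_loa),
    )


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float  # W+ = sum of ranks of positive differences
    n_nonzero: int
    method: str  # "exact", "normal", or "degenerate"
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p by enumerating the 2^n sign assignments.

    Uses a generating-function convolution over integerized (doubled)
    midranks, equivalent to full enumeration but polynomial time.
    """
    weights = np.rint(2.0 * ranks).astype(int)
    total = int(weights.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for w in weights:
        shifted = np.zeros_like(counts)
        shifted[w:] = counts[: counts.size - w]
        counts = counts + shifted
    u_obs = int(round(2.0 * w_obs))
    n_total = counts.sum()
    p_le = counts[: u_obs + 1].sum() / n_total
    p_ge = counts[u_obs:].sum() / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on ``d = x - y``.

    Zero differences are dropped. The null distribution is exact (full
    sign enumeration) for up to 25 non-zero differences; beyond that a
    normal approximation with midrank tie handling and continuity
    correction is used. If every difference is zero the result is flagged
    degenerate with p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(p_value=1.0, statistic=0.0, n_nonzero=0,
                              method="degenerate", degenerate=True)
    if n < 5:
        raise SampleSizeError(
            f"Wilcoxon test requires at least 5 non-zero differences; got {n}"
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(p_value=p, statistic=w_plus, n_nonzero=n, method="exact")
    mean_w = ranks.sum() / 2.0
    var_w = float((ranks ** 2).sum()) / 4.0
    if var_w == 0:
        return WilcoxonResult(p_value=1.0, statistic=w_plus, n_nonzero=n,
                              method="degenerate", degenerate=True)
    delta = w_plus - mean_w
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var_w)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(p_value=p, statistic=w_plus, n_nonzero=n, method="normal")


# --------------------------------------------------------------------------
# Cohorts and concordance
# --------------------------------------------------------------------------

@dataclass
class PairedCohort:
    """Per-case volumetric results and triage decisions from two packages."""

    case_ids: List[str]
    volumes_a: List[VolumetricResult]
    volumes_b: List[VolumetricResult]
    decisions_a: List[TriageDecision]
    decisions_b: List[TriageDecision]

    def __post_init__(self):
        lengths = {
            len(self.case_ids), len(self.volumes_a), len(self.volumes_b),
            len(self.decisions_a), len(self.decisions_b),
        }
        if len(lengths) != 1:
            raise ParameterError("cohort field lengths differ")
        if len(set(self.case_ids)) != len(self.case_ids):
            raise ParameterError("case_ids must be unique")

    def __len__(self) -> int:
        return len(self.case_ids)


@dataclass(frozen=True)
class SubgroupConcordance:
    name: str
    n: int
    eligible_a: int
    eligible_b: int
    concordant: int
    rate: Optional[float]


@dataclass
class ConcordanceTable:
    subgroups: List[SubgroupConcordance]
    overall_concordant: int
    overall_n: int
    overall_rate: float
    icc: float
    icc_ci: Tuple[float, float]


def triage_concordance(cohort: PairedCohort) -> ConcordanceTable:
    """Concordance of eligibility decisions, split at 70 mL package-A core
    volume (boundary cases go to the high-volume subgroup). The overall
    decision agreement is summarized by ICC on 0/1-coded decisions."""
    if len(cohort) == 0:
        raise ParameterError("cohort is empty")
    icv_a = np.array([v.icv for v in cohort.volumes_a])
    ea = np.array([d.eligible for d in cohort.decisions_a], dtype=int)
    eb = np.array([d.eligible for d in cohort.decisions_b], dtype=int)
    high = icv_a >= SUBGROUP_ICV_ML

    subgroups = []
    for name, sel in [
        (f"ICV > {SUBGROUP_ICV_ML:.0f} mL", high),
        (f"ICV < {SUBGROUP_ICV_ML:.0f} mL", ~high),
    ]:
        n = int(sel.sum())
        conc = int((ea[sel] == eb[sel]).sum())
        subgroups.append(
            SubgroupConcordance(
                name=name,
                n=n,
                eligible_a=int(ea[sel].sum()),
                eligible_b=int(eb[sel].sum()),
                concordant=conc,
                rate=(conc / n) if n else None,
            )
        )
    overall_conc = int((ea == eb).sum())
    if np.array_equal(ea, eb):
        icc, ci = 1.0, (1.0, 1.0)
    else:
        try:
            icc, ci = icc_two_way(ea.astype(float), eb.astype(float))
        except (DegenerateDataError, SampleSizeError):
            icc, ci = float("nan"), (float("nan"), float("nan"))
    return ConcordanceTable(
        subgroups=subgroups,
        overall_concordant=overall_conc,
        overall_n=len(cohort),
        overall_rate=overall_conc / len(cohort),
        icc=icc,
        icc_ci=ci,
    )


# --------------------------------------------------------------------------
# Reports and simulation
# --------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Agreement summary for one paired measure (e.g. core volume)."""

    measure: str
    n: int
    icc: float
    icc_ci: Tuple[float, float]
    icc_band: str
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_diff_ci: Tuple[float, float]
    loa_low_ci: Tuple[float, float]
    loa_high_ci: Tuple[float, float]
    wilcoxon_p: float
    wilcoxon_method: str = "exact"
    concordance: Optional[ConcordanceTable] = None

    def __post_init__(self):
        if not (self.loa_low <= self.mean_diff <= self.loa_high):
            raise ParameterError("limits of agreement must bracket the mean difference")
        if not (0.0 <= self.wilcoxon_p <= 1.0):
            raise ParameterError("p-value out of range")
        if not (-1.0 <= self.icc <= 1.0):
            raise ParameterError("ICC out of range")


def agreement_report(
    x: Sequence[float], y: Sequence[float], measure: str = "volume"
) -> AgreementReport:
    """Run ICC, Bland-Altman and Wilcoxon on one paired measure.

    Differences follow the reference-minus-variable convention: x is the
    reference package, y the comparator.
    """
    icc, ci = icc_two_way(x, y)
    ba = bland_altman(x, y)
    wil = wilcoxon_paired(x, y)
    return AgreementReport(
        measure=measure,
        n=ba.n,
        icc=icc,
        icc_ci=ci,
        icc_band=interpret_icc(icc),
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        mean_diff_ci=ba.mean_diff_ci,
        loa_low_ci=ba.loa_low_ci,
        loa_high_ci=ba.loa_high_ci,
        wilcoxon_p=wil.p_value,
        wilcoxon_method=wil.method,
    )


def simulate_paired_cohort(
    n_cases: int,
    bias: float,
    sd: float,
    seed: int = 0,
    modality: str = "CTP",
) -> PairedCohort:
    """Synthetic paired cohort: package B equals package A plus
    ``Normal(bias, sd)`` volume error (clipped at 0). Seeded."""
    if n_cases < 1:
        raise ParameterError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    # keep volumes well above zero so additive errors are almost never clipped
    icv_a = 15.0 + np.clip(rng.lognormal(mean=2.8, sigma=0.9, size=n_cases), 0.0, 300.0)
    pv_a = icv_a + 10.0 + np.clip(rng.lognormal(mean=3.2, sigma=1.0, size=n_cases), 0.0, 400.0)
    icv_b = np.clip(icv_a + rng.normal(bias, sd, n_cases), 0.0, None)
    pv_b = np.clip(pv_a + rng.normal(bias, sd, n_cases), 0.0, None)

    volumes_a = [mismatch_profile(i, p, modality) for i, p in zip(icv_a, pv_a)]
    volumes_b = [mismatch_profile(i, p, modality) for i, p in zip(icv_b, pv_b)]
    return PairedCohort(
        case_ids=[f"case{i:04d}" for i in range(n_cases)],
        volumes_a=volumes_a,
        volumes_b=volumes_b,
        decisions_a=[triage_defuse3(v) for v in volumes_a],
        decisions_b=[triage_defuse3(v) for v in volumes_b],
    )
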