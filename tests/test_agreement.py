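import itertools
import math

import numpy as np
import pytest

from strokeperf.agreement import (
    PairedCohort,
    agreement_report,
    bland_altman,
    icc_two_way,
    interpret_icc,
    simulate_paired_cohort,
    triage_concordance,
    wilcoxon_paired,
)
from strokeperf.errors import (
    DegenerateDataError,
    ParameterError,
    SampleSizeError,
)
from strokeperf.lesion import TriageDecision, mismatch_profile, triage_defuse3


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def icc21_bruteforce(x, y):
    """ICC(2,1) from first-principles sums of squares (explicit loops)."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def wilcoxon_full_enumeration(d):
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    total = len(ws)
    p_le = sum(w <= w_obs + 1e-12 for w in ws) / total
    p_ge = sum(w >= w_obs - 1e-12 for w in ws) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0, 30.0])
        icc, ci = icc_two_way(x, x)
        assert icc == pytest.approx(1.0)
        assert ci[0] <= icc <= ci[1]

    def test_antithetic_matches_oracle(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = -x
        icc, _ = icc_two_way(x, y)
        assert icc == pytest.approx(icc21_bruteforce(x, y), abs=1e-10)
        assert icc < 0

    def test_random_cohorts_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 51)
            x = rng.normal(50, 30, n)
            y = x + rng.normal(2, 10, n)
            icc, _ = icc_two_way(x, y)
            assert icc == pytest.approx(icc21_bruteforce(x, y), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        x = rng.normal(40, 20, 20)
        y = x + rng.normal(1, 8, 20)
        icc, ci = icc_two_way(x, y)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(20), 2),
            "raters": np.tile(["a", "b"], 20),
            "scores": np.column_stack([x, y]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, "targets", "raters", "scores")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds the CI to 2 decimals
        assert ci[0] == pytest.approx(row[ci_col][0], abs=6e-3)
        assert ci[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_two_way(np.full(6, 3.0), np.full(6, 3.0))

    def test_too_few_pairs(self):
        with pytest.raises(SampleSizeError):
            icc_two_way([1, 2, 3], [1, 2, 3])


class TestInterpretIcc:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.49, "poor"),
            (0.50, "moderate"),
            (0.75, "moderate"),
            (0.751, "good"),
            (0.87, "good"),
            (0.90, "good"),
            (0.91, "excellent"),
            (0.95, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_icc(value) == band

    def test_out_of_range(self):
        with pytest.raises(ParameterError):
            interpret_icc(1.5)


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

class TestBlandAltman:
    def test_hand_dataset(self):
        y = np.zeros(5)
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        r = bland_altman(x, y)
        assert r.mean_diff == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(math.sqrt(2.5))
        assert r.loa_high == pytest.approx(1.96 * math.sqrt(2.5))
        assert r.loa_low == pytest.approx(-1.96 * math.sqrt(2.5))

    def test_constant_difference(self):
        x = np.array([3.0, 4.0, 5.0])
        r = bland_altman(x + 2.0, x)
        assert r.mean_diff == pytest.approx(2.0)
        assert r.sd_diff == 0.0
        assert r.loa_low == pytest.approx(2.0)
        assert r.loa_high == pytest.approx(2.0)

    def test_identity(self):
        x = np.array([1.0, 5.0, 9.0, 2.0])
        r = bland_altman(x, x)
        assert r.mean_diff == 0 and r.sd_diff == 0
        assert r.loa_low == 0 and r.loa_high == 0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a, b = bland_altman(x, y), bland_altman(y, x)
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.loa_low == pytest.approx(-b.loa_high)
        assert a.loa_high == pytest.approx(-b.loa_low)

    def test_loa_ci_formula(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r = bland_altman(x, y)
        t = stats.t.ppf(0.975, 9)
        half = t * r.sd_diff * math.sqrt(3.0 / 10)
        assert r.loa_high_ci[1] - r.loa_high == pytest.approx(half)
        assert r.loa_low - r.loa_low_ci[0] == pytest.approx(half)

    def test_too_few(self):
        with pytest.raises(SampleSizeError):
            bland_altman([1.0, 2.0], [0.0, 0.0])


# --------------------------------------------------------------------------
# Wilcoxon
# --------------------------------------------------------------------------

class TestWilcoxon:
    def test_symmetric_fixture_p_one(self):
        d = np.array([-3.0, -1.0, 1.0, 3.0, -2.0, 2.0])
        r = wilcoxon_paired(d, np.zeros(6))
        assert r.method == "exact"
        assert r.p_value == pytest.approx(1.0)
        assert r.p_value == pytest.approx(wilcoxon_full_enumeration(d))

    def test_all_positive_extreme(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r = wilcoxon_paired(d, np.zeros(6))
        assert r.p_value == pytest.approx(2.0 / 64.0)

    def test_identical_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = wilcoxon_paired(x, x)
        assert r.degenerate and r.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = rng.normal(0.5, 2.0, n)
        d = np.where(d == 0, 0.5, d)
        r = wilcoxon_paired(d, np.zeros(n))
        assert r.p_value == pytest.approx(wilcoxon_full_enumeration(d), abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, -2.0, 3.0, 1.0])
        r = wilcoxon_paired(d, np.zeros(7))
        assert r.p_value == pytest.approx(wilcoxon_full_enumeration(d), abs=1e-12)

    def test_normal_approximation_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        d = rng.normal(0.8, 2.0, 40)
        r = wilcoxon_paired(d, np.zeros(40))
        assert r.method == "normal"
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_nonzero(self):
        with pytest.raises(SampleSizeError):
            wilcoxon_paired([1.0, 2.0, 0.0, 0.0, 0.0], np.zeros(5))


# --------------------------------------------------------------------------
# concordance and reports
# --------------------------------------------------------------------------

def _cohort_from_volumes(pairs_a, pairs_b):
    va = [mismatch_profile(i, p) for i, p in pairs_a]
    vb = [mismatch_profile(i, p) for i, p in pairs_b]
    return PairedCohort(
        case_ids=[f"c{i}" for i in range(len(va))],
        volumes_a=va,
        volumes_b=vb,
        decisions_a=[triage_defuse3(v) for v in va],
        decisions_b=[triage_defuse3(v) for v in vb],
    )


class TestTriageConcordance:
    def test_identical_decisions(self):
        pairs = [(10, 80), (90, 120), (5, 50), (30, 40)]
        table = triage_concordance(_cohort_from_volumes(pairs, pairs))
        assert table.overall_rate == 1.0
        assert table.icc == 1.0

    def test_one_discordant_hand_tally(self):
        a = [(10.0, 80.0), (20.0, 90.0), (30.0, 100.0), (70.0, 100.0)]
        b = [(10.0, 80.0), (20.0, 90.0), (30.0, 100.0), (50.0, 100.0)]
        table = triage_concordance(_cohort_from_volumes(a, b))
        assert table.overall_rate == pytest.approx(0.75)
        high = table.subgroups[0]
        low = table.subgroups[1]
        assert high.n == 1 and high.concordant == 0  # icv_a = 70 goes high
        assert low.n == 3 and low.concordant == 3
        assert high.eligible_a == 0 and high.eligible_b == 1

    def test_subgroups_partition_cohort(self):
        cohort = simulate_paired_cohort(57, bias=2.0, sd=6.0, seed=2)
        table = triage_concordance(cohort)
        assert sum(s.n for s in table.subgroups) == len(cohort)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            triage_concordance(PairedCohort([], [], [], [], []))


class TestSimulationRecovery:
    def test_bias_and_loa_coverage(self):
        bias, sd, n = 3.5, 5.0, 200
        cohort = simulate_paired_cohort(n, bias=bias, sd=sd, seed=20240101)
        icv_a = np.array([v.icv for v in cohort.volumes_a])
        icv_b = np.array([v.icv for v in cohort.volumes_b])
        report = agreement_report(icv_a, icv_b, measure="icv")
        # differences are reference (A) minus comparator (B) = -bias
        assert abs(report.mean_diff - (-bias)) < 2 * sd / math.sqrt(n)
        d = icv_a - icv_b
        coverage = np.mean((d >= report.loa_low) & (d <= report.loa_high))
        assert 0.92 <= coverage <= 0.98

    def test_report_invariants(self):
        cohort = simulate_paired_cohort(60, bias=1.0, sd=4.0, seed=3)
        x = [v.pv for v in cohort.volumes_a]
        y = [v.pv for v in cohort.volumes_b]
        r = agreement_report(x, y, measure="pv")
        assert r.loa_low <= r.mean_diff <= r.loa_high
        assert 0 <= r.wilcoxon_p <= 1
        assert -1 <= r.icc <= 1
        assert r.icc_band == interpret_icc(r.icc)
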