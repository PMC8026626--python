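import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from enfacedme import reference as ref
from enfacedme.cohort import CohortTable, EyeRecord
from enfacedme.stats import (
    GroupSummary,
    SeparationError,
    anova_oneway,
    chi_square_independence,
    kruskal_wallis,
    logistic_regression,
    pooled_mean_sd,
    pooled_proportion,
    table2_report,
    two_sample_t,
)


# ---------------------------------------------------------------------------
# pooling


def test_pooled_proportion_worked_examples():
    assert pooled_proportion([(0, 24), (5, 25)]) == pytest.approx(5 / 49)
    assert round(100 * pooled_proportion([(0, 24), (5, 25)]), 1) == 10.2
    assert pooled_proportion([(5, 16), (25, 37), (25, 26)]) == pytest.approx(55 / 79)
    assert round(100 * pooled_proportion([(5, 16), (25, 37), (25, 26)]), 1) == 69.6
    assert pooled_proportion([(0, 10)]) == 0.0
    with pytest.raises(ValueError):
        pooled_proportion([(5, 3)])


def test_pooled_mean_sd_worked_examples():
    dry = pooled_mean_sd([GroupSummary(24, 304.4, 42.7), GroupSummary(25, 385.2, 80.4)])
    assert dry.mean == pytest.approx(345.6, abs=0.1)
    wet = pooled_mean_sd([GroupSummary(16, 420.8, 82.4), GroupSummary(37, 407.9, 129.0),
                          GroupSummary(26, 493.5, 106.0)])
    assert wet.mean == pytest.approx(438.68, abs=0.01)
    single = GroupSummary(12, 100.0, 7.0)
    assert pooled_mean_sd([single]) == single


def test_pooling_matches_concatenated_raw_data():
    rng = np.random.default_rng(3)
    a, b = rng.normal(10, 2, 21), rng.normal(14, 3, 34)
    ga = GroupSummary(len(a), float(a.mean()), float(a.std(ddof=1)))
    gb = GroupSummary(len(b), float(b.mean()), float(b.std(ddof=1)))
    pooled = pooled_mean_sd([ga, gb])
    both = np.concatenate([a, b])
    assert pooled.mean == pytest.approx(both.mean())
    assert pooled.sd == pytest.approx(both.std(ddof=1))
    events = [(int((a > 11).sum()), len(a)), (int((b > 11).sum()), len(b))]
    assert pooled_proportion(events) == pytest.approx((both > 11).mean(), abs=0.02)


# ---------------------------------------------------------------------------
# χ²


def test_chi_square_matches_brute_force():
    table = np.array([[5, 44], [55, 24]], dtype=float)
    stat, df, p = chi_square_independence(table)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    brute = ((table - expected) ** 2 / expected).sum()
    assert stat == pytest.approx(brute)
    assert df == 1
    assert p < 0.001  # pooled EZ-disruption comparison


def test_chi_square_degenerate_cases():
    stat, _, p = chi_square_independence([[10, 10], [10, 10]])
    assert stat == 0.0 and p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chi_square_independence([[0, 0], [5, 3]])
    with pytest.raises(ValueError):
        chi_square_independence([[-1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# t / ANOVA / KW


def test_pooled_cst_comparison_is_significant():
    dry = GroupSummary(49, 345.65, 75.83)
    wet = GroupSummary(79, 438.69, 119.44)
    for mode in ("pooled", "welch"):
        _, _, p = two_sample_t(dry, wet, mode)
        assert p < 0.001


def test_identical_groups_give_t_zero():
    g = GroupSummary(10, 5.0, 1.0)
    t, _, p = two_sample_t(g, g)
    assert t == 0.0 and p == pytest.approx(1.0)


def test_t_matches_permutation_oracle():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0.0, 1.0, 10), rng.normal(1.0, 1.0, 10)
    ga = GroupSummary(10, float(a.mean()), float(a.std(ddof=1)))
    gb = GroupSummary(10, float(b.mean()), float(b.std(ddof=1)))
    t_obs, _, p_t = two_sample_t(ga, gb, "pooled")
    both = np.concatenate([a, b])
    count = 0
    n_perm = 20000
    for _ in range(n_perm):
        perm = rng.permutation(both)
        d = perm[:10].mean() - perm[10:].mean()
        obs = a.mean() - b.mean()
        count += abs(d) >= abs(obs) - 1e-12
    p_perm = count / n_perm
    assert p_t == pytest.approx(p_perm, abs=0.03)


def test_two_group_anova_equals_t_squared():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
    F, p_f = anova_oneway([a, b])
    ga = GroupSummary(12, float(a.mean()), float(a.std(ddof=1)))
    gb = GroupSummary(15, float(b.mean()), float(b.std(ddof=1)))
    t, _, p_t = two_sample_t(ga, gb, "pooled")
    assert F == pytest.approx(t**2)
    assert p_f == pytest.approx(p_t)


def test_kruskal_wallis_matches_rank_formula():
    groups = [np.array([1.0, 3.0, 5.0]), np.array([2.0, 4.0, 8.0]), np.array([6.0, 7.0, 9.0])]
    H, p = kruskal_wallis(groups)
    # brute-force rank formula (no ties)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    assert H == pytest.approx(h)


def test_kruskal_wallis_all_identical_is_zero():
    assert kruskal_wallis([np.ones(4), np.ones(5)]) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# logistic regression


def test_single_binary_predictor_matches_cross_product_ratio():
    # saturated 2x2: OR must equal (a*d)/(b*c)
    x = np.repeat([0, 0, 1, 1], [30, 10, 12, 28]).astype(float)
    y = np.repeat([0, 1, 0, 1], [30, 10, 12, 28]).astype(float)
    fit = logistic_regression(y, {"x": x})
    cross_product = (28 * 30) / (10 * 12)
    assert fit.loc["x", "odds_ratio"] == pytest.approx(cross_product, rel=1e-4)


def test_logistic_recovers_known_coefficient():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(500)
    y = (rng.uniform(size=500) < 1.0 / (1.0 + np.exp(-1.5 * x))).astype(float)
    fit = logistic_regression(y, {"x": x})
    assert abs(fit.loc["x", "coef"] - 1.5) <= 0.3


def test_null_ci_covers_one_at_nominal_rate():
    rng = np.random.default_rng(7)
    covered = 0
    for _ in range(100):
        x = rng.standard_normal(60)
        y = (rng.uniform(size=60) < 0.5).astype(float)
        try:
            fit = logistic_regression(y, {"x": x})
        except SeparationError:
            continue
        covered += fit.loc["x", "or_ci_low"] <= 1.0 <= fit.loc["x", "or_ci_high"]
    assert covered >= 90


def test_perfect_separation_is_flagged():
    x = np.concatenate([np.zeros(10), np.ones(10)])
    y = x.copy()
    with pytest.raises(SeparationError):
        logistic_regression(y, {"x": x})


# ---------------------------------------------------------------------------
# cohort report


def _synthetic_cohort(seed=0):
    rng = np.random.default_rng(seed)
    records = []
    counts = ref.type_counts()
    i = 0
    for label, n in counts.items():
        info = ref.PUBLISHED_COHORT[label]
        for _ in range(n):
            erm = rng.uniform() < info["n_erm"] / n
            records.append(EyeRecord(
                eye_id=f"e{i}", age_years=float(rng.normal(*info["age_years"])),
                sex="F" if rng.uniform() < info["n_female"] / n else "M",
                hba1c_pct=float(rng.normal(*info["hba1c_pct"])),
                bcva_logmar=float(abs(rng.normal(*info["bcva_logmar"]))),
                type_label=label,
                cst_um=float(abs(rng.normal(*info["cst_um"])) + 1.0),
                ez_disrupted=bool(rng.uniform() < info["n_ez_disrupted"] / n),
                erm_present=erm,
                mdrf_um=float(abs(rng.normal(*info["mdrf_um"]))) if erm else None,
                pvd_incomplete=bool(rng.uniform() < info["n_pvd_incomplete"] / n),
            ))
            i += 1
    return CohortTable(records)


def test_table_report_counts_and_percentages():
    cohort = _synthetic_cohort()
    report = table2_report(cohort)
    assert report["n_total"] == 128
    assert sum(b["n"] for b in report["types"].values()) == 128
    pcts = [round(report["types"][t]["pct"], 1) for t in ref.TYPE_ORDER]
    assert pcts == [18.8, 19.5, 12.5, 28.9, 20.3]
    assert "cst_um" in report["segment2_pooled"]
    assert report["segment2_pooled"]["cst_um"]["p"] <= 1.0


def test_degenerate_cohort_report_has_no_tests():
    records = [EyeRecord("only", 60.0, "F", 7.0, 0.2, "FC/NF", 300.0,
                         False, False, None, False)]
    report = table2_report(CohortTable(records))
    assert report["types"]["FC/NF"]["n"] == 1
    assert report["tests"] == {}
    assert report["segment2_pooled"] == {}
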