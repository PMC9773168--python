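"""Inferential battery: oracles, algebraic identities, error calibration."""

import numpy as np
import pandas as pd
import pytest

from cinestrain.stats import (
    ContrastSpec,
    bonferroni_alpha,
    bootstrap_ci,
    default_contrasts,
    oneway_anova,
    pearson,
    planned_contrast,
    run_battery,
    students_t,
)


def _pooled_t_by_hand(a, b):
    """Independent textbook pooled-variance t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def test_students_t_matches_textbook_formula():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = students_t(a, b)
    assert res.statistic == pytest.approx(_pooled_t_by_hand(a, b))
    assert res.df == 4
    swapped = students_t(b, a)
    assert swapped.statistic == pytest.approx(-res.statistic)
    assert swapped.p == pytest.approx(res.p)


def test_students_t_degenerate_variance():
    same = students_t([2.0, 2.0], [2.0, 2.0])
    assert same.statistic == 0.0 and same.p == 1.0 and same.degenerate
    diff = students_t([2.0, 2.0], [3.0, 3.0])
    assert np.isinf(diff.statistic) and diff.p == 0.0 and diff.degenerate


def test_identical_samples_give_t_zero():
    x = np.arange(10.0)
    res = students_t(x, x)
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_two_group_anova_f_equals_t_squared():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
    f, df1, df2, p_f = oneway_anova([a, b])
    t_res = students_t(a, b)
    assert f == pytest.approx(t_res.statistic**2, rel=1e-12)
    assert p_f == pytest.approx(t_res.p, rel=1e-12)
    assert (df1, df2) == (1, 25)


def test_anova_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(3)
    groups = [rng.normal(m, 1, 20) for m in (0.0, 0.3, 0.1)]
    f, df1, df2, p = oneway_anova(groups)
    df = pd.DataFrame(
        {"y": np.concatenate(groups), "g": np.repeat(["a", "b", "c"], 20)}
    )
    table = sm.stats.anova_lm(smf.ols("y ~ C(g)", df).fit())
    assert f == pytest.approx(table["F"].iloc[0], rel=1e-9)
    assert p == pytest.approx(table["PR(>F)"].iloc[0], rel=1e-9)


def test_anova_null_rejection_rate_near_alpha():
    rng = np.random.default_rng(4)
    rejections = 0
    reps = 2000
    for _ in range(reps):
        groups = [rng.normal(0, 1, 10) for _ in range(4)]
        _, _, _, p = oneway_anova(groups)
        rejections += p <= 0.05
    rate = rejections / reps
    assert 0.035 <= rate <= 0.065  # ±3 binomial SD around 0.05


def test_contrast_on_identical_groups_is_null():
    g = {"a": np.ones(10), "b": np.ones(10)}
    spec = ContrastSpec("a vs b", {"a": 1.0, "b": -1.0})
    res = planned_contrast(g, spec)
    assert res.estimate == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_two_cell_contrast_equals_pooled_t():
    rng = np.random.default_rng(5)
    g = {"a": rng.normal(0, 1, 14), "b": rng.normal(0.4, 1, 18)}
    spec = ContrastSpec("a vs b", {"a": 1.0, "b": -1.0})
    res = planned_contrast(g, spec)
    t_res = students_t(g["a"], g["b"])
    assert res.statistic == pytest.approx(t_res.statistic, rel=1e-12)
    assert res.p == pytest.approx(t_res.p, rel=1e-12)


def test_contrast_weight_validation():
    with pytest.raises(ValueError):
        ContrastSpec("bad", {"a": 1.0, "b": -0.5})
    with pytest.raises(ValueError):
        ContrastSpec("bad", {"a": 0.0, "b": 0.0})  # no signed weights at all
    spec = ContrastSpec("ok", {"a": 1.0, "b": -1.0})
    with pytest.raises(ValueError):
        planned_contrast({"a": np.ones(3), "b": np.array([])}, spec)


@pytest.mark.parametrize("m, expected", [(17, 0.003), (1, 0.05), (5, 0.01)])
def test_bonferroni_threshold(m, expected):
    assert bonferroni_alpha(m) == expected


def test_seventeen_default_contrasts_zero_sum():
    specs = default_contrasts()
    assert len(specs) == 17
    for spec in specs:
        w = np.array(list(spec.weights.values()))
        assert np.isclose(w.sum(), 0.0)
    lumped = next(s for s in specs if s.name == "All Males Healthy vs All Females Healthy")
    assert sorted(lumped.weights.values()) == pytest.approx([-1 / 3] * 3 + [1 / 3] * 3)


def test_bootstrap_ci_deterministic_and_degenerate():
    x = np.random.default_rng(6).normal(0, 1, 50)
    assert bootstrap_ci(x, seed=3) == bootstrap_ci(x, seed=3)
    lo, hi = bootstrap_ci(np.full(20, 7.0), seed=0)
    assert lo == hi == 7.0


def test_bootstrap_ci_coverage_on_normal_mean():
    rng = np.random.default_rng(7)
    hits, reps = 0, 400
    for i in range(reps):
        x = rng.normal(0, 1, 100)
        lo, hi = bootstrap_ci(x, np.mean, reps=1000, seed=rng)
        hits += lo <= 0.0 <= hi
    assert 0.90 <= hits / reps <= 0.98


def test_bootstrap_ci_shrinks_with_n():
    rng = np.random.default_rng(8)
    widths = []
    for n in (25, 100, 400):
        x = rng.normal(0, 1, n)
        lo, hi = bootstrap_ci(x, np.mean, reps=1000, seed=1)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_pearson_exact_and_null():
    x = np.arange(20.0)
    res = pearson(x, 2 * x)
    assert res.r == pytest.approx(1.0)
    res_neg = pearson(x, -x)
    assert res_neg.r == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson(x, np.zeros(20))


def test_pearson_null_r_small_at_large_n():
    rng = np.random.default_rng(9)
    res = pearson(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000), bootstrap_reps=200, seed=1)
    assert abs(res.r) < 0.1
    assert res.ci[0] < res.r < res.ci[1]


def _synthetic_table(rng, n_per_cell=12, mcs_shift=None):
    """Flat subject table over the 12 cells with N(0,1) noise variables."""
    rows = []
    for sex in ("male", "female"):
        for health in ("healthy", "unhealthy"):
            for band in ("45-54", "55-64", "65-74"):
                for _ in range(n_per_cell):
                    row = {
                        "sex": sex,
                        "health": health,
                        "age_band": band,
                        "age": rng.uniform(*[int(b) for b in band.split("-")]),
                        "BSA": rng.normal(1.85, 0.2),
                    }
                    for var in ("ESV", "EDV", "LVEF", "ESVi", "ACS", "MCS", "BCS", "GCS"):
                        row[var] = rng.normal(0.0, 1.0)
                    if mcs_shift and sex == "male" and health == "healthy":
                        row["BCS"] += mcs_shift
                    rows.append(row)
    return pd.DataFrame(rows)


def test_run_battery_shapes_and_threshold():
    rng = np.random.default_rng(10)
    table = _synthetic_table(rng, n_per_cell=8)
    res = run_battery(table, bootstrap_reps=100, seed=0, anova_gate=False)
    assert res.contrast_threshold == 0.003
    # 9 variables × 2 lumped t-tests
    assert len(res.t_tests) == 18
    assert len(res.anova) == 9
    assert len(res.contrasts) <= 9 * 17
    assert len(res.contrasts) % 17 == 0
    assert res.contrasts["p"].between(0, 1).all()
    # correlations: 4 lumped groups × 8 variables × {age, BSA}
    assert len(res.correlations) == 64


def test_battery_power_detects_planted_sex_difference():
    """A 1.5-SD healthy male/female BCS offset at n=40/cell is flagged by
    the lumped sex contrast at the corrected threshold."""
    rng = np.random.default_rng(11)
    table = _synthetic_table(rng, n_per_cell=40, mcs_shift=1.5)
    res = run_battery(table, bootstrap_reps=100, seed=0)
    sig = res.significant_contrasts
    assert (
        (sig["variable"] == "BCS")
        & (sig["comparison"] == "All Males Healthy vs All Females Healthy")
    ).any()


def test_gated_battery_familywise_error_controlled():
    """Under a global null the ANOVA gate plus Bonferroni keeps the
    familywise rejection rate of the 17-contrast battery at or below ~5%."""
    rng = np.random.default_rng(12)
    specs = default_contrasts()
    threshold = bonferroni_alpha(len(specs))
    reps, families_rejected = 600, 0
    for _ in range(reps):
        cells = {}
        for sex in ("male", "female"):
            for health in ("healthy", "unhealthy"):
                for band in ("45-54", "55-64", "65-74"):
                    cells[f"{sex}_{health}_{band}"] = rng.normal(0, 1, 15)
        _, _, _, p = oneway_anova(cells)
        if p > 0.05:
            continue
        any_hit = any(
            planned_contrast(cells, spec, threshold=threshold).significant for spec in specs
        )
        families_rejected += any_hit
    rate = families_rejected / reps
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
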