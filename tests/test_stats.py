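"""Statistical layer: degrees of freedom, degenerate cases, and agreement
with independent reference implementations (pingouin, scipy, statsmodels)."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from periplaque import (
    dunnett_pvalues,
    oneway_anova_dunnett,
    rm_anova_dunnett,
    twoway_anova,
    unpaired_t,
)


BIN_COLS = ["plaque", "0-5 um", "5-15 um", "15-25 um", "25-35 um"]


@pytest.fixture(scope="module")
def rm_fixture():
    rng = np.random.default_rng(17)
    mat = rng.normal(size=(3, 5)) * 2 + np.array([5.0, 6.0, 20.0, 21.0, 22.0])
    return pd.DataFrame(mat, columns=BIN_COLS)


# ---------------------------------------------------------------------------
# repeated measures


def test_rm_anova_df_matches_design(rm_fixture):
    """3 subjects x 5 bins: df = (4, 8)."""
    res = rm_anova_dunnett(rm_fixture, reference="25-35 um")
    assert res.df == (4.0, 8.0)


def test_rm_anova_identical_values_gives_null(rm_fixture):
    flat = pd.DataFrame(
        np.repeat([[1.0], [2.0], [3.0]], 5, axis=1), columns=BIN_COLS
    )
    res = rm_anova_dunnett(flat, reference="25-35 um")
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert all(p == 1.0 for _, p in res.posthoc)


def test_rm_anova_matches_pingouin(rm_fixture):
    pg = pytest.importorskip("pingouin")
    long = rm_fixture.reset_index().melt(
        id_vars="index", var_name="bin", value_name="y"
    )
    aov = pg.rm_anova(
        data=long, dv="y", within="bin", subject="index", detailed=True
    )
    res = rm_anova_dunnett(rm_fixture, reference="25-35 um")
    assert res.statistic == pytest.approx(float(aov.loc[0, "F"]), abs=1e-8)
    assert res.p_value == pytest.approx(float(aov.loc[0, "p_unc"]), abs=1e-8)


def test_rm_anova_rejects_missing_cells(rm_fixture):
    bad = rm_fixture.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="complete"):
        rm_anova_dunnett(bad)


def test_rm_dunnett_adjusted_at_least_unadjusted(rm_fixture):
    res = rm_anova_dunnett(rm_fixture, reference="25-35 um")
    mat = rm_fixture.to_numpy()
    n, k = mat.shape
    mse = res.extra["mse"]
    se = np.sqrt(2 * mse / n)
    ref = mat[:, -1].mean()
    for (label, p_adj), col in zip(res.posthoc, range(k - 1)):
        t = (mat[:, col].mean() - ref) / se
        p_raw = 2 * sps.t.sf(abs(t), (k - 1) * (n - 1))
        assert p_adj >= p_raw - 1e-12


# ---------------------------------------------------------------------------
# one-way ANOVA + Dunnett


def test_two_groups_f_equals_t_squared():
    rng = np.random.default_rng(4)
    g1, g2 = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
    res = oneway_anova_dunnett({"a": g1, "ref": g2}, reference="ref")
    t = unpaired_t(g1, g2)
    assert res.statistic == pytest.approx(t.statistic**2, abs=1e-10)
    assert res.p_value == pytest.approx(t.p_value, abs=1e-10)


def test_oneway_df_matches_axon_design():
    """4 groups totalling 361 axons: df = (3, 357)."""
    rng = np.random.default_rng(1)
    groups = {
        "0-5 um": rng.normal(12, 3, 90),
        "5-15 um": rng.normal(10, 3, 90),
        "15-25 um": rng.normal(10, 3, 90),
        "25-35 um": rng.normal(10, 3, 91),
    }
    res = oneway_anova_dunnett(groups, reference="25-35 um")
    assert res.df == (3.0, 357.0)


def test_oneway_matches_statsmodels_and_scipy():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(23)
    groups = {g: rng.normal(m, 1.0, n) for g, m, n in
              [("a", 0.0, 9), ("b", 0.6, 12), ("ref", 0.1, 10)]}
    res = oneway_anova_dunnett(groups, reference="ref")
    df = pd.DataFrame(
        [(g, v) for g, arr in groups.items() for v in arr], columns=["g", "y"]
    )
    table = sm.stats.anova_lm(smf.ols("y ~ C(g)", data=df).fit(), typ=2)
    assert res.statistic == pytest.approx(float(table.loc["C(g)", "F"]), abs=1e-8)
    assert res.p_value == pytest.approx(float(table.loc["C(g)", "PR(>F)"]), abs=1e-8)


@pytest.mark.parametrize("balanced", [True, False])
def test_dunnett_matches_scipy_oracle(balanced):
    """Adjusted p-values agree with scipy.stats.dunnett to within that
    oracle's own quasi-Monte-Carlo integration accuracy."""
    rng = np.random.default_rng(31)
    ns = (10, 10, 10, 10) if balanced else (7, 13, 9, 16)
    arrs = [rng.normal(0.5 * i, 1.0, n) for i, n in enumerate(ns)]
    groups = {f"g{i}": a for i, a in enumerate(arrs[:-1])}
    groups["ref"] = arrs[-1]
    res = oneway_anova_dunnett(groups, reference="ref")
    oracle = sps.dunnett(*arrs[:-1], control=arrs[-1])
    mine = np.array([p for _, p in res.posthoc])
    np.testing.assert_allclose(mine, oracle.pvalue, atol=5e-4)


def test_dunnett_determinism():
    lam = np.full(3, np.sqrt(0.5))
    p1 = dunnett_pvalues([2.0, -1.0, 3.5], df=8, lambdas=lam)
    p2 = dunnett_pvalues([2.0, -1.0, 3.5], df=8, lambdas=lam)
    np.testing.assert_array_equal(p1, p2)
    assert np.all((p1 >= 0) & (p1 <= 1))


def test_oneway_small_group_raises():
    with pytest.raises(ValueError, match="g1"):
        oneway_anova_dunnett({"g0": [1.0, 2.0], "g1": [1.0]}, reference="g0")


# ---------------------------------------------------------------------------
# two-way ANOVA


def _twoway_frame(ns, rng, effect=0.0):
    rows = []
    for (a, b), n in ns.items():
        for _ in range(n):
            rows.append((a, b, rng.normal(effect * (a == "amyloid"), 1.0)))
    return pd.DataFrame(rows, columns=["genotype", "age", "y"])


def test_twoway_error_df_matches_subject_design():
    """2x2 subject design with n = 3,3,4,4 gives error df = 10."""
    rng = np.random.default_rng(2)
    ns = {
        ("control", "6-8"): 3, ("amyloid", "6-8"): 3,
        ("control", "12"): 4, ("amyloid", "12"): 4,
    }
    res = twoway_anova(_twoway_frame(ns, rng), "y", "genotype", "age")
    assert res.df[1] == 10.0
    for term in res.extra["terms"].values():
        assert term["df"] == (1.0, 10.0)


def test_twoway_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(9)
    ns = {
        ("control", "6-8"): 3, ("amyloid", "6-8"): 3,
        ("control", "12"): 4, ("amyloid", "12"): 4,
    }
    data = _twoway_frame(ns, rng, effect=1.0)
    res = twoway_anova(data, "y", "genotype", "age")
    aov = pg.anova(
        data=data, dv="y", between=["genotype", "age"], ss_type=2
    ).set_index("Source")
    for term, key in [("genotype", "genotype"), ("age", "age"),
                      ("genotype*age", "genotype * age")]:
        assert res.extra["terms"][term]["F"] == pytest.approx(
            float(aov.loc[key, "F"]), abs=1e-8
        )
        assert res.extra["terms"][term]["p"] == pytest.approx(
            float(aov.loc[key, "p_unc"]), abs=1e-8
        )


def test_twoway_null_calibration():
    """With no true effects the three tests reject at ~alpha."""
    rng = np.random.default_rng(77)
    ns = {(a, b): 6 for a in ("control", "amyloid") for b in ("young", "old")}
    rej = np.zeros(3)
    reps = 200
    for _ in range(reps):
        res = twoway_anova(_twoway_frame(ns, rng), "y", "genotype", "age")
        ps = [t["p"] for t in res.extra["terms"].values()]
        rej += np.asarray(ps) < 0.05
    assert np.all((rej / reps >= 0.01) & (rej / reps <= 0.11))


def test_twoway_empty_cell_raises():
    rng = np.random.default_rng(0)
    ns = {("control", "6-8"): 3, ("amyloid", "6-8"): 3, ("control", "12"): 3}
    with pytest.raises(ValueError, match="per cell"):
        twoway_anova(_twoway_frame(ns, rng), "y", "genotype", "age")


# ---------------------------------------------------------------------------
# t test


def test_unpaired_t_basics():
    rng = np.random.default_rng(5)
    g1, g2 = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
    res = unpaired_t(g1, g2)
    assert res.df == (6.0,)
    ref_t, ref_p = sps.ttest_ind(g1, g2, equal_var=True)
    assert res.statistic == pytest.approx(ref_t, abs=1e-12)
    assert res.p_value == pytest.approx(ref_p, abs=1e-12)


def test_unpaired_t_identical_groups():
    g = np.array([1.0, 1.0, 1.0])
    res = unpaired_t(g, g)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_unpaired_t_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(13)
    g1, g2 = rng.normal(60, 5, 4), rng.normal(55, 5, 4)
    res = unpaired_t(g1, g2)
    tt = pg.ttest(g1, g2, correction=False)
    assert res.statistic == pytest.approx(float(tt["T"].iloc[0]), abs=1e-8)
    assert res.p_value == pytest.approx(float(tt["p_val"].iloc[0]), abs=1e-8)


def test_t_and_oneway_type1_calibration():
    """Under a normal null both tests reject at ~alpha = 0.05."""
    rng = np.random.default_rng(99)
    rej_t = rej_f = 0
    reps = 400
    for _ in range(reps):
        g = [rng.normal(0, 1, 8) for _ in range(4)]
        if unpaired_t(g[0], g[1]).p_value < 0.05:
            rej_t += 1
        res = oneway_anova_dunnett(
            {f"g{i}": gi for i, gi in enumerate(g)}, reference="g3"
        )
        if res.p_value < 0.05:
            rej_f += 1
    assert 0.01 <= rej_t / reps <= 0.11
    assert 0.01 <= rej_f / reps <= 0.11
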