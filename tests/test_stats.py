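"""Correlations, ANOVA machinery, EMM contrasts, Holm, and the normality screen."""

import math

import numpy as np
import pandas as pd
import pytest

from intelligibility.errors import DegenerateInputError
from intelligibility.stats import (
    cell_means_contrasts,
    emm_pairwise,
    holm_adjust,
    normality_screen,
    pearson,
    pooled_error_variance,
    split_plot_anova,
    subgroup_regressions,
    tukey_p,
    two_way_anova,
)


# ---------------------------------------------------------------------------
# Pearson


def test_pearson_perfect_linear():
    x = np.array([1.0, 2, 3, 5, 8])
    assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
    assert pearson(x, -x).r == pytest.approx(-1.0)


def test_pearson_six_point_toy_matches_hand_formula():
    x = np.array([0.1, 0.4, 0.35, 0.8, 0.9, 0.55])
    y = np.array([0.2, 0.5, 0.3, 0.7, 0.95, 0.4])
    n = 6
    r_hand = float(np.sum((x - x.mean()) * (y - y.mean()))
                   / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    t = r_hand * math.sqrt((n - 2) / (1 - r_hand**2))
    from scipy.stats import t as tdist

    p_hand = 2 * tdist.sf(abs(t), n - 2)
    res = pearson(x, y)
    assert res.r == pytest.approx(r_hand, rel=1e-12)
    assert res.p == pytest.approx(p_hand, rel=1e-9)
    assert res.n == n


def test_pearson_degenerate_input():
    with pytest.raises(DegenerateInputError):
        pearson([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# two-way ANOVA


def _balanced_closed_form(y, a, b):
    """Classical balanced two-way decomposition from cell/marginal means."""
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = df["y"].mean()
    na, nb = df["a"].nunique(), df["b"].nunique()
    n_cell = len(df) / (na * nb)
    ma = df.groupby("a")["y"].mean()
    mb = df.groupby("b")["y"].mean()
    mab = df.groupby(["a", "b"])["y"].mean()
    ss_a = n_cell * nb * float(((ma - grand) ** 2).sum())
    ss_b = n_cell * na * float(((mb - grand) ** 2).sum())
    ss_cells = n_cell * float(((mab - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = float(((df["y"] - df.set_index(["a", "b"]).index.map(mab)) ** 2).sum())
    return ss_a, ss_b, ss_ab, ss_err


def test_two_way_anova_balanced_matches_closed_form():
    rng = np.random.default_rng(3)
    a = np.repeat(["x", "y"], 12)
    b = np.tile(np.repeat(["u", "v"], 6), 2)
    y = rng.normal(size=24) + (a == "x") * 0.5 + (b == "u") * 0.2
    res = two_way_anova(y, a, b)
    ss_a, ss_b, ss_ab, ss_err = _balanced_closed_form(y, a, b)
    assert res.effects["A"].ss == pytest.approx(ss_a, rel=1e-10)
    assert res.effects["B"].ss == pytest.approx(ss_b, rel=1e-10)
    assert res.effects["A:B"].ss == pytest.approx(ss_ab, rel=1e-10)
    assert res.ss_error == pytest.approx(ss_err, rel=1e-10)
    for eff in res.effects.values():
        assert eff.partial_eta_sq == pytest.approx(eff.ss / (eff.ss + ss_err), rel=1e-10)


def test_two_way_anova_unbalanced_df_bookkeeping():
    rng = np.random.default_rng(4)
    sizes = {("hebrew", "DS"): 24, ("hebrew", "TD"): 24,
             ("english", "DS"): 8, ("english", "TD"): 6}
    rows = [(lang, grp) for (lang, grp), n in sizes.items() for _ in range(n)]
    a = [r[0] for r in rows]
    b = [r[1] for r in rows]
    y = rng.normal(size=len(rows))
    res = two_way_anova(y, a, b)
    assert res.df_error == 62 - 4
    assert all(e.df == 1 for e in res.effects.values())


def test_two_way_anova_degenerate_flagged():
    a = np.repeat(["x", "y"], 4)
    b = np.tile(["u", "v"], 4)
    y = np.where(a == "x", 1.0, 2.0)  # no within-cell variance
    res = two_way_anova(y, a, b)
    assert res.degenerate
    assert math.isnan(res.effects["A"].F)


def test_two_way_anova_empty_cell_raises():
    with pytest.raises(DegenerateInputError):
        two_way_anova([1, 2, 3], ["x", "x", "y"], ["u", "v", "u"])


# ---------------------------------------------------------------------------
# EMM contrasts


def test_emm_contrasts_equal_cell_mean_differences_unbalanced():
    rng = np.random.default_rng(5)
    sizes = [("a", "p", 11), ("a", "q", 4), ("b", "p", 7), ("b", "q", 19)]
    a, b, y = [], [], []
    for fa, fb, n in sizes:
        a += [fa] * n
        b += [fb] * n
        y += list(rng.normal(loc=hash((fa, fb)) % 5, size=n))
    res = two_way_anova(y, a, b)
    rows = emm_pairwise(res)
    for row in rows:
        left, right = row.label.split(" - ")
        assert row.estimate == pytest.approx(
            res.cell_means[left] - res.cell_means[right], rel=1e-10
        )
        assert row.t_ratio == pytest.approx(row.estimate / row.se, rel=1e-10)


def test_emm_se_and_t_against_pooled_variance_formulas():
    # 2x2 toy, hand-computed pooled variance
    data = {
        ("a", "p"): [1.0, 2.0, 3.0],
        ("a", "q"): [2.0, 4.0],
        ("b", "p"): [0.0, 1.0, 2.0, 3.0],
        ("b", "q"): [5.0, 6.0, 7.0],
    }
    a = [k[0] for k, v in data.items() for _ in v]
    b = [k[1] for k, v in data.items() for _ in v]
    y = [x for v in data.values() for x in v]
    res = two_way_anova(y, a, b)
    sse = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in data.values())
    dfe = sum(len(v) - 1 for v in data.values())
    mse = sse / dfe
    rows = {r.label: r for r in emm_pairwise(res)}
    r = rows["a p - b q"]
    se_hand = math.sqrt(mse * (1 / 3 + 1 / 3))
    assert r.se == pytest.approx(se_hand, rel=1e-10)
    assert r.t_ratio == pytest.approx((2.0 - 6.0) / se_hand, rel=1e-10)
    assert r.df == dfe


def test_identical_cell_means_give_zero_estimate_and_p_one():
    means = {"a": 0.5, "b": 0.5, "c": 0.5}
    ns = {"a": 5, "b": 7, "c": 3}
    rows = cell_means_contrasts(means, ns, mse=0.01, df_error=12)
    for r in rows:
        assert r.estimate == 0.0
        assert r.p_adj == pytest.approx(1.0)


def test_tukey_p_at_least_unadjusted():
    from scipy.stats import t as tdist

    rng = np.random.default_rng(6)
    for _ in range(200):
        t = float(rng.normal(scale=3))
        df = float(rng.integers(3, 60))
        k = int(rng.integers(2, 7))
        raw = 2 * tdist.sf(abs(t), df)
        assert tukey_p(t, k, df) >= raw - 1e-12


def test_pooled_error_variance():
    mse, df = pooled_error_variance([2.0, 3.0], [4, 6])
    assert df == 8
    assert mse == pytest.approx((3 * 4 + 5 * 9) / 8)


# ---------------------------------------------------------------------------
# split-plot ANOVA


def _split_plot_frame(n_per_group=(21, 21), effect=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for g, n in zip(["DS", "TD"], n_per_group):
        for _ in range(n):
            subj_eff = rng.normal(scale=0.2)
            base = 0.5 + (0.3 if g == "TD" else 0.0) + subj_eff
            for w, delta in (("word", effect), ("sentence", 0.0)):
                rows.append((f"s{sid}", g, w, base + delta + rng.normal(scale=0.1)))
            sid += 1
    return pd.DataFrame(rows, columns=["subject", "group", "stimulus", "y"])


def test_split_plot_df_forty_two_subjects():
    df = _split_plot_frame()
    res = split_plot_anova(df["y"], df["group"], df["stimulus"], df["subject"])
    assert res.df_subject_error == 40
    assert res.df_within_error == 40
    assert res.effects["group"].df == 1
    assert res.effects["stimulus"].df == 1


def test_split_plot_zero_within_difference_gives_zero_f():
    df = _split_plot_frame(effect=0.0)
    df["y"] = df.groupby("subject")["y"].transform("mean")  # no within variation
    res = split_plot_anova(df["y"], df["group"], df["stimulus"], df["subject"])
    assert res.effects["stimulus"].ss == pytest.approx(0.0, abs=1e-18)


def test_split_plot_ss_conservation():
    df = _split_plot_frame(seed=2)
    res = split_plot_anova(df["y"], df["group"], df["stimulus"], df["subject"])
    total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    assert res.ss_total == pytest.approx(total, rel=1e-10)


def test_split_plot_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    df = _split_plot_frame(n_per_group=(3, 3), seed=7)
    res = split_plot_anova(df["y"], df["group"], df["stimulus"], df["subject"])
    pg = pingouin.mixed_anova(
        data=df, dv="y", within="stimulus", subject="subject", between="group"
    ).set_index("Source")
    assert res.effects["group"].F == pytest.approx(pg.loc["group", "F"], rel=1e-8)
    assert res.effects["stimulus"].F == pytest.approx(pg.loc["stimulus", "F"], rel=1e-8)
    assert res.effects["group:stimulus"].F == pytest.approx(
        pg.loc["Interaction", "F"], rel=1e-8
    )


def test_split_plot_drops_incomplete_subjects():
    df = _split_plot_frame()
    df = df.drop(df[(df["subject"] == "s0") & (df["stimulus"] == "word")].index)
    res = split_plot_anova(df["y"], df["group"], df["stimulus"], df["subject"])
    assert res.n_subjects == 41
    assert res.n_dropped == 1
    assert res.df_subject_error == 39


def test_split_plot_between_contrast_uses_both_strata():
    df = _split_plot_frame(seed=3)
    res = split_plot_anova(df["y"], df["group"], df["stimulus"], df["subject"])
    rows = {r.label: r for r in emm_pairwise(res)}
    within = rows["DS sentence - DS word"]
    assert within.se == pytest.approx(
        math.sqrt(2 * res.ms_within_error / 21), rel=1e-10
    )
    between = rows["DS word - TD word"]
    se_hand = math.sqrt(
        (res.ms_subject_error + res.ms_within_error) / 2 * (1 / 21 + 1 / 21)
    )
    assert between.se == pytest.approx(se_hand, rel=1e-10)
    for r in rows.values():
        left, right = r.label.split(" - ")
        assert r.estimate == pytest.approx(
            res.cell_means[left] - res.cell_means[right], rel=1e-10
        )


# ---------------------------------------------------------------------------
# Holm and regressions


def test_holm_step_down_formula():
    adj = holm_adjust([0.01, 0.02, 0.03])
    assert adj == pytest.approx([0.03, 0.04, 0.04])


def test_holm_monotone_and_at_least_raw():
    rng = np.random.default_rng(8)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(2, 8))
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def test_subgroup_regressions_collinear_and_flat():
    x = np.array([0.1, 0.3, 0.5, 0.7, 0.2, 0.4, 0.6, 0.8])
    y = np.where(np.arange(8) < 4, 0.5 * x, 0.25)
    labels = ["lin"] * 4 + ["flat"] * 4
    rows = {r.label: r for r in subgroup_regressions(x, y, labels)}
    assert rows["lin"].slope == pytest.approx(0.5)
    assert rows["lin"].r_sq == pytest.approx(1.0)
    assert rows["flat"].slope == pytest.approx(0.0)
    assert rows["flat"].r_sq == pytest.approx(0.0)
    for r in rows.values():
        assert r.p_adj >= r.p_slope - 1e-15


def test_subgroup_regressions_degenerate_x():
    with pytest.raises(DegenerateInputError):
        subgroup_regressions([1, 1, 1], [1, 2, 3], ["g"] * 3)


# ---------------------------------------------------------------------------
# normality screen


def test_normality_screen_symmetric_data():
    res = normality_screen([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
    assert res.skewness == pytest.approx(0.0, abs=1e-12)
    assert res.pass_skew


def test_normality_screen_moment_oracle():
    v = np.array([0.1, 0.15, 0.3, 0.32, 0.5, 0.55, 0.7, 0.95])
    n = len(v)
    m2 = float(np.mean((v - v.mean()) ** 2))
    m3 = float(np.mean((v - v.mean()) ** 3))
    m4 = float(np.mean((v - v.mean()) ** 4))
    g1 = m3 / m2**1.5
    skew_hand = g1 * math.sqrt(n * (n - 1)) / (n - 2)
    g2 = m4 / m2**2 - 3
    kurt_hand = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
    res = normality_screen(v)
    assert res.skewness == pytest.approx(skew_hand, rel=1e-10)
    assert res.kurtosis == pytest.approx(kurt_hand, rel=1e-10)


def test_normality_screen_gaussian_sample_passes():
    rng = np.random.default_rng(9)
    res = normality_screen(rng.normal(size=10_000))
    assert res.pass_skew and res.pass_kurt
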