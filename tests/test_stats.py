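"""Mixed ANOVA against a hand-computed oracle, LSD post hocs, regressions."""

import numpy as np
import pandas as pd
import pytest

from myoquant.stats import aggregate_subject_means, fisher_lsd, pearson_regression, rm_anova


def _cohort(values_by_cell, n):
    """Balanced 2×2 long table; values_by_cell[(g,t)] is an array of length n."""
    rows = []
    for g in ("37Y", "50Y"):
        for s in range(n):
            for t in ("PRE", "POST"):
                rows.append(
                    {
                        "subject": f"{g}_{s}",
                        "group": g,
                        "time": t,
                        "value": values_by_cell[(g, t)][s],
                    }
                )
    return pd.DataFrame(rows)


def _split_plot_oracle(df):
    """Closed-form balanced two-way mixed ANOVA (between: group, within: time)."""
    t_levels = df["time"].unique()
    g_levels = df["group"].unique()
    t, g = len(t_levels), len(g_levels)
    subjects = df["subject"].unique()
    n_total = len(subjects)
    grand = df["value"].mean()
    ms = df.groupby("subject")["value"].mean()
    mg = df.groupby("group")["value"].mean()
    mt = df.groupby("time")["value"].mean()
    mgt = df.groupby(["group", "time"])["value"].mean()
    subj_group = df.drop_duplicates("subject").set_index("subject")["group"]
    n_per = n_total // g

    ss_group = t * n_per * ((mg - grand) ** 2).sum()
    ss_between_subj = t * ((ms - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_time = g * n_per * ((mt - grand) ** 2).sum()
    ss_int = n_per * sum(
        (mgt[(gg, tt)] - mg[gg] - mt[tt] + grand) ** 2 for gg in g_levels for tt in t_levels
    )
    ss_total = ((df["value"] - grand) ** 2).sum()
    ss_resid = ss_total - ss_between_subj - ss_time - ss_int

    f_group = (ss_group / (g - 1)) / (ss_subj_within / (n_total - g))
    f_time = (ss_time / (t - 1)) / (ss_resid / ((t - 1) * (n_total - g)))
    f_int = (ss_int / ((g - 1) * (t - 1))) / (ss_resid / ((t - 1) * (n_total - g)))
    return {"group": f_group, "time": f_time, "group*time": f_int}


def test_rm_anova_matches_hand_computed_split_plot():
    rng = np.random.default_rng(42)
    vals = {
        ("37Y", "PRE"): rng.normal(10, 1, 4),
        ("37Y", "POST"): rng.normal(12, 1, 4),
        ("50Y", "PRE"): rng.normal(10, 1, 4),
        ("50Y", "POST"): rng.normal(10.5, 1, 4),
    }
    df = _cohort(vals, 4)
    aov = rm_anova(df).set_index("effect")["F"]
    oracle = _split_plot_oracle(df)
    for effect, f in oracle.items():
        assert aov[effect] == pytest.approx(f, rel=1e-6)


def test_rm_anova_interaction_power():
    """A pure time shift in one group (effect/noise = 3) is detected as an
    interaction."""
    rng = np.random.default_rng(7)
    sigma = 1.0
    vals = {
        ("37Y", "PRE"): rng.normal(10, sigma, 6),
        ("37Y", "POST"): rng.normal(10 + 3 * sigma, sigma, 6),
        ("50Y", "PRE"): rng.normal(10, sigma, 6),
        ("50Y", "POST"): rng.normal(10, sigma, 6),
    }
    aov = rm_anova(_cohort(vals, 6)).set_index("effect")
    assert aov.loc["group*time", "p"] < 0.05


def test_rm_anova_rejects_constant_data():
    vals = {k: np.full(3, 5.0) for k in (("37Y", "PRE"), ("37Y", "POST"), ("50Y", "PRE"), ("50Y", "POST"))}
    with pytest.raises(ValueError, match="variance"):
        rm_anova(_cohort(vals, 3))


def test_rm_anova_rejects_missing_cell():
    df = _cohort(
        {k: np.arange(3.0) for k in (("37Y", "PRE"), ("37Y", "POST"), ("50Y", "PRE"), ("50Y", "POST"))},
        3,
    )
    with pytest.raises(ValueError):
        rm_anova(df[~((df.group == "50Y") & (df.time == "POST"))])


class TestFisherLSD:
    def _df(self, delta):
        rng = np.random.default_rng(0)
        vals = {
            ("37Y", "PRE"): rng.normal(10, 1, 6),
            ("37Y", "POST"): rng.normal(10 + delta, 1, 6),
            ("50Y", "PRE"): rng.normal(10, 1, 6),
            ("50Y", "POST"): rng.normal(10, 1, 6),
        }
        return _cohort(vals, 6)

    def test_identical_cells_give_high_p(self):
        df = self._df(0.0)
        df.loc[(df.group == "50Y") & (df.time == "POST"), "value"] = df.loc[
            (df.group == "50Y") & (df.time == "PRE"), "value"
        ].to_numpy()
        post = fisher_lsd(df).set_index(["cell_a", "cell_b"])
        assert post.loc[("50Y/POST", "50Y/PRE"), "p"] == pytest.approx(1.0)

    def test_large_separation_significant(self):
        post = fisher_lsd(self._df(10.0)).set_index(["cell_a", "cell_b"])
        assert post.loc[("37Y/POST", "37Y/PRE"), "p"] < 0.001

    def test_lsd_no_more_conservative_than_bonferroni(self):
        post = fisher_lsd(self._df(1.0))
        k = len(post)
        assert (post["p"] <= np.minimum(1.0, post["p"] * k) + 1e-12).all()


class TestPearson:
    def test_perfect_and_near_perfect(self):
        x = np.arange(10.0)
        assert pearson_regression(x, x)["r"] == pytest.approx(1.0)
        noisy = -x + np.random.default_rng(1).normal(0, 1e-3, 10)
        assert pearson_regression(x, noisy)["r"] == pytest.approx(-1.0, abs=1e-4)

    def test_against_direct_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = pearson_regression(x, y)["r"]
        brute = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(brute, rel=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r0 = pearson_regression(x, y)["r"]
        r1 = pearson_regression(3 * x + 2, -0.5 * y + 7)["r"]
        assert abs(r1) == pytest.approx(abs(r0))
        assert np.sign(r1) == -np.sign(r0)

    def test_rejects_constant_or_tiny(self):
        with pytest.raises(ValueError):
            pearson_regression([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_regression([1, 2], [1, 2])


def test_aggregate_subject_means():
    df = pd.DataFrame(
        {
            "subject": ["a", "a", "b"],
            "group": ["37Y"] * 3,
            "time": ["PRE"] * 3,
            "fiber_type": ["I"] * 3,
            "value": [1.0, 3.0, 5.0],
        }
    )
    out = aggregate_subject_means(df, "li")
    assert len(out) == 2
    assert out.loc[out.subject == "a", "value"].iloc[0] == pytest.approx(2.0)
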