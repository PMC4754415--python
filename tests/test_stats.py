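"""Behavior summaries, elementary tests, BH adjustment, mixed-model contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sdmnstates import (
    ExpressionLMM,
    StudyDesign,
    bh_adjust,
    cohens_d,
    corr_with_bh,
    summarize_behavior,
    tukey_hsd,
    two_sample_t,
    welch_anova,
)
from sdmnstates.design import EffectSpec

from conftest import truth_expression_table


# ----------------------------------------------------------------------
# behavior summaries


def _events(rows):
    return pd.DataFrame(rows, columns=["time_s", "behavior"])


def test_latency_is_first_bite_time():
    s = summarize_behavior(_events([(30.0, "bite"), (40.0, "chase")]), 1800.0)
    assert s.latency_first_bite_s == 30.0
    assert not s.latency_censored


def test_no_bite_censored_at_session_length():
    s = summarize_behavior(_events([(40.0, "chase")]), 1800.0)
    assert s.latency_first_bite_s == 1800.0
    assert s.latency_censored


def test_last_five_minute_window_counts():
    rows = [(1500.0 + 10 * i, "strike") for i in range(7)]
    s = summarize_behavior(_events(rows), 1800.0)
    assert s.aggressive_freq_last5 == 7
    early = [(60.0 * m, "bite") for m in range(1, 25)]
    s2 = summarize_behavior(_events(early), 1800.0)
    assert s2.aggressive_freq_last5 == 0
    assert s2.submissive_freq_last5 == 0


# ----------------------------------------------------------------------
# t-test, Cohen's d, Welch, Tukey


def test_pooled_t_matches_hand_computation():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = two_sample_t(x, y)
    # pooled var = 1, se = sqrt(1*(1/3+1/3)), t = -3/se
    assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
    assert res.df == 4


def test_identical_samples_t_zero_p_one():
    res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_degenerate_t_rejected():
    with pytest.raises(ValueError, match="pooled variance"):
        two_sample_t([1.0, 1.0], [1.0, 1.0])


def test_null_t_pvalues_uniform():
    rng = np.random.default_rng(0)
    ps = [two_sample_t(rng.normal(size=8), rng.normal(size=8)).p for _ in range(2000)]
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_cohens_d_unit_case_and_labels():
    d = cohens_d([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
    assert d.d == pytest.approx(1.0)
    assert d.d_type == "d_s"
    assert d.magnitude == "large"
    assert cohens_d([2.0, 4.0], [1.9, 3.9]).magnitude == "negligible"


def test_cohens_d_hand_value():
    # x={2,4}, y={1,3}: pooled sd = sqrt(2), d = 1/sqrt(2)
    d = cohens_d([2.0, 4.0], [1.0, 3.0])
    assert d.d == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-12)
    assert d.magnitude == "medium"


def test_cohens_dz_paired():
    d = cohens_d([2.0, 3.0, 5.0], [1.0, 1.0, 4.0], paired=True)
    diff = np.array([1.0, 2.0, 1.0])
    assert d.d == pytest.approx(diff.mean() / diff.std(ddof=1), rel=1e-12)
    assert d.d_type == "d_z"
    with pytest.raises(ValueError):
        cohens_d([1.0, 2.0], [1.0, 2.0], paired=True)  # zero SD of diffs


def test_welch_f_equals_welch_t_squared():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 12)
    y = rng.normal(0.5, 2, 9)
    w = welch_anova([x, y])
    t, p = sps.ttest_ind(x, y, equal_var=False)
    assert w.statistic == pytest.approx(t**2, rel=1e-10)
    assert w.p == pytest.approx(p, rel=1e-10)


def test_welch_approaches_classical_f_under_homoscedasticity():
    """Equal variances and sizes: Welch F = classical F divided by
    1 + 2(k-2)/(k^2-1) * Lambda, which tends to 1 as n grows."""
    rng = np.random.default_rng(2)
    for n, tol in ((15, 0.03), (400, 0.002)):
        base = rng.normal(0, 1, n)
        groups = [base + d for d in (0.0, 0.4, 0.9)]
        w = welch_anova(groups)
        f, _ = sps.f_oneway(*groups)
        k = 3
        lam = sum((1 - 1 / k) ** 2 for _ in groups) / (n - 1)
        denom = 1 + 2 * (k - 2) / (k**2 - 1) * lam
        assert w.statistic == pytest.approx(f / denom, rel=1e-8)
        assert abs(w.statistic - f) / f < tol


def test_welch_identical_groups_f_zero():
    g = [1.0, 2.0, 3.0, 4.0]
    w = welch_anova([g, list(g), list(g)])
    assert w.statistic == pytest.approx(0.0, abs=1e-12)
    assert w.p == pytest.approx(1.0)


def test_welch_zero_variance_group_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


def test_tukey_pairwise_count():
    rng = np.random.default_rng(3)
    out = tukey_hsd([rng.normal(size=8) for _ in range(4)])
    assert len(out) == 6
    assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


# ----------------------------------------------------------------------
# BH adjustment


def test_bh_hand_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.005, 0.5]), [0.01, 0.5])
    assert np.allclose(bh_adjust([0.2]), [0.2])


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_bh_monotone_bounded_and_equivariant(pvals):
    p = np.asarray(pvals)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    # order of adjusted values follows order of raw values
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
    perm = np.random.default_rng(0).permutation(len(p))
    assert np.allclose(bh_adjust(p[perm]), adj[perm])


def test_corr_with_bh_omits_short_pairs():
    df = pd.DataFrame({
        "a": [1.0, 2.0, 3.0, 4.0],
        "b": [1.1, 2.2, 2.9, 4.3],
        "c": [1.0, np.nan, np.nan, 2.0],
    })
    out = corr_with_bh(df, [("a", "b"), ("a", "c")])
    assert list(out["var_b"]) == ["b"]
    assert (out["p_adj"] >= out["p"] - 1e-15).all()


# ----------------------------------------------------------------------
# mixed model


@pytest.fixture(scope="module")
def balanced_design():
    return StudyDesign(
        n_per_treatment={"control": 8, "mirror": 8, "winner": 8, "loser": 8}
    )


def test_zero_random_variance_contrasts_equal_cell_means(balanced_design):
    """With no random effects the LMM contrast estimates are the raw
    cell-mean differences (ordinary least squares on cell means)."""
    eff = EffectSpec.null(balanced_design, sigma_subject=0.0, sigma_dyad=0.0)
    tbl = truth_expression_table(balanced_design, eff, seed=13)
    res = ExpressionLMM.from_expression_table(tbl, "bdnf").fit()
    con = res.contrasts()
    sub = tbl.loc[tbl["gene"] == "bdnf"].copy()
    sub["value"] = np.log(sub["relative_expression"])
    cell = sub.groupby(["treatment", "nucleus"])["value"].mean()
    for r in con.itertuples():
        t1, t2 = r.pair.split("-")
        expected = cell[(t1, r.nucleus)] - cell[(t2, r.nucleus)]
        assert r.estimate == pytest.approx(expected, abs=0.02)


def test_contrast_z_scale_invariant(expression_from_truth):
    """Multiplying expression by a positive constant shifts only the
    intercept on the log scale: z statistics unchanged."""
    res1 = ExpressionLMM.from_expression_table(expression_from_truth, "npas4").fit()
    scaled = expression_from_truth.copy()
    scaled["relative_expression"] = scaled["relative_expression"] * 7.3
    res2 = ExpressionLMM.from_expression_table(scaled, "npas4").fit()
    z1 = res1.contrasts()["z"].to_numpy()
    z2 = res2.contrasts()["z"].to_numpy()
    assert np.allclose(z1, z2, atol=1e-5)


def test_winner_loser_contrast_uses_paired_dz(expression_from_truth):
    con = ExpressionLMM.from_expression_table(expression_from_truth, "bdnf").fit().contrasts()
    wl = con.loc[con["pair"] == "winner-loser"]
    assert (wl["d_type"] == "d_z").all()
    others = con.loc[con["pair"] != "winner-loser"]
    assert (others["d_type"] == "d_s").all()


def test_omnibus_terms_and_injected_effect(balanced_design):
    """An injected treatment x nucleus shift shows up in the right contrast."""
    eff = EffectSpec.null(balanced_design)
    eff = EffectSpec(mu=eff.mu, delta={("winner", "Dm", "bdnf"): 2.0},
                     sigma_subject=0.2, sigma_dyad=0.1, sigma_resid=0.4)
    tbl = truth_expression_table(balanced_design, eff, seed=17)
    res = ExpressionLMM.from_expression_table(tbl, "bdnf").fit()
    omni = res.omnibus()
    assert list(omni["term"]) == ["treatment", "nucleus", "interaction"]
    inter_p = omni.loc[omni["term"] == "interaction", "p"].iloc[0]
    assert inter_p < 0.001
    con = res.contrasts()
    wc = con.loc[(con["pair"] == "control-winner") & (con["nucleus"] == "Dm")]
    assert wc["estimate"].iloc[0] == pytest.approx(-2.0, abs=0.5)
    assert wc["p"].iloc[0] < 0.001


def test_summary_renders(expression_from_truth):
    res = ExpressionLMM.from_expression_table(expression_from_truth, "wnt3").fit()
    text = res.summary()
    assert "variance components" in text
    assert "wnt3" in text
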