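"""Nonparametric statistics: oracles, alignment property, cross-checks."""

import itertools
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from causalddm.stats import (aligned_responses, art_anova, dscf_posthoc,
                             holm_correct, kruskal_wallis,
                             mixed_anova_balanced, normality_diagnostics,
                             oneway_anova, pearson, rank_biserial_from_w,
                             wilcoxon_rank_sum, wilcoxon_signed_rank)


# --- Wilcoxon signed-rank ---------------------------------------------------

def test_signed_rank_textbook_pairs():
    # 6 hand-worked pairs: diffs 2, -1, 4, 3, -2, 5 -> |d| ranks:
    # 1->1, 2->2.5, 2->2.5, 3->4, 4->5, 5->6; W+ = 2.5+5+4+6 = 17.5
    x = np.array([12.0, 9.0, 14.0, 13.0, 8.0, 15.0])
    y = np.array([10.0, 10.0, 10.0, 10.0, 10.0, 10.0])
    res = wilcoxon_signed_rank(x, y)
    assert res.statistic == pytest.approx(17.5)


def test_signed_rank_effect_size_matches_published_magnitude():
    assert round(rank_biserial_from_w(11049, 150), 2) == 0.83


def test_signed_rank_all_zero_differences_undefined():
    x = np.ones(10)
    res = wilcoxon_signed_rank(x, x)
    assert np.isnan(res.statistic)
    assert "undefined" in res.extras["note"]


# --- rank-sum ---------------------------------------------------------------

def test_rank_sum_matches_exact_enumeration():
    x = np.array([1.2, 3.4, 2.2, 5.1, 0.3])
    y = np.array([2.9, 4.4, 6.0, 1.8, 3.9])
    res = wilcoxon_rank_sum(x, y)
    # U by direct pair counting
    u_direct = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    assert res.statistic == pytest.approx(u_direct)
    # exact two-sided p by enumerating all C(10,5) labelings
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = 5
    obs = res.statistic
    mu = n1 * 5 / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(10), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    exact_p = count / total
    assert res.p_raw == pytest.approx(exact_p, abs=0.08)


def test_rank_sum_null_expectation():
    rng = np.random.default_rng(0)
    us = [wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30)).statistic
          for _ in range(200)]
    assert np.mean(us) == pytest.approx(450, rel=0.05)  # n1*n2/2


# --- Kruskal-Wallis + DSCF --------------------------------------------------

def test_kruskal_wallis_hand_example():
    g1, g2, g3 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]
    res = kruskal_wallis([g1, g2, g3])
    # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
    rbar = [2.0, 5.0, 8.0]
    h = 12.0 / (9 * 10) * sum(3 * (r - 5.0) ** 2 for r in rbar)
    assert res.statistic == pytest.approx(h)
    assert res.effect_size == pytest.approx((h - 2) / 6)


def test_kruskal_identical_groups():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(0.0, abs=1e-9)


def test_dscf_identical_pair_not_significant():
    rng = np.random.default_rng(5)
    base = rng.normal(0, 1, 40)
    shifted = rng.normal(3, 1, 40)
    table = dscf_posthoc([base, base.copy(), shifted], ["a", "b", "c"])
    same = table[(table.group_a == "a") & (table.group_b == "b")].iloc[0]
    assert same["p"] > 0.9
    diff = table[(table.group_a == "a") & (table.group_b == "c")].iloc[0]
    assert diff["p"] < 0.001


def test_dscf_degenerate_constants_no_crash():
    table = dscf_posthoc([[1.0] * 5, [1.0] * 5, [1.0] * 5])
    assert (table["p"] == 1.0).all()


def test_dscf_power_with_injected_separation():
    rng = np.random.default_rng(2)
    hits = 0
    sims = 40
    for _ in range(sims):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        c = rng.normal(1.2, 1, 50)
        t = dscf_posthoc([a, b, c], ["a", "b", "c"])
        pa = t[(t.group_a == "a") & (t.group_b == "c")]["p"].iloc[0]
        pb = t[(t.group_a == "b") & (t.group_b == "c")]["p"].iloc[0]
        hits += (pa < 0.05) and (pb < 0.05)
    assert hits / sims >= 0.95


# --- Holm -------------------------------------------------------------------

def test_holm_step_down_hand_case():
    assert np.allclose(holm_correct([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])
    assert np.allclose(holm_correct([0.2]), [0.2])
    assert np.allclose(holm_correct([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        holm_correct([0.5, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_holm_monotone_and_bounded(ps):
    adj = holm_correct(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# --- one-way ANOVA / Pearson / normality ------------------------------------

def test_oneway_anova_hand_example():
    g1, g2, g3 = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]
    res = oneway_anova([g1, g2, g3])
    # SSB = 3((2-4)^2 + (3-4)^2 + (7-4)^2) = 42; SSW = 6; F = 21/(6/6) = 21
    assert res.statistic == pytest.approx(21.0)
    assert res.df == (2, 6)
    d = res.extras["pairwise"]
    assert d.loc[0, "cohens_d"] == pytest.approx(-1.0)  # (2-3)/1


def test_oneway_equal_means():
    res = oneway_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_pearson_self_and_null_rate():
    x = np.arange(20.0)
    assert pearson(x, x).statistic == pytest.approx(1.0)
    rng = np.random.default_rng(8)
    n, sims, hits = 150, 400, 0
    for _ in range(sims):
        r = pearson(rng.normal(size=n), rng.normal(size=n))
        hits += abs(r.statistic) > 0.16  # ~ the two-sided .05 cutoff at n=150
    assert 0.02 < hits / sims < 0.09


def test_normality_diagnostics():
    rng = np.random.default_rng(1)
    sym = rng.normal(size=2000)
    d = normality_diagnostics(sym)
    assert abs(d["skewness"]) < 0.15
    rejections = sum(
        normality_diagnostics(rng.exponential(size=500))["shapiro_p"] < 0.05
        for _ in range(30))
    assert rejections >= 29
    assert "note" in normality_diagnostics(np.ones(10))


# --- ART ANOVA --------------------------------------------------------------

def _null_design(rng, n_sub=30, w_levels=2, g_levels=3):
    rows = []
    for s in range(n_sub):
        g = f"g{s % g_levels}"
        for w in range(w_levels):
            rows.append((f"s{s:02d}", g, f"w{w}", rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "grp", "cond", "y"])


def test_alignment_removes_nontarget_effects():
    # noise-free additive data: y = grp effect + cond effect (no interaction)
    rows = []
    geff = {"g0": 0.0, "g1": 2.0, "g2": -1.0}
    weff = {"w0": 0.0, "w1": 1.5}
    for s in range(12):
        g = f"g{s % 3}"
        for w in ("w0", "w1"):
            rows.append((f"s{s}", g, w, geff[g] + weff[w]))
    df = pd.DataFrame(rows, columns=["subject", "grp", "cond", "y"])
    art = aligned_responses(df, "y", "subject", within=["cond"], between=["grp"])
    agg = art["table"]
    for eff, aligned in art["aligned"].items():
        tmp = agg.copy()
        tmp["_a"] = aligned
        res = mixed_anova_balanced(tmp, "_a", "subject", ["cond"], ["grp"])
        for _, row in res.iterrows():
            if row["effect"] != ":".join(eff):
                assert row["ss"] == pytest.approx(0.0, abs=1e-16)


def test_art_type_one_error_near_nominal():
    """Pooled null rejection rate stays near alpha = .05.

    400 replicates over two independent streams; the band is nominal
    +/- ~2.8 Monte-Carlo SEs of the pooled estimate.
    """
    rejections, total = 0, 0
    for seed in (77, 78):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            df = _null_design(rng)
            res = art_anova(df, "y", "subject", within=["cond"], between=["grp"])
            rejections += int((res["p"] < 0.05).sum())
            total += len(res)
    rate = rejections / total
    assert 0.025 <= rate <= 0.075


def test_art_detects_injected_within_effect():
    rng = np.random.default_rng(3)
    df = _null_design(rng, n_sub=45)
    df.loc[df["cond"] == "w1", "y"] += 1.2
    res = art_anova(df, "y", "subject", within=["cond"], between=["grp"])
    p_cond = res.loc[res["effect"] == "cond", "p"].iloc[0]
    assert p_cond < 0.001


def test_mixed_anova_agrees_with_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(10)
    df = _null_design(rng, n_sub=24)
    df["y"] += np.where(df["cond"] == "w1", 0.7, 0.0)
    ours = mixed_anova_balanced(df, "y", "subject", ["cond"], ["grp"])
    theirs = pg.mixed_anova(df, dv="y", within="cond", between="grp",
                            subject="subject")
    for eff, key in (("grp", "grp"), ("cond", "cond"), ("grp:cond", "Interaction")):
        f_ours = ours.loc[ours["effect"] == eff, "F"].iloc[0]
        f_pg = theirs.loc[theirs["Source"] == key, "F"].iloc[0]
        assert f_ours == pytest.approx(f_pg, rel=1e-6)


def test_mixed_anova_agrees_with_r_aov():
    """Two-within split-plot F ratios cross-checked against R stats::aov."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(12):
        g = ["A", "B"][s % 2]
        for w1 in range(3):
            for w2 in range(2):
                y = rng.normal() + 0.5 * w1 + (0.8 if g == "B" else 0) * w2
                rows.append((f"s{s:02d}", g, f"f1_{w1}", f"f2_{w2}", y))
    df = pd.DataFrame(rows, columns=["subject", "grp", "f1", "f2", "y"])
    ours = mixed_anova_balanced(df, "y", "subject", ["f1", "f2"], ["grp"])
    csv = df.to_csv(index=False)
    rscript = textwrap.dedent("""
        d <- read.csv('stdin')
        for (c in c('subject','grp','f1','f2')) d[[c]] <- factor(d[[c]])
        m <- aov(y ~ grp*f1*f2 + Error(subject/(f1*f2)), data=d)
        s <- summary(m)
        for (stratum in s) {
          tab <- stratum[[1]]
          for (i in seq_len(nrow(tab))) {
            nm <- trimws(rownames(tab)[i])
            if (nm != 'Residuals') cat(nm, tab[i, 'F value'], '\\n')
          }
        }
    """)
    try:
        out = subprocess.run(["Rscript", "-e", rscript], input=csv, text=True,
                             capture_output=True, timeout=120)
    except FileNotFoundError:
        pytest.skip("Rscript not available")
    r_f = {}
    for line in out.stdout.splitlines():
        parts = line.split()
        if len(parts) == 2:
            r_f[parts[0]] = float(parts[1])
    assert r_f, f"R oracle produced no output: {out.stderr[:500]}"
    for eff, rname in (("grp", "grp"), ("f1", "f1"), ("grp:f1", "grp:f1"),
                       ("f2", "f2"), ("f1:f2", "f1:f2"), ("grp:f1:f2", "grp:f1:f2")):
        f_ours = ours.loc[ours["effect"] == eff, "F"].iloc[0]
        assert f_ours == pytest.approx(r_f[rname], rel=1e-6), eff


def test_between_factor_varying_within_subject_rejected():
    df = pd.DataFrame({
        "subject": ["s0", "s0", "s1", "s1"],
        "grp": ["a", "b", "a", "a"],
        "cond": ["w0", "w1", "w0", "w1"],
        "y": [1.0, 2.0, 3.0, 4.0],
    })
    with pytest.raises(ValueError, match="varies within subject"):
        art_anova(df, "y", "subject", within=["cond"], between=["grp"])
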