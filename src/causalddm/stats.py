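"""Nonparametric inferential statistics for the causality-judgment analyses.

Provides the aligned-rank-transform (ART) factorial ANOVA for mixed designs
(one between-subjects factor, up to two within-subjects factors), Wilcoxon
signed-rank and rank-sum tests with Z/√N effect sizes, Kruskal–Wallis with
η²[H] and Dwass–Steele–Critchlow–Fligner (DSCF) post-hocs, Holm correction,
one-way ANOVA with Cohen's d, Pearson correlation, and normality diagnostics
(skewness, excess kurtosis, Shapiro–Wilk).

Conventions: mid-ranks for ties throughout; zero differences dropped in the
signed-rank test; the Wilcoxon effect size is computed as r = Z/√N (N = input
pairs or pooled sample size).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult", "art_anova", "aligned_responses", "mixed_anova_balanced",
    "wilcoxon_signed_rank", "rank_biserial_from_w", "wilcoxon_rank_sum",
    "kruskal_wallis", "dscf_posthoc", "holm_correct", "oneway_anova",
    "pearson", "normality_diagnostics",
]


@dataclass
class TestResult:
    name: str
    statistic_name: str
    statistic: float
    df: tuple | float | None = None
    p_raw: float = np.nan
    p_adjusted: float = np.nan
    effect_size_name: str = ""
    effect_size: float = np.nan
    n: int | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# balanced split-plot ANOVA (used on aligned ranks)
# ---------------------------------------------------------------------------

def _gg_epsilon(Y2: np.ndarray, gidx: np.ndarray | None = None) -> float:
    """Greenhouse–Geisser epsilon from a subjects × levels matrix.

    With a between factor, uses the pooled within-group covariance (group
    means removed) so between-group separation does not distort epsilon.
    """
    p = Y2.shape[1]
    if p <= 2 or Y2.shape[0] <= p:
        return 1.0
    Yc = Y2.astype(float).copy()
    if gidx is not None:
        for g in np.unique(gidx):
            Yc[gidx == g] -= Yc[gidx == g].mean(0)
    S = np.cov(Yc, rowvar=False)
    Sc = S - S.mean(0, keepdims=True) - S.mean(1, keepdims=True) + S.mean()
    num = np.trace(Sc) ** 2
    den = (p - 1) * np.sum(Sc * Sc)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (p - 1), num / den)))


def mixed_anova_balanced(data: pd.DataFrame, dv: str, subject: str,
                         within: list, between: list | None = None) -> pd.DataFrame:
    """Split-plot ANOVA for a balanced design (≤1 between, ≤2 within factors).

    One observation per subject × within-cell (duplicates are averaged).
    Between-subjects effects are tested against subjects-within-groups;
    within effects (and their interactions with the between factor) against
    the corresponding factor × subjects-within-groups stratum.
    Greenhouse–Geisser correction is applied to within main effects with more
    than 2 levels and to their interactions with the between factor.
    """
    between = list(between or [])
    within = list(within)
    if len(between) > 1 or len(within) > 2 or len(within) == 0:
        raise ValueError("supported designs: 1 between (optional) x 1-2 within factors")
    b = between[0] if between else None
    if b is not None:
        per_subj = data.groupby(subject)[b].nunique()
        if (per_subj > 1).any():
            raise ValueError(f"between factor '{b}' varies within subject")

    agg = data.groupby([subject] + ([b] if b else []) + within, observed=True)[dv].mean().reset_index()
    subjects = sorted(agg[subject].unique())
    w1 = within[0]
    w1_levels = sorted(agg[w1].unique())
    p = len(w1_levels)
    if len(within) == 2:
        w2 = within[1]
        w2_levels = sorted(agg[w2].unique())
        q = len(w2_levels)
    else:
        w2, w2_levels, q = None, [None], 1

    if b:
        gmap = agg.groupby(subject, observed=True)[b].first()
        groups = sorted(gmap.unique())
    else:
        gmap = pd.Series("all", index=subjects)
        groups = ["all"]
    G = len(groups)
    N = len(subjects)
    gidx = np.array([groups.index(gmap[s]) for s in subjects])

    Y = np.full((N, p, q), np.nan)
    sub_i = {s: i for i, s in enumerate(subjects)}
    w1_i = {l: i for i, l in enumerate(w1_levels)}
    w2_i = {l: i for i, l in enumerate(w2_levels)}
    si = agg[subject].map(sub_i).to_numpy()
    w1i = agg[w1].map(w1_i).to_numpy()
    w2i = agg[w2].map(w2_i).to_numpy() if w2 else np.zeros(len(agg), dtype=int)
    Y[si, w1i, w2i] = agg[dv].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("design is not complete: missing subject x within cells")

    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_g = np.array([m_s[gidx == g].mean() for g in range(G)])
    n_g = np.array([(gidx == g).sum() for g in range(G)])
    m_j = Y.mean(axis=(0, 2))
    m_k = Y.mean(axis=(0, 1))
    m_jk = Y.mean(axis=0)
    m_sj = Y.mean(axis=2)
    m_sk = Y.mean(axis=1)
    m_gj = np.array([Y[gidx == g].mean(axis=(0, 2)) for g in range(G)])
    m_gk = np.array([Y[gidx == g].mean(axis=(0, 1)) for g in range(G)])
    m_gjk = np.array([Y[gidx == g].mean(axis=0) for g in range(G)])

    rows = []

    def add(name, ss, df1, err_ss, df2, gg=1.0):
        ms = ss / df1
        mse = err_ss / df2
        F = ms / mse if mse > 0 else np.inf
        d1, d2 = df1 * gg, df2 * gg
        pval = float(sps.f.sf(F, d1, d2))
        eta = ss / (ss + err_ss) if (ss + err_ss) > 0 else np.nan
        rows.append({"effect": name, "ss": ss, "df1": df1, "df2": df2,
                     "F": F, "p": pval, "eta2p": eta, "gg_eps": gg})

    ss_sb = p * q * float(np.sum((m_s - m_g[gidx]) ** 2))
    df_sb = N - G
    if b:
        ss_b = p * q * float(np.sum(n_g * (m_g - grand) ** 2))
        add(b, ss_b, G - 1, ss_sb, df_sb)

    # W1 stratum
    res_w1s = m_sj - m_s[:, None] - (m_gj[gidx] - m_g[gidx, None])
    ss_w1s = q * float(np.sum(res_w1s ** 2))
    df_w1s = (p - 1) * (N - G)
    eps1 = _gg_epsilon(m_sj, gidx if b else None) if p > 2 else 1.0
    ss_w1 = N * q * float(np.sum((m_j - grand) ** 2))
    add(w1, ss_w1, p - 1, ss_w1s, df_w1s, gg=eps1)
    if b:
        ss_bw1 = q * float(np.sum(n_g[:, None] * (m_gj - m_g[:, None] - m_j[None, :] + grand) ** 2))
        add(f"{b}:{w1}", ss_bw1, (G - 1) * (p - 1), ss_w1s, df_w1s, gg=eps1)

    if w2:
        res_w2s = m_sk - m_s[:, None] - (m_gk[gidx] - m_g[gidx, None])
        ss_w2s = p * float(np.sum(res_w2s ** 2))
        df_w2s = (q - 1) * (N - G)
        eps2 = _gg_epsilon(m_sk, gidx if b else None) if q > 2 else 1.0
        ss_w2 = N * p * float(np.sum((m_k - grand) ** 2))
        add(w2, ss_w2, q - 1, ss_w2s, df_w2s, gg=eps2)
        if b:
            ss_bw2 = p * float(np.sum(n_g[:, None] * (m_gk - m_g[:, None] - m_k[None, :] + grand) ** 2))
            add(f"{b}:{w2}", ss_bw2, (G - 1) * (q - 1), ss_w2s, df_w2s, gg=eps2)

        inter_g = m_gjk - m_gj[:, :, None] - m_gk[:, None, :] + m_g[:, None, None]
        res_w12s = (Y - m_sj[:, :, None] - m_sk[:, None, :] + m_s[:, None, None]
                    - inter_g[gidx])
        ss_w12s = float(np.sum(res_w12s ** 2))
        df_w12s = (p - 1) * (q - 1) * (N - G)
        ss_w12 = N * float(np.sum((m_jk - m_j[:, None] - m_k[None, :] + grand) ** 2))
        add(f"{w1}:{w2}", ss_w12, (p - 1) * (q - 1), ss_w12s, df_w12s)
        if b:
            dev = inter_g - (m_jk - m_j[:, None] - m_k[None, :] + grand)[None, :, :]
            ss_bw12 = float(np.sum(n_g[:, None, None] * dev ** 2))
            add(f"{b}:{w1}:{w2}", ss_bw12, (G - 1) * (p - 1) * (q - 1), ss_w12s, df_w12s)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aligned rank transform
# ---------------------------------------------------------------------------

def _effects_list(within, between):
    factors = list(between) + list(within)
    effs = []
    for r in range(1, len(factors) + 1):
        effs.extend(itertools.combinations(factors, r))
    return effs


def aligned_responses(data: pd.DataFrame, dv: str, subject: str,
                      within: list, between: list | None = None) -> dict:
    """Aligned response columns, one per effect of the factorial design.

    Alignment (cell-mean / additive-subject-effect form): the residual
    ``y − [cellmean(all factors) + (subject mean − subject's group mean)]``
    plus the inclusion-exclusion marginal-mean estimate of the target effect.
    On noise-free additive data every non-target effect vanishes from the
    aligned responses.
    """
    between = list(between or [])
    factors = between + list(within)
    agg = data.groupby([subject] + factors, observed=True)[dv].mean().reset_index()
    y = agg[dv].to_numpy(dtype=float)
    grand = y.mean()
    cell_mean = agg.groupby(factors, observed=True)[dv].transform("mean").to_numpy()
    subj_mean = agg.groupby(subject, observed=True)[dv].transform("mean").to_numpy()
    if between:
        group_mean = agg.groupby(between, observed=True)[dv].transform("mean").to_numpy()
    else:
        group_mean = np.full_like(y, grand)
    # within-effect targets: the subject effect is part of the alignment model
    # (it is not their error stratum); between-effect targets keep subject
    # deviations in, since subjects-within-groups is their error term
    resid_within = y - cell_mean - (subj_mean - group_mean)
    resid_between = y - cell_mean

    marg = {}
    for eff in _effects_list(within, between):
        resid = resid_within if any(f in within for f in eff) else resid_between
        est = np.zeros_like(y)
        for r in range(len(eff) + 1):
            for sub_f in itertools.combinations(eff, r):
                if sub_f:
                    mm = agg.groupby(list(sub_f), observed=True)[dv].transform("mean").to_numpy()
                else:
                    mm = np.full_like(y, grand)
                est += ((-1.0) ** (len(eff) - len(sub_f))) * mm
        marg[eff] = resid + est
    return {"table": agg, "aligned": marg}


def art_anova(data: pd.DataFrame, dv: str, subject: str, within: list,
              between: list | None = None) -> pd.DataFrame:
    """Aligned-rank-transform factorial ANOVA for a mixed design.

    For each effect, responses are aligned for that effect, mid-ranked, and a
    balanced split-plot ANOVA is run on the ranks; only the target effect's
    row is retained.  Returns one row per effect with F, dfs, p, partial η²
    and the GG epsilon applied.
    """
    between = list(between or [])
    art = aligned_responses(data, dv, subject, within, between)
    agg = art["table"]
    out = []
    for eff, aligned in art["aligned"].items():
        ranked = agg.copy()
        ranked["_art_rank"] = sps.rankdata(aligned)
        res = mixed_anova_balanced(ranked, "_art_rank", subject, within, between)
        name = ":".join(eff)
        row = res[res["effect"] == name]
        if len(row) != 1:
            raise RuntimeError(f"effect {name} missing from ANOVA table")
        out.append(row.iloc[0])
    return pd.DataFrame(out).reset_index(drop=True)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def rank_biserial_from_w(w: float, n: int) -> float:
    """Effect size r = Z/√N from a signed-rank W and pair count (no ties/zeros)."""
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return (w - mu) / sigma / math.sqrt(n)


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    W = sum of positive-difference ranks (zeros dropped, mid-ranks for ties);
    p from the normal approximation with tie correction; r = Z/√N with N the
    number of input pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    N = len(x)
    d = x - y
    nz = d != 0
    if not nz.any():
        return TestResult("wilcoxon_signed_rank", "W", np.nan, n=N,
                          extras={"note": "all differences zero; undefined"})
    d = d[nz]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = float(np.sum(counts ** 3 - counts)) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie)
    z = (w - mu) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("wilcoxon_signed_rank", "W", w, p_raw=float(p), n=N,
                      effect_size_name="r", effect_size=z / math.sqrt(N),
                      extras={"z": z, "n_nonzero": n})


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Mann–Whitney U test with tie-corrected normal approximation.

    U counts pairs won by ``x``; r = Z/√(n1+n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts ** 3 - counts)) / (N * (N - 1)) if N > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie)
    if sigma2 <= 0:
        return TestResult("wilcoxon_rank_sum", "U", u, n=N,
                          extras={"note": "degenerate (all values tied)"})
    z = (u - n1 * n2 / 2.0) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("wilcoxon_rank_sum", "U", u, p_raw=float(p), n=N,
                      effect_size_name="r", effect_size=z / math.sqrt(N),
                      extras={"z": z})


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with η²[H] = (H − k + 1)/(n − k)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    n = sum(len(g) for g in groups)
    if np.ptp(np.concatenate(groups)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    eta2 = (h - k + 1) / (n - k)
    return TestResult("kruskal_wallis", "H", float(h), df=k - 1, p_raw=float(p),
                      n=n, effect_size_name="eta2_H", effect_size=float(eta2))


def dscf_posthoc(groups, labels=None) -> pd.DataFrame:
    """Dwass–Steele–Critchlow–Fligner all-pairs post-hoc after Kruskal–Wallis.

    Each pair is re-ranked on its own; the tie-corrected standardized
    rank-sum statistic is referred to the studentized range with k groups and
    infinite df (q = √2·|z|), as in the standard DSCF construction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    labels = labels or [f"g{i}" for i in range(k)]
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        x, y = groups[i], groups[j]
        m, n = len(x), len(y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        w = float(ranks[:m].sum()) - m * (m + 1) / 2.0   # U for x
        Np = m + n
        _, counts = np.unique(pooled, return_counts=True)
        tie = float(np.sum(counts ** 3 - counts)) / (Np * (Np - 1)) if Np > 1 else 0.0
        sigma2 = m * n / 12.0 * ((Np + 1) - tie)
        if sigma2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (w - m * n / 2.0) / math.sqrt(sigma2)
            p = float(sps.studentized_range.sf(math.sqrt(2.0) * abs(z), k, 1e6))
        rows.append({"group_a": labels[i], "group_b": labels[j], "U": w,
                     "z": z, "p": p, "r": z / math.sqrt(Np)})
    return pd.DataFrame(rows)


def holm_correct(p_values):
    """Step-down Holm adjustment; output order matches input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([])
    _, adj, _, _ = multipletests(p, method="holm")
    return adj


def oneway_anova(groups, labels=None) -> TestResult:
    """One-way between-subjects ANOVA with η² and pairwise Cohen's d.

    Pairwise comparisons use pooled-sd independent t tests, Holm-corrected,
    reported in ``extras['pairwise']``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    f, p = sps.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    eta2 = ssb / (ssb + ssw) if (ssb + ssw) > 0 else np.nan
    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        x, y = groups[i], groups[j]
        if len(x) < 2 or len(y) < 2:
            raise ValueError("Cohen's d requires >= 2 observations per group")
        t, pt = sps.ttest_ind(x, y)
        sp = math.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                       / (len(x) + len(y) - 2))
        d = (x.mean() - y.mean()) / sp if sp > 0 else np.nan
        pairs.append({"group_a": labels[i], "group_b": labels[j],
                      "t": float(t), "p": float(pt), "cohens_d": d})
    pw = pd.DataFrame(pairs)
    if len(pw):
        pw["p_holm"] = holm_correct(pw["p"].to_numpy())
    return TestResult("oneway_anova", "F", float(f), df=(k - 1, n - k),
                      p_raw=float(p), n=n, effect_size_name="eta2p",
                      effect_size=float(eta2), extras={"pairwise": pw})


def pearson(x, y) -> TestResult:
    """Pearson correlation with two-tailed p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult("pearson", "r", np.nan, n=len(x),
                          extras={"note": "zero variance; undefined"})
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", "r", float(r), p_raw=float(p), n=len(x),
                      effect_size_name="r", effect_size=float(r))


def normality_diagnostics(x) -> dict:
    """Sample skewness, excess kurtosis (both bias-corrected) and Shapiro–Wilk."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        return {"skewness": np.nan, "kurtosis": np.nan, "shapiro_w": np.nan,
                "shapiro_p": np.nan, "note": "constant input; undefined"}
    w, p = sps.shapiro(x)
    return {
        "skewness": float(sps.skew(x, bias=False)),
        "kurtosis": float(sps.kurtosis(x, bias=False)),
        "shapiro_w": float(w),
        "shapiro_p": float(p),
    }
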