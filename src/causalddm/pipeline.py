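"""End-to-end orchestration of the causality-judgment analysis.

Stage order follows the study logic: trait clustering, psychometric PCA with
the fit-quality filter, one-way ANOVA on PCA, serial dependence (ART ANOVA,
Wilcoxon tests, Kruskal–Wallis + DSCF on the difference index), RT analyses,
then the hierarchical DDM (model comparison by DIC, diagnostics, optional
recovery).  Every stage persists its outputs under the run directory and a
manifest records config, seeds and stage status.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as tc
from . import psychometrics as psy
from . import stats as st
from .io import read_traits, read_trials

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    trials_path: str = ""
    traits_path: str = ""
    out_dir: str = "run"
    min_adj_r2: float = 0.9
    k_min: int = 2
    k_max: int = 10
    n_starts: int = 50
    seed: int = 0
    run_ddm: bool = True
    ddm_model_ids: tuple = (16,)
    ddm_chains: int = 2
    ddm_iterations: int = 2000
    ddm_burn_in: int = 1000
    ddm_priors: str = "informative"
    ddm_max_subjects: int = 24
    run_recovery: bool = False
    alpha: float = 0.05
    hdi_mass: float = 0.95

    @classmethod
    def from_json(cls, path):
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def config_hash(self):
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _cluster_stage(cfg, traits, out):
    X = tc.zscore_subscales(traits.set_index("subject_id"))
    best, table = tc.select_k(X.to_numpy(), range(cfg.k_min, cfg.k_max + 1),
                              seed=cfg.seed, n_starts=cfg.n_starts)
    table.to_csv(out / "cluster_scores.csv", index=False)
    labels = tc.label_clusters(best, feature_names=list(X.columns))
    assign = pd.DataFrame({
        "subject_id": traits["subject_id"].to_numpy(),
        "cluster_index": best.assignments,
        "cluster": [labels.get(c, f"cluster{c}") for c in best.assignments],
    })
    assign.to_csv(out / "cluster_assignments.csv", index=False)
    cent = pd.DataFrame(best.centroids, columns=X.columns)
    cent.insert(0, "cluster", [labels.get(i, f"cluster{i}") for i in range(best.K)])
    cent.to_csv(out / "cluster_centroids.csv", index=False)
    return best, table, assign


def _psychometrics_stage(cfg, trials, out):
    summ = psy.summarize_subjects(trials, min_adj_r2=cfg.min_adj_r2)
    summ.to_csv(out / "subject_summaries.csv", index=False)
    if not summ["included"].any():
        raise RuntimeError(
            f"all subjects excluded at min adjusted R^2 = {cfg.min_adj_r2}; "
            "nothing to analyze downstream")
    rts = psy.rt_summaries(trials)
    rts.to_csv(out / "rt_summaries.csv", index=False)
    return summ, rts


def _stats_stage(cfg, summ, rts, assign, out):
    data = summ.merge(assign[["subject_id", "cluster"]], on="subject_id")
    data = data[data["included"]].reset_index(drop=True)
    results = {}
    # one-way ANOVA on PCA by cluster
    groups, labels = [], []
    for cl, sub in data.groupby("cluster"):
        groups.append(sub["pca_all"].to_numpy())
        labels.append(cl)
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        results["anova_pca"] = st.oneway_anova(groups, labels)
    # 2x3 ART ANOVA on history-conditioned PCA
    long = pd.concat([
        data[["subject_id", "cluster", "pca_t1_causal"]]
            .rename(columns={"pca_t1_causal": "pca"}).assign(t1="causal"),
        data[["subject_id", "cluster", "pca_t1_noncausal"]]
            .rename(columns={"pca_t1_noncausal": "pca"}).assign(t1="non-causal"),
    ]).dropna(subset=["pca"])
    complete = long.groupby("subject_id").size() == 2
    long = long[long["subject_id"].map(complete)]
    if long["cluster"].nunique() >= 2:
        results["art_pca"] = st.art_anova(long, "pca", "subject_id",
                                          within=["t1"], between=["cluster"])
    # within-cluster signed-rank + overall, between-cluster rank-sum on t-1 causal
    wil = []
    ok = data.dropna(subset=["pca_t1_causal", "pca_t1_noncausal"])
    res = st.wilcoxon_signed_rank(ok["pca_t1_causal"], ok["pca_t1_noncausal"])
    wil.append({"scope": "all", "W": res.statistic, "p": res.p_raw, "r": res.effect_size})
    for cl, sub in ok.groupby("cluster"):
        r = st.wilcoxon_signed_rank(sub["pca_t1_causal"], sub["pca_t1_noncausal"])
        wil.append({"scope": cl, "W": r.statistic, "p": r.p_raw, "r": r.effect_size})
    wt = pd.DataFrame(wil)
    wt["p_holm"] = st.holm_correct(wt["p"].fillna(1.0).to_numpy())
    results["wilcoxon_pca"] = wt
    # Kruskal-Wallis + DSCF on the serial-dependence index
    groups = [sub["sd_index"].dropna().to_numpy() for _, sub in data.groupby("cluster")]
    labels = [cl for cl, _ in data.groupby("cluster")]
    if len(groups) >= 2 and all(len(g) for g in groups):
        results["kw_sd_index"] = st.kruskal_wallis(groups)
        results["dscf_sd_index"] = st.dscf_posthoc(groups, labels)
    # 10x3 ART on mean RT per lag
    rtall = rts[rts["condition"] == "all"].merge(
        assign[["subject_id", "cluster"]], on="subject_id")
    rtall = rtall[rtall["subject_id"].isin(data["subject_id"])]
    rtall = rtall.dropna(subset=["mean_rt_s"])
    full = rtall.groupby("subject_id")["lag_ms"].nunique()
    rtall = rtall[rtall["subject_id"].map(full) == full.max()]
    if rtall["cluster"].nunique() >= 2:
        results["art_rt"] = st.art_anova(rtall, "mean_rt_s", "subject_id",
                                         within=["lag_ms"], between=["cluster"])
    # persist tidy tables
    tidy = []
    for key, res in results.items():
        if isinstance(res, st.TestResult):
            tidy.append({"analysis": key, "statistic": res.statistic_name,
                         "value": res.statistic, "df": str(res.df),
                         "p": res.p_raw, "effect_size_name": res.effect_size_name,
                         "effect_size": res.effect_size})
        elif isinstance(res, pd.DataFrame):
            res.to_csv(out / f"stats_{key}.csv", index=False)
    pd.DataFrame(tidy).to_csv(out / "stats_scalar.csv", index=False)
    return results


def _ddm_stage(cfg, trials, assign, out, rng):
    from .ddm import MODEL_SPECS, build_model, dic, parameter_recovery, sample_posterior
    keep = assign["subject_id"].unique()
    if len(keep) > cfg.ddm_max_subjects:
        keep = rng.choice(keep, size=cfg.ddm_max_subjects, replace=False)
    sub = trials[trials["subject_id"].isin(keep)]
    clusters = assign.set_index("subject_id")["cluster"]
    rows = []
    fits = {}
    for mid in cfg.ddm_model_ids:
        model = build_model(MODEL_SPECS[mid], sub, clusters, priors=cfg.ddm_priors)
        t0 = time.time()
        samples = sample_posterior(model, chains=cfg.ddm_chains,
                                   iterations=cfg.ddm_iterations,
                                   burn_in=cfg.ddm_burn_in,
                                   seed=cfg.seed + mid)
        rhat_max = float(samples.rhat_table()["rhat"].max())
        rows.append({"model": mid, "dic": dic(model, samples),
                     "rhat_max": rhat_max, "seconds": time.time() - t0})
        fits[mid] = (model, samples)
    dic_table = pd.DataFrame(rows).sort_values("dic")
    dic_table.to_csv(out / "ddm_dic.csv", index=False)
    best_id = int(dic_table.iloc[0]["model"])
    model, samples = fits[best_id]
    # posterior summary per parameter cell (group means, natural scale)
    summ_rows = []
    from .ddm.diagnostics import hdi as hdi_fn
    for p in ("z", "v", "a", "t0"):
        draws = samples.group_cell_draws(p, natural=True)
        for c, key in enumerate(samples.cells[p]):
            lo, hi = hdi_fn(draws[:, c], cfg.hdi_mass)
            summ_rows.append({"param": p, "cell": str(key),
                              "median": float(np.median(draws[:, c])),
                              "hdi_low": lo, "hdi_high": hi})
    pd.DataFrame(summ_rows).to_csv(out / "ddm_posterior_summary.csv", index=False)
    samples.rhat_table().to_csv(out / "ddm_rhat.csv", index=False)
    recovery = None
    if cfg.run_recovery:
        recovery = parameter_recovery(sub, model, samples, seed=cfg.seed,
                                      chains=cfg.ddm_chains,
                                      iterations=cfg.ddm_iterations,
                                      burn_in=cfg.ddm_burn_in)
        pd.DataFrame([{"param": p, "r": r, "passed": recovery.passed[p]}
                      for p, r in recovery.correlations.items()]
                     ).to_csv(out / "ddm_recovery.csv", index=False)
    return dic_table, best_id, samples, recovery


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
                "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def stage(name, fn, *args):
        t0 = time.time()
        try:
            result = fn(*args)
        except Exception as e:
            manifest["stages"][name] = {"status": "failed", "error": str(e)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage '{name}' failed: {e}") from e
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 2)}
        return result

    trials = stage("read_trials", read_trials, cfg.trials_path)
    traits = stage("read_traits", read_traits, cfg.traits_path)
    best, cluster_table, assign = stage("clustering", _cluster_stage, cfg, traits, out)
    summ, rts = stage("psychometrics", _psychometrics_stage, cfg, trials, out)
    stage("stats", _stats_stage, cfg, summ, rts, assign, out)
    if cfg.run_ddm:
        included = summ.loc[summ["included"], "subject_id"]
        assign_inc = assign[assign["subject_id"].isin(included)]
        stage("ddm", _ddm_stage, cfg, trials[trials["subject_id"].isin(included)],
              assign_inc, out, rng)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    make_report(out)
    return out


def make_report(run_dir) -> Path:
    """Deterministic markdown report assembled from a run directory."""
    out = Path(run_dir)
    lines = ["# Causality-judgment analysis report", ""]

    def table(df, title):
        lines.append(f"## {title}")
        lines.append("")
        lines.append(df.to_string(index=False))
        lines.append("")

    scores = out / "cluster_scores.csv"
    if scores.exists():
        table(pd.read_csv(scores).round(3), "Cluster selection (K sweep)")
    else:
        lines.append("## Cluster selection\n\n(unavailable)\n")
    summ_p = out / "subject_summaries.csv"
    if summ_p.exists():
        s = pd.read_csv(summ_p)
        assign_p = out / "cluster_assignments.csv"
        if assign_p.exists():
            s = s.merge(pd.read_csv(assign_p)[["subject_id", "cluster"]],
                        on="subject_id", how="left")
            g = s[s["included"]].groupby("cluster").agg(
                n=("subject_id", "count"), pca=("pca_all", "mean"),
                pca_sd=("pca_all", "std"), sd_index=("sd_index", "mean"))
            table(g.round(2).reset_index(), "Group PCA / serial-dependence summary")
        lines.append(f"Included subjects: {int(s['included'].sum())} of {len(s)} "
                     f"(mean adjusted R^2 = {s['adj_r2_all'].mean():.3f})")
        lines.append("")
    else:
        lines.append("## Psychometrics\n\n(unavailable)\n")
    scalar = out / "stats_scalar.csv"
    if scalar.exists():
        table(pd.read_csv(scalar).round(4), "Scalar test results")
    ddm_p = out / "ddm_dic.csv"
    if ddm_p.exists():
        table(pd.read_csv(ddm_p).round(2), "DDM model comparison (DIC)")
        rhat = pd.read_csv(out / "ddm_rhat.csv")
        lines.append(f"max R-hat: {rhat['rhat'].max():.3f}")
        lines.append("")
    else:
        lines.append("## DDM\n\n(unavailable)\n")
    rec_p = out / "ddm_recovery.csv"
    if rec_p.exists():
        table(pd.read_csv(rec_p).round(3), "Parameter recovery")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
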