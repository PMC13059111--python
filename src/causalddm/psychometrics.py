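"""Psychometric estimation of the point of causality ambiguity (PCA).

The proportion of non-causal responses as a function of collision lag ``x``
(ms) is fit with a bounded logistic

    y = 1 / (1 + exp(b * (t - x)))

with lower asymptote 0 and upper asymptote 1.  The two free parameters are
the slope ``b`` (per ms) and the 50% threshold ``t`` (ms) — the PCA, the lag
at which causal and non-causal reports are equally likely.  Both are
constrained positive.  Subjects whose all-trials fit has adjusted R² < 0.9
are excluded from downstream analysis.

Choice-history conditioning splits trials by the previous trial's response
(t-1 causal vs t-1 non-causal); block-initial trials carry no history and are
excluded from both bins.  The serial-dependence index is
PCA(t-1 causal) − PCA(t-1 non-causal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "PsychometricFit",
    "SubjectSummary",
    "logistic",
    "proportions_by_lag",
    "fit_logistic",
    "pca_of",
    "filter_by_fit",
    "serial_dependence_index",
    "rt_summaries",
    "summarize_subjects",
]

#: canonical collision-lag grid (ms); the task samples 10 lags from 0 to 144
CANONICAL_LAGS = tuple(float(x) for x in range(0, 145, 16))

# multi-start grid for the bounded local optimizer (deterministic)
_B_STARTS = (0.02, 0.05, 0.1, 0.2)
_T_STARTS = (40.0, 80.0, 120.0)
_B_BOUNDS = (1e-4, 1.0)
_T_BOUNDS = (1e-3, 500.0)

CONDITIONS = ("all", "t1_causal", "t1_noncausal")


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted bounded logistic for one subject and history condition."""

    b: float            # slope, per ms
    t: float            # 50% threshold (PCA), ms
    adj_r2: float       # adjusted coefficient of determination
    n_points: int       # lag levels entering the fit
    condition: str = "all"
    sse: float = float("nan")

    def predict(self, lag_ms):
        return logistic(np.asarray(lag_ms, dtype=float), self.b, self.t)


@dataclass
class SubjectSummary:
    subject_id: str
    pca_all: float = np.nan
    pca_t1_causal: float = np.nan
    pca_t1_noncausal: float = np.nan
    sd_index: float = np.nan
    adj_r2_all: float = np.nan
    included: bool = False
    mean_rt_per_lag: dict = field(default_factory=dict)


def logistic(x, b, t):
    """Bounded logistic; strictly in (0, 1), increasing in ``x`` for b > 0."""
    return 1.0 / (1.0 + np.exp(np.clip(b * (t - x), -500.0, 500.0)))


def _require_columns(trials: pd.DataFrame, cols):
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")


def proportions_by_lag(trials: pd.DataFrame, condition: str = "all") -> pd.DataFrame:
    """Per-lag counts and non-causal proportions for one subject.

    ``condition`` selects all trials or one history bin ('t1_causal' /
    't1_noncausal').  History bins use ``prev_response``; rows with
    ``prev_response == 'none'`` (block-initial trials) are excluded from both
    bins.  Lags with zero trials in the bin are flagged (``n_trials == 0``,
    proportion NaN) and a warning is logged.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    _require_columns(trials, ["lag_ms", "response"])
    sub = trials
    if condition == "t1_causal":
        sub = trials[trials["prev_response"] == "causal"]
    elif condition == "t1_noncausal":
        sub = trials[trials["prev_response"] == "non-causal"]
    lags = sorted(trials["lag_ms"].unique())
    rows = []
    for lag in lags:
        at = sub[sub["lag_ms"] == lag]
        n = len(at)
        if n == 0:
            logger.warning("lag %.0f ms has no trials in condition %s", lag, condition)
            rows.append((lag, 0, np.nan))
        else:
            rows.append((lag, n, float((at["response"] == "non-causal").mean())))
    return pd.DataFrame(rows, columns=["lag_ms", "n_trials", "prop_noncausal"])


def fit_logistic(props: pd.DataFrame, condition: str = "all") -> PsychometricFit:
    """Least-squares fit of the bounded logistic to lag-aggregated proportions.

    Unweighted SSE over the defined (non-NaN) proportions; deterministic
    multi-start bounded local optimization.  Adjusted R² uses n = number of
    lag levels and p = 2 free parameters.  A degenerate input (all
    proportions identical) yields an undefined adjusted R² and is reported as
    a failed fit (adj_r2 = −inf).
    """
    props = props.dropna(subset=["prop_noncausal"])
    x = props["lag_ms"].to_numpy(dtype=float)
    y = props["prop_noncausal"].to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 lag levels with defined proportions; got {n}")

    def resid(theta):
        return logistic(x, theta[0], theta[1]) - y

    best = None
    for b0 in _B_STARTS:
        for t0 in _T_STARTS:
            sol = least_squares(
                resid, x0=[b0, t0],
                bounds=([_B_BOUNDS[0], _T_BOUNDS[0]], [_B_BOUNDS[1], _T_BOUNDS[1]]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            sse = float(np.sum(sol.fun ** 2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, sol.x[0], sol.x[1])
    sse, b, t = best
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        # flat data: R² undefined; mark as failed so the subject is excluded
        adj_r2 = -np.inf
    else:
        r2 = 1.0 - sse / sst
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2 - 1)
    return PsychometricFit(b=float(b), t=float(t), adj_r2=float(adj_r2),
                           n_points=n, condition=condition, sse=sse)


def pca_of(fit: PsychometricFit) -> float:
    """The point of causality ambiguity: the fitted 50% threshold (ms)."""
    return fit.t


def filter_by_fit(fits: dict, min_adj_r2: float = 0.9):
    """Partition ``{subject_id: PsychometricFit}`` by fit quality.

    Excluded iff adjusted R² < ``min_adj_r2`` (the boundary value is kept).
    Returns ``(included_ids, excluded_ids)`` as sorted lists.
    """
    included, excluded = [], []
    for sid in sorted(fits):
        if fits[sid].adj_r2 < min_adj_r2:
            excluded.append(sid)
        else:
            included.append(sid)
    return included, excluded


def serial_dependence_index(fit_causal: PsychometricFit,
                            fit_noncausal: PsychometricFit) -> float:
    """PCA(t-1 causal) − PCA(t-1 non-causal); larger = stronger history pull."""
    return pca_of(fit_causal) - pca_of(fit_noncausal)


def rt_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean RT per lag × history condition (long format).

    Empty cells yield NaN means and are kept so missingness propagates.
    """
    _require_columns(trials, ["subject_id", "lag_ms", "rt_s"])
    out = []
    lags = sorted(trials["lag_ms"].unique())
    for sid, sub in trials.groupby("subject_id", sort=True):
        for cond in CONDITIONS:
            if cond == "all":
                sel = sub
            elif cond == "t1_causal":
                sel = sub[sub["prev_response"] == "causal"]
            else:
                sel = sub[sub["prev_response"] == "non-causal"]
            for lag in lags:
                cell = sel.loc[sel["lag_ms"] == lag, "rt_s"]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    m = float(cell.mean()) if len(cell) else np.nan
                out.append((sid, cond, lag, len(cell), m))
    return pd.DataFrame(out, columns=["subject_id", "condition", "lag_ms",
                                      "n_trials", "mean_rt_s"])


def summarize_subjects(trials: pd.DataFrame, min_adj_r2: float = 0.9) -> pd.DataFrame:
    """Full per-subject psychometric summary table.

    Fits the all-trials and both history-conditioned logistics per subject,
    computes PCAs and the serial-dependence index, and applies the adjusted-R²
    inclusion rule to the all-trials fit (a subject with a failed conditional
    fit keeps NaN for that column).
    """
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        rec = {"subject_id": sid}
        fits = {}
        for cond in CONDITIONS:
            try:
                fits[cond] = fit_logistic(proportions_by_lag(sub, cond), cond)
            except ValueError:
                fits[cond] = None
        f_all = fits["all"]
        rec["pca_all"] = pca_of(f_all) if f_all else np.nan
        rec["adj_r2_all"] = f_all.adj_r2 if f_all else np.nan
        rec["pca_t1_causal"] = pca_of(fits["t1_causal"]) if fits["t1_causal"] else np.nan
        rec["pca_t1_noncausal"] = pca_of(fits["t1_noncausal"]) if fits["t1_noncausal"] else np.nan
        if fits["t1_causal"] and fits["t1_noncausal"]:
            rec["sd_index"] = serial_dependence_index(fits["t1_causal"], fits["t1_noncausal"])
        else:
            rec["sd_index"] = np.nan
        rec["included"] = bool(f_all is not None and np.isfinite(rec["adj_r2_all"])
                               and rec["adj_r2_all"] >= min_adj_r2)
        rows.append(rec)
    return pd.DataFrame(rows)
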