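"""Reading and writing the delimited interchange tables.

Trial tables use the fixed header (subject_id, cluster_truth, block,
trial_index, lag_ms, direction, response, rt_s, prev_response); the
cluster_truth column is optional on ingest (absent for real data).  Lag
values are snapped to the canonical 16-ms grid within ±1 ms, reconciling the
inconsistent lag labels that circulate for this task (46 vs 48 ms, etc.);
anything farther from the grid is a row error.  Malformed rows are collected
with line numbers and reported together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .psychometrics import CANONICAL_LAGS

__all__ = ["TrialValidationError", "read_trials", "write_trials", "read_traits"]

_REQUIRED = ["subject_id", "block", "trial_index", "lag_ms", "direction",
             "response", "rt_s", "prev_response"]
_RESPONSES = {"causal", "non-causal"}
_PREV = {"causal", "non-causal", "none"}
_DIRECTIONS = {"up", "down"}


class TrialValidationError(ValueError):
    def __init__(self, problems):
        self.problems = problems
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        super().__init__(f"invalid trial rows: {lines}{more}")


def snap_lag(value: float, grid=CANONICAL_LAGS, tol: float = 1.0):
    """Snap a lag to the canonical grid within ±tol ms; None if too far."""
    arr = np.asarray(grid)
    j = int(np.argmin(np.abs(arr - value)))
    if abs(arr[j] - value) <= tol:
        return float(arr[j])
    return None


def read_trials(path, column_map: dict | None = None,
                snap_tolerance: float = 1.0) -> pd.DataFrame:
    """Read and validate a trial table.

    ``column_map`` renames external column names onto the fixed schema (for
    ingesting third-party deposits whose headers differ).  Raises
    :class:`TrialValidationError` listing offending line numbers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} missing columns: {missing}")
    problems = []
    lag_snapped = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = row._asdict()
        try:
            rt = float(d["rt_s"])
            if not np.isfinite(rt) or rt <= 0:
                problems.append((i, f"non-positive RT {d['rt_s']!r}"))
        except (TypeError, ValueError):
            problems.append((i, f"malformed RT {d['rt_s']!r}"))
            rt = np.nan
        if d["response"] not in _RESPONSES:
            problems.append((i, f"unknown response token {d['response']!r}"))
        if d["prev_response"] not in _PREV:
            problems.append((i, f"unknown prev_response token {d['prev_response']!r}"))
        if d["direction"] not in _DIRECTIONS:
            problems.append((i, f"unknown direction {d['direction']!r}"))
        try:
            lag = snap_lag(float(d["lag_ms"]), tol=snap_tolerance)
        except (TypeError, ValueError):
            lag = None
        if lag is None:
            problems.append((i, f"lag {d['lag_ms']!r} not on the canonical grid"))
            lag_snapped.append(np.nan)
        else:
            lag_snapped.append(lag)
    if problems:
        raise TrialValidationError(problems)
    out = df.copy()
    out["lag_ms"] = lag_snapped
    out["block"] = out["block"].astype(int)
    out["trial_index"] = out["trial_index"].astype(int)
    out["rt_s"] = out["rt_s"].astype(float)
    return out


def write_trials(trials: pd.DataFrame, path):
    cols = [c for c in ["subject_id", "cluster_truth"] + _REQUIRED if c in trials.columns]
    # keep the fixed order, avoiding duplicates
    seen, ordered = set(), []
    for c in ["subject_id", "cluster_truth", "block", "trial_index", "lag_ms",
              "direction", "response", "rt_s", "prev_response"]:
        if c in trials.columns and c not in seen:
            ordered.append(c)
            seen.add(c)
    trials[ordered].to_csv(path, index=False)
    return Path(path)


def read_traits(path, column_map: dict | None = None) -> pd.DataFrame:
    from .clustering import SUBSCALES
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SUBSCALES if c not in df.columns]
    if missing:
        raise ValueError(f"traits table {path} missing subscales: {missing}")
    if "subject_id" not in df.columns:
        raise ValueError("traits table needs a subject_id column")
    return df
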