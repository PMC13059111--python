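"""Synthetic questionnaire and launching-task data with stored ground truth.

Emulates the study conditions of the causality-judgment task: 150 subjects in
three trait clusters (ASD-like n=44, low-trait n=56, SSD-like n=50), ten
collision lags from 0 to 144 ms, 400 trials per subject (20 per lag per
motion direction) in four blocks.  Choices and decision times are drawn from
the two-boundary diffusion process (upper boundary = non-causal); the drift
on a trial is ``drift_slope * (lag - drift_offset_ms)`` so short lags
accumulate toward causal and long lags toward non-causal judgments.

Serial dependence is generated by a starting-point shift: after a causal
response the next trial starts ``history_shift_delta`` closer to the causal
boundary, after a non-causal response the same amount toward the non-causal
boundary.  This z-shift mechanism is this package's generative assumption —
the phenomenon itself is well established but no generative model for it is
fixed by the task.  Block-initial trials carry no history.

Motion direction (up/down) is metadata only; it does not enter the
generative process.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit

from .clustering import AQ_SUBSCALES, SPQ_SUBSCALES, SUBSCALES

__all__ = [
    "GenConfig", "ClusterDDM", "generate_traits", "generate_task_data",
    "default_config", "recovery_config", "write_dataset",
]

CLUSTER_ORDER = ("ASD-like", "LT", "SSD-like")

#: item counts bounding each raw subscale score
SUBSCALE_MAX = dict(zip(AQ_SUBSCALES, (10,) * 5)) | dict(zip(
    SPQ_SUBSCALES, (9, 8, 7, 9, 7, 9, 9, 8, 8)))

# trait patterns (raw-score shifts = pattern x trait_effect x noise_sd): the
# ASD-like profile elevates the socio-affective + AQ subscales, the SSD-like
# profile the cognitive-perceptual SPQ subscales, and attention switching and
# imagination are elevated in BOTH (low only in LT).  After z-scoring, the
# unelevated dimensions land below the column mean, giving the diametric
# radar-plot profile; the shared elevations keep the three centroids
# non-collinear so silhouette selection resolves K = 3.
_ASD_UP = ("aq_social_skills", "aq_communication", "spq_no_close_friends",
           "spq_social_anxiety", "spq_constricted_affect")
_SSD_UP = ("spq_ideas_of_reference", "spq_odd_beliefs", "spq_unusual_perceptual",
           "spq_odd_behavior", "spq_odd_speech", "spq_suspiciousness")
_PATTERNS = {
    "ASD-like": {**{s: 1.0 for s in _ASD_UP},
                 "aq_attention_switching": 1.0, "aq_attention_to_detail": 0.8,
                 "aq_imagination": 1.0},
    "LT": {},
    "SSD-like": {**{s: 1.0 for s in _SSD_UP},
                 "aq_attention_switching": 1.0, "aq_imagination": 1.0},
}


@dataclass(frozen=True)
class ClusterDDM:
    """Cluster-level generative diffusion parameters."""
    z0: float               # baseline relative start in (0,1)
    a0: float               # boundary separation
    t0: float               # non-decision time, s
    drift_slope: float      # drift per ms of lag
    drift_offset_ms: float  # lag at which drift crosses zero


# defaults chosen to mirror the reported group phenomenology: SSD-like with a
# causal starting bias (z < .5), lower boundaries and faster responses, and a
# later drift zero-crossing (higher PCA); ASD-like with the highest boundary.
_DEFAULT_DDM = {
    "ASD-like": ClusterDDM(z0=0.52, a0=1.18, t0=0.20, drift_slope=0.035, drift_offset_ms=76.0),
    "LT": ClusterDDM(z0=0.50, a0=1.10, t0=0.195, drift_slope=0.035, drift_offset_ms=71.0),
    "SSD-like": ClusterDDM(z0=0.46, a0=0.90, t0=0.165, drift_slope=0.035, drift_offset_ms=82.0),
}


@dataclass(frozen=True)
class GenConfig:
    n_subjects_per_cluster: tuple = (44, 56, 50)     # ASD-like, LT, SSD-like
    lags_ms: tuple = tuple(float(x) for x in range(0, 145, 16))
    trials_per_lag: int = 40                          # 20 per direction
    n_blocks: int = 4
    cluster_ddm_params: dict = field(default_factory=lambda: dict(_DEFAULT_DDM))
    history_shift_delta: float = 0.10
    trait_effect: float = 1.5
    noise_sd: float = 2.0
    seed: int = 0
    # between-subject spread of the diffusion parameters (transformed scales)
    subject_sd_z_logit: float = 0.25
    subject_sd_v: float = 0.15
    subject_sd_log_a: float = 0.12
    subject_sd_log_t0: float = 0.15
    sim_dt: float = 1e-4

    def __post_init__(self):
        if len(self.n_subjects_per_cluster) != len(self.cluster_ddm_params):
            raise ValueError("one subject count per cluster required")
        if any(n <= 0 for n in self.n_subjects_per_cluster):
            raise ValueError("cluster sizes must be positive")
        lags = self.lags_ms
        if any(b <= a for a, b in zip(lags, lags[1:])):
            raise ValueError("lags_ms must be strictly increasing")
        if lags[0] < 0:
            raise ValueError("lags must be non-negative")
        if self.trials_per_lag <= 0 or self.trials_per_lag % self.n_blocks:
            raise ValueError("trials_per_lag must be a positive multiple of n_blocks")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for lab, prm in self.cluster_ddm_params.items():
            for shift in (-self.history_shift_delta, self.history_shift_delta):
                if not (0.0 < prm.z0 + shift < 1.0):
                    raise ValueError(
                        f"z0 ± history_shift_delta leaves (0,1) for cluster {lab}")
        if self.trait_effect < 0:
            raise ValueError("trait_effect must be non-negative")

    @property
    def clusters(self):
        return tuple(self.cluster_ddm_params)


def default_config(**kw) -> GenConfig:
    """The standard study-scale configuration (150 subjects, 400 trials)."""
    return GenConfig(**kw)


def recovery_config(n_subjects: int = 20, trials_per_lag: int = 100,
                    seed: int = 0, **kw) -> GenConfig:
    """Fixture for parameter-recovery runs: 2 clusters, 3 lags, no history
    shift (so the generative process matches the fitted model exactly)."""
    half = n_subjects // 2
    params = {
        "LT": _DEFAULT_DDM["LT"],
        "SSD-like": _DEFAULT_DDM["SSD-like"],
    }
    return GenConfig(
        n_subjects_per_cluster=(half, n_subjects - half),
        lags_ms=(0.0, 64.0, 144.0),
        trials_per_lag=trials_per_lag,
        n_blocks=4 if trials_per_lag % 4 == 0 else 1,
        cluster_ddm_params=params,
        history_shift_delta=0.0,
        seed=seed,
        **kw,
    )


def generate_traits(config: GenConfig, rng: np.random.Generator | None = None):
    """Questionnaire subscale scores with cluster ground truth.

    Raw integer scores per subscale, clipped to item-count bounds; the
    configured cluster separations are expressed in units of ``noise_sd``.
    Returns a DataFrame with subject_id, cluster_truth and the 14 subscales.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    sid = 0
    for label, n in zip(config.clusters, config.n_subjects_per_cluster):
        pattern = _PATTERNS.get(label, {})
        for _ in range(n):
            rec = {"subject_id": f"S{sid:03d}", "cluster_truth": label}
            for sc in SUBSCALES:
                mx = SUBSCALE_MAX[sc]
                base = 0.35 * mx
                shift = config.trait_effect * config.noise_sd * pattern.get(sc, 0.0)
                val = base + shift + rng.normal(0.0, config.noise_sd)
                rec[sc] = int(np.clip(round(val), 0, mx))
            rows.append(rec)
            sid += 1
    return pd.DataFrame(rows)


@njit(cache=True)
def _sim_sequential(z_trial_base, v_trial, a, delta, block_start, dt, seed, max_steps):
    """Sequential within-block diffusion simulation with history z-shifts."""
    np.random.seed(seed)
    n = z_trial_base.shape[0]
    choices = np.zeros(n, dtype=np.int8)
    dtimes = np.empty(n)
    sq = math.sqrt(dt)
    near = math.sqrt(15.0 * dt)
    prev = -1  # -1: no history
    for i in range(n):
        if block_start[i]:
            prev = -1
        z = z_trial_base[i]
        if prev == 0:      # previous causal -> start closer to causal boundary
            z = z - delta
        elif prev == 1:
            z = z + delta
        x = z * a
        v = v_trial[i]
        mu = v * dt
        absorbed = False
        step = 0
        while step < max_steps:
            step += 1
            xn = x + mu + sq * np.random.standard_normal()
            if xn >= a:
                choices[i] = 1
                dtimes[i] = step * dt
                absorbed = True
                break
            if xn <= 0.0:
                choices[i] = 0
                dtimes[i] = step * dt
                absorbed = True
                break
            if a - xn < near or xn < near or a - x < near or x < near:
                pu = math.exp(-2.0 * (a - x) * (a - xn) / dt) if (a - xn < near or a - x < near) else 0.0
                pl = math.exp(-2.0 * x * xn / dt) if (xn < near or x < near) else 0.0
                u = np.random.random()
                if u < pu:
                    choices[i] = 1
                    dtimes[i] = step * dt
                    absorbed = True
                    break
                if u < pu + pl:
                    choices[i] = 0
                    dtimes[i] = step * dt
                    absorbed = True
                    break
            x = xn
        if not absorbed:
            dtimes[i] = max_steps * dt
            choices[i] = 1 if x >= z * a else 0
        prev = choices[i]
    return choices, dtimes


def _logit(p):
    return math.log(p / (1.0 - p))


def _inv_logit(x):
    return 1.0 / (1.0 + math.exp(-x))


def generate_task_data(config: GenConfig):
    """Trial-level task data plus the ground-truth parameter table.

    Returns ``(trials, truth)``: one row per trial (subject_id,
    cluster_truth, block, trial_index, lag_ms, direction, response, rt_s,
    prev_response) and one truth row per subject × lag with the generating
    z, v, a, t0.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    lags = np.asarray(config.lags_ms)
    n_lags = len(lags)
    reps_per_block = config.trials_per_lag // config.n_blocks
    trial_rows = []
    truth_rows = []
    sid = 0
    for label, n_sub in zip(config.clusters, config.n_subjects_per_cluster):
        prm = config.cluster_ddm_params[label]
        for _ in range(n_sub):
            subject = f"S{sid:03d}"
            z_s = _inv_logit(_logit(prm.z0) + rng.normal(0, config.subject_sd_z_logit))
            # keep the history shift inside (0,1) for this subject too
            z_s = float(np.clip(z_s, config.history_shift_delta + 1e-3,
                                1 - config.history_shift_delta - 1e-3))
            a_s = prm.a0 * math.exp(rng.normal(0, config.subject_sd_log_a))
            t0_s = prm.t0 * math.exp(rng.normal(0, config.subject_sd_log_t0))
            v_s = {
                float(lag): prm.drift_slope * (lag - prm.drift_offset_ms)
                + rng.normal(0, config.subject_sd_v)
                for lag in lags
            }
            for lag in lags:
                truth_rows.append({
                    "subject_id": subject, "cluster_truth": label,
                    "lag_ms": float(lag), "z": z_s, "v": v_s[float(lag)],
                    "a": a_s, "t0": t0_s,
                })
            # block structure: each block holds reps_per_block repetitions of
            # every lag x direction combination, shuffled
            lag_seq = []
            dir_seq = []
            block_start = []
            for _b in range(config.n_blocks):
                lag_part = np.repeat(np.arange(n_lags), reps_per_block)
                dir_part = np.arange(len(lag_part)) % 2  # balanced per lag
                order = rng.permutation(len(lag_part))
                lag_seq.extend(lag_part[order].tolist())
                dir_seq.extend(dir_part[order].tolist())
                block_start.extend([True] + [False] * (len(lag_part) - 1))
            lag_idx = np.asarray(lag_seq)
            v_trial = np.array([v_s[float(lags[i])] for i in lag_idx])
            z_base = np.full(len(lag_idx), z_s)
            seed_i = int(rng.integers(1, 2**31 - 1))
            choices, dtimes = _sim_sequential(
                z_base, v_trial, a_s, config.history_shift_delta,
                np.asarray(block_start, dtype=np.bool_), config.sim_dt,
                seed_i, int(round(20.0 / config.sim_dt)))
            n_per_block = len(lag_idx) // config.n_blocks
            prev = "none"
            for i in range(len(lag_idx)):
                block = i // n_per_block + 1
                idx_in_block = i % n_per_block + 1
                if idx_in_block == 1:
                    prev = "none"
                resp = "non-causal" if choices[i] == 1 else "causal"
                trial_rows.append({
                    "subject_id": subject, "cluster_truth": label,
                    "block": block, "trial_index": idx_in_block,
                    "lag_ms": float(lags[lag_idx[i]]),
                    "direction": "up" if dir_seq[i] == 0 else "down",
                    "response": resp,
                    "rt_s": float(dtimes[i] + t0_s),
                    "prev_response": prev,
                })
                prev = resp
            sid += 1
    trials = pd.DataFrame(trial_rows)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def write_dataset(out_dir, config: GenConfig):
    """Generate and write traits, trials and ground truth under ``out_dir``."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traits = generate_traits(config)
    trials, truth = generate_task_data(config)
    traits.to_csv(out / "traits.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    truth.to_csv(out / "truth_params.csv", index=False)
    cfg = asdict(config)
    cfg["cluster_ddm_params"] = {k: asdict(v) for k, v in config.cluster_ddm_params.items()}
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=list))
    return {"traits": out / "traits.csv", "trials": out / "trials.csv",
            "truth": out / "truth_params.csv", "config": out / "config.json"}
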