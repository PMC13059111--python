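"""Psychometric fitting: logistic recovery, grid oracle, binning, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from causalddm.psychometrics import (CANONICAL_LAGS, PsychometricFit,
                                     fit_logistic, filter_by_fit, logistic,
                                     pca_of, proportions_by_lag, rt_summaries,
                                     serial_dependence_index,
                                     summarize_subjects)

LAGS = np.array(CANONICAL_LAGS)


def _props_df(y):
    return pd.DataFrame({"lag_ms": LAGS, "n_trials": 40, "prop_noncausal": y})


def _make_trials(n_blocks=4, trials_per_block=100, responses=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for b in range(1, n_blocks + 1):
        prev = "none"
        for t in range(1, trials_per_block + 1):
            lag = float(LAGS[k % 10])
            resp = responses[k] if responses is not None else (
                "non-causal" if rng.random() < logistic(lag, 0.05, 72.0) else "causal")
            rows.append({"subject_id": "S0", "block": b, "trial_index": t,
                         "lag_ms": lag, "direction": "up", "response": resp,
                         "rt_s": 0.3, "prev_response": prev})
            prev = resp
            k += 1
    return pd.DataFrame(rows)


def test_noiseless_logistic_recovered_exactly():
    y = logistic(LAGS, 0.08, 80.0)
    fit = fit_logistic(_props_df(y))
    assert fit.b == pytest.approx(0.08, abs=1e-6)
    assert fit.t == pytest.approx(80.0, abs=1e-6)
    assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)


def test_fit_never_beaten_by_grid_oracle():
    rng = np.random.default_rng(12)
    y = rng.binomial(40, logistic(LAGS, 0.06, 85.0)) / 40.0
    fit = fit_logistic(_props_df(y))
    bs = np.linspace(0.005, 0.5, 200)
    ts = np.linspace(1, 200, 200)
    B, T = np.meshgrid(bs, ts)
    pred = 1.0 / (1.0 + np.exp(B[..., None] * (T[..., None] - LAGS)))
    sse = ((pred - y) ** 2).sum(-1)
    assert fit.sse <= sse.min() + 1e-10


def test_prediction_at_threshold_is_half():
    fit = PsychometricFit(b=0.1, t=55.0, adj_r2=1.0, n_points=10)
    assert pca_of(fit) == 55.0
    assert fit.predict(55.0) == pytest.approx(0.5)


def test_flat_proportions_reported_as_failed_fit():
    fit = fit_logistic(_props_df(np.full(10, 0.5)))
    assert fit.adj_r2 == -np.inf


def test_history_bins_exclude_block_initial_trials():
    trials = _make_trials()
    pc = proportions_by_lag(trials, "t1_causal")
    pn = proportions_by_lag(trials, "t1_noncausal")
    assert pc["n_trials"].sum() + pn["n_trials"].sum() == 400 - 4


def test_all_causal_gives_zero_noncausal_proportion():
    trials = _make_trials(responses=["causal"] * 400)
    props = proportions_by_lag(trials, "all")
    assert (props["prop_noncausal"] == 0).all()


def test_filter_boundary_rule():
    fits = {f"S{i}": PsychometricFit(b=0.1, t=70, adj_r2=r, n_points=10)
            for i, r in enumerate([0.89, 0.90, 0.95])}
    inc, exc = filter_by_fit(fits)
    assert inc == ["S1", "S2"] and exc == ["S0"]
    assert filter_by_fit({}) == ([], [])


def test_serial_dependence_index_direction():
    fc = PsychometricFit(b=0.1, t=102.58, adj_r2=1, n_points=10, condition="t1_causal")
    fn = PsychometricFit(b=0.1, t=65.32, adj_r2=1, n_points=10, condition="t1_noncausal")
    assert serial_dependence_index(fc, fn) == pytest.approx(37.26)
    assert serial_dependence_index(fc, fc) == 0.0


def test_rt_summaries_constant_rt():
    trials = _make_trials()
    rts = rt_summaries(trials)
    filled = rts.dropna(subset=["mean_rt_s"])
    assert np.allclose(filled["mean_rt_s"], 0.3)
    # empty cells propagate as NaN rather than disappearing
    assert len(rts) == 30  # 10 lags x 3 conditions for one subject


def test_summarize_subjects_produces_consistent_index():
    trials = _make_trials(seed=5)
    summ = summarize_subjects(trials)
    row = summ.iloc[0]
    assert row["sd_index"] == pytest.approx(
        row["pca_t1_causal"] - row["pca_t1_noncausal"])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(b=st.floats(0.01, 0.15), t=st.floats(20.0, 130.0))
def test_logistic_curve_strictly_increasing_and_bounded(b, t):
    y = logistic(LAGS, b, t)
    assert np.all((y > 0) & (y < 1))
    assert np.all(np.diff(y) > 0)
    assert logistic(t, b, t) == pytest.approx(0.5)
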