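"""Hierarchical Bayesian estimation of the drift-diffusion model.

Eighteen candidate dependency structures let each core parameter (starting
bias z, drift v, boundary a, non-decision time t0) vary with collision lag,
trait cluster, both, or neither.  For every parameter the model places one
group-level Normal (mean, sd) per cell of its dependency cross on a
transformed scale (logit for z, log for a and t0, identity for v); each
subject contributes one value per applicable cell, drawn from that cell's
group distribution, and trials are likelihood-scored with the Wiener
first-passage density.

Sampling is adaptive Metropolis-within-Gibbs over scalar blocks: every
subject-level value and every group mean/sd is updated in turn with a
random-walk proposal whose scale adapts toward 0.44 acceptance during
burn-in.  Per-chain seeds derive from the master seed; draws after burn-in
are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .wfpt import _wfpt_pdf

__all__ = [
    "PARAMS", "ModelSpec", "MODEL_SPECS", "HierModel", "PosteriorSamples",
    "build_model", "sample_posterior", "dic",
]

PARAMS = ("z", "v", "a", "t0")
_TRANSFORMS = {"z": "logit", "v": "identity", "a": "log", "t0": "log"}

# proposal-scale hard bounds on the transformed scale
_BOUNDS = {"z": (-6.0, 6.0), "v": (-40.0, 40.0), "a": (-4.0, 2.5), "t0": (-7.0, 1.5)}


@dataclass(frozen=True)
class ModelSpec:
    """One of the 18 candidate dependency structures."""
    id: int
    depends: dict  # param -> frozenset subset of {"lag", "cluster"}

    def __post_init__(self):
        for p in PARAMS:
            if p not in self.depends:
                raise ValueError(f"spec must state dependencies for '{p}'")
            extra = set(self.depends[p]) - {"lag", "cluster"}
            if extra:
                raise ValueError(f"unknown dependency {extra} for '{p}'")


def _spec(mid, t0=(), z=(), v=(), a=()):
    return ModelSpec(mid, {"t0": frozenset(t0), "z": frozenset(z),
                           "v": frozenset(v), "a": frozenset(a)})


L, C, LC = ("lag",), ("cluster",), ("lag", "cluster")

#: the 18 candidate models: 1 = fully pooled baseline; 2-5 vary one
#: parameter with lag; 6-9 with cluster; 10-18 the combined structures,
#: with 16 the structure in which z, v, a depend on lag x cluster and t0 on lag.
MODEL_SPECS = {
    1: _spec(1),
    2: _spec(2, t0=L),
    3: _spec(3, z=L),
    4: _spec(4, v=L),
    5: _spec(5, a=L),
    6: _spec(6, t0=C),
    7: _spec(7, z=C),
    8: _spec(8, v=C),
    9: _spec(9, a=C),
    10: _spec(10, t0=L, z=L, v=L, a=L),
    11: _spec(11, t0=L, z=C, v=C, a=C),
    12: _spec(12, t0=L, z=LC, v=LC),
    13: _spec(13, t0=L, v=LC, a=LC),
    14: _spec(14, t0=L, z=LC, a=LC),
    15: _spec(15, z=LC, v=LC, a=LC),
    16: _spec(16, t0=L, z=LC, v=LC, a=LC),
    17: _spec(17, t0=C, z=LC, v=LC, a=LC),
    18: _spec(18, t0=LC, z=LC, v=LC, a=LC),
}


def _to_natural(p, x):
    if _TRANSFORMS[p] == "logit":
        return 1.0 / (1.0 + np.exp(-x))
    if _TRANSFORMS[p] == "log":
        return np.exp(x)
    return x


def _to_transformed(p, x):
    if _TRANSFORMS[p] == "logit":
        x = np.clip(x, 1e-6, 1 - 1e-6)
        return np.log(x / (1.0 - x))
    if _TRANSFORMS[p] == "log":
        return np.log(np.maximum(x, 1e-12))
    return x


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

class _Priors:
    """Group-level priors on the transformed scale.

    The informative regime mirrors the published hierarchical-DDM defaults
    (drawn from a pool of perceptual decision-making studies): group means
    v ~ N(2, 3), a ~ Gamma(1.5, scale .75), t0 ~ Gamma(.4, scale .2),
    logit z ~ N(0, .5).  Gamma priors on a and t0 are applied to the
    natural-scale mean exp(mu) with the log Jacobian.  Group sds get
    boundary-avoiding Gamma(2, scale/2) priors (density vanishing at 0),
    the standard stabilizer for centered hierarchical samplers; ``scale``
    sets the prior mean spread per parameter.  The non-informative regime
    widens everything (and uses Gamma(1.5, 10) for sds).
    """

    def __init__(self, regime="informative"):
        if regime not in ("informative", "noninformative"):
            raise ValueError("priors must be 'informative' or 'noninformative'")
        self.regime = regime
        if regime == "informative":
            self.sd_scale = {"z": 0.5, "v": 1.0, "a": 0.3, "t0": 0.3}
        else:
            self.sd_scale = {"z": 10.0, "v": 10.0, "a": 10.0, "t0": 10.0}

    def logp_mu(self, p, mu):
        if self.regime == "noninformative":
            centers = {"z": 0.0, "v": 0.0, "a": 0.0, "t0": -1.5}
            return -0.5 * ((mu - centers[p]) / 20.0) ** 2
        if p == "z":
            return -0.5 * (mu / 0.5) ** 2
        if p == "v":
            return -0.5 * ((mu - 2.0) / 3.0) ** 2
        if p == "a":      # Gamma(1.5, 0.75) on exp(mu), + Jacobian
            A = math.exp(mu)
            return 0.5 * math.log(A) - A / 0.75 + mu
        A = math.exp(mu)  # t0 ~ Gamma(0.4, 0.2)
        return -0.6 * math.log(A) - A / 0.2 + mu

    def logp_sd(self, p, sd):
        if sd <= 1e-4 or sd > 20.0:
            return -np.inf
        if self.regime == "noninformative":
            return 0.5 * math.log(sd) - sd / 10.0
        return math.log(sd) - 2.0 * sd / self.sd_scale[p]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class HierModel:
    spec: ModelSpec
    priors: _Priors
    subjects: list
    clusters: dict                 # subject -> cluster label
    lag_levels: list
    cluster_levels: list
    rt: np.ndarray
    upper: np.ndarray
    cells: dict = field(default_factory=dict)        # p -> list of cell keys
    inst_subject: dict = field(default_factory=dict) # p -> (n_inst,) subject idx
    inst_cell: dict = field(default_factory=dict)    # p -> (n_inst,) cell idx
    trial_inst: dict = field(default_factory=dict)   # p -> (n_trials,) inst idx
    trials_of_inst: dict = field(default_factory=dict)
    inst_of_cell: dict = field(default_factory=dict)

    @property
    def n_trials(self):
        return len(self.rt)

    def n_group_cells(self, p):
        return len(self.cells[p])


def _cell_key(deps, cluster, lag):
    key = []
    if "cluster" in deps:
        key.append(cluster)
    if "lag" in deps:
        key.append(lag)
    return tuple(key)


def build_model(spec: ModelSpec, trials: pd.DataFrame, cluster_assignments,
                priors: str = "informative") -> HierModel:
    """Assemble the hierarchical structure for one dependency spec.

    ``trials`` needs subject_id, lag_ms, rt_s and either a boolean ``upper``
    column or a response column with 'causal'/'non-causal' tokens.
    ``cluster_assignments`` maps subject_id to a cluster label (dict, Series,
    or DataFrame with subject_id/cluster columns).
    """
    if isinstance(cluster_assignments, pd.DataFrame):
        cluster_assignments = dict(zip(cluster_assignments["subject_id"],
                                       cluster_assignments["cluster"]))
    elif isinstance(cluster_assignments, pd.Series):
        cluster_assignments = cluster_assignments.to_dict()
    if len(trials) == 0:
        raise ValueError("empty trial table")
    subjects = sorted(trials["subject_id"].unique())
    missing = [s for s in subjects if s not in cluster_assignments]
    if missing:
        raise ValueError(f"no cluster assignment for subjects: {missing[:5]}")
    if "upper" in trials.columns:
        upper = trials["upper"].to_numpy(dtype=bool)
    else:
        upper = (trials["response"] == "non-causal").to_numpy()
    rt = trials["rt_s"].to_numpy(dtype=float)
    if (rt <= 0).any():
        raise ValueError("non-positive RTs in trial table")
    lag_levels = sorted(trials["lag_ms"].unique())
    cluster_levels = sorted(set(cluster_assignments[s] for s in subjects))

    model = HierModel(spec=spec, priors=_Priors(priors), subjects=subjects,
                      clusters=dict(cluster_assignments), lag_levels=lag_levels,
                      cluster_levels=cluster_levels, rt=rt, upper=upper)

    subj_idx = {s: i for i, s in enumerate(subjects)}
    t_sub = trials["subject_id"].map(subj_idx).to_numpy()
    t_lag = trials["lag_ms"].to_numpy(dtype=float)

    for p in PARAMS:
        deps = spec.depends[p]
        cells = []
        if "cluster" in deps and "lag" in deps:
            cells = [(c, l) for c in cluster_levels for l in lag_levels]
        elif "cluster" in deps:
            cells = [(c,) for c in cluster_levels]
        elif "lag" in deps:
            cells = [(l,) for l in lag_levels]
        else:
            cells = [()]
        cell_idx = {k: i for i, k in enumerate(cells)}
        inst_key = {}
        inst_subject, inst_cell = [], []
        for s in subjects:
            cl = cluster_assignments[s]
            if "lag" in deps:
                lags_for_s = lag_levels
            else:
                lags_for_s = [None]
            for l in lags_for_s:
                key = (subj_idx[s], cell_idx[_cell_key(deps, cl, l)])
                inst_key[key] = len(inst_subject)
                inst_subject.append(key[0])
                inst_cell.append(key[1])
        trial_inst = np.empty(len(rt), dtype=np.int64)
        for i in range(len(rt)):
            cl = cluster_assignments[subjects[t_sub[i]]]
            ck = cell_idx[_cell_key(deps, cl, t_lag[i] if "lag" in deps else None)]
            trial_inst[i] = inst_key[(t_sub[i], ck)]
        model.cells[p] = cells
        model.inst_subject[p] = np.asarray(inst_subject)
        model.inst_cell[p] = np.asarray(inst_cell)
        model.trial_inst[p] = trial_inst
        order = np.argsort(trial_inst, kind="stable")
        bounds = np.searchsorted(trial_inst[order], np.arange(len(inst_subject) + 1))
        model.trials_of_inst[p] = [order[bounds[j]:bounds[j + 1]]
                                   for j in range(len(inst_subject))]
        model.inst_of_cell[p] = [np.where(np.asarray(inst_cell) == c)[0]
                                 for c in range(len(cells))]
    return model


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ll_full(rt, upper, tz, tv, ta, tt0, out):
    total = 0.0
    for i in range(rt.shape[0]):
        p = _wfpt_pdf(rt[i], bool(upper[i]), tz[i], tv[i], ta[i], tt0[i])
        if p <= 0.0:
            out[i] = -np.inf
            total = -np.inf
        else:
            out[i] = math.log(p)
            if total > -np.inf:
                total += out[i]
    return total


@njit(cache=True)
def _ll_subset(rt, upper, tz, tv, ta, tt0, idx, which, newval, lls):
    """Log-likelihood over ``idx`` trials with parameter ``which`` replaced.

    which: 0=z, 1=v, 2=a, 3=t0 (natural scale).  Returns −inf totals fast.
    """
    total = 0.0
    for j in range(idx.shape[0]):
        i = idx[j]
        z = newval if which == 0 else tz[i]
        v = newval if which == 1 else tv[i]
        a = newval if which == 2 else ta[i]
        t0 = newval if which == 3 else tt0[i]
        p = _wfpt_pdf(rt[i], bool(upper[i]), z, v, a, t0)
        if p <= 0.0:
            return -np.inf
        lls[j] = math.log(p)
        total += lls[j]
    return total


@njit(cache=True)
def _ll_subset_vals(rt, upper, tz, tv, ta, tt0, idx, which, newvals, lls):
    """Like _ll_subset but with a per-trial replacement array ``newvals``."""
    total = 0.0
    for j in range(idx.shape[0]):
        i = idx[j]
        z = newvals[j] if which == 0 else tz[i]
        v = newvals[j] if which == 1 else tv[i]
        a = newvals[j] if which == 2 else ta[i]
        t0 = newvals[j] if which == 3 else tt0[i]
        p = _wfpt_pdf(rt[i], bool(upper[i]), z, v, a, t0)
        if p <= 0.0:
            return -np.inf
        lls[j] = math.log(p)
        total += lls[j]
    return total


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained MCMC draws and summaries for one model fit."""
    spec: ModelSpec
    chains: int
    kept: int
    cells: dict
    subjects: list
    inst_subject: dict
    inst_cell: dict
    group_mu: dict     # p -> (chains, kept, n_cells) transformed scale
    group_sd: dict
    subj: dict         # p -> (chains, kept, n_inst) transformed scale
    loglik: np.ndarray # (chains, kept)
    accept_rates: dict = field(default_factory=dict)

    def subject_posterior_means(self, p):
        """Posterior-mean subject-level values on the natural scale."""
        flat = self.subj[p].reshape(-1, self.subj[p].shape[-1])
        return _to_natural(p, flat).mean(0)

    def group_cell_draws(self, p, natural=True):
        """Pooled draws of each cell's group mean; (draws, n_cells)."""
        flat = self.group_mu[p].reshape(-1, self.group_mu[p].shape[-1])
        return _to_natural(p, flat) if natural else flat

    def rhat_table(self):
        from .diagnostics import gelman_rubin
        rows = []
        for p in PARAMS:
            for which, arr in (("mu", self.group_mu[p]), ("sd", self.group_sd[p])):
                for c in range(arr.shape[-1]):
                    rows.append({"param": p, "level": which,
                                 "cell": str(self.cells[p][c]),
                                 "rhat": gelman_rubin(arr[:, :, c])})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _init_state(model: HierModel, rng):
    """Data-driven initialization with per-chain jitter (transformed scale)."""
    state = {}
    for p in PARAMS:
        n_inst = len(model.inst_subject[p])
        vals = np.empty(n_inst)
        for i in range(n_inst):
            tr = model.trials_of_inst[p][i]
            if p == "t0":
                mn = model.rt[tr].min() if len(tr) else 0.3
                vals[i] = math.log(max(0.55 * mn, 1e-3)) + rng.normal(0, 0.1)
            elif p == "a":
                vals[i] = math.log(1.2) + rng.normal(0, 0.15)
            elif p == "z":
                vals[i] = rng.normal(0, 0.2)
            else:
                pu = model.upper[tr].mean() if len(tr) else 0.5
                pu = min(max(pu, 0.02), 0.98)
                vals[i] = math.log(pu / (1 - pu)) / 1.2 + rng.normal(0, 0.3)
        state[p] = vals
    mu, sd = {}, {}
    for p in PARAMS:
        ncell = model.n_group_cells(p)
        mu[p] = np.empty(ncell)
        sd[p] = np.empty(ncell)
        for c in range(ncell):
            members = model.inst_of_cell[p][c]
            mu[p][c] = state[p][members].mean()
            sd[p][c] = max(0.1, state[p][members].std() + 0.05)
    return state, mu, sd


def _run_chain(model: HierModel, iterations, burn_in, seed, progress=False):
    rng = np.random.default_rng(seed)
    subj, mu, sd = _init_state(model, rng)
    n_trials = model.n_trials
    rt, upper = model.rt, model.upper

    # per-trial natural-scale parameter arrays
    nat = {}
    tvals = {}
    for k, p in enumerate(PARAMS):
        nat[p] = _to_natural(p, subj[p])
        tvals[p] = nat[p][model.trial_inst[p]]
    trial_ll = np.empty(n_trials)
    total_ll = _ll_full(rt, upper, tvals["z"], tvals["v"], tvals["a"], tvals["t0"], trial_ll)
    # guard: push t0 down until the likelihood is finite
    tries = 0
    while not np.isfinite(total_ll) and tries < 50:
        subj["t0"] -= 0.3
        nat["t0"] = _to_natural("t0", subj["t0"])
        tvals["t0"] = nat["t0"][model.trial_inst["t0"]]
        total_ll = _ll_full(rt, upper, tvals["z"], tvals["v"], tvals["a"], tvals["t0"], trial_ll)
        tries += 1
    if not np.isfinite(total_ll):
        raise RuntimeError("could not find a finite-likelihood initialization")

    prop_scale = {p: np.full(len(subj[p]), 0.15) for p in PARAMS}
    # per-cell trial indices for the interweaved rescaling move
    cell_trials, cell_member_pos = {}, {}
    for p in PARAMS:
        cell_trials[p], cell_member_pos[p] = [], []
        for c in range(model.n_group_cells(p)):
            members = model.inst_of_cell[p][c]
            parts = [model.trials_of_inst[p][i] for i in members]
            cell_trials[p].append(np.concatenate(parts) if parts else
                                  np.empty(0, dtype=np.int64))
            cell_member_pos[p].append(np.concatenate(
                [np.full(len(tr), j) for j, tr in enumerate(parts)]) if parts
                else np.empty(0, dtype=np.int64))
    acc = {p: np.zeros(len(subj[p])) for p in PARAMS}
    acc_mu = {p: np.zeros(model.n_group_cells(p)) for p in PARAMS}
    acc_sd = {p: np.zeros(model.n_group_cells(p)) for p in PARAMS}
    window = 25

    kept = iterations - burn_in
    store_subj = {p: np.empty((kept, len(subj[p]))) for p in PARAMS}
    store_mu = {p: np.empty((kept, model.n_group_cells(p))) for p in PARAMS}
    store_sd = {p: np.empty((kept, model.n_group_cells(p))) for p in PARAMS}
    store_ll = np.empty(kept)
    lls_buf = np.empty(n_trials)
    priors = model.priors

    for it in range(iterations):
        for k, p in enumerate(PARAMS):
            lo, hi = _BOUNDS[p]
            inst_cell = model.inst_cell[p]
            for i in range(len(subj[p])):
                theta = subj[p][i]
                prop = theta + prop_scale[p][i] * rng.standard_normal()
                if prop < lo or prop > hi:
                    continue
                idx = model.trials_of_inst[p][i]
                natv = float(_to_natural(p, prop))
                new_ll = _ll_subset(rt, upper, tvals["z"], tvals["v"], tvals["a"],
                                    tvals["t0"], idx, k, natv, lls_buf)
                if not np.isfinite(new_ll):
                    continue
                old_ll = trial_ll[idx].sum()
                c = inst_cell[i]
                dprior = (-0.5 * ((prop - mu[p][c]) / sd[p][c]) ** 2
                          + 0.5 * ((theta - mu[p][c]) / sd[p][c]) ** 2)
                if math.log(rng.random()) < new_ll - old_ll + dprior:
                    subj[p][i] = prop
                    trial_ll[idx] = lls_buf[:len(idx)]
                    tvals[p][idx] = natv
                    acc[p][i] += 1
        # group-level updates (no trial likelihood involved).  Both use
        # independence proposals drawn from the likelihood-only conditional,
        # so the MH ratio reduces to the prior ratio and mixing is near-iid:
        #   mu' ~ N(x̄, s²/n);  sd'² ~ InvGamma(n/2, S/2) with
        #   accept = prior(sd')/prior(sd) · sd'/sd (measure Jacobian).
        for p in PARAMS:
            for c in range(model.n_group_cells(p)):
                members = model.inst_of_cell[p][c]
                x = subj[p][members]
                n_c = len(x)
                m, s = mu[p][c], sd[p][c]
                prop = x.mean() + s / math.sqrt(n_c) * rng.standard_normal()
                dpost = priors.logp_mu(p, prop) - priors.logp_mu(p, m)
                if math.log(rng.random()) < dpost:
                    mu[p][c] = prop
                    acc_mu[p][c] += 1
                m = mu[p][c]
                S2 = float(np.sum((x - m) ** 2)) + 1e-12
                u = (S2 / 2.0) / rng.gamma(n_c / 2.0)
                sprop = math.sqrt(u)
                lp_new = priors.logp_sd(p, sprop)
                if np.isfinite(lp_new):
                    dpost = (lp_new - priors.logp_sd(p, s)
                             + math.log(sprop) - math.log(s))
                    if math.log(rng.random()) < dpost:
                        sd[p][c] = sprop
                        acc_sd[p][c] += 1
        # interweaved rescaling move (every 5th iteration): jointly scales a
        # cell's group sd and its members' deviations from the group mean,
        # breaking the sd/subject-value funnel that slows centered sampling.
        # MH ratio = L(x')/L(x) * lambda * p_sd(lambda*s)/p_sd(s).
        if it % 5 == 4:
            for k, p in enumerate(PARAMS):
                lo, hi = _BOUNDS[p]
                for c in range(model.n_group_cells(p)):
                    members = model.inst_of_cell[p][c]
                    idx = cell_trials[p][c]
                    if len(idx) == 0:
                        continue
                    m, s = mu[p][c], sd[p][c]
                    lam = math.exp(0.2 * rng.standard_normal())
                    s_new = lam * s
                    lp_new = priors.logp_sd(p, s_new)
                    if not np.isfinite(lp_new):
                        continue
                    x_new = m + lam * (subj[p][members] - m)
                    if x_new.min() < lo or x_new.max() > hi:
                        continue
                    nat_new = np.asarray(_to_natural(p, x_new), dtype=float)
                    newvals = nat_new[cell_member_pos[p][c]]
                    new_ll = _ll_subset_vals(rt, upper, tvals["z"], tvals["v"],
                                             tvals["a"], tvals["t0"], idx, k,
                                             newvals, lls_buf)
                    if not np.isfinite(new_ll):
                        continue
                    old_ll = trial_ll[idx].sum()
                    dlog = (new_ll - old_ll + math.log(lam)
                            + lp_new - priors.logp_sd(p, s))
                    if math.log(rng.random()) < dlog:
                        subj[p][members] = x_new
                        sd[p][c] = s_new
                        tvals[p][idx] = newvals
                        trial_ll[idx] = lls_buf[:len(idx)]
        # diminishing adaptation during burn-in
        if it < burn_in and (it + 1) % window == 0:
            gain = min(0.25, 2.0 / math.sqrt((it + 1) / window))
            for p in PARAMS:
                rate = acc[p] / window
                prop_scale[p] *= np.exp(gain * (rate - 0.44))
                np.clip(prop_scale[p], 1e-4, 5.0, out=prop_scale[p])
                acc[p][:] = 0
        if it >= burn_in:
            j = it - burn_in
            for p in PARAMS:
                store_subj[p][j] = subj[p]
                store_mu[p][j] = mu[p]
                store_sd[p][j] = sd[p]
            store_ll[j] = trial_ll.sum()
    return store_subj, store_mu, store_sd, store_ll


def sample_posterior(model: HierModel, chains: int = 4, iterations: int = 2000,
                     burn_in: int = 1000, seed: int = 0) -> PosteriorSamples:
    """Run ``chains`` independent adaptive MCMC chains and collect draws.

    Desk-scale default is 4 x 2000 iterations (1000 burn-in); the full-scale
    setting of 10000/5000 is a parameter choice, not a code path.
    """
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    kept = iterations - burn_in
    g_mu = {p: np.empty((chains, kept, model.n_group_cells(p))) for p in PARAMS}
    g_sd = {p: np.empty((chains, kept, model.n_group_cells(p))) for p in PARAMS}
    s_all = {p: np.empty((chains, kept, len(model.inst_subject[p]))) for p in PARAMS}
    ll = np.empty((chains, kept))
    for ch in range(chains):
        chain_seed = (int(seed) * 1000003 + 7919 * ch) % (2**31 - 1)
        ss, sm, ssd, sll = _run_chain(model, iterations, burn_in, chain_seed)
        for p in PARAMS:
            s_all[p][ch] = ss[p]
            g_mu[p][ch] = sm[p]
            g_sd[p][ch] = ssd[p]
        ll[ch] = sll
    return PosteriorSamples(spec=model.spec, chains=chains, kept=kept,
                            cells=dict(model.cells), subjects=list(model.subjects),
                            inst_subject=dict(model.inst_subject),
                            inst_cell=dict(model.inst_cell),
                            group_mu=g_mu, group_sd=g_sd, subj=s_all, loglik=ll)


def dic(model: HierModel, samples: PosteriorSamples) -> float:
    """Deviance information criterion: DIC = D̄ + pD = 2·D̄ − D(θ̄).

    D̄ is the posterior mean deviance (−2 log L over retained draws); D(θ̄)
    evaluates the deviance at the posterior mean of the subject-level
    parameters (transformed scale, then mapped back).
    """
    dbar = float(np.mean(-2.0 * samples.loglik))
    tvals = {}
    for p in PARAMS:
        mean_t = samples.subj[p].reshape(-1, samples.subj[p].shape[-1]).mean(0)
        tvals[p] = np.asarray(_to_natural(p, mean_t))[model.trial_inst[p]]
    buf = np.empty(model.n_trials)
    ll_hat = _ll_full(model.rt, model.upper, tvals["z"], tvals["v"],
                      tvals["a"], tvals["t0"], buf)
    d_hat = -2.0 * float(ll_hat)
    return 2.0 * dbar - d_hat
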