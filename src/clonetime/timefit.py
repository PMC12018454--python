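"""Bayesian calibration of mutation-count trees into calendar time.

Branch lengths in mutations are converted to branch durations in years under
a Poisson model: the observed count on a branch is Poisson with mean

    duration x sensitivity x mutation rate  (+ embryonic excess),

with separate constant wild-type and mutant rates — the mutant rate applies
only to branches inside the driver clade, not to the trunk above its MRCA,
so the driver is implicitly acquired at the end of the trunk.  An excess of
``nu_embryo`` mutations attributable to development is spread over the part
of each branch lying inside the first year of life, so the excess enters
every root-to-tip path exactly once.  Because flat priors on free node times
would otherwise let coalescences drift out of the development window and
leave the excess unidentified, wild-type (non-clade) coalescences are
constrained to an embryonic window (default the first year) — the burst of
early coalescences these phylogenies show; the window can be widened or
disabled (``embryo_window=None``) for trees with late wild-type expansions.
Node times are parameterized by stick-breaking fractions along root-to-tip
paths, which enforces the constraint that every root-to-tip duration equals
that colony's sampling age exactly, in every posterior draw.

Sampling is adaptive random-walk Metropolis within Gibbs (numba-compiled),
default four chains; split-R-hat is reported for the rate parameters.
Several patients can be fit jointly with shared rates (a cohort fit), which
is what identifies the wild-type rate when each patient is sampled at a
single age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .trees import Tree
from .util import split_rhat

__all__ = [
    "branch_loglik",
    "TimeTree",
    "CohortTimeFit",
    "fit_time_tree",
    "fit_time_trees",
    "infer_latency",
    "trunk_no_wildtype",
]

RATE_PRIOR_HI = 200.0   # SNV / year, flat
NU_PRIOR_HI = 300.0     # development excess SNVs, flat


def branch_loglik(count, duration, sensitivity, rate, embryo_excess: float = 0.0):
    """Poisson log-probability of a branch's mutation count.

    Mean = duration * sensitivity * rate + sensitivity * embryo_excess;
    counts may be non-integer (sensitivity/CNA-corrected), in which case the
    continuous extension c log mu - mu - lgamma(c+1) is used.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    mu = duration * sensitivity * rate + sensitivity * embryo_excess
    if mu <= 0:
        return 0.0 if count == 0 else -math.inf
    return count * math.log(mu) - mu - math.lgamma(count + 1)


# ------------------------------------------------------------ numba kernels
@njit(cache=True)
def _times_tree(parent, preorder, lo, hi, is_tip, ages, A, f, t):
    for i in range(lo, hi):
        v = preorder[i]
        p = parent[v]
        if p < 0:
            t[v] = 0.0
        elif is_tip[v]:
            t[v] = ages[v]
        else:
            t[v] = t[p] + f[v] * (A[v] - t[p])


@njit(cache=True)
def _ll_tree(parent, lo, hi, t, counts, sens, in_clade, lw, lm, nu):
    ll = 0.0
    for v in range(lo, hi):
        p = parent[v]
        if p < 0:
            continue
        dur = t[v] - t[p]
        a = t[p] if t[p] < 1.0 else 1.0
        b = t[v] if t[v] < 1.0 else 1.0
        emb = b - a
        if emb < 0.0:
            emb = 0.0
        rate = lm if in_clade[v] else lw
        mu = sens[v] * (rate * dur + nu * emb)
        c = counts[v]
        if mu <= 0.0:
            if c > 0.0:
                return -1e300
        else:
            ll += c * math.log(mu) - mu - math.lgamma(c + 1.0)
    return ll


@njit(cache=True)
def _run_chain(
    parent, preorder, node_off, is_tip, ages, A, counts, sens, in_clade,
    tree_of_node, has_clade, iters, thin, seed, lw0, lm0, nu0,
):
    n = parent.shape[0]
    n_trees = node_off.shape[0] - 1
    np.random.seed(seed)
    f = np.full(n, 0.5)
    t = np.empty(n)
    for k in range(n_trees):
        _times_tree(parent, preorder, node_off[k], node_off[k + 1],
                    is_tip, ages, A, f, t)
    lw, lm, nu = lw0, lm0, nu0
    ll = np.empty(n_trees)
    for k in range(n_trees):
        ll[k] = _ll_tree(parent, node_off[k], node_off[k + 1], t, counts,
                         sens, in_clade, lw, lm, nu)
    free = np.empty(n, np.int64)
    n_free = 0
    for v in range(n):
        if parent[v] >= 0 and not is_tip[v]:
            free[n_free] = v
            n_free += 1
    scale_f = np.full(n, 0.15)
    acc_f = np.zeros(n)
    try_f = np.zeros(n)
    scale_r = np.array([0.05, 0.05, 10.0])  # log lw, log lm, nu (natural)
    acc_r = np.zeros(3)
    try_r = np.zeros(3)
    burn = iters // 2
    n_keep = (iters - burn) // thin
    out_rates = np.empty((n_keep, 3))
    out_t = np.empty((n_keep, n))
    kept = 0
    t_prop = np.empty(n)
    for it in range(iters):
        # node-time updates (reflected random walk on the stick fraction)
        for ii in range(n_free):
            v = free[ii]
            k = tree_of_node[v]
            old = f[v]
            prop = old + scale_f[v] * np.random.normal()
            prop = prop % 2.0
            if prop > 1.0:
                prop = 2.0 - prop
            if prop <= 0.0 or prop >= 1.0:
                continue
            f[v] = prop
            _times_tree(parent, preorder, node_off[k], node_off[k + 1],
                        is_tip, ages, A, f, t_prop)
            # copy this tree's segment into a scratch time vector view
            llp = _ll_tree(parent, node_off[k], node_off[k + 1], t_prop,
                           counts, sens, in_clade, lw, lm, nu)
            try_f[v] += 1.0
            if math.log(np.random.random()) < llp - ll[k]:
                ll[k] = llp
                for j in range(node_off[k], node_off[k + 1]):
                    t[j] = t_prop[j]
                acc_f[v] += 1.0
            else:
                f[v] = old
        # rate updates
        for r in range(3):
            if r == 1 and not has_clade:
                continue
            lw_p, lm_p, nu_p = lw, lm, nu
            if r == 0:
                lw_p = lw * math.exp(scale_r[0] * np.random.normal())
                if lw_p <= 0.0 or lw_p > 200.0:
                    continue
                jac = math.log(lw_p) - math.log(lw)
            elif r == 1:
                lm_p = lm * math.exp(scale_r[1] * np.random.normal())
                if lm_p <= 0.0 or lm_p > 200.0:
                    continue
                jac = math.log(lm_p) - math.log(lm)
            else:
                nu_p = nu + scale_r[2] * np.random.normal()
                if nu_p < 0.0 or nu_p > 300.0:
                    continue
                jac = 0.0
            tot_new = 0.0
            tot_old = 0.0
            ll_new = np.empty(n_trees)
            for k in range(n_trees):
                ll_new[k] = _ll_tree(parent, node_off[k], node_off[k + 1], t,
                                     counts, sens, in_clade, lw_p, lm_p, nu_p)
                tot_new += ll_new[k]
                tot_old += ll[k]
            try_r[r] += 1.0
            if math.log(np.random.random()) < tot_new - tot_old + jac:
                lw, lm, nu = lw_p, lm_p, nu_p
                for k in range(n_trees):
                    ll[k] = ll_new[k]
                acc_r[r] += 1.0
        # adaptation during burn-in
        if it < burn and (it + 1) % 50 == 0:
            for ii in range(n_free):
                v = free[ii]
                if try_f[v] > 0:
                    rate_acc = acc_f[v] / try_f[v]
                    scale_f[v] *= math.exp(0.6 * (rate_acc - 0.44))
                    if scale_f[v] > 1.0:
                        scale_f[v] = 1.0
                    acc_f[v] = 0.0
                    try_f[v] = 0.0
            for r in range(3):
                if try_r[r] > 0:
                    rate_acc = acc_r[r] / try_r[r]
                    scale_r[r] *= math.exp(0.6 * (rate_acc - 0.44))
                    acc_r[r] = 0.0
                    try_r[r] = 0.0
        if it >= burn and (it - burn) % thin == 0 and kept < n_keep:
            out_rates[kept, 0] = lw
            out_rates[kept, 1] = lm
            out_rates[kept, 2] = nu
            for v in range(n):
                out_t[kept, v] = t[v]
            kept += 1
    return out_rates[:kept], out_t[:kept]


# -------------------------------------------------------------- result types
@dataclass
class TimeTree:
    """Calendar-time calibration of one patient's mutation tree."""

    tree: Tree
    node_times_mean: np.ndarray
    node_time_draws: np.ndarray        # draws x nodes, years
    clade_node: int | None
    rates: dict                        # posterior draws: lambda_wt/lambda_mut/nu
    rhat: dict
    tip_ages: np.ndarray

    @property
    def clone_onset_draws(self) -> np.ndarray | None:
        if self.clade_node is None:
            return None
        return self.node_time_draws[:, self.clade_node]

    def durations_mean(self) -> np.ndarray:
        dur = np.zeros(self.tree.n_nodes)
        for v in range(self.tree.n_nodes):
            p = self.tree.parent[v]
            if p >= 0:
                dur[v] = self.node_times_mean[v] - self.node_times_mean[p]
        return dur

    def time_tree(self) -> Tree:
        """Topology with posterior-mean branch durations (years)."""
        out = self.tree.copy()
        out.lengths = self.durations_mean()
        return out


@dataclass
class CohortTimeFit:
    """Joint fit over several patients (rates shared across the cohort)."""

    patients: list
    rates: dict
    rhat: dict

    def rate_summary(self, name: str = "lambda_wt") -> dict:
        x = self.rates[name]
        lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
        return {"mean": float(np.mean(x)), "median": float(med),
                "ci95": [float(lo), float(hi)]}


def _prepare(tree: Tree, counts, ages, clade_node, sens, embryo_window=1.0):
    n = tree.n_nodes
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (n,):
        raise ValueError("counts must have one entry per node")
    ages_full = np.zeros(n)
    ages_tip = np.asarray(ages, dtype=float)
    if ages_tip.shape != (tree.n_tips,):
        raise ValueError("ages must have one entry per tip")
    ages_full[: tree.n_tips] = ages_tip
    is_tip = np.zeros(n, dtype=np.bool_)
    is_tip[: tree.n_tips] = True
    # A[v]: earliest sampling age among descendant tips (stick upper bound)
    A = np.full(n, np.inf)
    for v in tree.postorder():
        if tree.is_tip(v):
            A[v] = ages_full[v]
        p = tree.parent[v]
        if p >= 0 and A[v] < A[p]:
            A[p] = A[v]
    in_clade = np.zeros(n, dtype=np.bool_)
    if clade_node is not None:
        ch = tree.children()
        stack = list(ch[clade_node])
        while stack:
            v = stack.pop()
            in_clade[v] = True
            stack.extend(ch[v])
    s = np.ones(n) if sens is None else np.asarray(sens, dtype=float)
    if embryo_window is not None:
        # wild-type coalescences sit in the embryonic burst; the clade MRCA
        # (end of the trunk) and clade-internal nodes stay free
        for v in range(n):
            if (not is_tip[v] and not in_clade[v]
                    and (clade_node is None or v != clade_node)):
                A[v] = min(A[v], float(embryo_window))
    return counts, ages_full, is_tip, A, in_clade, s


def fit_time_trees(
    inputs: list[dict],
    chains: int = 4,
    iters: int = 20000,
    thin: int = 10,
    seed: int = 0,
    embryo_window: float | None = 1.0,
) -> CohortTimeFit:
    """Joint MCMC calibration of one or more patients with shared rates.

    Each input dict has keys ``tree`` (Tree), ``counts`` (per-node mutation
    counts), ``ages`` (per-tip sampling ages in years), and optionally
    ``clade_node`` and ``sens`` (per-branch detection sensitivity).
    """
    prepared = []
    for d in inputs:
        prepared.append(
            (_prepare(d["tree"], d["counts"], d["ages"],
                      d.get("clade_node"), d.get("sens"), embryo_window), d)
        )
    # concatenate into a forest with contiguous per-tree node blocks
    offs = [0]
    parent_all, pre_all, counts_all, sens_all = [], [], [], []
    ages_all, A_all, istip_all, clade_all, tree_of = [], [], [], [], []
    for k, ((counts, ages_full, is_tip, A, in_clade, s), d) in enumerate(prepared):
        tree = d["tree"]
        off = offs[-1]
        parent_all.append(np.where(tree.parent >= 0, tree.parent + off, -1))
        pre_all.append(np.asarray(tree.preorder(), dtype=np.int64) + off)
        counts_all.append(counts)
        sens_all.append(s)
        ages_all.append(ages_full)
        A_all.append(A)
        istip_all.append(is_tip)
        clade_all.append(in_clade)
        tree_of.append(np.full(tree.n_nodes, k, dtype=np.int64))
        offs.append(off + tree.n_nodes)
    parent = np.concatenate(parent_all)
    preorder = np.concatenate(pre_all)
    node_off = np.asarray(offs, dtype=np.int64)
    counts = np.concatenate(counts_all)
    sens = np.concatenate(sens_all)
    ages = np.concatenate(ages_all)
    A = np.concatenate(A_all)
    is_tip = np.concatenate(istip_all)
    in_clade = np.concatenate(clade_all)
    tree_of_node = np.concatenate(tree_of)
    has_clade = bool(in_clade.any())

    rate_chains, time_chains = [], []
    for c in range(chains):
        r, tdraws = _run_chain(
            parent, preorder, node_off, is_tip, ages, A, counts, sens,
            in_clade, tree_of_node, has_clade, iters, thin,
            (seed * 7919 + c * 104729 + 1) % (2**31 - 1),
            20.0, 30.0, 50.0,
        )
        rate_chains.append(r)
        time_chains.append(tdraws)
    rates_arr = np.stack(rate_chains)        # chains x draws x 3
    times_arr = np.concatenate(time_chains)  # all draws x nodes
    rhat = {
        "lambda_wt": split_rhat(rates_arr[:, :, 0]),
        "lambda_mut": split_rhat(rates_arr[:, :, 1]) if has_clade else float("nan"),
        "nu_embryo": split_rhat(rates_arr[:, :, 2]),
    }
    flat = rates_arr.reshape(-1, 3)
    rates = {
        "lambda_wt": flat[:, 0],
        "lambda_mut": flat[:, 1],
        "nu_embryo": flat[:, 2],
    }
    patients = []
    for k, ((counts_k, ages_full, is_tip_k, A_k, in_clade_k, s_k), d) in enumerate(prepared):
        sl = slice(node_off[k], node_off[k + 1])
        td = times_arr[:, sl]
        patients.append(
            TimeTree(
                tree=d["tree"],
                node_times_mean=td.mean(axis=0),
                node_time_draws=td,
                clade_node=d.get("clade_node"),
                rates=rates,
                rhat=rhat,
                tip_ages=np.asarray(d["ages"], dtype=float),
            )
        )
    return CohortTimeFit(patients=patients, rates=rates, rhat=rhat)


def fit_time_tree(
    tree: Tree,
    counts,
    ages,
    clade_node: int | None = None,
    sens=None,
    chains: int = 4,
    iters: int = 20000,
    thin: int = 10,
    seed: int = 0,
    embryo_window: float | None = 1.0,
) -> TimeTree:
    """Calibrate a single patient's tree (per-patient rates)."""
    fit = fit_time_trees(
        [dict(tree=tree, counts=counts, ages=ages, clade_node=clade_node,
              sens=sens)],
        chains=chains, iters=iters, thin=thin, seed=seed,
        embryo_window=embryo_window,
    )
    return fit.patients[0]


def infer_latency(tt: TimeTree, age_at_diagnosis: float) -> dict:
    """Years from clone onset (mutant-clade MRCA) to diagnosis, with 95% CI."""
    onset = tt.clone_onset_draws
    if onset is None:
        raise ValueError("no mutant clade on this tree")
    lat = age_at_diagnosis - onset
    if np.any(lat < 0):
        warnings.warn("clone onset after diagnosis in some draws; truncated at 0")
        lat = np.maximum(lat, 0.0)
    lo, med, hi = np.quantile(lat, [0.025, 0.5, 0.975])
    return {
        "latency_median": float(med),
        "ci95": [float(lo), float(hi)],
        "onset_median": float(np.median(onset)),
        "draws": lat,
    }


def trunk_no_wildtype(
    mean_root_to_tip_burden: float,
    cohort_lambda_mut: float,
    cohort_lambda_wt: float,
    age: float,
    burden_at_birth: float = 60.0,
) -> dict:
    """Approximate trunk molecular length when no wild-type colonies exist.

    The mutant clade's duration is its average root-to-tip burden divided by
    the cohort mutant rate; the remaining lifespan is the trunk duration,
    converted to molecular time at the cohort wild-type rate plus the
    expected burden at birth.
    """
    if cohort_lambda_mut <= 0 or cohort_lambda_wt <= 0:
        raise ValueError("rates must be positive")
    clade_duration = mean_root_to_tip_burden / cohort_lambda_mut
    trunk_duration = age - clade_duration
    if trunk_duration < 0:
        raise ValueError("clade duration exceeds the age at sampling")
    trunk_len = trunk_duration * cohort_lambda_wt + burden_at_birth
    return {
        "clade_duration": clade_duration,
        "trunk_duration": trunk_duration,
        "trunk_molecular_length": trunk_len,
    }
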