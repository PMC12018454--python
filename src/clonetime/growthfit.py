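"""Clonal growth-rate inference from coalescence times.

A driver-mutant clone is modelled as a deterministic three-parameter logistic
population trajectory

    N(t) = N / (1 + exp(-s * (t - t_m)))

with saturation size ``N`` (a composite of effective population size and
generation time, in year units), instantaneous per-year growth rate ``s`` and
curve midpoint ``t_m`` (years since conception).  Coalescence times of tips
sampled from the clone follow the backwards-in-time inhomogeneous Kingman
coalescent with pair rate k(k-1)/(2 N(t)); the likelihood of the observed
coalescence times is fit by MCMC under uniform priors

    s ~ U(0.001, s_upper),  t_m ~ U(age of MRCA, age at diagnosis),
    log10(N) ~ U(4, 7).

The annualized growth rate is S = exp(s) - 1 (reported as a percentage) and
the clone doubling time is 1/log2(1+S) = ln2/s years.

An orthogonal maximum-likelihood estimator based on the sum of internal
(shared) branch lengths of the ultrametric clade tree is provided as a
cross-check (`internal_length_mle`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .util import split_rhat, format_thousands

__all__ = [
    "LogisticTrajectory",
    "GrowthPosterior",
    "logistic_population",
    "cumulative_intensity",
    "coalescent_loglik",
    "fit_growth_times",
    "fit_growth",
    "escalate_prior",
    "annualized_growth",
    "annualized_growth_str",
    "doubling_time",
    "internal_length_mle",
]

LOG10N_PRIOR = (4.0, 7.0)
S_PRIOR_LOWER = 0.001


@dataclass(frozen=True)
class LogisticTrajectory:
    """Logistic clone-size trajectory (N dimensionless, s per year, t_m years)."""

    N: float
    s: float
    t_m: float

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.s <= 0:
            raise ValueError("s must be positive")


def logistic_population(t, traj: LogisticTrajectory):
    """Clone size N(t) = N / (1 + exp(-s (t - t_m))); increasing, in (0, N)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    with np.errstate(over="ignore"):
        out = traj.N / (1.0 + np.exp(-traj.s * (t - traj.t_m)))
    return out if out.ndim else float(out)


def _F(t, traj: LogisticTrajectory):
    """Antiderivative of 1/N(t) times N:  F(t) = t - e^{-s(t-t_m)}/s."""
    with np.errstate(over="ignore"):
        return t - np.exp(-traj.s * (t - traj.t_m)) / traj.s


def cumulative_intensity(t0: float, t1: float, traj: LogisticTrajectory) -> float:
    """Integrated inverse population size  Λ = ∫_{t0}^{t1} dt / N(t)  (closed form)."""
    if not (math.isfinite(t0) and math.isfinite(t1)):
        raise ValueError("integration bounds must be finite")
    if t1 < t0:
        raise ValueError("t0 must not exceed t1")
    if t0 == t1:
        return 0.0
    with np.errstate(over="ignore"):
        # difference written to stay accurate when both exponentials are tiny
        e0 = math.exp(min(-traj.s * (t0 - traj.t_m), 745.0))
        e1 = math.exp(min(-traj.s * (t1 - traj.t_m), 745.0))
    return ((t1 - t0) + (e0 - e1) / traj.s) / traj.N


def _inverse_F(c: float, traj: LogisticTrajectory) -> float:
    """Solve F(t) = c for t (F is strictly increasing).

    With u = s (t - t_m) and a = s (c - t_m) the equation is u - e^{-u} = a,
    whose solution is u = a + W(e^{-a}) (principal Lambert W branch).
    """
    a = traj.s * (c - traj.t_m)
    if a > 700.0:
        u = a  # W(e^-a) underflows to 0
    elif a < -30.0:
        # W(e^{-a}) is huge; solve w + log w = -a by Newton from w0 = -a - log(-a)
        w = -a - math.log(-a)
        for _ in range(50):
            f = w + math.log(w) + a
            w_new = w - f / (1.0 + 1.0 / w)
            if w_new <= 0:
                w_new = w / 2
            if abs(w_new - w) < 1e-13 * max(1.0, abs(w)):
                w = w_new
                break
            w = w_new
        u = a + w
    else:
        u = a + float(lambertw(math.exp(-a)).real)
    return traj.t_m + u / traj.s


def coalescent_loglik(
    coal_times: np.ndarray,
    n_tips: int,
    traj: LogisticTrajectory,
    t_sample: float,
    star_at_root: bool | str = False,
) -> float:
    """Log density of ordered coalescence times under the logistic coalescent.

    ``coal_times`` are calendar times (ascending), one per coalescence; a
    multifurcation contributes repeated equal times.  Going backwards from
    ``t_sample`` with k extant lineages the coalescence hazard at calendar
    time t is k(k-1)/(2 N(t)).

    A founder-cell star: lineages that survive back to the clone origin all
    merge there at once (the origin population is a single cell), which under
    the time-continuous model is a truncation event, not ordinary
    coalescences.  With ``star_at_root=True`` (or ``"auto"``, which switches
    on when two or more events coincide at the earliest time) the events at
    the earliest time contribute only survival mass — the integrated hazard
    above them — and no per-event hazard factors.
    """
    times = np.asarray(coal_times, dtype=float)
    if times.ndim != 1 or len(times) != n_tips - 1:
        raise ValueError("need exactly n_tips - 1 coalescence times")
    if np.any(np.diff(times) < 0):
        raise ValueError("coalescence times must be sorted ascending")
    if len(times) and times[-1] > t_sample:
        raise ValueError("coalescence times must not exceed the sampling time")
    tol = 1e-9
    if star_at_root == "auto":
        star_at_root = len(times) >= 2 and times[1] - times[0] <= tol
    ll = 0.0
    tau = t_sample
    k = n_tips
    for t in times[::-1]:
        pair = 0.5 * k * (k - 1)
        lam = cumulative_intensity(t, tau, traj)
        if not math.isfinite(lam):
            return -math.inf
        ll -= pair * lam
        if not (star_at_root and t - times[0] <= tol):
            nt = logistic_population(t, traj)
            if nt <= 0:
                return -math.inf
            ll += math.log(pair / nt)
        tau = t
        k -= 1
    return ll


def _coal_loglik_vec(
    u: np.ndarray, n_tips: int, s: float, t_m: float, N: float,
    t_sample: float, star: bool,
) -> float:
    """Vectorized twin of :func:`coalescent_loglik` used inside the MCMC.

    ``u`` must be sorted ascending; equality with the scalar implementation
    is asserted by the test suite.
    """
    m = len(u)
    grid = np.empty(m + 1)
    grid[:m] = u
    grid[m] = t_sample
    with np.errstate(over="ignore"):
        e = np.exp(np.minimum(-s * (grid - t_m), 745.0))
    F = grid - e / s
    lam = (np.diff(F)) / N                       # Λ over (u_j, u_{j+1})
    k = np.arange(2, m + 2, dtype=float)         # lineages below each event
    pair = 0.5 * k * (k - 1.0)
    if not np.all(np.isfinite(lam)):
        return -math.inf
    ll = -np.sum(pair * lam)
    nt = N / (1.0 + e[:m])
    if star:
        sel = u - u[0] > 1e-9
    else:
        sel = np.ones(m, dtype=bool)
    if np.any(nt[sel] <= 0):
        return -math.inf
    ll += np.sum(np.log(pair[sel] / nt[sel]))
    return float(ll)


# --------------------------------------------------------------------- MCMC
@dataclass
class GrowthPosterior:
    """Posterior samples of (s, t_m, log10 N) with derived growth summaries."""

    s: np.ndarray
    t_m: np.ndarray
    log10N: np.ndarray
    n_chains: int
    rhat: dict
    s_upper: float

    @property
    def S(self) -> np.ndarray:
        """Annualized growth fraction per draw, S = exp(s) - 1."""
        return np.expm1(self.s)

    @property
    def S_pct(self) -> np.ndarray:
        return self.S * 100.0

    @property
    def doubling_years(self) -> np.ndarray:
        return math.log(2) / self.s

    def summary(self) -> dict:
        def q(x):
            lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
            return {"median": float(med), "ci95": [float(lo), float(hi)]}

        out = {
            "s": q(self.s),
            "t_m": q(self.t_m),
            "log10N": q(self.log10N),
            "S_pct": q(self.S_pct),
            "doubling_days": q(self.doubling_years * 365.25),
        }
        out["rhat"] = self.rhat
        out["s_upper"] = self.s_upper
        return out


def fit_growth_times(
    coal_times: np.ndarray,
    n_tips: int,
    t_sample: float,
    t_mrca: float,
    age_at_diagnosis: float,
    seed: int,
    s_upper: float = 30.0,
    chains: int = 4,
    iters: int = 20000,
) -> GrowthPosterior:
    """MCMC fit of the logistic coalescent to observed coalescence times.

    Adaptive random-walk Metropolis with joint Gaussian proposals on
    (s, t_m, log10 N); step scales tuned toward ~30% acceptance during the
    burn-in half, which is then discarded.
    """
    times = np.sort(np.asarray(coal_times, dtype=float))
    if n_tips < 3:
        raise ValueError("clade too small: need at least 3 tips")
    t_m_lo, t_m_hi = t_mrca, age_at_diagnosis
    if not t_m_lo < t_m_hi:
        raise ValueError("midpoint prior is empty (MRCA age >= diagnosis age)")
    lo = np.array([S_PRIOR_LOWER, t_m_lo, LOG10N_PRIOR[0]])
    hi = np.array([s_upper, t_m_hi, LOG10N_PRIOR[1]])

    # The clade MRCA is the clone's founding cell: the earliest coalescence
    # (however many lineages it absorbs) is scored as truncation mass, not as
    # an ordinary hazard event — otherwise a root event sitting where N(t) is
    # near one cell rewards ever-steeper trajectories and biases s upward.
    def loglik(theta):
        s, t_m, l10n = theta
        return _coal_loglik_vec(times, n_tips, s, t_m, 10.0**l10n,
                                t_sample, True)

    rng = np.random.default_rng(seed)
    burn = iters // 2
    keep_s, keep_tm, keep_n = [], [], []
    for _c in range(chains):
        theta = lo + (hi - lo) * rng.uniform(0.05, 0.95, size=3)
        ll = loglik(theta)
        while not math.isfinite(ll):
            theta = lo + (hi - lo) * rng.uniform(0.05, 0.95, size=3)
            ll = loglik(theta)
        # Haario-style adaptive Metropolis: the three parameters ride a
        # strong ridge (steeper growth needs a later midpoint), so the
        # proposal covariance is learned from the chain during burn-in
        base_cov = np.diag((0.1 * (hi - lo)) ** 2)
        cov = base_cov.copy()
        chol = np.linalg.cholesky(cov)
        mean = theta.copy()
        m2 = np.zeros((3, 3))
        n_seen = 1
        lam = 1.0  # global scale tuned toward ~30% acceptance
        cs, ctm, cn = [], [], []
        acc = 0
        for it in range(iters):
            prop = theta + lam * (chol @ rng.standard_normal(3))
            if np.all(prop > lo) and np.all(prop < hi):
                llp = loglik(prop)
                if math.log(rng.uniform()) < llp - ll:
                    theta, ll = prop, llp
                    acc += 1
            if it < burn:
                delta = theta - mean
                mean += delta / (n_seen + 1)
                m2 += np.outer(delta, theta - mean)
                n_seen += 1
                if (it + 1) % 100 == 0:
                    rate = acc / 100.0
                    lam *= math.exp(0.7 * (rate - 0.3))
                    acc = 0
                    if n_seen > 300:
                        cov = m2 / (n_seen - 1) + 1e-10 * base_cov
                        try:
                            chol = np.linalg.cholesky(
                                (2.38**2 / 3.0) * cov + 1e-12 * np.eye(3))
                        except np.linalg.LinAlgError:
                            pass
            if it >= burn:
                cs.append(theta[0])
                ctm.append(theta[1])
                cn.append(theta[2])
        keep_s.append(cs)
        keep_tm.append(ctm)
        keep_n.append(cn)
    s_arr, tm_arr, n_arr = (np.asarray(a) for a in (keep_s, keep_tm, keep_n))
    rhat = {
        "s": split_rhat(s_arr),
        "t_m": split_rhat(tm_arr),
        "log10N": split_rhat(n_arr),
    }
    return GrowthPosterior(
        s=s_arr.ravel(),
        t_m=tm_arr.ravel(),
        log10N=n_arr.ravel(),
        n_chains=chains,
        rhat=rhat,
        s_upper=s_upper,
    )


def clade_coalescence_times(timetree, clade_node: int) -> tuple[np.ndarray, int, float, float]:
    """Extract (coal_times, n_tips, t_sample, t_mrca) for a clade of a time tree.

    ``timetree`` is a :class:`~clonetime.trees.Tree` with branch lengths in
    years; node times are depths from the root (conception).  A multifurcating
    node with c children contributes c-1 coincident coalescences.
    """
    depths = timetree.node_depths()
    ch = timetree.children()
    sets = timetree.tip_sets()
    clade_tips = np.flatnonzero(sets[clade_node])
    if len(clade_tips) < 3:
        raise ValueError("clade too small: need at least 3 tips")
    # internal nodes of the clade, including the MRCA node itself
    stack, internals = [clade_node], []
    while stack:
        v = stack.pop()
        if ch[v]:
            internals.append(v)
            stack.extend(ch[v])
    coal = []
    for v in internals:
        coal.extend([depths[v]] * (len(ch[v]) - 1))
    coal = np.sort(np.asarray(coal))
    t_sample = float(np.min(depths[clade_tips]))
    return coal, len(clade_tips), t_sample, float(depths[clade_node])


def fit_growth(
    timetree,
    clade_node: int,
    age_at_diagnosis: float,
    seed: int,
    s_upper: float = 30.0,
    chains: int = 4,
    iters: int = 20000,
) -> GrowthPosterior:
    """Fit clonal growth from a calendar-time tree's mutant clade.

    The tree should carry posterior-mean branch durations and be restricted to
    the earliest sampling timepoint before calling.
    """
    coal, n_tips, t_sample, t_mrca = clade_coalescence_times(timetree, clade_node)
    coal = np.minimum(coal, t_sample)  # guard tiny numerical overhangs
    return fit_growth_times(
        coal, n_tips, t_sample, t_mrca, age_at_diagnosis, seed,
        s_upper=s_upper, chains=chains, iters=iters,
    )


def escalate_prior(
    fit_fn,
    start_upper: float = 30.0,
    factor: float = 2.0,
    max_upper: float = 60.0,
    rel_tol: float = 0.05,
) -> tuple[float, GrowthPosterior]:
    """Double the growth-rate prior upper bound until the posterior stabilizes.

    ``fit_fn(s_upper)`` must return a :class:`GrowthPosterior`.  Returns the
    final bound and fit; stops when the posterior median of s moves by less
    than ``rel_tol`` between consecutive bounds, warning if never stabilized.
    """
    import warnings

    upper = start_upper
    fit = fit_fn(upper)
    med = float(np.median(fit.s))
    while upper < max_upper:
        nxt = min(upper * factor, max_upper)
        fit2 = fit_fn(nxt)
        med2 = float(np.median(fit2.s))
        if abs(med2 - med) <= rel_tol * max(med, 1e-12):
            return nxt, fit2
        upper, fit, med = nxt, fit2, med2
    warnings.warn("growth-rate posterior did not stabilize by max_upper")
    return upper, fit


# ---------------------------------------------------------------- transforms
def annualized_growth(s: float) -> float:
    """Annualized growth rate as a percentage: (exp(s) - 1) * 100."""
    if not math.isfinite(s):
        raise ValueError("s must be finite")
    return math.expm1(s) * 100.0


def annualized_growth_str(s: float) -> str:
    """Two-significant-figure display form, e.g. s=3.33 -> '2,700%'."""
    return format_thousands(annualized_growth(s)) + "%"


def doubling_time(S: float) -> tuple[float, float]:
    """Clone doubling time from the annualized growth fraction S.

    Returns (years, days); 1/log2(1+S) years, identically ln2/s.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    years = 1.0 / math.log2(1.0 + S)
    return years, years * 365.25


def internal_length_mle(timetree, clade_node: int) -> dict:
    """Growth-rate MLE from shared (internal) branch lengths of a clade.

    For an ultrametric clade with n tips sampled from a large exponentially
    growing population, the sum L of internal branch lengths is approximately
    the sum of n-2 independent Exp(r) intervals, giving the estimator
    r_hat = (n - 2) / L with standard error r_hat / sqrt(n - 2).  Deterministic
    in the input tree; used as an orthogonal cross-check of `fit_growth`.
    """
    ch = timetree.children()
    lengths = timetree.lengths
    stack, internal_edges, n_tips = [clade_node], [], 0
    first = True
    while stack:
        v = stack.pop()
        if ch[v]:
            if not first:
                internal_edges.append(v)
            stack.extend(ch[v])
        else:
            n_tips += 1
        first = False
    if len(internal_edges) < 2:
        raise ValueError("need at least 2 internal branches")
    L = float(np.sum([lengths[v] for v in internal_edges]))
    if L <= 0:
        return {"s_hat": math.inf, "ci95": [math.inf, math.inf], "n_tips": n_tips}
    s_hat = (n_tips - 2) / L
    se = s_hat / math.sqrt(n_tips - 2)
    return {
        "s_hat": s_hat,
        "ci95": [max(s_hat - 1.96 * se, 0.0), s_hat + 1.96 * se],
        "n_tips": n_tips,
        "sum_internal": L,
    }
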