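"""Small shared numerics and reporting helpers."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = [
    "two_sig_figs",
    "format_thousands",
    "prevalence_percent",
    "clopper_pearson",
    "split_rhat",
]


def two_sig_figs(x: float) -> float:
    """Round to two significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + 1)


def format_thousands(x: float) -> str:
    """Render a 2-s.f. rounded number with comma grouping, e.g. ``2,700``."""
    r = two_sig_figs(x)
    if r == int(r):
        return f"{int(r):,}"
    return f"{r:,}"


def prevalence_percent(carriers: int, cohort_size: int) -> float:
    """Carrier prevalence as a percentage, rounded to two significant figures."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    return two_sig_figs(100.0 * carriers / cohort_size)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial proportion confidence interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat convergence diagnostic for a scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    then the usual between/within variance ratio is formed.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-d (n_chains, n_draws)")
    half = chains.shape[1] // 2
    if half < 2:
        return float("nan")
    parts = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
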