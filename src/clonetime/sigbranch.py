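"""Mutational-signature refitting and per-branch attribution.

Single-base substitutions are classified into the standard 96 channels
(6 pyrimidine-centred substitution types x 16 trinucleotide contexts).
Branch groups of a phylogeny are refit against a fixed set of reference
spectra by maximum-likelihood multinomial mixture estimation (EM), per-group
exposures become the priors P0 for exact per-mutation Bayes membership
probabilities, and branch-level attributions are the averages of those
memberships.  C>T-at-CpG proportions — a readout of historical cell
divisions — are summarized with exact binomial confidence intervals.

The packaged SBS1 / SBSblood / SBS18 spectra are synthetic stand-ins built
programmatically with the defining features of each process (SBS1: C>T at
CpG; SBSblood: broad clock-like; SBS18: C>A-heavy); they are not the
published reference tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import clopper_pearson

__all__ = [
    "SUBSTITUTIONS",
    "BASES",
    "channel_index",
    "channel_to_context",
    "classify_channel",
    "is_ctcpg_channel",
    "synthetic_spectra",
    "read_signatures",
    "write_signatures",
    "ExposureEstimate",
    "fit_exposures",
    "membership_probability",
    "attribute_branch",
    "group_branches",
    "group_mutation_counts",
    "ctcpg_summary",
]

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"
_COMPL = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPL)[::-1]


def channel_index(sub: str, five: str, three: str) -> int:
    return SUBSTITUTIONS.index(sub) * 16 + BASES.index(five) * 4 + BASES.index(three)


def channel_to_context(channel: int) -> tuple[str, str]:
    """Inverse of the channel encoding: returns (trinucleotide, alt base)."""
    if not 0 <= channel < 96:
        raise ValueError("channel must lie in 0..95")
    sub, rest = divmod(channel, 16)
    five, three = divmod(rest, 4)
    ref, alt = SUBSTITUTIONS[sub].split(">")
    return BASES[five] + ref + BASES[three], alt


def classify_channel(ref_context: str, alt: str) -> tuple[int, bool]:
    """Map a trinucleotide context + alternate base to its 96 channel.

    Purine-centred input is reverse-complemented to the pyrimidine strand.
    Returns (channel, is_CtoT_CpG); the flag is true for C>T with a 3' G.
    """
    ctx = ref_context.upper()
    alt = alt.upper()
    if len(ctx) != 3 or any(b not in BASES for b in ctx) or alt not in BASES:
        raise ValueError(f"ambiguous or invalid bases: {ref_context!r}>{alt!r}")
    ref = ctx[1]
    if ref in "AG":
        ctx = _revcomp(ctx)
        alt = alt.translate(_COMPL)
        ref = ctx[1]
    if alt == ref:
        raise ValueError("alt equals ref")
    chan = channel_index(f"{ref}>{alt}", ctx[0], ctx[2])
    return chan, is_ctcpg_channel(chan)


def is_ctcpg_channel(channel: int) -> bool:
    sub, rest = divmod(channel, 16)
    return SUBSTITUTIONS[sub] == "C>T" and rest % 4 == BASES.index("G")


# ------------------------------------------------------------------- spectra
def synthetic_spectra() -> pd.DataFrame:
    """Deterministic synthetic 96-channel spectra for SBS1, SBSblood, SBS18.

    Synthetic stand-ins, not the published tables: SBS1 concentrates on C>T
    at NpCpG, SBSblood is a broad flat-ish clock-like spectrum with a mild
    T>C lean, SBS18 is dominated by C>A.  All channels strictly positive.
    """
    rng = np.random.default_rng(96_2024)
    sbs1 = np.full(96, 0.15 / 92)
    for five in BASES:
        sbs1[channel_index("C>T", five, "G")] = 0.85 / 4

    blood = rng.gamma(4.0, 1.0, size=96)
    for five in BASES:
        for three in BASES:
            blood[channel_index("T>C", five, three)] *= 1.8
            blood[channel_index("C>T", five, three)] *= 1.3
    blood /= blood.sum()

    sbs18 = np.full(96, 0.25 / 80)
    weights = rng.gamma(3.0, 1.0, size=16)
    weights /= weights.sum()
    k = 0
    for five in BASES:
        for three in BASES:
            sbs18[channel_index("C>A", five, three)] = 0.75 * weights[k]
            k += 1
    sbs18 /= sbs18.sum()

    idx = [f"{channel_to_context(c)[0]}>{channel_to_context(c)[1]}" for c in range(96)]
    return pd.DataFrame(
        {"SBS1": sbs1 / sbs1.sum(), "SBSblood": blood, "SBS18": sbs18}, index=idx
    )


def read_signatures(path) -> pd.DataFrame:
    """Read a COSMIC-style 96-row signature TSV (channels x signatures)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if len(df) != 96:
        raise ValueError(f"expected 96 channels, got {len(df)}")
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    return df


def write_signatures(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ----------------------------------------------------------------- exposures
@dataclass
class ExposureEstimate:
    """Mixing proportions of reference spectra for one mutation set."""

    proportions: pd.Series
    loglik: float
    n_mutations: int
    converged: bool
    non_identifiable: bool = False
    ci95: pd.DataFrame | None = None


def _dedup_groups(S: np.ndarray) -> list[list[int]]:
    groups, used = [], set()
    for i in range(S.shape[1]):
        if i in used:
            continue
        grp = [i]
        for j in range(i + 1, S.shape[1]):
            if j not in used and np.allclose(S[:, i], S[:, j], atol=1e-12):
                grp.append(j)
                used.add(j)
        groups.append(grp)
    return groups


def fit_exposures(
    counts96,
    spectra: pd.DataFrame,
    tol: float = 1e-10,
    max_iter: int = 10000,
    ci: bool = False,
    ci_draws: int = 800,
    seed: int = 0,
) -> ExposureEstimate:
    """Maximum-likelihood signature mixing proportions by EM.

    The observed 96-channel counts are modelled as a multinomial whose
    channel probabilities are a convex mixture of the reference spectra.
    The EM log-likelihood is checked to be non-decreasing every iteration.
    With ``ci=True``, 95% credibility intervals are drawn from the
    Dirichlet(1,...,1)-prior posterior via Gibbs sampling.
    """
    c = np.asarray(counts96, dtype=float)
    if c.ndim != 1 or len(c) != 96:
        raise ValueError("counts96 must be a 96-vector")
    if c.sum() <= 0:
        raise ValueError("no mutations to fit")
    S = spectra.to_numpy(dtype=float)
    K = S.shape[1]
    if K < 2:
        raise ValueError("need at least 2 reference spectra")
    pi = np.full(K, 1.0 / K)
    last_ll = -math.inf
    converged = False
    for _ in range(max_iter):
        mix = S @ pi
        with np.errstate(divide="ignore"):
            ll = float(np.sum(c * np.log(np.where(c > 0, mix, 1.0))))
        assert ll >= last_ll - 1e-9, "EM log-likelihood decreased"
        if ll - last_ll < tol and last_ll > -math.inf:
            converged = True
            break
        last_ll = ll
        r = S * pi[None, :] / mix[:, None]  # responsibilities per channel
        pi = (c @ r) / c.sum()
    dup = _dedup_groups(S)
    non_ident = any(len(g) > 1 for g in dup)
    if non_ident:
        for g in dup:
            if len(g) > 1:
                pi[g] = pi[g].sum() / len(g)
    est = ExposureEstimate(
        proportions=pd.Series(pi, index=spectra.columns),
        loglik=last_ll,
        n_mutations=int(c.sum()),
        converged=converged,
        non_identifiable=non_ident,
    )
    if ci:
        est.ci95 = _exposure_ci(c, S, spectra.columns, pi, ci_draws, seed)
    return est


def _exposure_ci(c, S, names, pi0, n_draws, seed) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    K = S.shape[1]
    pi = pi0.copy()
    burn = max(100, n_draws // 4)
    draws = np.empty((n_draws, K))
    nz = np.flatnonzero(c > 0)
    cnz = c[nz].astype(int)
    Snz = S[nz]
    for it in range(burn + n_draws):
        r = Snz * pi[None, :]
        r /= r.sum(axis=1, keepdims=True)
        n_k = np.zeros(K)
        for j in range(len(nz)):
            n_k += rng.multinomial(cnz[j], r[j])
        pi = rng.dirichlet(1.0 + n_k)
        if it >= burn:
            draws[it - burn] = pi
    lo, mean, hi = (
        np.quantile(draws, 0.025, axis=0),
        draws.mean(axis=0),
        np.quantile(draws, 0.975, axis=0),
    )
    return pd.DataFrame({"mean": mean, "lo95": lo, "hi95": hi}, index=names)


def membership_probability(channel: int, spectra: pd.DataFrame, P0) -> pd.Series:
    """Exact Bayes posterior that a mutation in ``channel`` came from each
    signature:  P(Sig | mut) ∝ P(mut | Sig) P0(Sig)."""
    p0 = np.asarray(P0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("P0 must sum to 1")
    lik = spectra.to_numpy(dtype=float)[channel]
    num = lik * p0
    tot = num.sum()
    if tot <= 0:
        raise ValueError("channel has zero probability under every signature")
    return pd.Series(num / tot, index=spectra.columns)


def attribute_branch(channels, spectra: pd.DataFrame, P0) -> pd.Series | None:
    """Branch-level attribution: mean of per-mutation membership probabilities.

    Returns None for an empty branch (caller skips and flags).
    """
    channels = list(channels)
    if not channels:
        return None
    rows = [membership_probability(c, spectra, P0) for c in channels]
    out = pd.concat(rows, axis=1).mean(axis=1)
    return out / out.sum()


# ------------------------------------------------------------ branch groups
GROUP_NAMES = ["wt", "pre_cml", "early_cml", "cml", "early_in_life"]


def group_branches(tree, clade_node: int | None) -> dict[str, set[int]]:
    """Structural branch groups of a colony phylogeny.

    cml: every branch of the driver clade (below its MRCA); early_cml: the
    shared (internal) branches within the expansion — a subset of cml;
    pre_cml: the trunk, i.e. the branch above the clade MRCA; wt: every other
    branch.  The early-in-life group is a molecular-time cutoff on mutations,
    not branches (see `group_mutation_counts`).
    """
    ch = tree.children()
    root = tree.root
    cml, early = set(), set()
    if clade_node is not None:
        stack = list(ch[clade_node])
        while stack:
            v = stack.pop()
            cml.add(v)
            if ch[v]:
                early.add(v)
            stack.extend(ch[v])
    pre = {clade_node} if clade_node is not None else set()
    wt = {v for v in range(tree.n_nodes) if v != root} - cml - pre
    return {"wt": wt, "pre_cml": pre, "early_cml": early, "cml": cml}


def group_mutation_counts(
    tree,
    mut_branches,
    channels,
    clade_node: int | None,
    top_n: int = 100,
    per_lineage: bool = False,
) -> pd.DataFrame:
    """96-channel counts per branch group (rows: group, cols: 0..95).

    ``tree`` must carry molecular branch lengths (mutation counts).  The
    early-in-life group is the first ``top_n`` mutations of molecular time:
    by default a global root-depth cutoff — a mutation counts as early if its
    branch starts above the cutoff, taking at most the branch's portion below
    it.  With ``per_lineage=True`` the cutoff applies along each root-to-tip
    path independently (same rule, since branch start depth is shared).
    Groups overlap by construction (cml ⊇ early_cml; early_in_life cuts
    across the others), mirroring how the five groups are defined.
    """
    mut_branches = np.asarray(mut_branches)
    channels = np.asarray(channels)
    groups = group_branches(tree, clade_node)
    depth0 = tree.node_depths() - tree.lengths  # molecular depth at branch start
    counts = pd.DataFrame(
        0, index=GROUP_NAMES, columns=range(96), dtype=int
    )
    order = np.argsort(mut_branches, kind="stable")
    # within-branch ordering is arbitrary; mutation-id order is used
    early_taken: dict[int, int] = {}
    for i in order:
        b = int(mut_branches[i])
        chan = int(channels[i])
        for g, members in groups.items():
            if b in members:
                counts.loc[g, chan] += 1
        room = top_n - depth0[b]
        taken = early_taken.get(b, 0)
        if room > taken:
            counts.loc["early_in_life", chan] += 1
            early_taken[b] = taken + 1
    return counts


def ctcpg_summary(channels, branches=None, exclude_branches=()) -> dict:
    """Proportion of C>T-at-CpG changes with an exact 95% binomial CI.

    ``exclude_branches`` (e.g. the driver-clade trunk) are dropped before
    counting when per-mutation branch ids are supplied.
    """
    channels = np.asarray(channels)
    if branches is not None and len(exclude_branches):
        branches = np.asarray(branches)
        keep = ~np.isin(branches, list(exclude_branches))
        channels = channels[keep]
    n = len(channels)
    if n == 0:
        raise ValueError("no mutations after exclusions")
    k = int(sum(is_ctcpg_channel(int(c)) for c in channels))
    lo, hi = clopper_pearson(k, n)
    return {"k": k, "n": n, "proportion": k / n, "ci95": (lo, hi)}
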