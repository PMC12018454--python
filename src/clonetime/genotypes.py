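"""Depth-sensitive genotyping of mutant-read count matrices.

Each site x colony cell is called present (1), absent (0) or missing from the
observed mutant reads MTR out of depth DEP by comparing two binomial
likelihoods: MTR ~ Binomial(DEP, expected VAF) if the colony carries the
mutation versus MTR ~ Binomial(DEP, p_err) if it does not.  The call is made
only when one likelihood is at least ``bf`` (default 20) times the other;
otherwise the genotype is missing.  Expected VAF is 0.5 for heterozygous
autosomal sites and 1/ploidy for X/Y, CNA and LOH sites; an LOH site can
never be confidently absent, so 0 calls there are overridden to missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1  # third genotype state

__all__ = [
    "MISSING",
    "SiteMeta",
    "GenotypeMatrix",
    "expected_vaf",
    "genotype_site",
    "build_genotype_matrix",
    "export_genotype_fasta",
    "import_genotype_fasta",
]


@dataclass(frozen=True)
class SiteMeta:
    """Per-site metadata needed for genotyping."""

    chrom: str = "chr1"
    pos: int = 1
    ref: str = "C"
    alt: str = "T"
    context96: int = 0
    ploidy_class: str = "autosomal"
    ploidy: int = 2
    loh_flag: bool = False

    def __post_init__(self):
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass
class GenotypeMatrix:
    """Sites x colonies states in {0, 1, MISSING} plus per-cell evidence."""

    states: pd.DataFrame             # int8 values 0 / 1 / MISSING
    log_lr: pd.DataFrame | None = None  # log10 L(present)/L(absent)

    @property
    def sites(self):
        return self.states.index

    @property
    def colonies(self):
        return self.states.columns


def expected_vaf(site) -> float:
    """Expected clonal VAF: 0.5 autosomal, 1/ploidy for X/Y, CNA and LOH."""
    ploidy = int(getattr(site, "ploidy", 2))
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    cls = getattr(site, "ploidy_class", "autosomal")
    loh = bool(getattr(site, "loh_flag", False))
    if cls == "autosomal" and not loh:
        return 0.5
    return 1.0 / ploidy


def genotype_site(mtr, dep, p_mut, p_err: float = 0.01, bf: float = 20.0):
    """Likelihood-ratio genotype call(s); vectorized over mtr/dep.

    Returns 1 where L(present) >= bf * L(absent), 0 where
    L(absent) >= bf * L(present), MISSING otherwise (including zero depth).
    Ties at exactly bf assign the state.
    """
    mtr = np.asarray(mtr)
    dep = np.asarray(dep)
    if np.any(mtr < 0) or np.any(mtr > dep):
        raise ValueError("require 0 <= mtr <= dep")
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = stats.binom.logpmf(mtr, dep, p_mut)
        l0 = stats.binom.logpmf(mtr, dep, p_err)
    log_bf = np.log(bf)
    out = np.full(np.broadcast(mtr, dep).shape, MISSING, dtype=np.int8)
    present = l1 - l0 >= log_bf
    absent = l0 - l1 >= log_bf
    # -inf vs -inf (both impossible) stays missing
    both_dead = ~np.isfinite(l1) & ~np.isfinite(l0)
    out[present & ~both_dead] = 1
    out[absent & ~both_dead] = 0
    out[dep == 0] = MISSING
    if out.ndim == 0:
        return int(out)
    return out


def build_genotype_matrix(
    mtr: pd.DataFrame,
    dep: pd.DataFrame,
    sites: pd.DataFrame,
    p_err: float = 0.01,
    bf: float = 20.0,
) -> GenotypeMatrix:
    """Genotype every site x colony cell, honouring the LOH override.

    ``sites`` is indexed by mutation id with at least ``ploidy_class``,
    ``ploidy`` and ``loh_flag`` columns (the simulator dialect).
    """
    if not mtr.index.equals(dep.index) or not mtr.columns.equals(dep.columns):
        raise ValueError("mtr and dep must be aligned")
    if not mtr.index.isin(sites.index).all():
        raise ValueError("every site needs metadata")
    meta = sites.loc[mtr.index]
    vafs = np.array([
        expected_vaf(row) for row in meta.itertuples()
    ])
    M = mtr.to_numpy()
    D = dep.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = stats.binom.logpmf(M, D, vafs[:, None])
        l0 = stats.binom.logpmf(M, D, p_err)
    log_bf = np.log(bf)
    states = np.full(M.shape, MISSING, dtype=np.int8)
    both_dead = ~np.isfinite(l1) & ~np.isfinite(l0)
    states[(l1 - l0 >= log_bf) & ~both_dead] = 1
    states[(l0 - l1 >= log_bf) & ~both_dead] = 0
    states[D == 0] = MISSING
    loh = meta["loh_flag"].to_numpy(dtype=bool)
    states[loh[:, None] & (states == 0)] = MISSING
    lr = (l1 - l0) / np.log(10)
    return GenotypeMatrix(
        states=pd.DataFrame(states, index=mtr.index, columns=mtr.columns),
        log_lr=pd.DataFrame(lr, index=mtr.index, columns=mtr.columns),
    )


def export_genotype_fasta(gm: GenotypeMatrix, path) -> None:
    """Write the parsimony-input FASTA dialect: one record per colony,
    mutant = A, wild-type = T, missing = ? in site order."""
    states = gm.states
    if states.empty:
        raise ValueError("empty genotype matrix")
    lut = {1: "A", 0: "T", MISSING: "?"}
    with open(path, "w") as fh:
        for colony in states.columns:
            seq = "".join(lut[int(v)] for v in states[colony])
            fh.write(f">{colony}\n{seq}\n")


def import_genotype_fasta(path) -> GenotypeMatrix:
    """Round-trip reader for the A/T/? FASTA dialect."""
    names, seqs = [], []
    with open(path) as fh:
        cur = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                names.append(line[1:])
                if cur:
                    seqs.append("".join(cur))
                    cur = []
            else:
                cur.append(line)
        if cur:
            seqs.append("".join(cur))
    if len(names) != len(seqs) or not names:
        raise ValueError("malformed FASTA")
    lut = {"A": 1, "T": 0, "?": MISSING}
    arr = np.array([[lut[ch] for ch in s] for s in seqs], dtype=np.int8).T
    idx = [f"s{i:06d}" for i in range(arr.shape[0])]
    return GenotypeMatrix(states=pd.DataFrame(arr, index=idx, columns=names))
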