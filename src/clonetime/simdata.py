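"""Synthetic patient cohorts with known ground truth.

Each simulated patient mimics the structure seen in colony phylogenies from
chronic myeloid leukaemia: an embryonic burst of coalescences in the first
year of life, near-independent ("comb"-like) wild-type lineages accumulating
somatic SNVs at a clock-like rate, and a single driver clade hanging off a
long trunk, expanding logistically and accumulating mutations at an elevated
rate.  Read counts, trinucleotide contexts and telomere lengths are emitted
so that every downstream stage (genotyping, tree building, time calibration,
growth fitting, signature attribution) can be exercised and validated against
the recorded truth without any external data.

Defaults reflect the study conditions this generator emulates: wild-type
accumulation of 18 SNV/yr, a mutant-clade excess of ~92 SNVs over the default
6.3-year latency, ~15x sequencing depth, telomere length 6,180 bp at birth
shrinking by 30.8 bp/yr with an extra 556.9 bp loss in mutant colonies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .growthfit import (
    LogisticTrajectory,
    logistic_population,  # noqa: F401  (re-exported: trajectory evaluation)
    _F,
    _inverse_F,
)
from .sigbranch import synthetic_spectra, channel_to_context
from .trees import Tree

__all__ = [
    "SimConfig",
    "SimulatedPatient",
    "LogisticTrajectory",
    "logistic_population",
    "simulate_coalescence_times",
    "simulate_patient",
    "simulate_cohort",
    "emit_read_counts",
    "emit_telomeres",
    "amplicon_length",
    "write_patient",
]

DEFAULT_LATENCY = 6.3
# per-group mixing over (SBS1, SBSblood, SBS18); CML is SBS1/SBS18-shifted
DEFAULT_MIXTURES = {
    "wt": (0.15, 0.65, 0.20),
    "cml": (0.35, 0.40, 0.25),
    "embryonic": (0.10, 0.70, 0.20),
}


@dataclass(frozen=True)
class SimConfig:
    """Truth parameters for one synthetic cohort."""

    n_patients: int = 1
    colonies_per_patient: int = 90
    age_at_diagnosis: float = 50.0
    clone_s: float = 3.33           # per year
    clone_log10N: float = 5.0
    latency_years: float = DEFAULT_LATENCY
    mutant_fraction: float = 0.45
    lambda_wt: float = 18.0         # SNV / year
    lambda_mut: float = 18.0 + 91.7 / DEFAULT_LATENCY
    nu_embryo: float = 42.0         # excess development SNVs (first year)
    burden_at_birth: float = 60.0   # = lambda_wt * 1 yr + nu_embryo
    depth_mean: float = 15.0
    clonality: float = 1.0
    seq_error: float = 0.01
    signature_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURES))
    telomere_L0: float = 6180.0
    telomere_attrition: float = 30.8
    telomere_mut_extra: float = 556.9
    telomere_noise_sd: float = 400.0
    n_germline_sites: int = 200
    contaminated_fraction: float = 0.0
    contaminated_clonality: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "lambda_wt", "lambda_mut", "nu_embryo", "burden_at_birth",
            "depth_mean", "telomere_L0", "telomere_attrition",
            "telomere_mut_extra", "telomere_noise_sd", "seq_error",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.clonality <= 1:
            raise ValueError("clonality must lie in (0, 1]")
        if not 0 <= self.mutant_fraction <= 1:
            raise ValueError("mutant_fraction must lie in [0, 1]")
        for grp, mix in self.signature_mixture.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"signature mixture for {grp!r} must sum to 1")
        if self.latency_years >= self.age_at_diagnosis:
            raise ValueError("clone origin would precede conception")

    def trajectory(self) -> LogisticTrajectory:
        """Truth trajectory; midpoint placed so the clone starts from ~1 cell
        at origin = age - latency."""
        N = 10.0 ** self.clone_log10N
        t_origin = self.age_at_diagnosis - self.latency_years
        t_m = t_origin + math.log(N - 1.0) / self.clone_s
        return LogisticTrajectory(N=N, s=self.clone_s, t_m=t_m)


@dataclass
class SimulatedPatient:
    """One synthetic patient: tree, mutations, reads, telomeres, full truth."""

    patient_id: str
    config: SimConfig
    tree: Tree                      # branch lengths = true durations (years)
    node_times: np.ndarray          # years since conception
    tip_ages: np.ndarray
    colony_names: list
    mutant_tips: np.ndarray         # tip indices inside the driver clade
    clade_node: int | None
    t_origin: float | None
    clonality: np.ndarray           # realized per-colony clonality
    provenance: pd.DataFrame        # mut_id, branch, channel96, signature, embryonic
    sites: pd.DataFrame
    mtr: pd.DataFrame | None = None
    dep: pd.DataFrame | None = None
    germline_mtr: pd.DataFrame | None = None
    germline_dep: pd.DataFrame | None = None
    telomeres: pd.DataFrame | None = None

    @property
    def latency_true(self) -> float | None:
        """Diagnosis age minus the realized clade-MRCA time."""
        if self.clade_node is None:
            return None
        return float(self.config.age_at_diagnosis - self.node_times[self.clade_node])


# ---------------------------------------------------------------- coalescent
def simulate_coalescence_times(
    n_tips: int,
    traj: LogisticTrajectory,
    t_origin: float,
    t_sample: float,
    rng,
) -> np.ndarray:
    """Draw ordered coalescence times under the logistic-trajectory coalescent.

    Time-rescaled Kingman process run backwards from ``t_sample``: with k
    lineages the next event solves k(k-1)/2 * Λ(t*, τ) = Exp(1) using the
    closed-form integrated intensity.  Lineages that fail to coalesce by
    ``t_origin`` are forced into a star event at the origin.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not t_origin < t_sample:
        raise ValueError("t_origin must precede t_sample")
    rng = np.random.default_rng(rng)
    times: list[float] = []
    tau = float(t_sample)
    k = n_tips
    forced = False
    while k >= 2:
        e = rng.exponential()
        pair = 0.5 * k * (k - 1)
        target = _F(tau, traj) - e * traj.N / pair
        t_star = _inverse_F(target, traj)
        if t_star <= t_origin:
            times.extend([t_origin] * (k - 1))
            forced = True
            break
        times.append(t_star)
        tau = t_star
        k -= 1
    if forced:
        import logging

        logging.getLogger(__name__).warning(
            "lineages failed to coalesce by the clone origin; "
            "forced star coalescence at t_origin"
        )
    return np.sort(np.asarray(times))


def _merge_backward(lineage_ids, coal_times_desc, next_id, rng):
    """Pairwise-merge lineages at given (descending) event times.

    Returns (edges, node_times, root_id, next_id): edges as (child, parent).
    """
    lineages = list(lineage_ids)
    edges, node_times = [], {}
    for t in coal_times_desc:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[i], lineages[j]
        new = next_id
        next_id += 1
        node_times[new] = float(t)
        edges.append((a, new))
        edges.append((b, new))
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(new)
    assert len(lineages) == 1
    return edges, node_times, lineages[0], next_id


# ---------------------------------------------------------------- simulation
def simulate_patient(config: SimConfig, patient_id: str = "SIM01",
                     emit_reads: bool = True) -> SimulatedPatient:
    """Simulate one patient end to end (tree, mutations, reads, telomeres)."""
    rng = np.random.default_rng(config.seed)
    n = config.colonies_per_patient
    age = config.age_at_diagnosis
    n_mut = int(round(n * config.mutant_fraction))
    if n_mut == 1:
        n_mut = 2  # a clade needs at least two sampled tips
    n_wt = n - n_mut

    colony_names = [f"{patient_id}_c{i:03d}" for i in range(n)]
    tip_times = {i: age for i in range(n)}
    next_id = n
    all_edges: list[tuple[int, int]] = []
    node_times: dict[int, float] = dict(tip_times)

    clade_node = None
    t_origin = None
    trunk_lineage = None
    mutant_tips = np.arange(n_wt, n)
    if n_mut >= 2:
        traj = config.trajectory()
        t_origin = age - config.latency_years
        coal = simulate_coalescence_times(n_mut, traj, t_origin, age, rng)
        edges, ntimes, clade_node, next_id = _merge_backward(
            list(mutant_tips), coal[::-1], next_id, rng
        )
        all_edges.extend(edges)
        node_times.update(ntimes)
        trunk_lineage = clade_node

    # embryonic burst: wild-type lineages (plus the trunk lineage) all
    # coalesce within the first year of life
    top_lineages = list(range(n_wt))
    if trunk_lineage is not None:
        top_lineages.append(trunk_lineage)
    if len(top_lineages) >= 2:
        emb_times = np.sort(rng.uniform(0.0, 1.0, size=len(top_lineages) - 1))[::-1]
        edges, ntimes, root, next_id = _merge_backward(
            top_lineages, emb_times, next_id, rng
        )
        all_edges.extend(edges)
        node_times.update(ntimes)
    else:
        root = top_lineages[0]

    # conception root: the zygote-to-first-coalescence stem carries mutations
    # shared by every colony
    conception = next_id
    next_id += 1
    node_times[conception] = 0.0
    all_edges.append((root, conception))

    n_nodes = next_id
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for child, par in all_edges:
        parent[child] = par
    times = np.array([node_times[v] for v in range(n_nodes)])
    lengths = np.zeros(n_nodes)
    for v in range(n_nodes):
        if parent[v] >= 0:
            lengths[v] = times[v] - times[parent[v]]
    tree = Tree(parent, colony_names, lengths)

    # clade membership: nodes strictly below the clade MRCA carry the mutant
    # rate; the trunk (branch above the MRCA) stays wild-type
    in_clade = np.zeros(n_nodes, dtype=bool)
    if clade_node is not None:
        ch = tree.children()
        stack = list(ch[clade_node])
        while stack:
            v = stack.pop()
            in_clade[v] = True
            stack.extend(ch[v])

    # ------------------------------------------------------------- mutations
    spectra = synthetic_spectra()
    signames = list(spectra.columns)
    mut_branch, mut_channel, mut_sig, mut_emb = [], [], [], []
    for v in range(n_nodes):
        p = parent[v]
        if p < 0:
            continue
        t0, t1 = times[p], times[v]
        rate = config.lambda_mut if in_clade[v] else config.lambda_wt
        emb_dur = max(0.0, min(t1, 1.0) - min(t0, 1.0))
        post_dur = (t1 - t0) - emb_dur
        n_emb = rng.poisson((rate + config.nu_embryo) * emb_dur)
        n_post = rng.poisson(rate * post_dur)
        for count, is_emb in ((n_emb, True), (n_post, False)):
            if count == 0:
                continue
            if is_emb:
                mix = config.signature_mixture["embryonic"]
            elif in_clade[v]:
                mix = config.signature_mixture["cml"]
            else:
                mix = config.signature_mixture["wt"]
            sigs = rng.choice(len(signames), size=count, p=np.asarray(mix))
            for si in sigs:
                chan = rng.choice(96, p=spectra.iloc[:, si].to_numpy())
                mut_branch.append(v)
                mut_channel.append(int(chan))
                mut_sig.append(signames[si])
                mut_emb.append(is_emb)

    n_muts = len(mut_branch)
    mut_ids = [f"m{i:06d}" for i in range(n_muts)]
    provenance = pd.DataFrame(
        {
            "mut_id": mut_ids,
            "branch": mut_branch,
            "channel96": mut_channel,
            "signature": mut_sig,
            "embryonic": mut_emb,
        }
    )

    # ----------------------------------------------------------------- sites
    chrom = rng.integers(1, 23, size=n_muts)
    pos = rng.integers(1, 240_000_000, size=n_muts)
    ctx = [channel_to_context(c) for c in mut_channel]
    sites = pd.DataFrame(
        {
            "mut_id": mut_ids,
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "ref": [t[0][1] for t in ctx],
            "alt": [t[1] for t in ctx],
            "context96": mut_channel,
            "trinucleotide": [t[0] for t in ctx],
            "ploidy_class": "autosomal",
            "ploidy": 2,
            "loh_flag": False,
        }
    ).set_index("mut_id")

    clonality = np.full(n, config.clonality)
    if config.contaminated_fraction > 0:
        n_bad = int(round(n * config.contaminated_fraction))
        bad = rng.choice(n, size=n_bad, replace=False)
        clonality[bad] = config.contaminated_clonality

    patient = SimulatedPatient(
        patient_id=patient_id,
        config=config,
        tree=tree,
        node_times=times,
        tip_ages=np.full(n, age),
        colony_names=colony_names,
        mutant_tips=mutant_tips if n_mut >= 2 else np.array([], dtype=int),
        clade_node=clade_node,
        t_origin=t_origin,
        clonality=clonality,
        provenance=provenance,
        sites=sites,
    )
    if emit_reads:
        emit_read_counts(patient, config.depth_mean, clonality,
                         config.seq_error, rng)
        _emit_germline(patient, rng)
        emit_telomeres(patient, config.telomere_L0, config.telomere_attrition,
                       config.telomere_mut_extra, config.telomere_noise_sd, rng)
    return patient


def simulate_cohort(config: SimConfig, ages=None) -> list[SimulatedPatient]:
    """Simulate ``config.n_patients`` patients with per-patient derived seeds."""
    if ages is None:
        ages = [config.age_at_diagnosis] * config.n_patients
    out = []
    for i, age in enumerate(ages):
        cfg = replace(config, age_at_diagnosis=float(age),
                      seed=(config.seed * 1000 + i) % (2**31))
        out.append(simulate_patient(cfg, patient_id=f"SIM{i + 1:02d}"))
    return out


# -------------------------------------------------------------- observations
def emit_read_counts(patient: SimulatedPatient, depth_mean: float,
                     clonality, seq_error: float, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per site x colony depths and mutant read counts.

    DEP ~ Poisson(depth_mean); MTR ~ Binomial(DEP, clonality * expected VAF)
    where the colony carries the mutation, Binomial(DEP, seq_error) otherwise.
    Autosomal heterozygous expected VAF is 0.5.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(rng)
    tree = patient.tree
    sets = tree.tip_sets()
    n_muts = len(patient.provenance)
    n_col = tree.n_tips
    carrier = np.zeros((n_muts, n_col), dtype=bool)
    branches = patient.provenance["branch"].to_numpy()
    for i, b in enumerate(branches):
        carrier[i] = sets[b]
    clon = np.broadcast_to(np.asarray(clonality, dtype=float), (n_col,))
    dep = rng.poisson(depth_mean, size=(n_muts, n_col))
    p = np.where(carrier, clon[None, :] * 0.5, seq_error)
    mtr = rng.binomial(dep, p)
    cols = patient.colony_names
    idx = patient.provenance["mut_id"]
    patient.mtr = pd.DataFrame(mtr, index=idx, columns=cols)
    patient.dep = pd.DataFrame(dep, index=idx, columns=cols)
    return patient.mtr, patient.dep


def _emit_germline(patient: SimulatedPatient, rng) -> None:
    """Heterozygous germline sites carried by every colony (sensitivity input)."""
    cfg = patient.config
    m, n_col = cfg.n_germline_sites, patient.tree.n_tips
    if m == 0:
        return
    dep = rng.poisson(cfg.depth_mean, size=(m, n_col))
    p = patient.clonality[None, :] * 0.5
    mtr = rng.binomial(dep, np.broadcast_to(p, dep.shape))
    idx = [f"g{i:04d}" for i in range(m)]
    patient.germline_mtr = pd.DataFrame(mtr, index=idx, columns=patient.colony_names)
    patient.germline_dep = pd.DataFrame(dep, index=idx, columns=patient.colony_names)


def emit_telomeres(patient: SimulatedPatient, L0: float, attrition: float,
                   mut_extra: float, noise_sd: float, rng) -> pd.DataFrame:
    """Per-colony telomere length: L0 - attrition*age, extra loss in mutants."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    rng = np.random.default_rng(rng)
    n = patient.tree.n_tips
    mean = L0 - attrition * patient.tip_ages
    is_mut = np.zeros(n, dtype=bool)
    is_mut[patient.mutant_tips] = True
    mean = mean - np.where(is_mut, mut_extra, 0.0)
    vals = mean + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    patient.telomeres = pd.DataFrame(
        {"colony_id": patient.colony_names, "telomere_bp": vals,
         "bcr_abl1": is_mut}
    )
    return patient.telomeres


def amplicon_length(segment_lengths) -> int:
    """Total amplicon length (bp) of concatenated exonic segments."""
    segs = list(segment_lengths)
    if not segs:
        raise ValueError("empty segment list")
    if any(s <= 0 for s in segs):
        raise ValueError("segment lengths must be positive")
    return int(sum(segs))


# --------------------------------------------------------------------- files
def write_patient(patient: SimulatedPatient, outdir) -> None:
    """Write the on-disk dialect: sites/mtr/dep/colonies TSVs, truth JSON, Newick."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    patient.sites.to_csv(out / "sites.tsv", sep="\t")
    patient.mtr.to_csv(out / "mtr.tsv", sep="\t")
    patient.dep.to_csv(out / "dep.tsv", sep="\t")
    if patient.germline_mtr is not None:
        patient.germline_mtr.to_csv(out / "germline_mtr.tsv", sep="\t")
        patient.germline_dep.to_csv(out / "germline_dep.tsv", sep="\t")
    is_mut = np.zeros(patient.tree.n_tips, dtype=bool)
    is_mut[patient.mutant_tips] = True
    colonies = pd.DataFrame(
        {
            "colony_id": patient.colony_names,
            "age_years": patient.tip_ages,
            "timepoint": 0,
            "bcr_abl1": is_mut,
            "clonality": patient.clonality,
        }
    )
    if patient.telomeres is not None:
        colonies["telomere_bp"] = patient.telomeres["telomere_bp"].to_numpy()
    colonies.to_csv(out / "colonies.tsv", sep="\t", index=False)
    patient.provenance.to_csv(out / "provenance.tsv", sep="\t", index=False)
    patient.tree.write_newick(out / "tree_true.nwk")
    truth = asdict(patient.config)
    truth["patient_id"] = patient.patient_id
    truth["t_origin"] = patient.t_origin
    truth["clade_mrca_time"] = (
        None if patient.clade_node is None
        else float(patient.node_times[patient.clade_node])
    )
    truth["latency_true"] = patient.latency_true
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
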