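# clonetime

Timing and growth of driver-mutant clonal expansions in blood, reconstructed
from whole-genome sequences of single-cell-derived haematopoietic colonies.

In chronic myeloid leukaemia a single acquired event — the *BCR::ABL1*
fusion — launches a clonal expansion that reaches diagnosis within years.
Because somatic mutations accumulate in haematopoietic stem cells in a
clock-like fashion, the mutations shared between colonies record the
clone's history: when it started, and how fast it grew.  `clonetime`
implements that reconstruction end to end, with a synthetic-cohort
generator providing ground truth for every stage:

1. **Genotyping** (`clonetime.genotypes`) — per site and colony, mutant
   reads MTR out of depth DEP are called present/absent/missing by a
   binomial likelihood ratio: present requires
   `Binom(MTR; DEP, VAF) ≥ 20 × Binom(MTR; DEP, 0.01)` (and conversely for
   absent), with expected VAF 0.5 for autosomal heterozygous sites and
   1/ploidy for X/Y, CNA and LOH sites.
2. **Phylogeny** (`clonetime.phylogeny`) — maximum parsimony on the binary
   genotype matrix (greedy perfect-phylogeny construction plus NNI/SPR hill
   climbing on the Fitch score, missing genotypes as wildcards),
   depth-sensitive hard assignment of each mutation to its
   maximum-likelihood branch, colony QC (sensitivity < 60%, private-branch
   VAF significantly below 0.4, cross-colony contamination) and
   sensitivity/CNA-corrected branch lengths.
3. **Time calibration** (`clonetime.timefit`) — Bayesian MCMC under a
   Poisson branch model, `count ~ Poisson(duration × sensitivity × rate)`,
   with separate wild-type and mutant rates (the mutant rate starts below
   the driver clade's MRCA, so the fusion is acquired at the end of the
   trunk), a development excess in the first year of life, and root-to-tip
   durations constrained to equal each colony's sampling age.  Latency =
   age at diagnosis − clade-MRCA time.
4. **Growth inference** (`clonetime.growthfit`) — the clade's coalescence
   times are fit to a three-parameter logistic trajectory
   `N(t) = N / (1 + e^{−s(t−t_m)})` under the inhomogeneous Kingman
   coalescent with pair rate `k(k−1)/(2N(t))`, priors
   `s ~ U(0.001, 30)`, `t_m ~ U(age of MRCA, age at diagnosis)`,
   `log10 N ~ U(4, 7)`.  Annualized growth `S = e^s − 1` (percent) and
   doubling time `1/log2(1+S) = ln 2 / s` years; an internal-branch-length
   maximum-likelihood estimator cross-checks the Bayesian fit.
5. **Signatures** (`clonetime.sigbranch`) — 96-channel spectra per branch
   group refit against fixed SBS1/SBSblood/SBS18 reference spectra by
   multinomial EM; exact Bayes per-mutation membership probabilities
   `P(Sig|mut) ∝ P(mut|Sig) P0(Sig)` averaged per branch; C>T-at-CpG
   proportions with exact binomial intervals as a readout of division
   history.

The generator (`clonetime.simdata`) emulates the observed regime: an
embryonic burst of coalescences in the first year, wild-type accumulation of
18 SNV/yr, a driver clade expanding logistically with an excess of ~92
mutations over its lifetime, ~15× sequencing depth, and telomeres starting
at 6,180 bp, losing 30.8 bp/yr plus an extra 556.9 bp in mutant colonies.

## Worked example

```python
import numpy as np
from clonetime.simdata import SimConfig, simulate_patient
from clonetime.genotypes import build_genotype_matrix
from clonetime.phylogeny import (build_parsimony_tree, assign_mutations,
                                 annotate_driver_clades)
from clonetime.timefit import fit_time_tree, infer_latency
from clonetime.growthfit import fit_growth, annualized_growth_str

cfg = SimConfig(colonies_per_patient=60, age_at_diagnosis=45.0,
                depth_mean=30.0, clone_s=3.33, latency_years=6.3, seed=3)
p = simulate_patient(cfg)
gm = build_genotype_matrix(p.mtr, p.dep, p.sites)
tree = build_parsimony_tree(gm, seed=1)
asn = assign_mutations(tree, p.mtr, p.dep)
calls = {n: (i in set(p.mutant_tips)) for i, n in enumerate(p.colony_names)}
clade = annotate_driver_clades(tree, calls)
tt = fit_time_tree(tree, asn.branch_counts(tree.n_nodes).astype(float),
                   np.full(tree.n_tips, 45.0), clade_node=clade, seed=2)
lat = infer_latency(tt, 45.0)
print(f"latency {lat['latency_median']:.1f} yr, CI "
      f"({lat['ci95'][0]:.1f}, {lat['ci95'][1]:.1f})")
gp = fit_growth(tt.time_tree(), clade, 45.0, seed=3)
print("growth", annualized_growth_str(float(np.median(gp.s))),
      "doubling", round(float(np.median(gp.doubling_years * 365.25))), "days")
```

prints (truth: latency 6.3 yr, s = 3.33/yr, i.e. 2,700%/yr):

```
latency 5.2 yr, CI (2.7, 7.7)
growth 3,000% doubling 74 days
```

The credible intervals cover the simulated truth.  Point estimates move
with the Poisson noise of the shared trunk (~700 mutations, so roughly
±1.5 yr of onset at one standard deviation), and growth rates read off a
point (posterior-mean) time tree inherit that calibration noise — the
recovery suite therefore validates the growth fit on coalescence times
directly (see `docs/methods.md`).

The numbered drivers under `analysis/` run the same pipeline over a
four-patient synthetic cohort spanning explosive (s = 5.59/yr) to slow
(s = 0.9/yr) clones, writing tables under `results/`.

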