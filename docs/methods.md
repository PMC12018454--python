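# Methods

`clonetime` reconstructs the history of a driver-mutant clonal expansion in
blood from the somatic mutations of single-cell-derived colonies.  This
note records the models, their assumptions, the defaults and why they were
chosen, the numerical choices, and what the synthetic data do and do not
establish about behaviour on real data.

## The synthetic cohort generator

`simdata` produces patients with known ground truth at every level:

* **Tree shape.** All wild-type coalescences are drawn uniformly in the
  first year of life — the embryonic burst of coalescences that colony
  phylogenies show near the root — so wild-type lineages are
  near-independent ("comb"-like) afterwards.  One lineage carries the
  driver: a trunk runs from its embryonic split to the clone origin at
  `age − latency`, and the clade below it coalesces under a logistic
  trajectory `N(t) = N/(1 + e^{−s(t−t_m)})` via the time-rescaled Kingman
  coalescent (closed-form integrated intensity, inverted with Lambert W).
  Lineages that survive backwards to the origin merge there in a star: the
  origin population is a single founder cell.  An explicit zygote root
  holds the stem branch above the first coalescence.
* **Mutations.** Each branch receives `Poisson(rate × duration)` mutations
  — `lambda_wt = 18`/yr outside the clade, `lambda_mut` inside — plus a
  development excess at rate `nu_embryo`/yr over the branch's overlap with
  the first year, so the expected burden at birth is
  `lambda_wt + nu_embryo = 60` SNVs.  `lambda_mut` defaults to
  `18 + 91.7/latency`, making the clade's lifetime excess +91.7 mutations
  at the default 6.3-year latency.  Each mutation draws a 96-channel
  trinucleotide context from a per-group signature mixture
  (wild-type / clade / embryonic) over the packaged spectra.
* **Observations.** `DEP ~ Poisson(depth_mean)` (default 15×),
  `MTR ~ Binomial(DEP, clonality × expected VAF)` for carriers and
  `Binomial(DEP, seq_error)` otherwise; heterozygous germline sites are
  emitted for sensitivity estimation; telomeres are
  `6,180 − 30.8 × age − 556.9·[mutant] + N(0, 400²)` bp (the colony-level
  noise scale is a modelling choice; no colony-level noise model is implied
  by the emulated regime).  Optional low-clonality colonies exercise QC.
* **Latency as a dial.** The clone origin is placed so latency matches the
  configured target; truth (origin, MRCA time, per-mutation branch and
  signature) is recorded for recovery tests.  In grid experiments the
  latency is set to `ln(N)/s + 2` years so the clone is near saturation at
  sampling — the same presentation assumption the midpoint prior encodes.

**What passing on this generator does not show:** real colonies have
mapping artefacts, germline leakage, copy-number changes beyond flags,
relatedness among wild-type cells (late clonal haematopoiesis), and index
hopping; none are simulated.  Topology recovery and rate calibration here
quantify statistical, not bioinformatic, performance.

## Genotyping

The likelihood-ratio rule calls a cell present when
`L(present) ≥ 20 × L(absent)` (ties assign the state — "at least" is read
as ≥), absent in the converse case, missing otherwise and at zero depth.
The error rate defaults to 0.01 per read and is exposed for sensitivity
analysis.  LOH sites cannot be confidently absent, so 0 calls become
missing.  Sites are assumed biallelic.

## Parsimony trees

Carrier sets are nested greedily in order of pooled evidence weight
(number of identical columns supporting the set), then size — a clade
supported by hundreds of trunk mutations must nest before a singleton
noisy column can poison the partition — with conflicting sets skipped.
The topology is then refined by first-improvement nearest-neighbour
interchange on the total parsimony score, with subtree-prune-regraft moves
(both regraft-to-node and edge-bisection) when NNI stalls, under random
restarts alternating between shuffled greedy constructions and random
topologies.  Scores come from the exact two-state Sankoff dynamic program
(unit costs), which unlike sequential pairwise Fitch intersection is exact
and order-independent on multifurcating trees; missing genotypes are
wildcards (zero cost in either state).  Small instances (≤ 8 tips) get at least 24 restarts, which the
test suite verifies reaches the exhaustive-search optimum on ≤ 7 tips;
larger noise-free instances terminate early at the perfect-phylogeny lower
bound (one change per column pattern containing both states).  The search
is deterministic given its seed; acceptance is by tree score only.

## Mutation assignment, sensitivity, QC, branch lengths

Each mutation is hard-assigned to the branch maximizing the read-count
likelihood (carriers at `clonality × expected VAF`, non-carriers at the
error rate); exact ties go to the rootmost branch (largest carrier set,
then fewest hops from the root).  Per-colony sensitivity is the germline
heterozygous detection rate times `VAF/0.5` (capped at 1).  QC drops
colonies with sensitivity < 0.60; with pooled private-branch reads failing
a one-sided exact binomial test of VAF ≥ 0.4 at α = 0.01 (the "significantly
lower than 0.4" rule made concrete — no particular test or level is
implied by the rule itself); or with binomial evidence that their private
mutations appear above `2 × p_err` in non-ancestral colonies.  Branch
lengths divide raw counts by the branch detection sensitivity
`1 − ∏(1 − s_c)` over descendant colonies and by `1 − masked fraction` for
uniform CNA masking.

## Time calibration

Node times are parameterized by stick-breaking fractions along root-to-tip
paths (`t_v = t_parent + f_v (A_v − t_parent)`, `f_v ~ U(0,1)`, `A_v` the
earliest sampling age below `v`), which enforces the root-to-tip age
constraint exactly in every draw and supports heterochronous tips.  Branch
counts are Poisson with mean `duration × sensitivity × rate`; the mutant
rate applies strictly below the clade MRCA, so the driver is acquired at
the end of the trunk.  Priors: rates `U(0, 200)`/yr, development excess
`nu ~ U(0, 300)` SNVs.

Two deliberate structural choices:

* **Development excess over the first year, with constrained wild-type
  coalescences.**  The excess is spread over each branch's overlap with the
  first year (each path crosses development once).  With free node times
  and flat priors this excess is unidentified: coalescences drift out of
  the window and the node-time marginalization (wider likelihood peaks at
  lower slopes — an Occam-width effect) drives `nu → 0` and biases the
  wild-type rate up by roughly `nu/age`.  Non-clade coalescences are
  therefore constrained to an embryonic window (default 1 year,
  `embryo_window`), the same structural assumption the generator makes.
  Trees with late wild-type expansions (e.g. old-age clonal
  haematopoiesis) should widen or disable the window — at the cost of
  weaker excess identification.
* **Cohort fits.**  Within a single-age patient only
  `lambda_wt × age + nu` is well identified along ridges; fitting several
  patients of different ages jointly with shared rates
  (`fit_time_trees`) separates rate from excess.  Latency uses per-patient
  fits; with multiple sampling timepoints, each tip is constrained to its
  own age and latency uses the earliest-timepoint tree.

Sampling is adaptive random-walk Metropolis within Gibbs, numba-compiled:
single-site reflected updates of the fractions with per-node step
adaptation toward 44% acceptance, log-scale rate updates, 4 chains ×
20,000 iterations (thinning 10, 50% burn-in) by default; split-R̂ is
reported for the rates.  Counts may be non-integer after sensitivity
correction (continuous Poisson extension).  Donors with no wild-type
colonies use `trunk_no_wildtype`: clade duration = mean root-to-tip burden
/ cohort mutant rate; trunk molecular length = remaining years × cohort
wild-type rate + burden at birth (default 60 SNVs, configurable).

Whether "onset of clonal expansion" is the clade MRCA or the (untimeable)
fusion event along the trunk is not resolvable from a phylogeny; onset is
equated with the clade-MRCA time, and the trunk end time is the same
quantity in this model.

## Growth inference

The clade's coalescence times (from the calendar-time tree restricted to
the earliest timepoint, posterior-mean branch lengths) are fit by MCMC
under the inhomogeneous Kingman likelihood with the closed-form integrated
intensity `∫dt/N(t) = (1/N)(t − e^{−s(t−t_m)}/s)`.  Priors:
`s ~ U(0.001, s_upper)` with `s_upper` escalated (doubling, to 60) until
the posterior median moves < 5%; `t_m ~ U(age of MRCA, age at diagnosis)`
(patients present with a dominant clone); `log10 N ~ U(4, 7)`.  `N` is a
composite effective size × generation time in year units.  The earliest
coalescence is scored as truncation mass (survival only, no hazard
factor): the MRCA is the clone's founding cell, and scoring it as an
ordinary event where `N(t)` approaches one cell rewards ever-steeper
trajectories and biases `s` upward.  The sampler is Haario-style adaptive
Metropolis (the three parameters ride a strong ridge), 4 chains; `N` and
`t_m` are weakly identified at saturation and their R̂ is reported but not
gated on.  The fit is unconditioned on the number of sampled clade tips.

The orthogonal check `internal_length_mle` estimates
`ŝ = (n−2)/Σ internal branch lengths` with standard error `ŝ/√(n−2)` —
for an ultrametric clade sampled from a large exponentially growing
population the internal (shared) lineage lengths are approximately n−2
independent `Exp(s)` intervals.  Agreement within ~2-fold of the Bayesian
fit is the expected regime.

**Known limitation.**  Fitting growth from a point (posterior-mean) time
tree ignores calibration uncertainty: weakly-pinned clade node times are
spread by their prior, and at high `s` the pipeline growth estimate runs
above truth (within ~2-fold in our runs) even though the growth module is
well calibrated on coalescence times directly (the recovery grid: 40-tip
clades at s ∈ {0.75, 1.5, 3, 6, 12}, 40 replicates each, ≥ 85% CI
coverage).  Latency estimates carry the Poisson noise of the trunk
(≈ √(λ·trunk duration)/λ ≈ 1.5 yr at age 45).

## Signature attribution

Reference spectra are consumed from 96-row COSMIC-style TSV.  The packaged
SBS1/SBSblood/SBS18 spectra are synthetic stand-ins constructed
programmatically with each process's defining features (SBS1: C>T at NpCpG;
SBSblood: broad clock-like with a mild T>C lean; SBS18: C>A-dominated) —
conclusions about real spectra require the published tables.  Exposures are
multinomial-mixture MLEs by EM (log-likelihood asserted non-decreasing,
convergence at Δ < 1e-10); duplicate spectra yield an equal split and a
non-identifiability flag.  Credibility intervals come from Gibbs sampling
under a flat Dirichlet prior.  Branch groups follow the five-way scheme:
driver expansion (CML), its shared internal branches (early CML), the
trunk (pre-CML lineage), wild-type, and early-in-life — the first 100
mutations of molecular time, implemented as a global root-depth cutoff
(a per-lineage variant is exposed as a flag; branch start depth is shared
either way).  The CML ⊇ early-CML overlap is by construction, as in the
five-group scheme.  Branches with < 50 mutations are attributed but
flagged small rather than pooled (pooling belongs to de-novo extraction,
which is out of scope).  C>T-at-CpG summaries use exact Clopper–Pearson
intervals and honour trunk exclusion.

## Problem sizes and scaled-down suites

The test suite runs the acceptance-grade checks at full stated size
(exhaustive genotype oracle to depth 60, exhaustive tree search to 7 tips,
the 5 × 40-replicate growth grid, 20,000-draw mixture recovery) and the
module-level calibration properties at reduced replicate counts (e.g.
latency CI coverage over 6 replicates, cohort rate recovery with 20–30
colonies per patient), keeping the default suite around 10–15 minutes on
one CPU.  The analysis drivers use 40-colony patients at 15× depth —
within the emulated regime — and the acceptance script uses 30-colony
patients at 30× as its recovery setting.
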