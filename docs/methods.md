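# Methods

## Dynamics

Networks follow standard stochastic logical-model semantics: states are
binary vectors, and the process jumps by single-node flips. A non-forced
node i is eligible to flip only while its value disagrees with its rule's
current evaluation; the waiting time is exponential with rate `up_i`
(0→1, rule satisfied) or `down_i` (1→0, rule violated). Forced nodes
never flip. Time is in arbitrary units; rates are reciprocal arbitrary
time, and only rate ratios and the window length are meaningful.

Two solvers share this definition:

* **Gillespie ensemble** (`estimate_activity`): exact jump sampling;
  activity is the ensemble fraction ON at each grid time, with binomial
  standard error. One root seed; the stream for trajectory i is derived
  as `default_rng([seed, i])`, so any trajectory is reproducible in
  isolation and the whole pipeline is bit-identical for identical
  configuration. Absorbing states simply idle until `t_max`.
* **Exact master equation** (`exact_master_equation`): builds the sparse
  generator over the 2^n states of the non-forced nodes (capped at
  n = 12 by default) and propagates the initial product-Bernoulli
  distribution with `scipy.sparse.linalg.expm_multiply`. The transition
  skeleton depends only on (network, forcings) and is cached; rates are
  reapplied per patient. Used as the test oracle for the Monte Carlo
  path, and as the engine for cohort-scale experiments, where its
  determinism removes Monte Carlo noise from the statistics.

AUC is the trapezoid integral of the activity curve over [0, t_max]. By
linearity of the trapezoid rule, the integral of the ensemble-mean curve
equals the mean of per-trajectory integrals exactly, so a separate
per-trajectory AUC path would be redundant and is not provided. Steady
state is declared when the activity spread over the trailing
`steady_window` fraction of the grid is ≤ `steady_tol`; the attained
level is the window mean. Failure to converge is recorded per node in
the output (`steady_bp`/`steady_ap`), never fatal.

Defaults: `t_max = 50`, `n_grid = 101`, `n_trajectories = 5000`,
`steady_tol = 0.01`, `steady_window = 0.2`. The toy fixtures converge
well within the window at these settings, and the steady tolerance is of
the order of the Monte Carlo error at the default ensemble size. Cohort
experiments in the test suite use `n_grid = 51` with the exact engine —
a problem-size choice that leaves all reported statistics unchanged to
well below their Monte Carlo/rank-test resolution.

## Personalization

Expression is normalized per gene across the cohort (min-max by default;
rank percentiles optionally). The transfer to dynamics is deliberately
the simplest monotone form: with normalized expression x clamped to
[0.01, 0.99], `up = s·x`, `down = s·(1−x)`, initial ON-probability x,
scale default s = 1. Higher expression therefore means a higher
propensity to be ON, and an input-free node's stationary activity is
exactly x. The transfer sits behind one function so alternative forms
can be swapped. Nodes without expression data receive symmetric defaults
(up = down = s/2, initial 0.5).

Discrete forcing policy: only unambiguous, extreme evidence forces —
inactivating mutation or ploidy −2 → 0; activating mutation or ploidy
+2 → 1; `effect = unknown` and |ploidy| ≤ 1 contribute nothing.
Mutation evidence takes precedence over copy number on conflict (both
directions are logged; a strict mode raises instead, and the precedence
is configurable). Fusion nodes without a single genomic locus (AR_ERG)
are never forced from omics by default. Gene symbols map to node names
by exact match after an optional alias table.

The lRR→ploidy step function uses half-open intervals with inclusive
upper bounds (−1.1, −0.2, 0.2, 0.7) and an open top class; it is total
and monotone in lRR.

## Knockout statistic and group comparison

A perturbation overrides the patient's own forcings. Before/after runs
share the seed policy (common random numbers) to reduce ΔAUC variance
under Monte Carlo; an independent-seed option exists. ΔAUC(%) is
undefined (NaN, not an error) when the baseline AUC falls below
10⁻³·t_max, guarding the division for nodes essentially OFF at baseline.

The group comparison tests a node only when at least one group's
|median ΔAUC| reaches the 3% filter (configurable to mean or
any-sample), applies the two-sided Mann-Whitney U test (exact
enumeration when n_A·n_B ≤ 400 without ties, tie-corrected normal
approximation otherwise), and adjusts with Benjamini-Hochberg across the
*tested* nodes only, at α = 0.05. Applying the filter before BH treats
the 3% rule as a pre-test filter; both the filter statistic and the
threshold are exposed.

## Methylation–expression integration

β = M/(M+U+a) and M-value = log2((M+a)/(U+a)) with offset a = 100.
Upstream array preprocessing, DMR calling and batch correction are
inputs, not computations: the module consumes a β matrix plus a DMR
table (1-based inclusive coordinates; member probes listed in genomic
order). Each DMR is represented by the member probe with the largest
probe-wise β range across samples; exact ties break to the earliest
probe in genomic order, which is deterministic. Spearman correlations
are reported per (tissue, group) stratum and overall, skipping strata
with n < 3; p-values are exact permutation enumerations for tie-free
n ≤ 9 and t-approximations otherwise. Raw p-values are reported always,
with a BH-adjusted column across all reported records by default, since
it is not obvious a priori whether consumers adjust across gene–DMR
pairs.

## Synthetic cohorts

The generator emulates the *shape* of a two-group (AA/EA) multi-omics
study — mutation lists with functional-effect labels, a gene × sample
lRR matrix, a gene × sample expression matrix, metadata, and probe-level
β values organized into DMRs — not the marginal distributions of any
real dataset. Channels are orthogonal and composable; all generators are
deterministic given the seed.

Defaults (the study conditions of the packaged experiments): 10 samples
per group; log2 expression = per-gene baseline U(3, 8) + N(0, 0.5)
noise; lRR = N(0, 0.3), so |ploidy| = 2 essentially only arises under a
planted shift; background mutation probability 0.01 per gene per sample
with a random effect label, reflecting the low mutational burden of
primary prostate tumors. Planted effects add a group-specific mutation
rate, lRR shift, log2-expression shift (default recovery experiment:
+4 log2 units on TGFB in group AA), or a methylation–expression coupling
with a target |Spearman ρ| realized through a Gaussian copula
(rho_S = (6/π)·asin(r/2)), made inverse by sign convention; magnitude 1
degenerates to an exactly monotone-decreasing link and magnitude 0 to
independence.

The toy AR network is hand-written and frozen so that exact
master-equation expectations — the direction of every node's knockout
response — are fixed oracles. Two design features matter for what the
recovery experiments can show. First, ΔAUC is a before/after ratio:
factors that do not interact with the perturbed node in the logic cancel
to first order, so a detectable planted effect must modulate the AR
interaction itself; in the fixture, SMAD = TGFB | !AR makes the TGF-β
ligand tone set how much activity AR-derepression can add. Second,
min-max normalization guarantees one expression-depleted patient per
gene per cohort, whose clamped rates freeze that node's dynamics for the
whole window; nodes that are not single transcripts (ligand tones
Androgen and GrowthFactor, the family-level SMAD read-out, the
Proliferation phenotype) are therefore excluded from the omics gene
universe, where real profiling would also not report them.

What passing the synthetic experiments shows — and does not. They
demonstrate that the pipeline recovers a planted group difference of the
stated size through the full personalize → simulate → knockout → filter
→ test chain, and that with exchangeable groups its false-positive
fraction stays at or below α. They do not show that real cohorts carry
effects of that size, nor calibrate the transfer function against real
expression dynamics; the generator matches schemas and structure, not
empirical moments.

## Numerical choices and degenerate inputs

* Exact-solver probabilities are clipped to [0, 1] after propagation;
  the distribution itself is conserved to 10⁻⁹.
* Monte Carlo vs exact comparisons use a 5-standard-error band plus a
  2/n cushion for grid points where the exact probability is 0 or 1 and
  the binomial error degenerates.
* Constant genes normalize to 0.5 (no information either way).
* Empty perturbations are allowed (before = after exactly, paired
  seeds); fully forced models are valid and yield constant curves.
* Mann-Whitney with identical groups returns p = 1; empty groups are
  errors, as are >2 group labels (run pairwise instead).

## Known limitations

* The exact solver is limited to ≤ 12 non-forced nodes (4096 states);
  larger models fall back to Monte Carlo.
* The expression→rate transfer is linear and uncalibrated; it encodes a
  monotonicity assumption, not measured kinetics.
* Only binary knockouts are modelled — no dose, no partial inhibition.
* Synchronous updating, attractor enumeration, and rate fitting to
  time-series data are out of scope.
* The packaged networks are small fixtures; published large models load
  through the same rule-file reader but their curation is external.
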