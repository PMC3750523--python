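# Methods

`multinoise` simulates stochastic gene expression with protein
multimerization and quantifies how multimerization reshapes the mean,
the noise, the responsiveness and the circuit-level behaviour of the
functional protein pool. This note records the model, the estimators, the
numerical choices, and the known limitations.

## The expression model

Time is measured in units of the protein lifetime: the protein
degradation rate is d_P = 1 unless stated otherwise, and all other rates
are expressed relative to it.

A single gene is four reactions:

1. **Transcription.** The start site S is consumed the moment it is
   available (an effectively infinite rate) and is released, together with
   one transcript M, after a delay drawn from Gam(α_M, (α_M k_M)⁻¹). The
   interval between consecutive transcript productions is therefore gamma
   with mean 1/k_M and coefficient of variation α_M^(−1/2). α_M = 1
   recovers a Poisson production process and Poissonian stationary mRNA,
   M ~ Poi(k_M/d_M); α_M > 1 (a multi-step initiation) gives
   sub-Poissonian mRNA, α_M < 1 super-Poissonian. Integer α_M can be read
   as the number of equal rate-limiting initiation steps.
2. **mRNA decay**: first order at rate d_M.
3. **Translation**: propensity k_P·M; the protein may optionally carry a
   maturation delay τ_P (fixed or truncated-normal). The default is
   τ_P = 0 — for a single gene a deterministic τ_P only time-shifts the
   protein series, and the truncated-normal option exists to check that
   maturation noise does not change any qualitative conclusion.
4. **Protein decay**: first order at rate d_P.

**Homomers** of order N add association reactions
P_{×k} + P_{×(n−k)} → P_{×n} for every 2 ≤ n ≤ N, k ≤ n/2, their
reversals, and the subunit-loss chain P_{×n} → P_{×(n−1)} at rate n·d_P
(any one of the n subunits may degrade). **Heterodimers** couple two
independently transcribed genes through P₁ + P₂ ⇌ P₁,₂ plus the two
single-subunit degradations P₁,₂ → P₂ and P₁,₂ → P₁. The standard study
conditions set association rates to infinity (INSTANT) and dissociation
to zero; both are configurable.

Each builder can maintain a bookkeeping species X_i — the total number of
subunits of protein i across all forms — updated only by production and
degradation events. Because X_i never enters a propensity, the identity
X_i = Σ_k k·P_{i×k} must hold as an exact integer identity at every
sample; the sweeps verify it on every run. The functional pool when all
forms are active is Y₁ = Σ_n P_{1×n} (each complex counts once).

**Toggle switch.** Two genes each repress the other through its order-N
homomer: the effective transcription rate of gene j is
k′_M/(1 + P_{i×N}/K). This state-dependent rate is only well defined
event-wise for memoryless (α_M = 1) initiation, so the toggle is built
with a Markovian transcription propensity, zero release delay and no
explicit promoter occupancy — for exponential intervals this coincides in
law with the delayed formulation — and α_M ≠ 1 is rejected. The standard
parameterization is d_M = 6·d_P, k′_M = 30·N (so the expected transcript
number per gene-equivalent is 5 and the mean repressor-multimer level
~25 is order-independent), k_P = 5·d_P, and K = 25·C where C is the
repression scale swept over [10⁻⁴, 10⁴].

## The simulator

The engine is an exact delayed-SSA: the next reaction is chosen by the
direct method from the current propensities, delayed products are held on
a time-ordered waitlist, and the earlier of next-reaction time and next
release wins. Propensities are re-evaluated after every event (necessary
for state-dependent rates). Mass-action propensities use the
combinatorial convention a = rate · Π C(x_i, m_i).

INSTANT reactions are resolved as a deterministic fixpoint after every
state change: fire one instance of the highest-priority applicable
instant reaction, rescan from the top, repeat until none applies.
Priority is an explicit field (builders set it to the order of the
multimer being formed, so higher-order assembly wins; ties break
lexically by product names). One-at-a-time firing matters: with 7 free
monomers in a trimer system it yields 2 trimers + 1 monomer, whereas
exhausting reactions one by one would strand dimers. A generous firing
cap turns a cycle of instant reactions into an error rather than a hang.

Two backends share these semantics: a numba-compiled kernel for models
whose rates are constants, INSTANT, or the structured repression law
(every model in this package), and a pure-Python loop that additionally
accepts arbitrary Python callables as rates. A simulation is reproducible
bit-for-bit from (model, initial state, seed, backend), and the backend
choice is itself a deterministic function of the model. Degenerate
(fixed) delays consume no randomness. Sampling starts at t = 0 and
includes the transient, matching the study's sampling protocol; samples
reflect the state after any event at exactly the sample time.

The engine is validated two ways: against closed-form stationary laws
(birth–death/Poisson, the monomer gene's M ~ Poi(k_M/d_M) and mean
protein k_M k_P/(d_M d_P)), and against a dense master-equation
enumeration of a finite-rate homodimer CTMC on a truncated
(mRNA, monomer, dimer) lattice, comparing stationary marginals by
chi-square at α = 0.01.

## Statistics

* **Noise** η is the squared coefficient of variation, variance/mean², of
  a copy-number series pooled over the whole run (transient included);
  a burn-in window can be excluded for sensitivity checks by slicing the
  series.
* **Gain** is the ratio of a statistic (mean or η) in the tested model to
  the same statistic in the null model. Tested and null runs at a grid
  point share a seed by default (paired seeds), which reduces the
  Monte-Carlo variance of the ratio; a config flag disables it.
* **Monte-Carlo standard errors** use batch means (20 batches by
  default): trajectory samples are autocorrelated, so the series is cut
  into contiguous batches, the statistic is computed per batch, and the
  SE is the batch-level standard deviation over √B. Gains carry
  first-order propagated SEs. Where a statistic is undefined (a complex
  that never formed has no η; a zero null has no ratio) the sweep reports
  NaN rather than failing the grid point.
* **Cross-correlation** is Pearson-normalized (mean-centred,
  variance-normalized, FFT-based) on a lag grid; the reported series pair
  is X₁ (total subunits — the quantity transcription controls directly)
  against P_{1×N}. With instant association and zero dissociation the
  free-monomer count is just X₁ mod N, so it is not a meaningful
  "monomer" signal. The **half-life** is the smallest positive lag at
  which the correlation first falls to half its zero-lag value, located
  by linear interpolation between lag-grid points (NaN if it never
  falls that far within the lag window). This experiment samples at 0.1
  time-unit intervals.
* **Switching time.** The toggle state is A when P_{1×N} > P_{2×N}, B
  when the inequality reverses; ties keep the incumbent state (no switch
  on a tie), and leading ties are ignored. `mean_switching_time` averages
  completed dwells (Δ times the samples between consecutive switches) and
  requires at least two switches. The sweep driver additionally reports
  time_per_switch = total sampled time / number of switches, which equals
  the dwell mean when switching is frequent and remains informative under
  strong repression, where a run can lock into one state and the few
  completed dwells all come from the initial transient race; the
  qualitative order comparisons use time_per_switch. Strong-repression
  rows pool dwells and switches across replicate runs.
* **Stationarity check.** For an ensemble of replicate trajectories on a
  common grid, each time's cross-replicate distribution of the multimer
  count is compared with the final-time distribution by a two-sample KS
  test (α = 0.05); the reported fraction is the share of times not
  rejected. Within one replicate the sample at t and at t_end are weakly
  dependent for t near t_end, which makes the test slightly conservative
  there. For goodness-of-fit of counts against a discrete law
  (Poisson mRNA) a naive one-sample KS is invalid under ties, so the
  package tests the seeded randomized probability integral transform
  U = F(x−1) + V·pmf(x), exactly Uniform(0,1) under the null.

## Interval-model fitting

Transcription-interval samples are fitted by maximum likelihood with a
gamma law (scipy, location fixed at 0) and with a sequential
three-exponential (hypoexponential) law — the sum of three independent
exponential steps with distinct rates, the natural competing model for a
sequential initiation process. The hypoexponential density is evaluated
as l₁l₂l₃ times the second divided difference of e^(−λt) over the rates,
with first divided differences computed through expm1 after factoring the
slower exponential; this is stable both for nearly equal and for widely
separated rates. Rates are parameterized as ordered with relative gaps
bounded below (10⁻³) and optimized by multi-start Nelder-Mead. The
preferred model is the one with the higher maximized likelihood. On 10⁴
synthetic samples the gamma fit recovers (shape, scale) within a few
percent and the likelihood comparison selects the generating family in
both directions.

## Synthetic genome-wide table

`generate_fixture` draws a per-gene table (mean copies/cell, squared CV,
essentiality, homogeneous-subunit count) with the qualitative structure
of genome-wide E. coli surveys: ~12% of genes essential; subunit-count
distributions patterned on the reported class compositions (essential
genes skewed toward multimers); lognormal means with a higher essential
median (34 vs 9) rising with subunit count; and noise
η = (floor + 2/μ)·lognormal scatter with an extrinsic floor of 0.12, so
highly expressed genes sit on the floor. The generator emulates the
*structure* of such data — it does not model operon organisation,
measurement error, heterogeneous complexes, or any real gene identity, so
tests passing on it show only that the summarizer and the qualitative
class contrasts behave correctly, not that real data would reproduce any
particular number. Real data enter only through the documented CSV schema
(gene, essential, subunits, mean, cv2).

## Problem sizes

Default sweeps use a coarse factorial grid — d_M, k_M, k_P ∈
{0.1, 1, 10}, α_M = 1 (27 points), 10⁴ time units per run, sampled every
time unit — which keeps a full sweep in the low minutes on one CPU while
preserving every qualitative ordering; `SweepConfig.full_scale()` selects
the full-size conditions (9 log-spaced values per rate, α_M ∈
{1, 2, 3, 5, 10}, 10⁵ time units). The cross-correlation experiment uses
0.1-unit sampling over 10⁴ units (10⁵ samples); the toggle runs 10⁵
samples at Δ = 1/30 per replicate. The acceptance script runs the same
scaled sizes.

## Known limitations and observed deviations from the ideal limits

* **Compensated multimer noise gains exceed 1/N for N ≥ 3.** With the
  transcription rate scaled by N, the noise gain of the order-N homomer
  has the ideal lower bound 1/N, but only the dimer attains it
  (0.510 ± 0.009 at mean level 100). The assembly scheme defines no
  reactions between sub-maximal complexes (only k ≤ n/2 pairs up to
  order N), so partial complexes produced by the subunit-loss chain
  accumulate into a fluctuating pool (at mean subunit level 500: ~31
  subunits held in partials, variance ~589) that adds noise to the top
  multimer: measured compensated gains at mean 100 are 0.51, 0.39, 0.33,
  0.28 for N = 2..5, monotone decreasing and each above 1/N.
* **The heterodimer/homodimer(2k_M) mean ratio reaches 1 only
  asymptotically.** The deficit is E[(X₁−X₂)⁺]/E[P₁ₓ₂] ∝ 1/√μ: measured
  0.86 at mean 100 and 0.946 at mean 1000.
* **Toggle, weak repression, N = 2.** Time-per-switch at weak repression
  is 0.73, 0.77, 0.31 time units for N = 1, 2, 3: the highest order
  switches much faster than the monomer, but the dimer sits ~5% above the
  monomer, stably across seeds and C ∈ [10², 10⁴], under the
  ties-keep-incumbent rule. Conventions that end a dwell on a tie would
  deflate the N ≥ 2 estimates (multimer counts have smaller spread, hence
  more ties); this package deliberately does not count ties as switches.
* The delayed formulation ties transcript release to promoter release
  (elongation is folded into the initiation interval); promoter ON/OFF
  states, explicit repressor-operator binding, cell division and
  partitioning, and spatial effects are out of scope.
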