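# Methods

`wormbiome` analyzes time-resolved abundance data from defined microbial
communities sampled from three compartments of a host-colonization
experiment — worm-free **control** plates, the worm-associated **substrate**
lawn, and the **host** animals themselves — and asks two questions: how much
of community assembly is stochastic (drift and dispersal) versus
deterministic (selection), and which genome-encoded functions the
deterministic part favors.  This note documents the models, the synthetic
data generator, the numerical choices, and the limits of what the test
suite demonstrates.

## Data model

The central object is a sample × taxon matrix of integer read counts with
per-sample metadata (source, time in hours, replicate, optional plate ID
shared by paired host/substrate samples).  Functional analyses additionally
use a binary taxon × function trait table in which every function belongs
to exactly one of eight subsystems (`cazyme`, `exchange`, `gut`,
`interactions`, `medium`, `metabolism`, `uast`, `virulence`), and
phylogenetic β-diversity uses a rooted tree over the taxa.  All formats are
plain TSV / newick; orientation is an explicit flag, never sniffed, and
malformed input always raises a typed error naming the offending record.

## Synthetic community generator

The generator emulates the design of a defined-community colonization
experiment: 43 taxa, 3 sources × 6 sampling times (16–186 h) × 10
replicates = 180 samples, sequenced to 10 000 reads.

* **Metacommunity.** Relative abundances are normalized lognormal(0, σ²)
  draws, σ = 1.5 by default — a heavy-tailed pool with a few dominant and
  many rare taxa, the standard shape for species-abundance distributions.
* **Local dynamics.** Each replicate community of `N` = 10 000 individuals
  follows a Moran birth–death process with immigration: per generation,
  `N` replacement events occur; a uniformly chosen individual dies and is
  replaced, with probability `m`, by an immigrant drawn from the
  metacommunity (weighted by the source's fitness vector `w`), otherwise by
  the offspring of a surviving local individual drawn ∝ count × `w`.  A
  Moran scheme (rather than Wright–Fisher) matches the continuous-turnover
  interpretation of the dispersal parameter that the neutral fit estimates:
  one immigration probability per death–replacement, with the same
  stationary beta approximation.  With all-ones fitness the process is
  exactly neutral.  Hours map to generations via `generations_per_hour`
  (default 1, keeping runs desk-scale).  The default immigration
  probability is `m` = 0.1 — dispersal-limited but not isolated.  The event
  loop is compiled with numba; a full 180-sample default dataset generates
  in a few seconds.
* **Initial state.** Every community starts from an even split across taxa,
  mirroring a defined inoculum mixed at equal proportions.  This choice has
  a visible consequence discussed under *Limitations*.
* **Sequencing.** Reads are a multinomial draw of the latent composition at
  fixed depth.
* **Traits.** Function presence is Bernoulli(0.3) per taxon; for `gut`
  functions the presence *odds* are multiplied by `gut_link` (default 2)
  for a designated set of host-adapted taxa (default 20 of 43).  Every
  function is redrawn until it has at least one carrier.
* **Emergent host selection.** The host source's fitness vector is derived
  from the trait table, `w_t = 1 + (gut_link − 1) · carriage_t`, where
  `carriage_t` is the fraction of gut functions taxon `t` encodes.  Host
  enrichment of gut functions downstream is therefore an emergent property
  of the dynamics, not painted onto the read counts.  Control and substrate
  use all-ones fitness, so sources differ only through fitness (and seed),
  making detected source effects attributable.
* **Tree.** A random bifurcating topology with exponential(1) branch
  lengths — enough to exercise phylogenetic distances, with no claim of
  realism.

A single seed drives everything; per-sample and per-stage seeds are spawned
deterministically via `SeedSequence([seed, …])`, so stages re-run
standalone reproduce pipeline results bit for bit.

## Diversity

α-diversity: Shannon in **nats** (the common ecology default; no log base
is universal), Simpson as 1 − Σp², and bias-corrected Chao1
(S_obs + F₁(F₁−1)/(2(F₂+1)), robust when no doubletons exist).
β-diversity: Bray–Curtis on counts; Aitchison distance as Euclidean
distance between CLR-transformed compositions after adding a pseudocount
(default 0.5, configurable — zero handling is otherwise undefined for
log-ratio methods); and normalized weighted UniFrac, bounded in [0, 1] and
comparable across depths.  No rarefaction is applied; each metric carries
its own normalization.  PCoA uses Gower double-centering and reports
negative eigenvalues rather than silently dropping them.  PERMANOVA uses
the classical squared-distance sums decomposition with seeded label
permutations and the (1 + exceedances)/(1 + n_perm) estimator, switching to
exhaustive enumeration (exact p) when the number of distinct label
arrangements is at most `n_perm`.  Between-source distance trends pair
samples by shared plate where available, else by 100 seeded random
bijections per time point.

## Neutral assembly fit

Under neutral drift–immigration dynamics the long-run local relative
abundance of a taxon with metacommunity frequency `p` is approximately
Beta(Nm·p, Nm·(1−p)).  The probability of detecting the taxon above a
relative-abundance threshold `d` is `F(p) = 1 − I_d(Nm·p, Nm·(1−p))`, and
`Nm` is fitted by least squares of observed occurrence frequencies against
`F(p)` over a bounded search on log Nm ∈ [log 10⁻², log 10⁷]
(least squares, not a binomial likelihood, matching the standard practice
for this occurrence-curve fit; fits that end on a bound are flagged).
Defaults: `d` = 1/median library size (one read at typical depth — the
natural sequencing detection limit) and `N` = median library size for
`m = Nm/N`, both logged with each result.  R² is computed against the mean
observed frequency and is undefined (flagged) when all taxa occur equally.
Confidence intervals come from a seeded bootstrap over taxa (default 500).
Fits are per (source, time) group, because the dispersal parameter is
reported per time and sample type; the metacommunity estimate is the
group's mean relative abundance vector.

## Stochasticity (tNST)

For every within-group sample pair, the observed dissimilarity `D_ij`
(Jaccard on presence/absence by default; Bray–Curtis optional) is compared
with its mean `Ē_ij` under a null model.  The default null, **PF**, keeps
each sample's richness Fixed and draws taxa with probability Proportional
to their regional occurrence frequency; abundances are then assigned by a
multinomial draw of the sample's library size over the drawn taxa ∝
regional relative abundance, with each drawn taxon first given one read so
realized richness is exact (relevant only for abundance-weighted
dissimilarities).  Selection strength is the normalized departure in either
direction,

    SS_ij = (Ē_ij − D_ij)/Ē_ij          if D_ij < Ē_ij
    SS_ij = (D_ij − Ē_ij)/(D_max − Ē_ij) otherwise,  D_max = 1,

with SS = 0 when D = Ē exactly (including both 0 or both 1); NST_ij =
1 − SS_ij and the group tNST is the pair mean.  Values above 0.5 read as
stochasticity-dominated, below 0.5 as determinism-dominated.  Group
comparisons use a pair-level bootstrap (resampling each group's NST_ij
values, two-sided p with the +1 correction); pair-level rather than
sample-level resampling is a documented choice.

**When can tNST discriminate?**  A point that shaped the test design: with
very deep sequencing of a defined community, every taxon is detected in
every sample, the PF null then reproduces the observed (saturated)
occupancy exactly, and tNST compresses toward 1 regardless of the assembly
regime.  The regime-separation tests therefore use shallow sequencing
(500 reads) of a moderately spread metacommunity (σ = 0.8, 20 taxa,
N = 20 000, 100 generations, 12 replicates): neutral assembly
(m = 0.5, flat fitness) keeps all taxa above the detection limit, so
observed variation matches the null (tNST > 0.5), while strong selection
(ratio 5 on 5 taxa, m = 0.05) pushes disfavored taxa below it, creating
occupancy heterogeneity that the null redistributes but replicate
communities agree on (tNST < 0.5).  Outside such a detection window the
index is honestly uninformative, which is also why the deeply sequenced
default dataset shows high tNST in all sources.

## Functional profiling and attribution

A function's abundance in a sample is the summed read count of all taxa
predicted to carry it (counts, not relative abundances, are summed; a
relative-abundance switch exists for sensitivity analysis).  Functional
diversity is the Shannon index of a sample's function profile.  Taxon
contribution fits, per function, a ridge regression of the function's
abundance on all taxon abundances — columns centered and scaled, response
centered, penalty chosen per function by seeded 5-fold cross-validation
over a 13-point log grid (10⁻³…10³) — and summarizes coefficients per
taxon and subsystem.  Ridge (L2) is used because taxon abundances are
strongly collinear in compositional data and L2 gives stabler attributions
than L1; coefficients are reported on the standardized scale so they are
comparable across taxa.

## Differential abundance

A compact negative-binomial Wald stage: median-of-ratios size factors
enter a log-link NB GLM as offsets; the design is intercept + source +
time, both categorical (time as 6 levels — no linearity in hours is
assumed), with `control` as the reference level and no interaction;
per-feature dispersion is estimated by Cox–Reid-adjusted maximum
likelihood over log α ∈ [10⁻⁸, 10²] with the GLM coefficients and
dispersion alternated twice from a Poisson initialization.  The Wald
statistic for a source contrast uses the coefficient covariance from the
final IRLS fit, with standard-normal p-values and Benjamini–Hochberg
adjustment across features.  Deliberate simplifications relative to the
heavyweight tools: no dispersion shrinkage toward a mean–dispersion trend,
no fold-change shrinkage, no independent filtering.  The stage is
validated by calibration (type-I error within [0.03, 0.07] on a Poisson
null) and recovery (spiked log₂ fold changes of 2 recovered within ±0.5),
not by numerical identity with any external package.  All-zero features
are excluded and reported; non-converged fits keep their row with p = NA.

## Problem sizes used in the test suite

Simulation-based tests run at desk scale, chosen once: neutral-fit
recovery uses the generating curve directly (Nm = 120, 500 taxa, 50
samples, 20 seeds); end-to-end neutral R² uses 25 replicates at N = 2 000
and depth 2 000 (10 seeds); tNST regime separation uses the shallow-depth
window described above (20 + 20 seeds); the R²-discrimination check uses
N = 500 where drift is strong enough that selection visibly distorts the
occurrence curve; functional-enrichment and pipeline-null checks run the
full default 180-sample design (10 and 3 seeds).

## Limitations

* The generator's even inoculum means α- and functional diversity start at
  their maximum, so **host functional diversity declines over time** in
  synthetic data even though gut-linked selection is acting; the robust
  emergent signature of host selection here is the rising *gut-function
  share* of the host profile (and the NB contrasts), not a rising Shannon
  index.  Real colonization series that begin from sparse founder
  communities can show the opposite diversity trend; the generator does
  not model founder dynamics, worm demography, or age-dependent grinder
  decay (an aging effect could be emulated with time-varying fitness, off
  by default).
* tNST values are only directionally meaningful; they depend on the
  dissimilarity index, null model and sequencing depth (see the detection
  window above), none of which can be pinned to a single "true" value.
* The NB stage's omissions (no shrinkage, no independent filtering) make
  it slightly conservative at small sample sizes relative to shrinkage
  estimators.
* Passing tests demonstrate internal correctness and recoverability of
  planted effects under the generator's assumptions — multinomial
  sequencing noise, source effects expressed purely through fitness — not
  robustness to real-data pathologies such as contamination, batch
  effects, or compositional artifacts beyond what CLR handles.
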