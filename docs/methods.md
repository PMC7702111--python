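# Methods

This note documents the models behind `pond_assembly`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate about real data.

## Amplicon error model and denoiser

Reads are modelled as fixed-length amplicons carrying two kinds of
substitution error: PCR errors, which arise once per duplication at rate
ε_pcr per base and are inherited by all descendant molecules
(*propagating*), and sequencing errors at rate ε_seq per base per read
(*non-propagating*).  Under exponential amplification a sampled molecule
has passed through Binomial(cycles, ½) duplications, so the denoiser
summarizes both sources as an effective per-base rate
ε_eff = ε_seq + (cycles/2)·ε_pcr.  The exact lineage-weighted expectation
differs from this by O(1); the simulator-versus-denoiser consistency test
(error-free read fraction against (1−ε_eff)^L) bounds the discrepancy.

Defaults ε_pcr = 1e-5 /base/cycle, 30 cycles, ε_seq = 1e-3 /base are
plausible modern-platform values and are configurable everywhere; nothing
downstream depends on them being exact.

**Decision rule.**  A query unique sequence at distance *d* from an accepted
genotype of total count *N* is an error variant with expected count
μ = N·(ε_eff/3)^d.  The query becomes a new genotype only if the Poisson
upper tail P(X ≥ count | μ) falls below α for *every* candidate parent
within the search radius (default 10 substitutions; beyond it μ underflows
and sequences are genotypes automatically).  α defaults to 1e-40.  That
value is deliberately extreme: a deep run implicitly performs thousands of
such tests (≈ 3L·d₁ variants per genotype), and shared PCR lineages make
variant counts over-dispersed relative to the Poisson model, so a
"reasonable-looking" per-test α of 1e-3 would admit several false genotypes
per run.  True genotypes at usable depths have tail probabilities far below
any of this (a 2-substitution pair at 10:1 abundance and 50k reads sits at
~10^-10000), so sensitivity is unaffected.  A UNOISE-style abundance-skew
threshold β(d) = 1/2^(αd+1) is available via `method="unoise"` for
comparison.

**Distance.**  Hamming distance on equal-length sequences; unequal lengths
are compared prefix-anchored with the length difference counted as terminal
mismatches.  This dialect matters only for inputs that violate the
fixed-length amplicon assumption.

**Chimeras.**  Before acceptance, each candidate genotype is scanned for a
single breakpoint splitting it into an exact prefix of one accepted
genotype and an exact suffix of another, both at least `min_parent_skew`
(default 2×) more abundant.  Multi-crossover chimeras and inexact-segment
matches are out of scope.  Note the decision order: a chimera whose
breakpoint falls near a read end is within a few substitutions of one
parent and is legitimately consumed as that parent's error cloud before the
chimera check runs; the chimera benchmark therefore scores only chimeric
sequences that are actually presented to the check.

**Funneling** is transitive — counts accumulate on the ultimate accepted
ancestor, matching the "ancestor sequence" reading — and denoising is
pooled across samples with per-sample count tracking, because the chimera
check is defined against the whole data set.  The expected-error filter
reads its 0.5 threshold as *maximum expected errors per sequence*
(EE = Σ 10^(−Q/10)), the standard interpretation.

## Synthetic reads

PCR is simulated as an explicit branching process: every molecule
duplicates each cycle, copies mutate at ε_pcr per base, and the population
is subsampled to at most 2^18 molecules.  Amplification starts from one
template molecule per eventual read (real extractions supply many
templates): starting from a single template would let a cycle-1 mutation
into a quarter of all reads, which no abundance-based test could reject.
The cap matters too — each subsampling step adds genetic drift that real,
effectively uncapped PCR lacks — and 2^18 keeps that artifact below the
decision threshold at the depths the benchmarks use.  Chimeras replace a
read with a two-template splice at a uniform breakpoint.  Quality strings
are constant per read at Q = −10·log₁₀(ε_seq); sufficient for testing the
expected-error filter, though real per-base quality profiles decay along
the read.

## Metacommunity generator

Local communities of `individuals_per_site` individuals assemble from a
regional pool.  With probability *w* (the niche weight) an individual is
recruited deterministically with weight ∝ regional abundance ×
exp(−(env − optimum)²/2σ²) on a single environmental axis; otherwise
neutrally ∝ regional abundance.  Species optima are fixed; the two pond
types sit at env = ∓1.

Two deliberate design choices:

* **The regional pool is a deterministic lognormal-quantile rank-abundance
  curve** (σ = 2, 1000 species).  Drawing the pool at random adds a large
  replicate-to-replicate variance component that is a property of the pool
  draw, not of assembly, and obscures the *w* signal the generator exists
  to encode.
* **Recruitment passes through a Pólya-urn founder stage**: site-level
  recruitment probabilities are a Dirichlet draw with concentration
  `n_founders` × weight (default 200), i.e. each pond is a modest founder
  pool grown clonally.  Pure multinomial sampling has no ecological drift,
  and communities assembled that way are systematically *more* similar than
  the richness- and frequency-preserving null expects (RC → −1 everywhere);
  unbounded drift overshoots in the other direction.  200 effective
  colonists per pond reproduces, at desk scale, the qualitative shape of a
  real two-type pond survey — per-pond richness ≈ 130 out of a 1000-species
  pool and within-type Bray-Curtis ≈ 0.5 — while leaving neutral
  communities inside the null band.  Defaults were frozen during generator
  design and are not touched by any test.

With defaults, depth 2000 per site and 20 sites in two types, w = 0 yields
NST ≈ 85–90% and ≥ 90% of RC pairs inside ±0.95; w = 1 yields between-type
NST < 25% with between-type RC almost entirely above +0.95.

The occupancy mixture (`simulate_occupancy_mixture`) superimposes a
150-species abundant, purely niche-sorted component (environments jittered
within type so determinism acts within groups too) on an 850-species rare,
strongly drifting neutral component; stratifying NST by occupancy then
declines from the stochastic regime at k = 1 toward the deterministic
regime where only widespread taxa remain.

What these simulations do **not** capture: taxon-specific read-depth
biases, temporal dynamics, spatial autocorrelation within a site, more than
one environmental axis, and any coupling between community composition and
the simulated gas chemistry beyond the built-in methanotroph–CH₄ relation.
Passing benchmarks demonstrates correctness and calibration of the
statistics under these controlled conditions, not that field data will show
the same effect sizes.

## Null models

The shared null preserves each sample's observed richness, draws species
identities without replacement with probability ∝ occurrence frequency
across samples (Gumbel top-k, equivalent to sequential weighted sampling),
seeds every drawn species with one individual — so realized richness equals
observed richness — and distributes the remaining individuals
multinomially ∝ regional relative abundance restricted to the drawn set.
An equiprobable species draw is available behind a flag.  Correctness is
anchored by an exhaustive-enumeration oracle on 3-species pools.

Raup-Crick uses the ½-weight tie convention (ties matter at small rep
counts); bins are (−1,−0.95), [−0.95,0.95], (0.95,1).  NST follows the
selection-strength formulation SS = (E−D)/E for D < E, else
(D−E)/(D_max−E) with D_max = 1, ST = 1−SS, NST = 100·mean(ST) over the
pairs in scope; the extreme-case anchors (null-indistinguishable ⇒ 100%,
maximal divergence ⇒ 0%) pin the convention rather than any particular
software's internals.  The two-group NST difference test bootstraps samples
within groups (999 draws, two-sided, centred).

Occupancy stratification offers cumulative (≥ k, default) and exact (= k)
modes, since either reading of "present in an increasing number of systems"
is defensible; occupancy is computed on the pond-level (replicate-pooled)
table.

βMNTD is the abundance-weighted mean nearest-taxon patristic distance,
cross-checked to machine precision against R `picante::comdistnt`.  The
βNTI null relocates communities to random tips; by default each sample
receives an *independent* whole-tree permutation per replicate.  A single
matrix-wide permutation (available as `shuffle="whole_matrix"`) leaves any
pair of compositionally identical samples with a degenerate null (βMNTD is
exactly 0 in every draw), whereas the per-sample null gives such pairs a
proper distribution and scores them strongly negative, which is the
behaviour the clustering interpretation requires.

Null replicate counts default to 1000 (minimum 100); tests and the demo use
150–300 so the suite stays in minutes — Monte-Carlo error scales as
1/√reps and is verified to.

## Geochemistry

Henry constants default to standard compilation values (CO₂:
0.0334 mol L⁻¹ atm⁻¹, 2400 K; CH₄: 1.4e-3 mol L⁻¹ atm⁻¹, 1700 K) with
atmospheric mixing ratios 407 ppm CO₂ / 1.85 ppm CH₄ (2018 global means);
at 15.5 °C these reproduce the 17.7 µM CO₂ and 3.1e-3 µM CH₄
air-equilibrium references.  Freshwater is assumed (no salinity
correction).  The headspace inversion is an ideal-gas mass balance at 1 atm
with the ambient-air contribution subtracted; a negative inferred
concentration is clamped to zero with a warning.  The forward equilibration
model lives alongside the inversion, and their round trip is identity to
numerical tolerance.  Box-Cox λ is selected on a grid (−5…5, step 0.01) by
the normal profile log-likelihood; isotope mixing corrections and
atmospheric flux estimation are out of scope.

## Numerical and reproducibility conventions

All stochastic operations take explicit integer seeds; no global random
state is used anywhere, and the pipeline manifest records every seed and
parameter actually applied, including defaults.  Dereplication breaks count
ties lexicographically.  Permutation p-values use the +1 correction and are
never exactly zero.  OTU tables are OTUs-as-rows everywhere, TSV with a
header row.  Rarefaction is multinomial with replacement by default
(without-replacement subsampling available); the demo pipeline rarefies per
sample before any pooling, with the alternative order available through the
library.  Degenerate inputs (all-zero samples, zero-variance distance
matrices, empty occupancy strata, zero null variance in βNTI) warn and are
excluded or reported as NaN rather than silently propagated.
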