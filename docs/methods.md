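# Methods

This note records the models, conventions and numerical choices behind
`temposel`, in the order the pipeline uses them.

## Data model and populations

Genotypes are biallelic calls on near-homozygous inbred lines, coded
A0/A1/HET/MISSING.  Residual heterozygosity in such material is rare and
mostly technical, so HET is treated as a *wildcard* in every
identity-based computation (ancestry match runs, H tracts) and as a
*half-dose* in every frequency- or distance-based one (IBS scores 0.5
against a homozygote and 1.0 against another HET; diversity counts a
HET–homozygote pair as half a difference; allele counts take 0.5).
MISSING is excluded pairwise and terminates identity runs.  Lines whose
HET fraction exceeds 1% trigger a warning.

Populations follow maturity group: MG 00/0/I → MG 0-I, MG III/IV →
MG III-IV, MG V and later → MG V+, MG II excluded (historically admixed
between the northern groups).  Release decades form cohorts
(pre-1970 pool, 1970s … 2000s) mapped to effective generations
(0, 15, 25, 35, 45): the first gap is wider because the pooled early
cohort spans three decades of releases.  Both assignments are pure
functions of (maturity group, year).

## Ancestry by haplotype sharing

For a marker m and candidate ancestor a, the match extent is the number
of consecutive agreeing markers ending at m (counting m once) plus the
run starting at m+1, truncated at chromosome ends.  The marker is
assigned to the best ancestor only when its extent beats the second best
by strictly more than the margin threshold (default 5 markers); ties and
narrow wins are AMBIGUOUS.  Extents are in marker counts with one
genome-wide threshold, appropriate for chips laid out at roughly uniform
genetic spacing (~0.1 cM/marker).  Fractional contributions divide each
ancestor's assigned markers by all unambiguously assigned markers,
pooled over a population's lines; ancestors above 3% are "founding
ancestors".  The fast implementation is a two-pass run-length scan
(O(lines × ancestors × markers)); a brute-force per-marker expansion is
kept in the test suite as the oracle and matches it exactly.

## Windowed diversity

π is the mean over line pairs of (differing / comparable markers) inside
50-marker windows advanced by 10; windows are defined on marker index,
with bp spans reported from their first/last markers and the midsite
labelled by the window's central (25th) marker.  Cohort-versus-reference
change is log₂(π_x/π_a), clipped to ±8; π_x = 0 reports the −8 floor
(printed "<−8"-style) and π_a = 0 masks the window (the ratio is
undefined without reference diversity).  Sub-threshold windows
(default < −2.3) merge when their index ranges touch; each region reports
the minimum-ratio window and the percentage of founding ancestors
carrying the focal population's major window haplotype there.
"Carrying" means ≥90% marker identity with the major haplotype rather
than exact 50-marker equality: founders identical across the whole
window would leave π_a = 0 and mask the region, so exact matching would
make a 100%-founders region unreportable.

## Time-serial statistics

Per locus, the tracked allele is the major allele of the first cohort,
and cohort frequencies are half-dose counts over called lines.

* **Δf** — OLS slope of frequency on generation.  The series is
  truncated after the first timepoint whose frequency leaves
  (0.05, 0.95), inclusive of that timepoint; series with fewer than two
  usable points report 0 and are flagged.
* **Logistic β** — slope of a binomial-family GLM of frequency on
  generation over *all* timepoints.  The in-house vectorized IRLS
  follows R `glm` numerics (mustart = (wy+0.5)/(w+1), relative deviance
  tolerance 1e-8, 25-iteration cap) because absorbed trajectories
  (frequencies hitting 0/1) dominate the null tail and their fitted |β|
  depends on those conventions; it agrees with R to ~1e-13 on converged
  fits and with statsmodels on interior series.  Sample-size-weighted
  fits are available and are the default when sizes are known; the scan
  and power analyses use unweighted proportions.  Fully fixed series are
  degenerate and report a signed-infinity sentinel with a flag.
* **Temporal F_st** — with J(p) = p² + (1−p)², endpoints p₁, p₂ after
  Δf-style truncation, J_w their mean, J_b the homozygosity of the
  pooled mean: F_st = (J_w − J_b)/(1 − J_b); both endpoints fixed for
  the same allele give 0 by convention.

## Effective population size

`NeModel` is an exact hidden-Markov likelihood: states are allele counts
0..N, transitions are binomial Wright–Fisher matrices raised to the
generation gaps, and each timepoint contributes a binomial observation
term (counts out of the per-cohort sample sizes).  N is profiled on an
integer grid inside the search bounds (default 20–1000): a geometric
coarse grid brackets the maximum, trisection narrows it to integers, and
the 95% CI comes from the likelihood-ratio drop of 1.92 with the
crossing interpolated between adjacent integers and rounded outward
(truncating inward measurably under-covers).  Three numerical choices
matter:

* **Census data** (sample = population) use a conditional path
  likelihood — products of transition probabilities between the nearest
  state per observation — with a frequency-scale Jacobian (one log N per
  transition per locus).  Without the Jacobian, likelihoods are not
  comparable across candidate N: coarser state grids concentrate more
  mass per state and the MLE collapses to the lower bound.
* **Ascertainment**: the study filters loci to an initial major-allele
  frequency band (0.5–0.6).  The model accepts that band as an
  initial-state prior, discretized by cell overlap (a hard indicator
  resonates with the state lattice and produces a jagged profile), and
  conditions the likelihood on the first observation, whose marginal
  carries no drift information.  With both in place the estimator is
  unbiased at the study's sampling depths (mean MLE 199.4 at true
  N = 200, 5000 loci) with 95%-CI coverage 19/20.
* Transition matrices are cached per (N, gaps), which makes repeated
  fits over similar data cheap.

The estimate is reported in haploid individuals (each inbred line is one
haplotype).

## Neutral thresholds and the scan

The Δf detection threshold for a population is the (1 − tail) quantile
(default 95th) of |Δf| over simulated neutral Wright–Fisher loci at the
estimated N_e, with starting frequencies resampled from the population's
own initial-frequency spectrum and observation through the population's
actual cohort sizes.  Scan loci use all markers with initial major
frequency < 0.95.  Windows combine the mean of the top-3 per-marker |Δf|
(one marker is noisy, a 50-marker average is insensitive) with the log₂
diversity ratio of the 2000s cohort against the pre-1970s cohort, and
are classified by two thresholds: fast + diversity-loss → hard sweep,
fast only → soft sweep, loss only → haplotype sneak, neither → neutral
(boundary values inclusive; diversity thresholds are quoted as positive
magnitudes of log₂ reduction).  Cross-population candidates are markers
whose |Δf| exceeds the source population's threshold while another
population is fixed (≥0.95 / ≤0.05) on the opposite side of the source's
direction of change; their Δf values are exported ×1000 by presentation
convention, with internal units unchanged.

## Haplotype spectra and H

Window spectra count distinct complete 50-marker strings per cohort
(lines with HET/MISSING in the window leave that window's denominator).
Early-cohort haplotypes take ranks 1–7 by descending frequency with the
rest lumped as OTHER; late spectra match identities by exact string
equality, and the per-window maximum haplotype change is the largest
|late − early| over all strings.  Haplotype change uses only the first
and last cohorts while allele Δf uses all cohorts with truncation — an
intentional asymmetry, preserved because the two measures answer
different questions (total turnover vs. pre-fixation rate).  The
sneak-ratio contrast compares max-haplotype-change / max-allele-change
between sneak and neutral windows by one-sided label permutation on the
median difference (default 10⁵ permutations; a permutation test is used
because the contrast's sampling distribution is unknown); zero-denominator
windows are excluded and counted.  H(x) is the mean over line pairs of
the maximal identical tract containing marker x (0 when the pair
disagrees at x itself — the alternative of skipping such pairs would
overstate sharing at polymorphic sites), in marker units.

## Wright–Fisher simulation and the power study

The simulator is haploid (lines are immortalized haplotypes): each
generation applies the deterministic selection update
p* = p(1+s)/(1+ps) — relative fitness 1+s against 1 — followed by
binomial(N, p*) reproduction, absorbing at 0 and 1.  At s = 0 the
simulator matches the closed-form drift mean and variance
(p₀(1−p₀)(1−(1−1/N)^t)), the primary correctness oracle.

The power study crosses selection coefficients (0.02, 0.05, 0.1) with
initial favored-allele frequencies (0.2, 0.5, 0.8) and two observation
modes at N = 200, generations (0, 15, 25, 35, 45): census, and sampling
at per-timepoint depths (31, 28, 59, 59, 22).  Sampled observation draws
*distinct lines without replacement* (hypergeometric) — genotyped
varieties are distinct members of the breeding population, and
with-replacement binomial draws overstate the observation noise.  Each
cell simulates matched selected and neutral arms at the same p₀; the
threshold is the 95th percentile of the neutral |statistic| (absolute
values throughout, since allele polarity versus selection is unknown in
real data), and power is the percentage of selected loci above it.
Fixation truncation for Δf and F_st follows the *population* frequency
path, which the simulation knows — it is the allele that reaches
fixation, not its sample estimate; logistic β uses all timepoints.
Default 5000 replicates per arm put the Monte-Carlo SE of a power
estimate below 0.7 percentage points; the grid at that depth runs in a
few seconds.

### What the synthetic data do and do not emulate

The generators reproduce the structural features the methods rely on —
homozygous ancestor haplotypes with controllable relatedness (including
~85%-IBS near-duplicate pairs), crossover mosaics with known donor
truth, decade cohorts with genuine serial drift (optional closed-pool
breeding mode), frequency-dependent sampling noise, and selection of
tunable strength.  They do not emulate linkage-disequilibrium decay
shaped by real recombination landscapes, marker ascertainment bias of a
genotyping chip, population admixture, or phenotype-driven selection on
linked complexes.  Passing tests therefore demonstrate correctness of
the statistics and estimators under their stated models, not robustness
to every pathology of real panel data.

## Known limitations

* The logistic-β null distribution at extreme starting frequencies is
  dominated by absorbed trajectories whose fitted |β| is
  convention-sensitive; power values for those cells are reproducible
  under this package's (R-matched) conventions but are intrinsically
  fragile across implementations.
* The N_e likelihood assumes one constant N across the sampled interval
  and neutral, unlinked loci; linked selection compresses apparent N_e.
* Ancestry tracing assumes the true donor is in the ancestor panel;
  unsampled donors surface as inflated ambiguity, not as errors.
* Window statistics assume dense, evenly spaced markers; windows with
  fewer than three usable loci are skipped, not imputed.
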