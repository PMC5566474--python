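# Methods

## Scope and conventions

All coordinates are 0-based half-open (BED convention) in every module;
1-based inputs are not auto-detected. A fragment's midpoint is
floor((start+end)/2), deterministic for even lengths. Fragment-level
coverage counts each sequenced molecule once; overlapping mate reads are
never double-counted.

## Synthetic cfDNA cohort

The generator emulates the statistical structure of plasma cfDNA so that
downstream operations can be tested as parameter-recovery problems rather
than against fixtures.

**Genome.** I.i.d. bases with a piecewise GC landscape (default 45% GC,
100 kb). The mononucleotide-run census (runs ≥ 4) is returned alongside, as
these runs are the slippage-indel opportunities.

**Nucleosome model.** Centers sit on a fixed grid at the spacing (default
180 bp) plus independent integer jitter (default ±10 bp). A fixed grid
rather than a statistical positioning model keeps ground-truth centers
unambiguous for peak-recovery scoring. Each nucleosomal fragment protects
`protection_length` = 167 bp (chromatosome: core particle plus linker
histone) around a randomly chosen center.

**End trimming (nicking).** Each fragment end independently sits at the
protected-core edge with probability `linker_accessibility` (default 0.5),
or at the k-th helical-turn nick position, k·10.4 bp inward, with k
geometric (ratio `nick_decay` = 0.75, capped at 12 turns), blurred by a
σ = 1 bp Gaussian. This is the simplest generative model that reproduces
both the 167-nt mode and the ~10.4-nt sub-periodicity of the fragment
length histogram; the underlying biology (endonucleolytic nicking of the
exposed minor groove once per helical turn) motivates the 10.4-bp lattice
but does not prescribe a distribution over turns.

**TF footprints.** Configured sites emit fragments of their footprint
length (35–80 bp, ±3 bp jitter) centered on the site, when the site is
occupied (per-site Bernoulli). By default no TF sites are configured; the
pipelines add them where footprint analyses are exercised.

**End bias.** Ligation preference is modeled as per-position, per-base
weights at the first three 5′ positions and the 3′ terminal positions,
applied by acceptance sampling (not reweighting), so downstream code sees
an ordinary fragment collection. No quantitative magnitude for the bias is
established in the literature for this chemistry; the default profile is
uniform, and the weights are explicit calibration knobs.

**Reads and errors.** Each molecule receives a random 13-base UMI and a PCR
family of size 1 + Poisson(mean − 1) (default mean 3). Reads are emitted in
reference orientation with a CIGAR. Substitutions are uniform per base
(each of the three alternatives equally likely); slippage indels occur only
inside mononucleotide runs — single-base deletions at T-runs and
insertions at A-runs, with per-traversal probability rising exponentially
with run length (2·10⁻⁴·e^{0.75(L−2)}, capped at 0.25). Every injected
event is recorded in a ledger, so error-rate estimators are scored against
exact injected counts, not approximations. Base qualities are set from the
substitution rate (Q = −10·log₁₀ rate, capped at 40); there is no
quality-ramp model along the read.

**Bisulfite calls.** A biomarker region r with reference densities M_r and
tissue mixture p has true density d_r = Σ_t p_t M_rt; each of its CpGs
(default 10 per 500-bp region) draws methylated counts Binomial(depth, d′)
with d′ = d(1−e) + (1−d)e folding in a symmetric conversion/call error e.
Synthetic reference matrices draw densities Beta(0.2, 0.2): biomarker
panels are selected for tissue discrimination, so reference densities are
bimodal, and this conditioning is what makes depth-100 mixture recovery
accurate; with uniform-random reference densities the same solver is
correct but the information per region is materially lower.

**What the generator does not emulate.** Real GC-dependent coverage bias
(the synthetic genome is homogeneous unless a landscape is configured),
mappability gaps, CNVs and chromosomal structure, sequence-dependent
nucleosome positioning, quality decay along reads, chimeric molecules, and
incomplete bisulfite conversion beyond a symmetric error. Passing the
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every artifact of real libraries.

## Window protection score

WPS(p) = (fragments spanning the whole w-window centered at p) − (fragments
with an endpoint inside it). Both termini (start and end−1) count as
endpoints; a fragment contributes at most once per position, with spanning
taking precedence at the single boundary position where both conditions
hold. Even windows anchor as [p − w/2, p + w/2). Size classes follow the
plasma convention: long = 120–180 nt with w = 120; short = 35–80 nt with
w = 16. The production implementation uses difference arrays and is tested
for exact equality against a literal per-position oracle.

Scaling standardizes a track to mean 0, SD 1 (population SD) over its
region. Multi-replicate analyses pool fragments before computing WPS
rather than averaging per-replicate tracks.

## Nucleosome peak calling

The long-class raw track is adjusted by subtracting a centered running
median (window 1001 bp), then smoothed with a Savitzky-Golay filter
(window 21, order 2). Candidate regions are maximal runs of positive
smoothed score, merging runs separated by ≤ 5 bp below zero; regions of
50–450 bp are retained and the center is the median position of the
maximal-scoring run. All constants are parameters of `PeakCallingParams`.

**Spacing statistic.** The repeat length is reported as the mode (1-bp
resolution, 3-bp moving-average smoothing) of the gaps between consecutive
called centers. A per-peak nearest-neighbor variant is available
(`method="nearest"`), but note that min(left gap, right gap) is a biased
readout: under center jitter its mode falls systematically below the true
repeat length (~5 bp low on perfect centers at ±10 bp jitter, more with
calling noise), so adjacent gaps are the default. Cross-sample comparison
uses signed distances from each center to the nearest center of the other
set, histogrammed in 6-bp bins with one bin centered on zero.

## Fragment-length periodicity

The length histogram over 50–160 nt is detrended with a 21-bin running
median; local maxima (minimum separation 8 bins, prominence ≥ 5% of the
detrended maximum) are regressed as peak position vs peak index, and the
slope is the period. Requiring ≥ 3 maxima rejects smooth unimodal
histograms instead of returning a meaningless slope.

## Dinucleotide profile

Fragments of exactly 167 nt contribute a 241-base window centered on their
midpoint, giving 240 dinucleotide positions. Position-specific frequencies
(16 dinucleotides summing to 1 per position) are normalized per
dinucleotide by a reflect-padded running median of width 101, so 1.0 is
the local background and nucleosome-phased W/S oscillations stand out.

## Coverage and error metrics

* **Poisson agreement:** R² between observed per-depth base fractions and
  the Poisson pmf at the observed mean, over depths with expected mass
  ≥ 10⁻⁶ (tail truncation keeps SS_tot stable). Computed on the fraction
  scale.
* **GC bias:** per 100-nt sliding window (step 50), mean depth divided by
  the genome-wide mean window depth, aggregated by integer GC percent; a
  linear regression of normalized coverage on GC summarizes the trend.
* **Lorenz/Gini:** windows sorted ascending; Gini computed both as
  1 − 2·(trapezoidal Lorenz area) and by the pairwise mean-absolute-
  difference identity, required to agree to 10⁻⁹.
* **Error rates:** events per aligned base from CIGAR walks. Run masking
  excludes positions inside mononucleotide runs ≥ 4 plus one flanking base
  each side (indel placement at run boundaries is alignment-ambiguous).
  The per-run-length indel profile divides events attributed to runs of
  length L (anchor within or adjacent to the run) by aligned traversals of
  such runs.
* **Template reuse:** observed fragments vs a null of length-matched
  fragments placed uniformly (subject to the same end-bias acceptance
  rule) with UMIs permuted. The one-way chi-square uses two categories at
  the coordinate-position level — positions carrying ≥ 2 distinct UMIs vs
  the rest. Position-level counting is what keeps the statistic
  calibrated: fragment-level counting increments by two per collision,
  inflating the variance ~2× over the Poisson reference and collapsing
  null p-values toward zero. Expected counts below 5 trigger an exact
  binomial fallback.

## UMI error correction

Extraction takes the first 13 bases of read 1 as the UMI, requiring mean
UMI Phred strictly above 20 and, when a fixed spacer follows the UMI, at
most 2 spacer mismatches. Families require exact fragment-coordinate
identity and UMI Hamming distance ≤ 1 to a representative; clustering is
greedy by descending UMI frequency (ties lexicographic), which is
deterministic and near-optimal at 13-base UMIs where 1-mismatch collisions
are rare. All families are retained regardless of size.

Consensus: uniform prior; member base b with Phred-derived ε contributes
likelihood 1−ε to b and ε/3 to each alternative; the call is the posterior
argmax with ties broken by summed supporting quality then lexicographically;
the output quality is the Phred of 1 − max posterior, capped at 60.
Members are harmonized to the modal family length by clipping — there is
no in-family indel realignment, so a slippage indel inside a family shifts
the clipped tail rather than being re-anchored.

## Methylation deconvolution

Region densities pool retained CpG calls (depth within [2, 2000], SNP
positions masked) as Σ methylated / Σ total; regions with no surviving CpG
are missing and are dropped pairwise from the sample vector and reference
matrix (no imputation). Regions enter the objective with equal weight
regardless of CpG count.

The mixture solves min ‖Mp − x‖² subject to p ≥ 0, Σp = 1 with a primal
active-set method: the equality-constrained subproblem on the free
coordinates is solved via the bordered KKT system; bound-blocking steps
add constraints, and negative multipliers release them. The returned
solution is certified against the KKT conditions (reported as
`kkt_violation`, required < 10⁻⁶ in tests) and cross-checked in the test
suite against an exhaustive simplex-grid search on 2–3-tissue problems.
Rank deficiency after row dropping yields a valid minimizer flagged as
possibly non-unique.

## FFT spacing and tissue ranking

Per gene, the scaled long-class WPS over the 10 kb downstream of the TSS
(strand-aware, ≥ 80% covered) is mean-subtracted and Fourier-transformed;
the band intensity is the mean squared magnitude over the discrete
frequency bins whose periods fall in 190–199 bp (bins selected by period,
not interpolated — reproducible without resampling). Expression is
log2(x+1)-transformed (variance stabilization; switchable) and each
tissue's Pearson ρ against the per-gene intensities is computed over
shared genes (≥ 100 required); tissues rank ascending in ρ, most negative
first, since nucleosome-spacing periodicity is depressed downstream of
genes active in the contributing tissue. Rankings are compared by Spearman
rank correlation.

## Problem sizes and determinism

Every generator draws from `numpy.random.default_rng` seeded from the
configuration, so cohorts and pipeline bundles are byte-reproducible from
their emitted config. The validation suite exercises the pipeline at the
scales the estimators need: 10⁵ fragments for fragment-length and
nucleosome-recovery statistics, ~10⁶ aligned bases for error-rate
recovery, 200 replicate tests for chi-square calibration, and 100 trials
for noisy deconvolution recovery; synthetic genomes are 10–100 kb, which
is ample for these per-position statistics while keeping the whole suite
fast on one core.

## Known limitations

* The alignment-record reader is a minimal tab-delimited seam (proper-pair
  flag subset only), not a SAM/BAM implementation; binary alignment
  formats are out of scope by design.
* Consensus calling assumes substitutions only within families; in-family
  indels are clipped, not realigned.
* Duplex (two-strand) consensus is not implemented.
* The chi-square template-reuse test's null captures fragmentation and
  ligation bias but not coverage heterogeneity along a real genome.
* Bisulfite analysis consumes per-CpG calls; bisulfite alignment and call
  extraction are upstream tools' responsibility.
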