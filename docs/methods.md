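# Methods

This note documents the models, estimators and numerical choices behind
`sbg`, the assumptions they make, and what the synthetic validation does
and does not demonstrate about real data.

## Data model

The in-memory currency is a sample × SNP matrix of B-allele dosage codes
{0, 1, 2} with a distinct missing code, a map of (chromosome, 1-based bp
position, A/B alleles) sorted by position within chromosome, and per-sample
metadata (sire, dam, sex, year of birth, region), any entry of which may be
absent. The B allele is the first-listed allele of an extended MAP line
when declared, otherwise the lexicographically later observed allele; a
SNP with a single observed allele is coded 0 (all-A). Orientation affects
labels only — every statistic downstream is orientation-symmetric or
defined per SNP. BED gene annotation is converted to 1-based inclusive
coordinates at the read boundary; GENEPOP output codes A/B as 01/02 with
`0000` for missing. `write_plink_text` emits a 6-column MAP by default so
a write/read cycle is exactly lossless; a strict 4-column dialect is
available by flag (orientation is then recoverable only when B is
lexicographically later).

## Quality control

* **Call rate** (default > 0.95, strict inequality): SNPs are filtered
  before samples, so a sample is judged on the reliable SNP set. The
  order matters for borderline samples and is fixed and documented.
* **MAF** (default > 0.05, strict): a SNP at exactly the threshold is
  removed.
* **VIF pruning** (window 50 SNPs, step 5, VIF = 1/(1−R²) ≤ 50): within
  each sliding window the highest-VIF SNP is removed repeatedly until all
  pass; removals are global. R² comes from regressing each SNP's
  mean-imputed dosage on the other window members via the pseudo-inverse,
  capped at 1 − 1e-12 so perfect collinearity yields a finite, huge VIF.
  Standard tools leave tie-breaking unspecified; here ties go to the
  lower-MAF SNP, then map order, making runs reproducible. SNP-level
  parity with other implementations is therefore not guaranteed — only
  the contract that every window of surviving SNPs has VIF ≤ the
  threshold.
* **Relatedness**: method-of-moments IBD from IBS sharing counts.
  Expected IBS-given-IBD probabilities use allele products estimated
  *without replacement* from the 2N sampled alleles (the small-sample
  correction), the IBD mixture is solved in cascade, clipped to the
  simplex and renormalised; pi-hat = P(IBD=2) + P(IBD=1)/2. Exclusion is
  greedy: repeatedly drop the sample in the most pairs above the
  threshold (ties: higher missingness, then sample order). With a
  duplicate pair exactly one member is dropped; a mutually related
  triangle loses two.

## Synthetic data

The generators produce every statistical structure the pipeline assumes,
with full ground truth. Shared machinery: chromosome lengths follow the
fixed declining profile w_i = n − i + 3 normalised to the configured total
(default 31 autosomes, 2,242,960 kb); SNP positions are uniform per
chromosome; recombination is uniform at 1 Morgan / 100 Mb through
Haldane's map function, chromosomes assorting independently; a single
integer-seeded PCG64 generator drives everything, so outputs are exactly
reproducible.

* **Two-population Wright–Fisher** (`simulate_wright_fisher`): an
  ancestral pool of `pop_size` diploids with founder frequencies uniform
  in [maf_floor, 1−maf_floor] is evolved `burn_in_generations`, thinned to
  SNPs with pool MAF ≥ maf_floor (evenly subsampled to `n_snps`), then
  copied into two populations evolved independently for `generations`.
  Selected loci carry genic selection (parent sampling weight (1+s) per
  copy) in the *selected* population only, with the favoured allele
  re-oriented to the pool-minor allele — a sweep from low frequency. A
  selected allele lost to drift triggers a bounded re-draw of the selected
  population. Output datasets are a random `sample_size` of diploids per
  population, so sampling noise and drift scale are controlled separately.
* **Half-sib families** (`simulate_half_sib_family`): each offspring draws
  one sire allele by a fair Mendelian coin and one dam allele
  Bernoulli(p) per SNP (dams random under HWE at the supplied population
  frequencies). Genotyping error is a symmetric code flip with the given
  rate — adequate for concordance testing, not an array intensity model —
  and missingness is applied last.
* **Temporal cohorts** (`simulate_temporal_cohorts`): each simulated year
  produces a cohort whose sires are sampled from the previous cohort's
  males; a fraction `skew(t)` of matings (linear from `skew_start` to
  `skew_end` across the recorded span) is routed to `top_sires` popular
  males (default 2). Dams come from the previous cohort with probability
  `dam_recruit` (default 0.75) and otherwise from an effectively unlimited
  outside base population at the founder frequencies — representing the
  broad mare population surrounding the genotyped elite slice. This
  constant gene inflow makes the zero-skew process stationary after the
  burn-in (default 8 years), so the null condition has no inbreeding
  trend by construction; with rising skew, paternal ancestry concentrates,
  matings between paternal relatives become common, and autozygous
  segments and a heterozygosity deficit accumulate — a genuine programmed
  trend rather than generic drift. Founder-segment ancestry is propagated
  through the same crossovers, so each individual's true autozygous genome
  fraction is part of the output (in validation it correlates ≈ 1.0 with
  detected F_ROH).
* **Implanted ROH** (`implant_roh`): forces one individual homozygous over
  an interval by resolving each het to a homozygote with a fair per-SNP
  coin (the phase being unobserved); missing calls stay missing. Used to
  verify boundary recovery of the detector (within one inter-SNP spacing
  on a 50 SNP/Mb map).

## Inbreeding

* **F_IS** follows the `--het`-style moments estimator: per SNP j with
  pooled sample frequency p_j over n_j non-missing calls, the expected
  homozygosity contribution is 1 − 2 p_j q_j · n_j/(n_j − 1); per
  individual F = (O_hom − E_hom)/(L − E_hom), clamped to [−1, 1]. SNPs
  with n_j < 2 are skipped with a warning; L = E_hom raises. Frequencies
  are those of the *whole loaded dataset* — in a temporal study that pools
  all cohorts, which is precisely what makes a diversity decline visible
  as a rising F_IS in later cohorts.
* **ROH** uses the sliding-window scan with the standard parameters
  (window 30 SNPs, ≤ 1 het, ≤ 2 missing per window; hit fraction 0.05;
  runs split at gaps > 1,000 kb; kept if length > 1,000 kb — 5,000 kb for
  the recent-inbreeding scan — with ≥ 30 SNPs and ≤ 1,000 kb/SNP).
  The window hit-fraction threshold is the one scan parameter the standard
  parameter set leaves implicit; the established default 0.05 is adopted
  and exposed. A chromosome shorter than the window is scanned as a single
  truncated window (behaviour standard tools leave undocumented; defined
  here). Segment ends are SNP positions, not inter-SNP midpoints —
  F_ROH depends on this convention, so it is fixed and stated. The
  detector is validated by exact equivalence with a brute-force
  enumeration of every window and run on fuzzed panels.
* **F_ROH** = Σ segment lengths / L_AUTO with L_AUTO = 2,242,960 kb for
  the horse autosomes; synthetic runs pass their own genome length.
  Individuals without segments report 0; totals exceeding L_AUTO raise
  (they imply overlapping segments upstream).
* **Trends and contrasts**: annual mean/SD/SE per year of birth with a
  normal 1.96·SE 95% CI (the CI construction is a choice, stated here);
  unweighted OLS of annual means on year, slope P two-sided from t with
  n_years − 2 df; a zero-variance response short-circuits to slope 0,
  R² = 0, P = 1. Regional contrasts are pairwise pooled-variance t-tests
  on individual values (Welch by flag; individual-level vs annual-mean
  input is a flag because the choice is not dictated by the analysis).
  The year window is exposed (`min_year`/`max_year`) rather than baked in.
  Performance correlation is plain Pearson with the t-transform P,
  dropping (and counting) incomplete pairs.

## Sire genotype reconstruction

At each locus with ≥ `min_offspring` (default 20) non-missing offspring:
offspring of sire genotype G are multinomial over (AA, AB, BB) with
probabilities (p, q, 0), (p/2, 1/2, q/2), (0, p, q) for G = AA, AB, BB,
where p is the population frequency of A and the dam is a random HWE
draw. Mendelian logic is applied as hard rules: both homozygote classes
observed ⇒ only AB remains; any candidate expecting probability zero for
an observed class is excluded. The remaining candidates get a Pearson X²
over positive-expectation classes, converted to likelihoods by evaluating
the chi-square *density* at X² and normalising. df = 2 for the density:
the paper-style density conversion needs a df, df = 1 diverges at a
perfect fit (X² = 0) which breaks normalisation, and any df ≤ 2 gives a
monotone density so assignment reduces to argmin X²; df is exposed.
Exact ties break toward the candidate with the higher HWE population
genotype frequency, then toward the heterozygote. A locus whose
candidates are all excluded (a fixed allele contradicted by offspring) is
flagged inconsistent and left uncalled. `confidence_min` (default 0 —
always assign) withholds low-confidence calls for cautious use.

Validation: obligate-heterozygote rule holds on 100% of fuzzed loci;
concordance with the simulated truth is non-decreasing in offspring count
and reaches exact recovery at n = 500 for MAF in [0.1, 0.9]. At the
design point n = 20 (error-free, MAF > 0.05, 5,000 SNPs) the measured
median concordance is 98.8%: the residual errors are the intrinsic
ambiguity of the density-based score between a homozygous sire at skewed
frequency and a heterozygous sire — configurations where even the exact
multinomial likelihoods nearly tie. This operating level is a property of
the published scoring rule, not of the implementation (which matches the
rule's hand-worked examples exactly).

## Composite selection signals

Constituents between a selected and a reference population:

* **F_ST**: Wright's two-group variance ratio, Var(p; divisor 2)/(p̄ q̄)
  with p̄ the unweighted mean of the two sample frequencies — chosen for
  exactness of the limiting cases (0 at equal frequencies, 1 at fixed
  differences). Sample-size-corrected estimators are deliberately out of
  contract.
* **ΔSAF**: the tracked allele is the one at higher frequency in the
  selected population; ΔSAF = p_sel − p_ref of that allele (≥ 0, ties 0).
  The orientation rule is this package's resolution of an underspecified
  sign convention.
* **XP-EHH**: per core SNP, EHH(x) is the probability two random distinct
  haplotypes are identical over [core, x]; each population's EHH is
  integrated trapezoidally over bp outward in both directions until
  EHH < 0.05 (exposed) or the chromosome end; raw = ln(I_sel/I_ref),
  standardised genome-wide. Phased input is required; the synthetic
  generators are haplotype-based so phasing is free, and real-data use
  expects pre-phased haplotypes. The production scan computes all cores
  of a chromosome with one incrementally updated histogram of pairwise
  mismatch reaches; it is tested for exact equality against a literal
  pair-enumeration oracle.

Composite: per test, genome-wide ascending average ranks over SNPs where
every constituent is finite; r′ = rank/(n+1) ∈ (0,1); z = Φ⁻¹(r′);
z̄ = mean over the m tests; one-sided upper-tail P from N(0, 1/m);
CSS = −log₁₀ P. The composite (not the constituents) is smoothed by an
unweighted mean over ±500 kb on the same chromosome — the results of the
approach are phrased in terms of the smoothed composite, and constituent
smoothing is available behind a flag. Regions: the top ⌈1%·n⌉ smoothed
values (ties at the cutoff included — region counts depend on this, hence
the explicit rule), chained on a chromosome with gaps ≤ 1 Mb; chains with
≥ 5 members are reported with member min/max positions and the top raw
CSS; genes overlap the region ± 500 kb as closed intervals. Significance
tiers quoted as "top x%" use ⌊x%·n⌋ members (a 48,896-SNP panel has a
48-SNP 0.1% tier).

**Known limitation — null calibration.** The N(0, 1/m) reference assumes
the m rank vectors are independent. Under pure drift, F_ST ≈
(p₁−p₂)²/(4 p̄ q̄) and ΔSAF = |p₁−p₂| are monotone functions of the same
deviate, and their genome-wide ranks correlate at ≈ 0.96 in validation
runs; Var(z̄) therefore exceeds 1/m and the composite P is mildly
anti-conservative in the tails (Kolmogorov–Smirnov distance ≈ 0.06 from
uniform on a 5,000-SNP drift-only panel). CSS values should be read as a
ranking statistic, as the approach's own literature uses them; the
validation suite keeps a strict uniformity check in place to make the
miscalibration visible rather than hiding it. Empirical region-level
error control, if needed, should come from drift simulations like the
ones shipped here.

## Population structure and Ne

* **GRM**: dosages centred by 2p and scaled by √(2p(1−p)) (missing → 0
  after centring; fixed SNPs excluded with a count), cross-products
  divided by the pairwise non-missing SNP count.
* **PCA with outlier iteration**: eigendecomposition of the GRM;
  coordinates are eigenvectors scaled by √eigenvalue; any sample whose
  coordinate on one of the top 10 components lies more than `sigma`
  (default 10, the permissive setting appropriate when genuinely diverged
  reference populations must not be discarded; 6 is the aggressive
  default of the reference workflow) standard deviations from the
  component mean is removed, and the decomposition repeats on the
  submatrix up to 5 sweeps. σ = ∞ is a no-op; removing every sample
  raises.
* **LD-based Ne**: Burrows composite disequilibrium Δ̂ (with the n/(n−1)
  factor) from unphased dosages over pairwise-complete samples,
  normalised by Weir's √[(p_A q_A + D_A)(p_B q_B + D_B)] with D the
  within-locus HWE departure — the convention under which the published
  sampling expectation E[r²] = 1/S + 3.19/S² (S ≥ 30; small-sample
  constants 0.0018 + 0.907/S + 4.44/S² below 30) holds, as verified
  against iid simulations. Only interchromosomal pairs enter by default:
  physical linkage inflates r² and biases Ne downward (the
  same-chromosome option exists for tool comparison and is flagged as
  biased). Ne = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′) for S ≥ 30, the
  analogous small-sample form below; r²′ ≤ 0 flags an infinite estimate.
  The CI treats n_pairs · r²/χ² as the sampling interval of r² with the
  pair count as df; pairs sharing loci are not independent, so the CI is
  anti-conservative and labelled as this package's own construction, not
  a claim of equivalence to any reference tool. A year-of-birth filter
  restricts to a current breeding cohort rather than hard-coding one.

## Validation design and problem sizes

The validation suite (and `scripts/acceptance.py`) regenerates everything
from the synthetic generators at scaled problem sizes chosen to preserve
the statistical regime of the motivating study while running on one CPU
in minutes:

* Selection scans: 5 chromosomes / 250 Mb / 5,000 SNPs — the real panel's
  marker density (≈ 22 SNPs/Mb) on a smaller genome — with 500 diploids
  per population, 100 sampled (200 haplotypes), 40 post-split
  generations. The implanted sweep (s = 0.1) starts from rare standing
  variation (`sweep_maf_band` = (0.08, 0.25)); a sweep of an allele
  already near frequency 0.5 in both populations is a different, much
  weaker scenario and is not what the power check targets. Under these
  conditions the sweep locus falls inside a called region in roughly
  three-quarters of runs; the remaining misses are sweeps whose top-1%
  cluster falls just short of 5 members against the drift-plus-sampling
  background at S = 100 per population.
* Ne recovery: 20 chromosomes / 2 Gb / 2,000 effectively unlinked SNPs,
  15 generations of drift at the target Ne, 50 diploids sampled. Medians
  over 20 replicates recover Ne = 50/100/200 monotonically with the
  Ne = 100 median near 100.
* Inbreeding trends: 2 chromosomes / 80 Mb / 2,400 SNPs (30 SNPs/Mb so
  1-Mb ROH clear the 30-SNP floor), 12 yearly cohorts of 100, skew rising
  0 → 0.9 to two top sires versus a zero-skew control.

What passing these checks shows: the estimators implement their stated
formulas exactly (hand-worked examples, brute-force oracles, step-literal
references), recover known parameters from data generated under their own
assumptions, and respond directionally to programmed signals. What they
do not show: robustness to array-specific genotyping artefacts, phasing
error in real XP-EHH input, non-uniform recombination, overlapping
generations, or ascertainment-biased MAF spectra — none of which the
generators emulate.
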