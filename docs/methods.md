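# Methods

## Scope

`embex` implements the expression-analysis stages of a somatic-embryogenesis
(SE) induction study on spruce primordial-shoot explants: four explant
series — G6 (responsive), G6NR (its nonresponsive clone, same genotype), and
the nonresponsive genotypes G2 and G12 — followed over an induction time
course. Two measurement tracks are covered: absolute qPCR (molecules per
10 ng total RNA) with a normalization that preserves the absolute scale, and
a post-mapping RNA-seq differential-expression stage. Read mapping, de novo
assembly and functional annotation are upstream/downstream of this package
and out of scope.

## Sample-specific normalization (qPCR)

The model assumes observed absolute quantities factor as

    q_obs(sample, gene) = q_true(sample, gene) × t(sample) × e,

where `t` is a multiplicative technical scale introduced by sample
preparation (RNA extraction, quantification, reverse transcription) and `e`
is multiplicative measurement error. Reference genes are assumed to have
constant true expression within a series, so their departure from the series
average estimates `t`.

For each series, each reference gene's quantity is averaged over the series'
samples; within each sample the reference quantity is divided by that series
mean (a *fractional value*); the fractions are averaged across reference
genes (arithmetic mean by default, matching the procedure's description of
"averaging the two reference gene values"; a geometric-mean option exists
for users who prefer log-symmetric averaging). Dividing every quantity in a
sample by its factor removes `t` while keeping units of molecules/10 ng,
because the factor is dimensionless and averages to exactly 1 within each
series — an identity of the construction, asserted to 1e-9 relative
tolerance in the tests.

Consequences used as test oracles: with a single reference gene, normalized
reference quantities equal the series mean exactly; with zero measurement
error, factors equal the planted technical scales centered to their series
mean, exactly. A zero or missing reference measurement is an error (the
factor would be undefined), never imputed. Series membership comes from
explicit labels only.

The divergence summary reports `min(factor)×100`, `max(factor)×100` and the
half-range `(max−min)/2` — the "± x%" figure used when the factor spread is
quoted as a symmetric variance bound.

## Time-course profiles and association calls

Profiles are per-(gene, series) trajectories of normalized quantity over
induction day, with replicates averaged per (series, day). The distance
between two profiles on the same day grid is the mean absolute log2 ratio
with pseudocount ε (default 1 molecule/10 ng):

    d(a, b) = mean_d | log2((q_a(d)+ε) / (q_b(d)+ε)) |.

Fold change is the comparison scale used throughout the study, and the
pseudocount handles genes that are exactly zero at some days
(early-transient expression). The distance is a pseudometric; tests verify
symmetry and the triangle inequality on random triples.

A gene is called **responsiveness-associated** when d(G6, G6NR) — the clone
pair differing only in response — exceeds the threshold;
otherwise **genotype-associated** when the mean of d(G6, G2) and d(G6, G12)
exceeds it; otherwise **none**. The default threshold of 1.0 log2 unit
(2-fold) follows the study's convention that expression differences should
exceed that scale to be considered biologically meaningful; the visual
"nearly identical profiles" judgment it formalizes carries no published
number, so the threshold is configurable. The call is monotone in the
threshold: raising it never converts `none` into an associated call.

## Differential expression (RNA-seq)

Per collection day, responsive and nonresponsive libraries (≥2 replicates
each) are compared:

- **RPKM** = count / (gene length in kb × library size in millions); library
  size defaults to the column sum.
- **Library adjustment**: counts are scaled to the geometric-mean library
  size and rounded to integer pseudo-counts, since the conditional exact
  test assumes comparable libraries.
- **Tagwise dispersion**: per-gene negative-binomial (NB) dispersion by
  within-group method of moments, `max(0, (s² − m̄)/m̄²)` averaged over
  groups with ≥2 samples, then shrunk toward the all-gene median with weight
  0.3. The shrinkage stabilizes the very noisy 3-replicate moment estimates;
  the weight trades per-gene fidelity against stability and 0.3 keeps the
  gene-level signal dominant. This is this package's own documented
  estimator; equivalence with any particular toolchain's "default tagwise
  dispersion" is explicitly not claimed.
- **Exact test**: the within-group sum of n iid NB(μ, φ) counts is NB with
  mean nμ and size n/φ, and conditioning on the grand total makes the split
  between the groups parameter-free given the group sizes and φ (negative
  hypergeometric; binomial in the Poisson limit φ=0). The two-sided p-value
  enumerates all splits of the total and sums the probabilities of splits no
  more likely than the observed one, ties included (the standard exact-test
  convention); p ∈ (0, 1]. Dispersion 0 is handled as the Poisson limit.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels).
- **Filter**: keep genes with adjusted p < 0.05 (a flag switches to raw p)
  and fold ≥ 2 toward either phenotype; fold is the ratio of phenotype mean
  RPKM, reported as +∞ when only the denominator is zero and undefined (NaN,
  never passing) for 0/0. The FDR-adjusted value is used by default because
  the procedure states FDR correction was applied alongside the p < 0.05
  cut. The published per-day fold entries come from the original tool's
  internal effect estimate and match the plain RPKM-mean ratio only
  approximately at some days; this package reports the ratio.
- **Summary**: per (day, induced phenotype), the DEG count and the mean over
  retained genes of the induced phenotype's mean RPKM. Averaging the induced
  phenotype only (not both) is this package's documented choice.

## Synthetic data

The generators define the study conditions under which the pipeline is
verified by parameter recovery.

**qPCR**: four series × five induction days (0, 3, 7, 15, 21 — the design
names five time points without enumerating them; the grid is configurable),
one sample per series × day (20 samples), two reference genes at distinct
stable levels. Technical scale is log-normal with zero log-mean; the default
sigma 0.16 makes twenty sampled scale factors typically span roughly
0.67–1.35, the divergence range the factors are meant to emulate.
Measurement error is mean-one log-normal at CV 0.25, the quantification
accuracy reported for the underlying qPCR methodology. Because estimated
factors absorb measurement noise on top of the planted scales, the observed
factor spread somewhat overestimates the technical variance — the same
overestimation the study notes for its own divergence figures. Target
shapes: `flat`; `late_induced` (geometric ramp from baseline to
baseline × peak_fold at the final day — dehydrin-like); `early_transient`
(peak at day 3, half-peak at day 7, zero at day 0 and from day 15 — modeled
on a transcript detected at days 3 and 7 only, with roughly half the day-3
level at day 7). An `association` field plants series-level differences
(responsiveness: G6 elevated; genotype: G6 and G6NR elevated) at a known
fold, giving ground truth for the classifier.

**RNA-seq**: two phenotypes × four days (3, 7, 15, 21) × three replicates
(24 libraries). Gene propensities are heavy-tailed log-normal weighted by
length; counts are NB at the configured dispersion (default 0.1, a typical
bulk biological-replicate value) with per-sample library sizes uniform in
the configured range; a requested dispersion of 0 substitutes Poisson
sampling and flags it in the truth metadata. A `de_fraction` of genes gets a
true fold (uniform in `fold_range`, default 2–8) in a randomly chosen
induced phenotype, applied at all days; weights are renormalized per sample
so library sizes stay fixed (a second-order perturbation of non-DE genes at
small DE fractions). Replicates are independent NB draws — biological
replicate correlation beyond NB overdispersion is deliberately not modeled,
so passing recovery tests demonstrate correctness of the estimators under
the stated model, not robustness to correlated replicates, batch effects or
misassigned reads.

**Reads**: uniform-random bases, uniform Q40 qualities, lengths uniform in
the given bounds — sufficient for exercising the positional trimming rules,
not for mapping.

## Read trimming and QC rules

The trimmer applies, in fixed order: remove the first `head_trim` bases
(default 15), cap at `max_length` (batch-dependent: 205 or 170), drop reads
shorter than `min_length` (default 20). The source protocol lists the
operations without an explicit order; head-trim → cap → drop matches common
read-cleaning practice and makes the rules composable. Adapter removal
precedes these rules and is assumed done. Qualities (Phred+33) are sliced
with the sequence. The gDNA check passes strictly below 5 genome copies per
10 ng RNA. The contig filter keeps length ≥ 500 inclusive ("minimum contig
size 500" read as ≥; configurable).

## Numerical choices and problem sizes

Exact-test enumeration is vectorized over all splits of the total in log
space with log-sum-exp normalization; tie detection uses a 1e-10 log
tolerance. Pseudo-count rounding is to nearest integer. Degenerate inputs:
all-zero genes get dispersion 0 and p = 1; empty factor sets, zero series
means, missing samples and malformed records raise errors naming the
offender. Simulation-based tests use 100–2000 genes and 100 qPCR replicate
datasets — sizes at which the binomial calibration bands and recovery
assertions are tight while the whole suite runs in seconds. The DEG
sensitivity floor (0.8 at planted fold 4, 3 replicates per group, dispersion
0.1) was recorded at first implementation as a regression guard, not a power
claim.

## Known limitations

- Reference-gene *selection* (stability ranking) is upstream; the
  normalization assumes references were already validated.
- The exact test conditions on totals of rounded pseudo-counts; for very
  small totals the test is discrete and conservative.
- RPKM is used because it is the unit of the downstream tables; no TMM/TPM
  alternatives are offered.
- The association classifier encodes one specific design (responsive clone,
  nonresponsive clone, two nonresponsive genotypes); other designs need
  explicit series-role arguments.
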