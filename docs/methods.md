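# Methods

## The model

A sample's transcriptome is treated as carrying an *effective age*: a
latent time coordinate that advances at 1 day/day in controls and at
a constant factor *a* in mutants with altered intrinsic aging.
Aging-related genes are those whose log2 expression tracks this
coordinate monotonically; the clock inverts the relationship, mapping
a profile back to an age in days.

## Preprocessing

**Batch baseline subtraction.** Two hybridization batches sharing one
technical replicate: the per-probe difference between the replicate's
batch-B and reference-batch copies estimates the batch-B offset and
is subtracted from every batch-B column; the redundant replicate
column is then dropped. The estimate carries the replicate's own
hybridization noise (SD ≈ noise_sd per probe), which therefore
remains in the corrected batch — the correction removes the
systematic offset, not noise.

**Quantile normalization** equalizes per-sample distributions by
replacing each column's sorted values with the row-wise mean of all
sorted columns. Ties receive the mean of the reference values at
their rank positions (via average ranks and linear interpolation),
which is deterministic and order-independent. The operation is
idempotent. It is applied jointly across all samples after baseline
subtraction; within-batch normalization is not implemented.

**Noise floor.** Per-probe CV (SD/mean of log2 values) is smoothed
against per-probe mean expression by lowess (default span 0.3). A
straight line is fitted to the smoothed curve over the upper half of
the mean range; the floor is the largest mean, within the lower half,
at which the curve departs *upward* from that line by more than
2× the high-end residual SD and the departure is sustained at all
smaller means. The one-sided, lower-half, sustained formulation is
deliberate: with a flat CV–mean relationship, smoother wiggle at the
top of the range would otherwise trigger spuriously. Note the default
span smooths across ~30% of probes, so a sharp changepoint is
detected somewhat above its true location; reduce `span` when the
transition is expected to be abrupt. Values below the floor are set
to the floor and probes never exceeding it are discarded. A fixed
floor (e.g. the conventional 7.5 on RMA-scale data) can be supplied
instead.

Cohort-level outlier samples are removed via an explicit exclusion
list; no automatic detector is provided, because the usual criterion
(inspection of box plots and PCA) is not algorithmic.

## Aging-gene selection

The polyserial correlation assumes the ordinal age class discretizes
a latent standard normal at thresholds τₖ = Φ⁻¹(cumulative class
proportions). The default estimator is the two-step form
ρ̂ = r·s_y / Σₖ φ(τₖ), where r is the Pearson correlation of
expression with rank-coded classes (1..K) and s_y their sample SD;
estimates are clipped to [−1, 1]. A maximum-likelihood variant
(`polyserial_rho_ml`), maximizing the exact latent bivariate-normal
likelihood with empirical thresholds, serves as an independent
cross-check; the two agree to <0.03 across random configurations at
n = 800.

Significance comes from a permutation null: B rounds (default 20) of
age-label randomization, each shared across probes to preserve the
inter-gene correlation structure, pooling all B·p estimates. A probe
is aging-related when its true-label ρ̂ falls outside mean ± 2 SD of
the pool (two-sided, nominally P < 0.05; ≈4.6% of probes flag under
a global null). Age classes are rank-coded by default; raw-day coding
is available but makes no difference to a polyserial fit beyond the
threshold positions.

## Differential expression

Sample class (genotype × age within a tissue) is the single ANOVA
factor. Gates, in order: BH-corrected ANOVA q < 0.05 across probes;
Tukey-HSD p < 0.05 for the specific pair (Tukey–Kramer studentized
range statistic; probes failing the ANOVA gate are not tested); and
|Δ mean log2| ≥ log2 1.5 ≈ 0.585. Fold change is the difference of
log2 class means, mutant − control.

The studentized-range survival function is evaluated by monotone
cubic interpolation of `scipy.stats.studentized_range.sf` on a fixed
151-point grid cached per (k, df) — the scipy routine integrates
numerically per scalar (~10 ms) and would dominate runtime across
probes × contrasts × LOO rounds. Interpolation error is ~1e-4 in p.

Overlaps between probe sets use the Yates-corrected χ² (1 df,
two-sided) on the 2×2 membership table over the stated probe
universe. Concordance of shared effects reports the squared Pearson
correlation of log2 fold changes and the percentage of sign-matched
probes. Rescue classification, over null-affected probes: *full* if
no longer affected in rescue-vs-control; *partial* if still affected
but with strictly smaller |fold change| (movement toward control —
sign loss with smaller magnitude counts, overshoot past control does
not); otherwise *none*.

## The clock

**Classifier discovery.** One leave-one-out round per control sample:
the affected-probe procedure runs on the remaining samples with age
class as the factor, and a probe qualifies if affected in at least
one pairwise class comparison. Those probes are the round's k-NN
features (Euclidean distance on log2 values, default k = 3, majority
vote with a summed-distance tie break); the held-out sample's class
prediction scores the round. Selection frequencies are exact
multiples of 1/n_rounds; probes at frequency 1.0 are the aging
classifiers. A round with zero features is recorded as failed with a
warning and contributes no selections. k = 3 is the smallest odd
neighborhood robust at 4–5 replicates per class; class imbalance
(the 4-replicate day-3 cell) is not reweighted.

**Model fit.** The samples × classifiers matrix is centered by
per-probe training means (no scaling — classifier expression shares
the log2 scale) and decomposed by SVD. Candidate components are the
smallest set reaching 95% cumulative variance, capped at
n_samples − 2. Forward stepwise selection regresses numeric age
(days) on components, at each step adding the one that most
decreases AIC, stopping when no addition decreases it; the AIC trace
is therefore strictly decreasing along accepted steps. Forward-only
search keeps the fit deterministic. Numeric days (not class rank) is
the response because predictions are reported in days.

**Prediction.** A profile is centered with the *training* means,
projected onto the training loadings, and pushed through the linear
coefficients. Predictions are not clipped to the training range —
a strongly accelerated mutant may legitimately land beyond day 45.
Acceleration is 100·(physiological − chronological)/chronological,
defined for positive chronological age. Group summaries report
mean ± SEM with one-way ANOVA and Tukey post hoc computed on the
predictions themselves.

## Profile similarity

Over the intersection of aging-related and mutant-affected probes,
every mutant sample is Pearson-correlated with every control sample
(5 mutants × 19 controls = 95 pairs in the reference head design);
correlations are grouped by control age and compared by ANOVA +
Tukey. By default each mutant replicate is correlated individually;
`on_means=True` instead correlates the mutant group's mean profile,
an alternative reading of how such comparisons are sometimes
summarized.

## The simulator

The generator states the study world explicitly: 2,000 probes,
ages {3, 10, 30, 45} days, 5 replicates per cell (optionally 4 at
day 3, mirroring a removed outlier), baselines uniform on
[8.5, 13] log2 units, homoscedastic Gaussian noise (SD 0.25),
20% aging probes with linear log2 trends — slope magnitudes
|N(0.03, 0.01)| log2/day, signs balanced half up, half down — a
second batch with per-probe offsets N(0, 0.3) anchored by a
technical replicate, and mutants whose aging probes are evaluated at
effective age a × chronological (default a = 1.3, ≈30% acceleration).
Mutant-specific (non-aging) probes are shifted by at least
log2 1.5 + 0.65 ≈ 1.24 log2 units — a margin of ≈4 standard errors
above the fold-change gate at the stated noise and replication, so
that "discoverably affected" holds with probability ≈1 rather than
≈0.5 at the bare threshold.

What the simulator does *not* emulate: probe-level microarray
artifacts (GC bias, cross-hybridization, saturation), count-based
noise, mean–variance coupling, nonlinear or non-monotone age
trajectories, and correlated gene modules. A green recovery test
therefore establishes that the pipeline inverts its own stated
generative model — not that the model captures every property of
real microarray data.

## Numerical choices and degenerate inputs

- All randomness derives from `numpy.random.default_rng` seeded from
  a single integer; the pipeline fans out per-stage child seeds as
  `crc32(stage) XOR seed (mod 2³¹)`.
- Polyserial estimation errors on constant expression or a single
  age class; quantile normalization requires ≥2 samples; the noise
  floor requires ≥10 probes and a non-degenerate matrix; clock
  fitting requires ≥2 classifiers, ≥4 samples and ≥3 distinct ages.
- Fold-change ties at exactly log2 1.5 count as affected (≥).
- ANOVA on a zero-variance probe yields p = 1 (flagged nothing)
  rather than NaN propagation.

## Known limitations

- The permutation count B = 20 relies on pooling across probes for a
  stable null SD; with few probes (<200) the 2-SD band is noisy and
  B should be raised.
- The LOO feature step reuses the full affected-probe thresholds;
  with very small designs (2 replicates per class after holdout) the
  Tukey gate is underpowered and rounds may fail.
- The clock is tissue-specific by construction; transferring a
  fitted clock across tissues is unsupported.
- Classifier counts and physiological ages depend on the planted
  simulation world; they are not comparable to values from any real
  microarray study.
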