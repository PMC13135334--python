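# Methods

This note records the statistical conventions, numerical choices, and
simulator design behind `aacsia`, at the level of detail a user needs
to judge what a result does and does not mean.

## Data model

The canonical unit is one sample's per-amino-acid isotope measurement:
the mean of triplicate injections (‰), its replicate standard
deviation, and the replicate count. Missing measurements are absent
keys, never sentinel values, because historical datasets have
heterogeneous amino-acid coverage (e.g. carbon data present in some
years only); every batch operation is therefore complete-case per
analysis, skipping and reporting samples that lack a required value.

Habitat assignment from metadata uses fixed thresholds: distance from
shore < 1 km → reef (depth is ignored, since reef tows are surface
tows over reefs); ≥ 1 km with tow depth ≤ 200 m → offshore surface;
≥ 1 km with depth > 200 m → offshore deep. Exactly 1 km is treated as
offshore and exactly 200 m as surface, matching the strict inequality
in the deep definition.

## Mean-centering

Centering subtracts the within-sample mean over the chosen EAA set
from each EAA's δ¹³C. It operates on the triplicate means; replicate
SDs are carried through unchanged rather than re-centered (centering
is a translation, which leaves the dispersion of a mean estimate
untouched). The default set is the six fingerprinting EAAs (Ile, Leu,
Lys, Phe, Thr, Val); a five-EAA set omitting Ile supports comparison
with literature data that did not report it. Profiles centered over
different subsets differ by a per-sample constant on the shared amino
acids, so subsets must never be mixed in one feature matrix.

## Trophic position

TP = ((δ¹⁵N_T − δ¹⁵N_S) − β)/TDF + 1 with β and TDF treated as
error-free constants; parameterizations are data, not code — the
presets GlxPhe (3.4‰, 7.6‰) and AlaPhe (3.2‰, 4.5‰) ship, and any
quadruple can be supplied because discrimination factors are
system-dependent and contested. First-order uncertainty from replicate
noise is √(sd_T² + sd_S²)/TDF; at the typical 0.42‰ triplicate SD this
is ≈ 0.08 TP units for Glx–Phe and ≈ 0.13 for Ala–Phe, which bounds
how precisely any single-sample TP can be read. TP is computed from
per-sample means, not injection-level replicates.

## Univariate statistics

* Regressions are OLS on ln(distance/km), slope significance by
  two-tailed t-test, fit by adjusted R². A constant response returns
  slope 0 with p = 1 (a flat gradient is a result, not an error).
* BH correction is applied once per analysis family (the six EAA
  regressions are one family, the two source-AA regressions another,
  the TP regressions a third; per-amino-acid two-group comparisons
  form one family).
* The parametric/nonparametric gate: Shapiro–Wilk per group (a
  constant group counts as failing) and Levene's test with group-median
  centering, all at α = 0.05. Per-group Shapiro rather than pooled
  residuals is the conservative reading when the routing rule is
  otherwise unspecified. The gate is deterministic.
* Post hoc tests run only when the omnibus p < 0.05, strictly; Dunn's
  pairwise z-tests use joint mid-ranks with the standard tie
  correction and BH adjustment.
* Mann–Whitney uses exact enumeration when the pooled sample is ≤ 12
  and tie-free (reproducible at toy scale), otherwise the normal
  approximation with tie and continuity corrections.
* δ¹⁵N source-AA regressions exclude offshore-deep samples by default
  (their baseline resembles the reef's, so pooling them bends the
  nearshore–offshore trend); the exclusion is switchable.

## PERMANOVA and dispersion

The pseudo-F is computed from squared Euclidean inter-point distances:
SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_groups Σ_{i<j∈g} d²/n_g,
F = (SS_among/(k−1)) / (SS_within/(n−k)). On univariate data this
equals the classical one-way ANOVA F exactly, which the tests exploit
as an oracle. Permutations preserve group sizes. When the number of
distinct group-size-preserving assignments is ≤ 10,000 the null is
enumerated exhaustively and p is the tail fraction including the
observed assignment (no +1); otherwise seeded Monte-Carlo sampling
uses the (count + 1)/(n_perm + 1) convention with default
n_perm = 9,999. F comparisons in the tail count use a 1e-12 relative
tolerance so exactly tied permutations (mirror assignments) are
counted.

Dispersion homogeneity is tested betadisper-style: per-sample
Euclidean distances to the own-group centroid are computed once under
the observed grouping, and the one-way F on those distances is
compared against label permutations of the fixed distances. It is
reported alongside every omnibus PERMANOVA; pairwise contrasts are BH
corrected and reported with both raw and adjusted p-values.

## Linear discriminant analysis

Axes are generalized eigenvectors of the between-class scatter against
the pooled within-class covariance (denominator n − k), normalized to
unit within-class variance (aᵀWa = 1) and oriented so each axis's
largest-magnitude loading is positive, making loadings and score plots
reproducible across runs. Variance proportions are eigenvalue shares.
Priors default to training-class frequencies and can be set uniform or
arbitrary. Posteriors use the shared-covariance Gaussian model.

A fully mean-centered EAA block is rank-deficient by construction (the
features sum to zero), so the within-class covariance is singular. On
singularity a ridge λ·trace(W)/p with λ = 1e-8 is added (logged once
per feature space), and classification uses the symmetric
pseudo-inverse with a 1e-7 relative eigenvalue cutoff — equivalently,
the Gaussian model is restricted to the effective-rank subspace, where
the centered data actually live. Leave-one-out cross-validation refits
means, covariance, and frequency priors on every fold, so the held-out
sample cannot leak into its own classification.

## The forward simulator

The generator emulates the structure the analysis assumes, not any
measured dataset:

* distances are drawn uniformly on the log scale within each habitat's
  range, depths uniformly; the assigned habitat is asserted against
  the scenario label;
* the Phe δ¹⁵N baseline is linear in ln(distance) per habitat; Lys
  tracks Phe with a constant offset;
* each sample draws a true TP from a normal distribution truncated at
  1 (a consumer cannot sit below the producer baseline), and trophic
  AA values are generated by inverting the TP equation under each
  parameterization, so zero-noise estimation recovers TP exactly;
* the consumer δ¹³C EAA vector is a producer-weight mixture of
  endmember fingerprints plus small trophic-transfer noise
  (default 0.2‰) plus an arbitrary per-sample baseline constant that
  centering removes;
* every stored value receives Gaussian measurement noise with the
  replicate SD (default 0.42‰, a typical contemporary triplicate
  precision for both isotope systems) and carries n_reps = 3. The
  noise on the stored mean is taken at the full replicate SD rather
  than SD/√3, a deliberately conservative choice.

The shipped default scenario uses three habitats (reef n = 16 at
0.2–0.95 km, offshore surface n = 24 at 2–100 km, offshore deep
n = 16 at 250–1000 m depth) and four producer endmembers with
within-group SD 0.5‰ and 12 training cultures each. Reef consumers
eat diatoms and sit at TP 2.0 with an elevated baseline (7.5‰
intercept); offshore surface consumers eat prasinophytes at TP 2.4
with a lower, declining baseline; deep consumers have a mixed diet,
an elevated baseline (microbially reworked organic matter), and the
longest food chain (TP 2.9). Sample sizes are a desk-scale compromise
between typical carbon and nitrogen coverage in multi-year field
datasets. **All of these numbers are synthetic calibrations** chosen
once to reproduce the qualitative orderings a near-island system
shows (baseline declining offshore, reef < surface < deep TP,
diet shifting from large eukaryotic producers nearshore to
picoplankton offshore); none is a measured value.

What passing tests on this generator show: the estimators and tests
recover parameters under the model's own assumptions at realistic
noise. What they do not show: robustness to feature covariance within
habitats (the generator draws features independently given habitat),
non-Gaussian measurement error, producer libraries missing relevant
taxa (cyanobacteria in particular are absent from the default
endmember set, as they are from most published culture libraries),
selective feeding, or oceanographic transients (eddies) that shift
baselines within a season.

## Pipeline and reproducibility

One master seed derives per-stage seeds by hashing the stage name, so
toggling stages does not perturb the others. Report tables are TSVs
with a header line recording the package version, seed, and a SHA-256
configuration hash; floats are written at 10 significant digits, and
identical configuration + seed reproduces every table byte for byte.
Non-significant omnibus tests suppress post hoc output but are noted
in the run log. Statistical non-significance never sets a non-zero
exit status; only data-contract violations abort, naming the stage and
samples.

## Known limitations

* No Bayesian multi-TDF TP models and no compound-specific β
  estimation from producers; β/TDF uncertainty is not propagated.
* Euclidean distances only (appropriate for δ-scale features); no
  Bray–Curtis or other dissimilarities.
* No effect sizes, mixed models, or spatial autocorrelation handling
  in the gradient statistics.
* The producer training library is simulated; substantive source
  attribution requires a real culture library with regionally relevant
  taxa.
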