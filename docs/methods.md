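# Methods

This note documents the statistical procedures `mfstudy` implements, the
modeling choices that were genuinely open, the synthetic-data model and
its defaults, and the limits of what the test suite demonstrates.

## Study data model

A study is five-way: readers × modalities × slides × ROIs × marks. All
coordinates are micrometers in a per-slide frame. ROI rectangles are
half-open, `[x0, x0+w) × [y0, y0+h)` (default 200 × 200 µm), so a mark on
a shared edge belongs to exactly one ROI and containment is
deterministic. Identifiers are opaque strings; reader, modality and
candidate orderings are fixed at first appearance (or by the study-design
file) so matrix indices are reproducible. CSV files are UTF-8, comma
separated, "." decimal, headers mandatory; floats are written at repr
precision so `read(write(x)) == x` exactly, with display columns rounded
to the printed-table conventions (three decimals for κ and accuracy,
half-up integer percents for pool shares).

## Pooling

Marks are clustered per ROI by single linkage: two marks are the same
candidate iff a chain of pairwise distances ≤ `match_radius_um` connects
them. Single linkage (rather than centroid linkage) makes the result
independent of mark order; it equals connected components of the
≤-radius graph, which is the oracle the tests compare against. The
default radius, 10 µm, is twice the stated registration accuracy of the
stage/WSI co-registration platform that presents the ROIs; it is a
config parameter. Candidates never span ROIs because ROIs are disjoint
presentation units. Two marks from the same (reader, modality) landing in
one cluster cannot be a single cell marked twice, so pooling raises an
ambiguity error rather than guessing.

Candidates are sorted by (slide, ROI, centroid y, centroid x) and given
sequential IDs, so pooling is permutation-invariant up to canonical
relabeling.

## Ground truth

The reference-modality (microscope) detection multiplicity k of each
candidate drives the automatic consensus rule: multiplicity ≥ threshold
(default 4 of 5 readers) auto-accepts the candidate as a true MF with
provenance `auto_consensus`. The threshold is inclusive: in the modeled
study the 29 candidates seen by all five readers plus the 8 seen by four
make exactly the 37 auto-accepted candidates, which fixes the inclusive
reading. Every remaining candidate must appear in the panel adjudication
table (provenance `panel`); a missing candidate is an error, and a panel
label contradicting an auto-accepted candidate is a conflict error unless
`auto_wins` is set. Truth is an input or a rule over inputs — the package
never classifies images.

## Agreement

Cohen's κ is computed from 2×2 tables over the **full pooled candidate
set**: a candidate a rater never marked counts as that rater's negative.
Without this finite universe p_e is undefined; using the pool for every
pair also makes inter- and intra-observer tables directly comparable.
When both raters are unanimous with the same label, p_e = 1 and κ is
defined as 1 with a warning (the observed agreement is perfect), which
keeps tiny fixtures testable instead of propagating NaN. Kappa bins:
poor < 0, slight [0, 0.2), fair [0.2, 0.4), moderate [0.4, 0.6),
substantial [0.6, 0.8), almost perfect ≥ 0.8.

## Bland–Altman on log counts

Counts are per (reader, modality, slide); the log₁₀ transform stabilizes
the variance of count differences and turns differences into count
ratios (10^b). Zero counts are replaced by 0.5 — the standard continuity
correction — with a warning listing the affected cells; the comparison
stays total instead of dropping pairs.

The SD of an individual difference and the CI of the mean difference
come from a two-way crossed random-effects moment (ANOVA) decomposition
of the reader × slide difference matrix:
σ²_res = MSE, σ²_reader = (MSR − MSE)/S, σ²_slide = (MSC − MSE)/R,
negative moment estimates truncated at zero. Then
SD(d) = √(σ²_reader + σ²_slide + σ²_res) and
Var(b) = σ²_reader/R + σ²_slide/S + σ²_res/(RS). This is the simplest
estimator that carries both reader-to-reader variation and the
correlation from all readers counting the same slides; component recovery
is validated by simulation. With a single reader (or slide) the estimate
degrades, with a warning, to the classical single-rater formulas, which
the implementation reproduces exactly. Limits of agreement use exactly
2·SD (not 1.96); the CI on b uses the normal 1.96.

## MRMC accuracy analysis

Accuracy = (Se + Sp)/2 per reader × modality cell, with Se = tp/n_true
and Sp = 1 − fp/n_false over the adjudicated pool. For binary marks this
is the trapezoidal area under the one-threshold ROC and proportional to
Youden's J.

The covariance of all R·M accuracy cells is a **delete-one-slide
jackknife**: recompute the full accuracy matrix leaving out each slide's
candidates in turn; with G slides,
Cov(i,j) = (G−1)/G · Σ_g (θ_i,(g) − θ̄_i)(θ_j,(g) − θ̄_j).
Slides are the exchangeable clusters, so within-slide correlation between
candidates propagates into every variance and covariance. The jackknife
was chosen over a U-statistic moment decomposition because it meets the
same requirement (clustered covariances for all 25 cells) with no
unstated constants, and it is verified against exact enumeration on
3-slide instances and against the closed form
[Se(1−Se)/n₊ + Sp(1−Sp)/n₋]/4 in the independent-candidate limit.

Reader-averaged modality accuracy is the plain mean over readers; its
variance is the mean of the corresponding (reader, reader) covariance
block. Scanner-vs-reference differences use
Var(Δ) = (1/R²)Σ_{r,r'}[Cov_m + Cov_ref − 2·Cov_cross], a two-sided
normal z-test, and Holm's step-down over the family of comparisons
(reject while p_(i) ≤ α/(m−i+1)). Normal quantiles are used throughout
rather than adjusted degrees of freedom; with few slides this makes the
intervals anti-conservative (see Limitations). A non-positive Var(Δ) —
possible after jackknife truncation when two modalities are nearly
identical — is floored at 10⁻¹² with a warning, which makes the
degenerate equal-modality case return Δ = 0, p = 1 instead of failing.

## Synthetic-study generator

The generator emulates the modeled study's structure: `n_slides` = 4
slides, 10 ROIs per slide (200 µm square, laid out on a grid with 3×
spacing so ROIs never touch), 5 readers, 5 modalities (4 scanners + the
reference microscope). Per ROI, true MFs and false (distractor)
candidates arrive as Poisson counts with means 1.85 and 2.0 — chosen so
a default study realizes ≈74 true and ≈80 false candidates, the modeled
study's pool composition. Candidates are placed uniformly with a minimum
spacing of `min_candidate_spacing_um` (default 25 µm; see below), by
bounded rejection sampling (a too-crowded ROI is a config error).

Detection is Bernoulli with probability
`logistic(μ + τ_m + ρ_r + η_s + δ_c)`, where μ is `mu_se` = 1.1 for true
and `mu_fp` = −1.7 for false candidates (baseline microscope operating
point Se ≈ 0.75, Sp ≈ 0.85, matching reader accuracies around 0.8);
τ_m is the per-modality detection shift (reference pinned at 0);
ρ_r ~ N(0, 0.3²), η_s ~ N(0, 0.2²), δ_c ~ N(0, 0.8²) are reader, slide
and candidate effects. The additive structure induces exactly the two
correlations the analysis claims to handle — same-reader correlation
across candidates and within-slide correlation across readers. The
candidate SD dominates because cell-to-cell ambiguity (an obvious
metaphase vs a pyknotic nucleus) is the main driver of disagreement in
MF counting.

Default scanner effects τ = (−0.53, −0.47, −1.12, −0.61) are calibrated
so the **expected whole-study mark count** of each scanner relative to
the microscope matches the count deficits the modeled study reported
(ratios ≈ 0.82, 0.84, 0.63, 0.79 — "16 to 36% fewer"). Realized marks
get isotropic Gaussian position jitter (`jitter_sd_um` = 2, within the
registration accuracy), clipped to the ROI.

Every random component draws from its own substream
(`SeedSequence(seed, crc32(component keys))`), so adding a modality or
reader leaves all other draws untouched, and a fixed seed reproduces the
study byte-for-byte.

`designed_auc` integrates the logistic over the combined Gaussian effect
(Gauss–Hermite, 80 nodes) to give the generative accuracy target the
estimation pipeline should recover; it matches the closed form exactly
when all σ are 0 and Monte-Carlo integration to within Monte-Carlo error
otherwise.

**Candidate spacing.** A generated study must be recoverable by the
pooling stage: if two candidates sit closer than the pooling radius,
their mark clouds chain into one cluster and the same reader appears
twice in it — an input the pipeline correctly rejects. The default
spacing of 25 µm exceeds radius (10) + 2 × 3σ jitter (12), making
splits/merges rare (≥99% of marked candidates are reconstructed exactly,
verified over replicates). Biologically this just says two distinct
mitotic cells a few microns apart are rare at these densities.

**What the generator does not emulate.** No images and no morphology;
truth labels are exact rather than panel-derived; detection probabilities
are exchangeable within class (no spatial or ROI-level difficulty
structure beyond the slide effect); reader effects are additive on the
logit scale with no reader × modality interaction. Passing tests
therefore demonstrate estimator correctness under a known generative
model, not performance claims about any real scanner.

## Test problem sizes

Simulation-backed properties use sizes chosen to put each estimator in
its intended regime: accuracy recovery uses 20 slides × 50 ROIs over 100
replicates (binomial noise small against the 0.02 tolerance); the
closed-form jackknife comparison uses 250 independent candidates over
200 replicates; null CI coverage uses 200 studies of 16 slides × 10
ROIs, enough slide clusters for the jackknife/z interval to be near
nominal (95.0% observed).

## Known limitations

- With only 4 slide clusters — the modeled study's own size — the
  delete-one-slide jackknife plus normal quantiles undercovers (≈83%
  observed at the null instead of 95%). This is inherent to few-cluster
  resampling; a cluster-count-aware reference distribution would be the
  remedy and is out of scope. Confidence intervals and p-values from
  4-slide studies should be read accordingly.
- Normal quantiles (no degrees-of-freedom adjustment) also mean printed
  CIs from other MRMC software using adjusted df will differ slightly.
- Per-candidate raw marks of the modeled study are not printed in its
  report, so its per-pair kappas and per-reader accuracies cannot be
  recomputed here from raw data; worked examples are closed over the
  printed summary tables instead.
- The moment estimator in the Bland–Altman stage truncates negative
  variance components at zero, which biases the total-variance estimate
  upward slightly when a true component is near zero.
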