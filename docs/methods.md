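# Methods

## Connectivity and contrasts

Connectivity is the Fisher z-transform of the Pearson correlation between
two regions' mean timecourses. Correlations are clipped to |r| ≤ 1 − 1e−12
before `atanh`, so perfectly (anti)correlated pairs yield a large finite z
(|z| ≈ 13.8) instead of ±inf; a constant timecourse is an error naming the
region, never a silent NaN. Pairs are vectorised in lexicographic (i, j)
order with 0 ≤ i < j < R (`PairIndex`); every downstream vector and table
references this one ordering.

Group contrasts are Welch two-sample t-tests per pair, two-sided p from the
t distribution with Welch–Satterthwaite degrees of freedom, sign convention
t > 0 ⇔ mean FC(NC) > mean FC(PD). Samples are scans (replicates pooled) by
default; `sample_unit="subject_mean"` averages each subject's replicate FC
vectors first. Pairs with zero pooled variance get t = 0, p = 1 (detected
at the data's floating-point scale, not by exact equality — the batched
one-pass moments accumulate rounding error of order eps·‖x‖²). No per-edge
multiple-testing correction is applied: inference runs through permutation
of aggregate statistics.

Directional analyses restrict two-sided p-values by the sign of t
("plus" = t > 0 everywhere = FC decreased in the patient group); a t of
exactly 0 is excluded from both directions.

## Permutation machinery

The reproducibility statistic R between two contrasts is the Pearson
correlation of their t-vectors. Its null is generated by permuting group
labels *independently* in the two collections and recomputing both
contrasts and R; the p-value is the plain fraction of null R at or above
the observed one (ties count, no +1 correction, so p = 0 is attainable;
the conservative companion (N·p + 1)/(N + 1) is always available). Labels
are permuted at the subject level by default — all scans of a subject move
together, the exchangeable unit when replicate scans exist — with
`perm_unit="scan"` as the laxer alternative. The min(max(p)) permutation
test works the same way, with "≤ observed" as the rejection direction and
the sign-consistency filter re-applied per permutation.

For speed, permuted Welch statistics are evaluated for all N label
assignments at once via matrix products of the indicator matrix with the
FC matrix and its square (one-pass moments). The observed contrast uses an
accurate two-pass path. Correctness of the batched path against the
single-labeling path and against exhaustive enumeration over all label
assignments on 3+3-subject cohorts is part of the test suite.

## Split engine

`split_subjects` partitions each group's subjects into halves (sizes
differing by at most one, side 1 taking the extra subject; assignment
randomised per split) with all of a subject's scans on one side.
`split_replicates` puts every subject on both sides with its replicate
scans randomly divided. A batch of splits records each split's (R, p) and
summarises the median R and the fraction of splits with p above 0.01 and
0.05 — the "fraction of non-reproducible splits" that diagnoses
heterogeneity.

## Classifiers

Features are the n pairs with the largest training-set |Welch t|
(deterministic tie-break by ascending pair index; the selection never sees
test data). Features are standardised by training-set mean/sd; classifiers
are a linear SVM at fixed C = 1 (no tuning — the evaluation protocol, not
the classifier, is under study) and Gaussian naive Bayes with the standard
1e−9 relative variance floor. Performance is the balanced average accuracy
Aacc = (acc(NC) + acc(PD))/2. Split-half evaluation stratifies by group at
the subject level, so replicate scans never straddle the train/test
boundary (`split_unit="scan"` reproduces the laxer design).

A subtlety worth recording: on a cohort that carries a real effect, a
*single* random permutation of the labels is not a null — the shuffled
labels retain a chance alignment with the true ones, which a classifier
learns and generalises to held-out subjects (we measured a +0.05..+0.09
bias in mean Aacc). The label-randomisation control therefore re-permutes
the subject labels on every repeat (`permute_labels=True`), whose Aacc
distribution is centred at 0.5 by symmetry.

## Synthetic cohort generator

The generator emulates exactly the hierarchy the split analyses exploit:
a baseline correlation matrix shared by all subjects (low-rank loadings
W W' + I normalised to unit diagonal, rank 5 by default); disease effects
as signed shifts delta_z of selected pairs in Fisher-z space,
c ↦ tanh(atanh(c) + delta_z), with PD subjects drawing a subtype when
several effect sets are configured; Gaussian z-space noise at the subject
level (sigma_subject, persistent across a subject's scans) and the
replicate-scan level (sigma_scan); after every z-space perturbation,
projection to the nearest valid correlation matrix (Higham alternating
projections, eigenvalue clipping at 0, Frobenius tolerance 1e−8, at most
100 iterations, final clip + diagonal renormalisation). Scan timeseries are
zero-mean multivariate normal draws from the scan's correlation matrix; an
optional AR(1) filter applies per region to correlated innovations
(x_t = φ·x_{t−1} + sqrt(1−φ²)·e_t, stationary start), which leaves the
stationary cross-region correlation equal to the target, so FC ground
truth stays exact. Everything is reproducible from the config seed.

Two design knobs exist specifically for multi-dataset designs:
`base_seed` shares the baseline connectome across datasets that describe
the same population (without it, cross-dataset transfer fails trivially
because each dataset has a different baseline FC — no real multi-site
study has that); `subtype_assignment="stratified"` allocates subtypes by
largest-remainder exact counts in shuffled order, removing the composition
noise of the random draw in small designed cohorts (a 12-subject patient
arm drawn at 50/50 is 8/4 or worse about a third of the time).

What the generator does *not* model: hemodynamics, physiological noise,
in-scanner motion, voxel-level structure, site-specific acquisition
differences beyond independent sampling, or non-Gaussian FC distributions.
Passing tests therefore demonstrate that the *statistics* behave as
claimed under the stated hierarchy — not that any particular clinical
dataset is homogeneous or heterogeneous.

## Study conditions of the in-silico experiments

The canned experiments (`fcrepro.experiments`) fix one set of conditions,
chosen by a power analysis targeting per-half group t-values of ≈ 2–3 on
affected pairs — the regime case–control rs-fMRI cohorts actually occupy —
and held fixed across all analyses:

| parameter | value | note |
| --- | --- | --- |
| delta_z | 0.25 | per-subtype Fisher-z effect, 20 pairs per subtype |
| subtype pairs | regions 0–9 vs 10–19 | disjoint region blocks, no coupling |
| sigma_subject | 0.15 | subject-level z-noise (persists across replicates) |
| sigma_scan | 0.10 | replicate-scan-level z-noise |
| T, TR | 120, 2 s | FC estimation noise ≈ 1/sqrt(T−3) ≈ 0.09 |
| cohort | 12 + 12 subjects × 2 replicates, R = 20 | split analyses |
| classifier designs | 15 + 15 subjects (30 + 30 scans) | delta_z = 0.8 for transfer |

Split batches default to 100 splits × 500 permutations and the split-half
classifier control to 500 repeats — desk-scale versions of the >1000
splits / 10,000 repeats a full study would run; every count is a flag.

## Numerical and interface choices

* "Ideal" band filtering zeroes discrete-Fourier coefficients strictly
  outside [low, high] (band-edge bins pass, DC removed whenever low > 0);
  filtering is exactly idempotent. Edge handling at the bin boundary is a
  convention; nothing downstream depends on it.
* Double-TR decimation keeps even 0-based indices (the first timepoint
  stays) and doubles tr_seconds.
* Global signal regression removes intercept + cross-region mean by least
  squares; a constant global signal degenerates to demeaning.
* Collections are TSV directories (one T×R matrix per scan plus
  metadata.tsv) — diffable and inspectable; NIfTI volumes enter only
  through the atlas-based ROI extraction front-end.
* Pipeline stages derive their seeds from the global seed by stable
  hashing of the stage name, so adding a stage never shifts another
  stage's randomness.

## Known limitations

* The permutation engine enumerates nothing: at tiny cohort sizes the
  Monte-Carlo p has resolution 1/N and can be 0; use the corrected
  companion when a strictly positive p is needed.
* The nearest-correlation projection slightly redistributes very large
  planted effects (delta_z ≳ 1 on many pairs of a small parcellation);
  ground-truth targets are stored *after* projection, so downstream checks
  remain exact.
* `low_motion` is a metadata flag only; no motion is estimated.
* Welch inference assumes scans are independent samples within a group;
  pooling replicate scans (the default, mirroring printed cohort tables)
  mildly violates this — the subject-level permutation null and
  `sample_unit="subject_mean"` are the principled alternatives.
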