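# Methods

## The SPAR transform

A quasi-periodic signal x(t) sampled at f_s, with average cycle length L
(the mean spacing of successive R peaks, in samples), is embedded with
Takens delay coordinates of dimension N ∈ 3..9 and delay τ = round(L/N)
(half-away-from-zero, floored at 1).  The t-th delay vector is
(x(t), x(t+τ), …, x(t+(N−1)τ)); there are M = n − (N−1)τ of them, every
entry an exact copy of a signal sample — no interpolation anywhere in the
pipeline.  The 2D projection with index k ∈ 1..⌊(N−1)/2⌋ uses

    u_j = √(2/N) cos(2πkj/N),   v_j = √(2/N) sin(2πkj/N),   j = 0..N−1.

For valid k, both weight vectors sum to zero (geometric-series identity)
and form an orthonormal pair, so:

* the projection is orthogonal to (1, …, 1) — adding a constant to the
  signal leaves the point cloud unchanged up to floating-point rounding
  (the cancellation is exact in real arithmetic; in double precision the
  residual is at machine-epsilon scale, and slow baseline wander is
  attenuated in proportion to how close it is to constant across one
  delay span);
* a pure sinusoid of period Nτ samples maps to a circle under k = 1, the
  closed-form sanity limit.

The √(2/N) scaling is a design choice (the construction only fixes the
directions): it makes the basis orthonormal so attractor size is
comparable across N.  Any fixed scaling would do, because the radial
features below use per-cloud bin edges; a different constant would merely
rescale r bin edges.  The phase convention puts weight cos 0 = 1 on the
first coordinate; changing it rotates the attractor rigidly, which the θ
histogram absorbs as a circular shift.  All M delay vectors are kept — no
transient trimming.

## Preprocessing

R peaks come from a Pan–Tompkins-style detector: 5–15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, a threshold at
0.3× the 99th percentile of the integrated signal, a 200 ms refractory
period, and refinement of each detection to the band-passed local maximum
within ±50 ms.  Only the *mean* RR interval is consumed downstream, so the
detector choice has second-order effect; on the synthetic generator it
recovers every planted beat within 20 ms.  Records with fewer than two
detected beats are excluded, never imputed.  L is computed per analysed
lead (`attractor_from_record` operates on one lead at a time); since L is
a single mean, per-lead versus per-record estimation changes τ by at most
a sample or two.

Before embedding, each lead is min–max normalised to [0, 1].  The study's
source data gives no amplitude-handling detail; normalisation is adopted
so that density features cannot encode per-record gain, which also makes
the feature magnitudes comparable across records (θ maxima ≈ 0.03–0.05 at
60 bins, r maxima ≈ 0.2–0.4 at 20 bins on realistic synthetic
morphology).  No band-pass or notch filtering is applied by default.

Decimation (500 → 125 Hz) is pure sample selection — every fourth sample,
no anti-alias filter — so retained values are bit-identical and the two
sampling rates differ only in which samples are seen.

## Density features

Both histograms are taken about the projection origin (0, 0), the image of
any constant signal — not the cloud centroid — so that θ is meaningful
across records.  Bins are half-open [low, high); the maximum-radius point
is included in the top annulus.  Radial edges span [0, max radius] of the
cloud itself (a fixed global maximum is available as an option); angular
edges are 2πi/bins.  Densities are normalised to sum to 1 (the alternative
max-1 normalisation is inconsistent with the observed feature magnitudes
above).  Bin indices are computed by searchsorted against exactly nested
edge grids, so merging adjacent bins of a 2B-bin profile reproduces the
B-bin profile without boundary leakage.  Supported resolutions:
r ∈ {10, 20, 30, 40, 50, 60, 70, 150, 300}, θ ∈ {20, 40, 60, 80, 100,
120, 250, 500}; defaults 20/60 (the KNN-model choice; 40/100 suits
decision trees).

## Classification harness

Leave-one-patient-out CV: one fold per patient, all of a patient's records
held out together, metrics pooled over per-record predictions.  Case (PAF)
is the positive class; on a balanced table accuracy equals the mean of
sensitivity and specificity identically.  Undefined ratios (zero
denominator) are reported as missing, never zero.

KNN supports the 10 search-space metrics (cityblock, chebychev,
correlation, cosine, euclidean, hamming, jaccard, minkowski, seuclidean,
spearman).  Distances are computed with scipy's `cdist`; `spearman` is the
correlation distance between within-row rank transforms, `minkowski` uses
exponent 3 (1 and 2 being already present as cityblock/euclidean), and
`seuclidean` scales by the per-feature variance of each training fold
(zero-variance features contribute nothing).  Hamming and jaccard are
near-degenerate on continuous densities and are retained for completeness
of the space.  Distance ties are broken by training-row order; vote ties
toward "control" (configurable), preferring fewer false positives.
Decision trees use Gini impurity with only the minimum leaf size tuned
(1–182), no depth limit.

Hyperparameter search: spaces of ≤ 200 points (the whole tree space) are
evaluated exhaustively; larger spaces (KNN: 10 × 50 = 500 points) use a
Gaussian-process surrogate (Matérn ν = 2.5 on a one-hot-metric +
scaled-neighbour encoding) with expected-improvement acquisition,
30 evaluations by default, the first third random, deterministic given
the seed.  When several configurations tie for the best accuracy across
(lead, N, k) combinations, the modal configuration is taken; if the mode
is not optimal for the queried combination, that combination's
first-listed optimum is used.

Demographics: age maps linearly onto [Age1, Age1+Age2] after per-table
min–max scaling; sex maps to the scalar Sex1 (male) / Sex2 (female).  The
defaults (0.0103, 0.9983, 0.0486, 0.0317) are the published optimised
values for these four constants.  Stratified reporting uses decade bands
with everything under 50 pooled; count-weighted band accuracies pool to
the overall accuracy by construction.  Misclassification analysis flags a
record when wrong predictions reach ceil(threshold × predictions) —
12 of 16 at the default 0.75.

A note on the source tables: the published overall confusion matrix sums
to 364 records while the cohort holds 362, and the printed 67.4%
sensitivity differs slightly from the table-derived 123/182 = 67.6%.  This
package always reports exact arithmetic from the counts it is given and
makes no attempt to reconcile the discrepancy.

## Cohort construction

Cases: all SR records of every patient with at least one AFIB and one SR
record (AFIB records are never classified).  Controls: SR records of
patients with no AFIB record and no diagnostic superclass, matched 1:1 to
case records on sex (exact) and age (same decade band, 20–89; ages outside
are rejected with a warning), without replacement.  Within a stratum,
candidates at minimal |age difference| are drawn with a seeded RNG,
preferring patients not yet used; a second record from the same control
patient is taken only when the stratum would otherwise run out — which is
how a balanced record count can span fewer patients than records.
Unmatched cases are reported, not fatal.  Remaining non-case SR records
form test group 1 (patients with ≥ 1 superclass) and test group 2
(patients with none); both are disjoint from the training cohort.  The
`require_prior_af` option restricts cases to SR records dated at or after
the patient's first AFIB record, when recording dates are available.
Exact tie-breaking inside a stratum is underdetermined by the published
selection rule, so counts on the real registry may shift marginally with
the seed for controls (never for cases, which involve no sampling).

## Synthetic data generator

Each beat is a sum of five Gaussian bumps: P (0.15 mV, −0.20 s, 80 ms),
Q (−0.10, −0.04, 20 ms), R (1.00, 0.00, 40 ms), S (−0.15, 0.04, 20 ms),
T (0.30, 0.30, 160 ms), where the width is the ±2σ span and offsets are
relative to the R peak.  The sum-of-Gaussians model was chosen over an
ODE-based generator for exact analytic ground truth (R-peak times are
known, not estimated) and speed.  RR intervals are truncated normal
(default mean 0.8 s, SD 0.05 s, floor 0.3 s); defaults are 10 s at 500 Hz
with 0.05 mV sinusoidal baseline wander at 0.33 Hz (respiratory range) and
0.02 mV white noise — a clean resting recording.  The 12 leads are fixed
linear mixtures of two latent sources (QRS complex; P+T waves) with
lead-specific gains, enough to exercise per-lead code without a torso
model.

The two-class difference multiplies designated wave parameters (default:
P-wave amplitude and width, the physiologically plausible PAF correlate)
by `class_effect`; 1.0 is the null.  Registries mirror case demographics
onto the first controls so that every case stratum is matchable and the
planted cohort balances.

What the generator does *not* emulate: real inter-patient morphology
variance, pathological beats, electrode artefacts, muscle noise,
non-stationary rhythm.  Passing tests therefore demonstrate that the
pipeline is correct and that planted morphology differences of known size
are recovered — not that any particular accuracy transfers to clinical
recordings.

## Problem sizes and numerical choices

The end-to-end parameter-recovery experiments use 40+40 single-record
patients (80 records, n chosen to give a reasonably tight binomial
interval around chance while keeping the full suite fast), θ-density
features at N = 3, k = 1, 60 bins, 125 Hz, 1-NN Euclidean, at effect
sizes 1.0 / 1.2 / 1.5 with 0.01 mV noise and fixed seeds.  Under the null
the LOPO point estimate scatters around 0.5 (1-NN LOPO is in fact slightly
pessimistic under the null, since holding a patient out leaves the
opposite class over-represented in training); under effect 1.5 the classes
separate completely.  Headline published accuracies (81.2 % etc.) are
functions of the real accession and the full optimisation grid and are
reproduced only by the optional integration path, not by the synthetic
suite.

Degenerate inputs: constant signals are rejected at normalisation;
point clouds collapsed onto the origin get all radial mass in the
innermost annulus and angle 0; flat signals raise "insufficient beats";
empty clouds are errors.  All randomness flows through
`numpy.random.default_rng` seeds; every public stochastic routine is
reproducible given its seed.
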