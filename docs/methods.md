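# Methods

This note documents the models and procedures implemented in `avoidpop`,
their assumptions, the parameters that matter, and the design decisions
taken where the procedure was genuinely open. It states no empirical claim
that the test suite and `scripts/acceptance.py` do not themselves compute.

## Task model

Two-way signaled active avoidance: each trial is a tone (CS) of at most
10 s, preceded by a uniform 25–40 s inter-trial interval. If the animal
shuttles to the opposite chamber while the tone plays (*success*), the tone
terminates at the shuttle crossing; otherwise (*failure*) a foot-shock is
delivered at CS + 10 s and the animal escapes within ~2 s. The avoidance-run
(Av-run) onset is the time the animal's speed reaches 5 cm/s during the CS.
Trials in which the animal shuttles before 4 s are excluded from neural
analysis, so cue- and action-related signals remain temporally separable.

## Preprocessing

Raw traces are neuropil-corrected (F − r·F_neuropil, r = 0.7), converted to
ΔF/F with a sliding-percentile baseline — F₀(t) is the 10th percentile
(linear interpolation between order statistics) of a 25-s window *centered*
on t and truncated at the recording edges — then dropped frames are linearly
interpolated and the session-length trace z-scored per neuron. The centered
window is a choice: only the window length and overlap are fixed by the
procedure; a trailing window would lag slow baseline changes by half a
window. ΔF/F is invariant to positive rescaling of the raw trace, so the
acquisition gain is irrelevant downstream.

Photometry: both channels are Gaussian-smoothed (100 ms SD; only "smoothed"
is specified, this is the package's default) and linearly detrended with the
channel mean retained, then the 405-nm reference is fit to the 465-nm signal
by affine least squares; ΔF/F (%) = 100·(s465 − fit)/fit. Because the 405-nm
channel carries artifacts but no calcium signal, the regression removes
shared motion/bleaching components. For avoidance sessions the corrected
trace is spliced per trial, concatenated and z-scored; other experiments
z-score before splicing (both orders are exposed; they differ only through
the normalization constants).

Kinematics: speed is the Gaussian-filtered central-difference derivative of
the tracked body point over a 15-frame (0.5 s at 30 Hz) support; Av-run
onset is the first in-CS frame with speed ≥ 5 cm/s (one frame of slack at
the CS offset, since a run that terminates the tone can quantize one frame
past it); freezing is speed < 0.25 cm/s sustained ≥ 0.5 s; flight is
speed > 50 cm/s.

## auROC modulation test

For a task variable (CS, Av-run, pre-Av-run, shock), the baseline sample
pools each neuron's fluorescence over the variable's baseline window across
trials (CS/run/shock: −2–0 s; pre-run: −3 to −2 s before the run). At each
response-window timepoint (0–2 s; pre-run: −2–0 s) the across-trial values
are compared to the pooled baseline with the area under the ROC curve,
computed as the rank-sum statistic U/(n₁n₂) with half-credit ties; the
neuron's statistic is the mean auROC over response timepoints. The null
rebuilds the statistic after circularly shifting the whole session trace by
a uniform random offset (one offset per permutation, shared across neurons
of a session), which preserves autocorrelation while destroying event
alignment; 1000 permutations by default. Classification is two-sided at
α = 0.05: activated above the 97.5th, suppressed below the 2.5th null
percentile. Pooling the baseline across trials is the default (a per-trial
mode is a config option); ties take half credit, the standard rank-sum
convention.

Because the indicator kernel is zero at the event sample itself, a noiseless
transient response yields a statistic of 0.95 (one of ten response
timepoints ties with baseline), not 1.0; saturation at 1.0 occurs from the
first post-onset sample onward.

## Population geometry

The embedding is PCA of the n × 2t matrix formed by concatenating the
success- and failure-trial-averaged responses per neuron (windows −2–+3 s
around CS onset, −3–+3 s around run onset), with per-neuron mean-centering;
components live in neuron space and time samples are the observations.
Single trials are projected onto the components that explain ≥ 80% of the
trial-averaged variance.

Trajectory divergence: per bootstrap (100 by default) a random 80% neuron
subset is drawn (the subset size is unspecified by the procedure; 80% is the
package default), PCA refit, trials equalized to the smaller condition, and
the per-timepoint Mahalanobis distance computed between the success and
failure projection clouds using the pooled within-condition covariance at
that timepoint — with Ledoit-Wolf shrinkage whenever trials < dimensions or
the plain estimate is singular (the covariance estimator is a package
choice). Distances are z-scored to the pre-event baseline period (−2–0 s for
CS, −3 to −2 s for run alignment) within each bootstrap; a timepoint is
significant when fewer than 5% of bootstraps fall below z = 1.65.

Coding direction: d = x̄_success − x̄_failure averaged over 0–3 s after CS
onset (for run alignment the default window is −3–0 s, a package choice);
cd = d/‖d‖, and projections are cdᵀx per trial. If ‖d‖ = 0 the result is
flagged and all projections are zero. Residual PCs are computed after
projecting the cd component out of the trial-averaged activity; they are
orthogonal to cd by construction and retained up to 85% of residual
variance.

## Decoding

Pseudo-trials emulate simultaneous recording: single-trial activity is
denoised by reconstruction from the top PCs (≥ 80% trial-averaged
variance), neurons are sampled without replacement, and each neuron
contributes an independently permuted trial ordering within outcome class;
features concatenate the classification window's timepoints (CS: 0–2 s;
pre-run: −1.4–0 s) or a single bin for time-resolved decoding. The
classifier is a linear-kernel SVM (C = 1) with feature standardization fit
on training folds, scored by stratified leave-one-out (one trial per class
per fold); 100 bootstrap re-assemblies capture construction variability.

**Known property, not a bug:** the PC reconstruction and the pseudo-trial
resampling both reuse the complete trial set across CV folds, so raw LOO
accuracy is optimistic — on pure-noise cohorts it can reach 1.0. Inference
therefore always uses the matched label-shuffle null: outcome labels are
permuted at the trial level *before* trial averaging, PCA, denoising and
assembly, and the identical pipeline is rerun (1000 shuffles by default);
p = (1 + #{null ≥ observed})/(1 + n_shuffle). Calibration of the decoder
itself (accuracy ≈ 0.5 when labels are independent of features) holds at
the feature level and is verified there.

## Functional clustering and spatial tests

Features are the four trial-averaged epoch responses (CS-success,
CS-failure, shock, Av-run) concatenated per neuron, PCA-reduced to 80%
variance. k-means runs for k = 1…20 with 5 restarts each (best inertia
kept). Model selection uses the knee of the log-inertia curve — the k at
maximum distance below the chord joining the curve's endpoints — rather
than the raw second difference of inertia: on any convex decreasing curve
the raw second difference peaks at k = 2 regardless of where the true knee
is, whereas the log-chord criterion marks where the relative improvement
collapses; data clustered perfectly at some k (zero inertia) short-circuit
to the smallest such k. The silhouette score validates the chosen
partition. For display, rows are min–max normalized to [0, 1] (constant
rows map to 0.5) and sorted within cluster by correlation with the cluster
mean.

Spatial organization: along each anatomical axis (AP, ML, DV) neuron
positions fall into 8 equal-width bins; the per-bin mean of the quantity
under test (a PC/CD coefficient, or a cluster-membership indicator) is
normalized by the summed *absolute* bin means — the absolute value handles
signed coefficients, for which a plain sum can vanish; raw bin means are
also reported. The statistic is the SD of the relative concentrations; the
null shuffles values across neurons (10,000 shuffles by default);
p = (1 + #{null ≥ obs})/(1 + n_shuffle), Holm-Bonferroni across whichever
family of tests is run together. Empty bins contribute zero concentration.

## Encoding GLM

The indicator kernel rises linearly to its peak over 0.15 s, decays
exponentially with a 0.8-s constant, is truncated at 1.5 s and normalized to
peak 1 (the rise/decay/support are fixed; the linear-rise functional form is
the package's choice and configurable). Event impulse trains (cue onset
split by outcome, shock onset, run onset, and an anticipatory-run regressor
placed 1 s before the run so it is linearly independent of the onset
regressor) are convolved with the kernel on the session timeline, shifted by
up to 2 s — forward for event onsets, backward for the anticipatory
regressor — sliced into per-trial windows and concatenated, with a single
intercept. Shifts may be fixed or optimized by one pass of coordinate
ascent over a frame-resolution grid maximizing training R² (whether the
original shifts were fixed or fitted is ambiguous; both modes exist, fixed
zero shifts are the pipeline default).

Fits are OLS per unit; rank deficiency raises an error naming the collinear
columns. Leave-one-trial-out CV refits on the remaining trials and scores
the concatenated held-out predictions (R², mean per-fold MSE). A
predictor's contribution zeroes its columns *without refitting*: the drop
in R² relative to the full model (the zeroed model's R² floored at 0, since
predicting worse than the mean explains nothing) in percent, plus the
nested F statistic ((SSE₀ − SSE)/q)/(SSE/(n − p)). Derived indices:
cue-outcome = β_CS-success − β_CS-failure; action = β_anticipatory +
β_run-onset; groups are summarized by mean ± SEM with one-sample t and
Wilcoxon tests. Bulk photometry signals run through the identical path as a
single "virtual neuron".

## Connectivity statistics

Counts are converted to per-subject input proportions (zero-total subjects
excluded). Per region: one-way ANOVA across subtypes with eta-squared effect
size (the effect-size measure is otherwise unnamed; eta-squared is used and
labeled), Benjamini-Hochberg FDR across regions, Tukey HSD pairwise tests
where the adjusted p clears α. Proportions are compositional: a genuine
enrichment of one region necessarily depletes the rest slightly, so "only
region X differs" holds in the detectable-effect sense, not literally.
PCA runs on z-scored proportions with 3 retained components; per group pair,
two-sample t-tests on each PC are combined with Fisher's method, the mean
cross-group Euclidean distance in PC space maps to the similarity index
1/(1 + d), and a permutation test reassigns subjects to groups (add-one
p-values). Hierarchical clustering of group mean PC vectors uses average
linkage on Euclidean distance (linkage unspecified; average chosen).
The subtype decoder is a linear SVM with the native one-vs-one multiclass
scheme, scored by leave-one-subject-out CV; bootstrap resampling (train on a
with-replacement resample, test on the full data) gives an accuracy
distribution; the permutation null shuffles subtype labels and repeats the
LOOCV; significance requires the observed accuracy to exceed the null's
95th percentile. Hemispheres are summed by default.

## Synthetic-data generator

The generator is the package's test bed; it emulates the statistical
structure the analyses assume, with planted ground truth returned alongside
every output.

*Trials*: outcomes are Bernoulli(p_success = 0.5 by default; 30 trials per
session at 5 Hz); ITIs uniform 25–40 s; success latencies uniform on
[4, 10) s — the task fixes only the 10-s ceiling and the 4-s exclusion, so
the latency law is a modeling choice recorded in the ground truth; failures
get the shock at CS + 10 s and an escape 0.5–2 s later.

*Traces*: each neuron draws a motif from a 10-entry dictionary whose
phenotypes mirror the functional cluster taxonomy of this preparation
(CS-activated with success or failure bias, transient CS, CS-suppressed,
unmodulated, shock, pre-run ramp, run onset, safe-chamber entry, mixed
CS+run), with mixing proportions matching realistic cluster-size ratios.
Amplitudes (1.2–3 z-units at the response peak) are set so the phenotypes
are distinct at the generator's default noise — the dictionary exists to
plant recoverable structure; weaker or overlapping motifs can be configured
explicitly. The noiseless signal is the sum of amplitude-weighted
kernel-convolved event trains (sustained CS motifs use a tone-length boxcar
normalized to plateau 1); per-frame Gaussian noise (SD 1 z-unit) and a slow
random-walk baseline (step SD 0.01/frame, emulating bleaching and focus
drift) are added, and the result maps to raw fluorescence as
F = 100·(1 + 0.05·s), keeping the sliding-percentile baseline strictly
positive. `dff_from_raw` inverts the map so estimator tests can work in the
units in which amplitudes are planted; the session z-score pipeline recovers
the same shapes up to the session SD.

*Behavior*: 30-Hz tracks integrate a speed profile — 0.5 cm/s baseline with
45 cm/s² linear ramps to 40 cm/s at each run — constructed so the smoothed
speed crosses 5 cm/s exactly at the planted onset (linear ramps are
invariant under symmetric smoothing), plus 0.02-cm positional jitter.

*Photometry*: the 465-nm channel carries the weighted kernel-convolved event
mixture plus a shared low-pass-filtered Gaussian motion artifact; the 405-nm
channel carries only the gain-scaled artifact plus channel noise, so
isosbestic regression is testable against ground truth.

*Input counts*: per subject, region proportions are
Dirichlet(concentration × subtype profile) and counts
Multinomial(total_cells); infinite concentration is the deterministic limit
(counts are rounded profile multiples).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: biophysical calcium dynamics and spike-to-
fluorescence nonlinearity, cross-neuron noise correlations, session-to-
session representational drift, behavioral idiosyncrasy beyond the speed
threshold model, and optical crosstalk between neighboring ROIs.

## Problem sizes, tolerances and reproducibility

Recovery and calibration suites run at desk scale chosen for statistical
sufficiency: 500 neurons × 1000 permutations for the type-I calibration of
the modulation classifier (binomial 99% band 3.5–6.5% at α = 0.05), a
1600-neuron 8-session cohort for clustering recovery, 100 bootstraps for
decoding, 200 repetitions × 1000 shuffles for spatial-test calibration.
Exact algebraic identities (auROC vs brute-force pairs, Mahalanobis vs
direct solve, noiseless GLM recovery) are asserted at 1e-6–1e-12.

All randomness flows through NumPy Generators; the pipeline derives
per-stage seeds by CRC-hashing the stage name against one global seed, so
stages reproduce in isolation and two runs with the same config and seed
write byte-identical tables. Session bundles round-trip bitwise through the
HDF5 + CSV container (`%.17g` formatting with round-trip parsing).

## Known limitations

- The decoder's raw accuracy is only interpretable against its matched
  shuffle null (see Decoding); the package deliberately does not report
  raw accuracies as stand-alone evidence.
- The GLM is OLS: no regularization, Poisson likelihood or spline kernels;
  heavily collinear designs error out rather than being ridge-stabilized.
- The spatial test uses equal-width bins on the observed coordinate range;
  strong outliers in coordinates can concentrate most neurons in few bins.
- `run_pipeline` pools sessions by subsampling trials to the smallest
  session, discarding surplus trials.
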