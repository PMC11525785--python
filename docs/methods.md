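# Methods

This note documents the models, numerical choices and validation logic of
`salnet`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## The measurement model

The pipeline quantifies condition-dependent functional connectivity of the
salience network (SN) — dorsal anterior cingulate cortex (dACC), left insula
(lIns), right insula (rIns) — from 62-channel EEG (extended 10-20 layout,
mastoids excluded) recorded at 1000 Hz under three conditions: eyes-closed
rest (RS), and the standard (Std) and deviant (Dev) trials of a passive
duration-deviant auditory oddball stream (750 trials, 10% deviants, 600 ms
onset-to-onset interval; 50 ms standard and 100 ms deviant tones).

### Preprocessing

Continuous data are band-pass filtered 0.1–50 Hz with a 6th-order
Butterworth filter applied zero-phase (forward–backward with
`scipy.signal.sosfiltfilt`). Zero-phase application preserves the component
latencies that the mismatch-negativity window depends on; the cost is that
the effective magnitude order doubles (the response is |H|²), which the
filter tests account for by treating the single-pass magnitude as a lower
bound on attenuation.

Epochs are 700 ms everywhere — `round(0.7 × fs)` samples. Resting data are
cut into consecutive non-overlapping windows; oddball data into one epoch
per event spanning the half-open interval [−100, 600) ms around onset
(0-based sample indexing; stimulus onset is sample 100 at 1 kHz), split into
Std and Dev sets by event code. Events too close to a recording edge are
dropped and logged. Each epoch and channel is linearly detrended; oddball
epochs are then baseline-corrected by the mean of [−100, 0) ms.

Epochs whose absolute maximum over *all* channels exceeds 75 µV are
rejected (per epoch, never per channel). The threshold is applied after
baseline correction — the stage order (filter → segment → detrend/baseline
→ reject → subsample) is fixed by construction because permuting rejection
and subsampling changes the result. Finally 250 / 300 / 45 epochs (RS / Std
/ Dev) are drawn uniformly without replacement with a seeded generator; if
fewer survive rejection, all are kept with a warning. Manual
independent-component artifact rejection used on real clinical data has no
automated counterpart here; the amplitude criterion stands alone. This is a
known fidelity gap, acceptable for synthetic data that contain no ocular or
myogenic artifacts.

### Source localization

The inverse operator is a depth-weighted L2 minimum norm,

    K = W Gᵀ (G W Gᵀ + λ C)⁻¹,

with gain matrix `G` (channels × voxels), diagonal depth weights
`W_vv = ‖g_v‖^(−2γ)` and noise covariance `C = I` (no empty-room data exist
in this design; a hook accepts a measured covariance). Defaults: γ = 0.5
(the conventional depth-weighting order of minimum-norm toolboxes;
configurable in [0, 1], where γ = 0 is the unweighted minimum norm) and
λ = trace(G W Gᵀ)/(n_channels · SNR²) with SNR = 3, the standard
regularization heuristic when the toolbox default is otherwise unstated.

Each ROI is the set of voxels within 5 mm (Euclidean) of its seed; if the
ball is empty on a coarse grid, the nearest voxel is used with a warning, so
an ROI is never silently empty. The representative ROI time course per
epoch is the first principal component (SVD without temporal centering —
epochs are already detrended) of the voxel block, scaled as the PC score
time course so a single-voxel ROI returns exactly that voxel's signal. Its
sign is aligned to correlate positively with the mean voxel signal; without
a fixed convention, epoch-to-epoch sign flips would corrupt evoked averages
(they would not affect the wPLI, which is invariant to a common phase
offset). PCA is computed per epoch, not across concatenated epochs,
matching the per-epoch connectivity computation downstream. The explained
variance fraction is reported per epoch as a quality measure.

ROI seed coordinates default to literature-standard salience-network seeds
— dACC (0, 22, 35) mm, lIns (−38, 14, −6), rIns (38, 14, −6) in the
MNI-like frame of the lead field — and are editable in the run config; they
are package defaults, not measured quantities.

### Connectivity

For each epoch, band and ROI pair, both representative signals are band-pass
filtered (zero-phase 6th-order Butterworth at the band edges — the same
design as every other filter in the pipeline), the instantaneous phase is
taken as the angle of the analytic signal, and the weighted phase-lag index
is

    wPLI = |E[sin Δϕ(t)]| / E[|sin Δϕ(t)|],

where Δϕ(t) is the per-sample phase difference and E(.) the arithmetic mean
over the trimmed interior of the epoch: 0.1 s is discarded at each end,
which suppresses filter/Hilbert edge transients and, for oddball epochs,
simultaneously discards the pre-stimulus baseline. The index is 1 for any
constant nonzero lag and 0 when positive and negative lags balance. Two
degenerate cases are handled explicitly: a zero denominator (every
sin Δϕ = 0, e.g. perfectly in-phase signals) returns 0 with a quality flag
so epoch averaging stays total — zero-lag locking is invisible to the wPLI
by design, since the index exists to reject zero-lag (volume-conduction)
coupling; and the debiased wPLI variant is deliberately not implemented.
Analysis bands are α 8–12, low-β 12–18, high-β 18–30 and γ 30–50 Hz. Theta
is excluded: a 0.7 s epoch holds at most ~2.4 cycles of a 4 Hz oscillation,
too few for a stable phase estimate. Per-epoch values are averaged per
(subject, band, condition, edge); global SN strength is the sum of the
three averaged edges, hence lies in [0, 3].

### Statistics

Each SN measure is analyzed with a mixed-design (split-plot) ANOVA:
condition (RS/Std/Dev) within subjects, group (nrMDD vs rMDD) between.
Mauchly's test screens sphericity; when it rejects at α = 0.05, the
Greenhouse–Geisser ε-corrected p-values are reported as primary for the
condition effect *and* the interaction (both share ε and the within dfs).
The backing routine is `pingouin.mixed_anova`; since pingouin only reports
the corrected p for the within effect, the corrected interaction p is
computed from its ε as `F.sf(F_inter, ε·df1, ε·df2)` and is cross-checked in
the tests against an independent sums-of-squares implementation. Normality
is screened by the conventional rule |skewness| < 2 and |kurtosis| < 7,
using the Fisher *excess* kurtosis convention; constant input is flagged
invalid rather than passed.

Testing is gated: global strength first, the three edges only when the
strength interaction p ≤ 0.10. The gate threshold is a screening choice
exposed in config — "notable" has no canonical numeric value — and because
gating alters error rates, `calibrate_gated_procedure` simulates the gated
family's empirical type-I rate under the null so a report can state it
rather than assume the nominal level.

Post-hoc group contrasts use a percentile bootstrap of the mean difference
(default n = 5,000 resamples, seeded): each group resampled with
replacement, 95% CI from the 2.5/97.5 percentiles, two-sided p as
2·min(P(diff* ≤ 0), P(diff* ≥ 0)) floored at 1/n. Percentile rather than
BCa intervals: the simplest method consistent with reporting a plain 95%
CI. A caveat the calibration tests quantify: at groups of 14 and 17 the
percentile CI truly covers at ≈93%, not 95% — the familiar small-sample
shrinkage of the bootstrap distribution. Studies at this scale should read
the interval accordingly.

### Features and classification

The feature table holds, per subject: deviant-condition wPLI per edge
(FCdev), the deviant-minus-standard difference per edge (FCdiff ∈ [−1, 1],
the connectivity analogue of a mismatch difference wave), resting absolute
band power, and MMN amplitude. Band power is sensor-level (Welch PSD of
each whole 700 ms epoch under a Hann window, integrated over the band,
averaged over the region's electrodes and epochs, stored raw in µV² — no
log transform; downstream z-normalization absorbs scale, though only
partially for non-linear monotone effects). All four bands × six regions
enter as candidates and feature selection prunes — the candidate pool must
contain everything selection could pick. The six regions (LF/RF from the
Fp/AF/F rows split by hemisphere, LC/RC from FC/C/CP plus temporal rows,
LPO/RPO from P/PO/O; midline electrodes unassigned) and the frontocentral
MMN set {F3, Fz, F4, FC3, FCz, FC4, C3, Cz, C4} are package defaults,
editable in config. MMN amplitude is the mean over the inclusive
[130, 280] ms window of the deviant-minus-standard difference of
epoch-averaged, frontocentral-averaged, 0.1–30 Hz-filtered curves.

Classification of nrMDD (positive/reference class) vs rMDD uses
leave-one-subject-out CV. Strictly inside each training fold: features are
ranked by Fisher score — the two-class criterion (μ₁−μ₂)²/(σ₁²+σ₂²) with
unbiased class variances, ties broken by fixed column order; a
class-size-weighted generalized variant is available behind a config switch
— the top k (k = 1..15) are z-normalized with training mean/sd and fitted
by four deterministic classifiers: LDA (least-squares solver, no
shrinkage), linear-kernel SVM (C = 1, signed margins as scores), KNN (k = 5,
Euclidean, positive-class vote fraction as score) and Gaussian naive Bayes.
These hyperparameters are package defaults where the procedure leaves them
open. Accuracy, sensitivity and specificity are computed per (k,
classifier); with N subjects every accuracy is an exact multiple of 1/N and
the tests assert this granularity. The best configuration is chosen by
accuracy, ties broken toward smaller k and then the fixed order
LDA > SVM > KNN > NB. ROC curves pool the decision scores across folds of
one configuration (pooling yields a single curve; per-fold curves on one
held-out point are undefined) and AUC is the trapezoidal area; both the
default-threshold confusion metrics and the full threshold sweep are
emitted, since either reading of "the operating point" may be wanted. The
MDD-vs-HC contrast is not classified.

## The synthetic-data generator

The generator exists so every downstream stage can be validated against
known ground truth without any clinical recording. It emulates: the
sampling rate, channel count and montage; resting-block and oddball-stream
timing (onsets strictly increasing at the fixed ISI, Bernoulli deviants);
band-limited inter-ROI phase coupling whose strength and
condition-dependence differ by group; a deviant-evoked frontocentral
deflection; and additive Gaussian sensor noise.

**Coupling model.** Per band, the dACC hub phase advances at the band's
center frequency (10, 15, 24, 40 Hz); each insula's phase equals the hub
phase plus a mean lag plus von Mises(0, κ) jitter, piecewise-constant over
25 ms blocks (the jitter coherence time — long enough that the planted
phase survives band-pass filtering, short enough that a 0.5 s trimmed epoch
interior holds 20 independent draws). The von Mises law was chosen because
it yields a closed Monte-Carlo oracle: the expected wPLI is
|E sin Δϕ|/E|sin Δϕ| under von Mises(Δϕ₀, κ), strictly increasing in κ for
Δϕ₀ ∉ {0, π}, equal to 1 at κ = ∞ and to ~0 at κ = 0. Two caveats are
properties of the wPLI itself, worth keeping testable: a planted mean lag
of 0 with κ > 0 produces wPLI ≈ 0 despite strong locking (the generator
warns rather than forbids); and band-pass filtering narrows the jitter, so
the wPLI measured after the filter exceeds the von Mises oracle — the
oracle comparison is therefore made on the ground-truth phase series, while
the filtered path is validated by monotonicity in κ (Spearman ρ = 1.0 over
κ ∈ {0, 0.5, 1, 2, 4, ∞} at 250 epochs in the tests).

With the hub model, the lIns–rIns edge is implied rather than independently
specifiable: default mean lags +π/4 (dACC–lIns) and −π/4 (dACC–rIns) give
the third edge a mean lag of π/2 and a concentration that grows with both
hub κs, so all three edges move together with the planted condition effect.

**Planted group effect.** The default coupling spec plants the
condition-dependent reversal in the high-beta band: HC κ rises 0.5 → 1.0 →
2.0 across RS → Std → Dev, rMDD tracks HC (0.6 → 1.0 → 1.8), and nrMDD
reverses (2.0 → 1.0 → 0.5); other bands sit at κ = 1 everywhere. A
`null` preset removes all group and condition dependence for calibration
runs. Between-subject variability of coupling — uncharacterized in real
cohorts of this design — is a multiplicative lognormal random effect on κ
with log-sd 0.2, a modest heterogeneity chosen once as realistic.

**Forward model.** The lead field is the analytic single-shell homogeneous
sphere (radius 85 mm) with radially oriented sources: the closed form of the
Legendre series for a radial dipole,
`g(f, x) = 2(x−f)/d³ + (1/d − 1)/f`, `d = √(1−2fx+f²)`, with f the
fractional source eccentricity and x the cosine of the source–electrode
angle (limit 3x at the center). Electrode positions come from the standard
10-05 montage projected onto the sphere; source voxels sit on a coarse grid
(default 15 mm, central 10 mm exclusion where radial orientation is
undefined) that always contains the three ROI seeds as exact grid points.
The overall gain scale is arbitrary and normalized so the strongest source
column has unit norm, making source amplitudes roughly sensor µV. A seeded
random-matrix mode exists solely for unit tests of the downstream linear
algebra. The deviant-evoked deflection is added at sensor level on the
frontocentral set: a Hann-shaped waveform with peak −3 µV over 130–280 ms
post-onset, deterministic by default (amplitude jitter is available but
off, so evoked-recovery tests are exact). Sensor noise is white Gaussian,
default sd 2 µV.

**What the generator does not emulate,** and what passing tests therefore
do not show about real data: ocular/muscle/cardiac artifacts (so the
amplitude-rejection stage is exercised only synthetically), realistic
anatomy or a BEM forward model (a common template already limits real
source accuracy; a sphere is one step further), 1/f background spectra
(sources are narrowband oscillations; band power features see planted
oscillations plus flat noise), non-stationarity across a session, and any
coupling structure beyond the hub model. Results on synthetic cohorts
demonstrate that the pipeline recovers what was planted — correctness, not
clinical validity.

## Problem sizes and determinism

Generator defaults are the study conditions (1000 Hz, 62 channels, 300 s
rest, 750 trials, 10% deviants, 600 ms ISI, cohort 14/17/21). Tests and
demos run reduced cohorts — the end-to-end test uses 3/3/2 subjects, 10 s
rest and 80 trials; statistical power and calibration simulations (100–
1,000 replicates) run at the coupling-model level via
`simulate_network_cohort`, which draws the planted block-wise phase
differences directly and evaluates the same wPLI expression the
connectivity stage uses, skipping sensor projection and source localization
whose correctness is established once by the sensor-level tests. These are
the package's chosen problem sizes for its own validation; all stages
accept full-scale configs.

Every random draw descends from explicit seeds (simulation seed for data,
analysis seed for epoch subsampling and bootstrap); cohort generation is
bit-identical under a fixed seed, and each run's `manifest.json` records
the config hash and seeds.

## Storage formats

Recordings are stored as a documented array-on-disk layout (`data.npy` in
µV + `meta.json` + `events.tsv`), epochs as `.npy` with a JSON sidecar, the
lead field as plain-text matrices; EDF files are readable (converted to µV
on ingest) but not written, since no EDF writer is available in the
dependency set. An oddball recording without an event table is an error,
never a silent fall-back to resting state.
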