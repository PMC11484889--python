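# Methods

This note documents the models and procedures finchcall implements, the
conventions and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the design decisions taken where the
procedure descriptions left the design open.

## Conventions

All times are seconds (float64) from recording start; intervals are
half-open `[onset, offset)`. Converting seconds to sample indices floors
onsets and ceils offsets, so segment lengths are never off by more than one
sample and abutting intervals never share a sample. Event CSVs carry six
decimals (1 µs), below one sample at the 40 kHz recording rate, so CSV
round-trips are lossless in practice. WAV is the only audio container
(PCM16 or float32; integer payloads are rescaled to [-1, 1] by the dtype's
full scale); multi-channel files yield channel 0 unless another is
requested. Intracellular sweeps live in an HDF5 layout
(`/sweeps/<id>/vm` as float32 plus per-sweep attributes and a stimulus
table), and run constants in a YAML-serializable `RunConfig`.

## Vocal segmentation and bout assembly

The segmenter is a moving-RMS amplitude envelope (default 5 ms window)
thresholded at an absolute level or, by default, at 6× the envelope's 5th
percentile — a noise-floor proxy that works because these recordings are
mostly silence. Runs at or above threshold become events after merging
across gaps shorter than 10 ms and discarding events shorter than 15 ms.
Call detection on the backpack channel uses the same segmenter with a
higher default factor (12×) plus 20–300 ms duration bounds: the backpack
still hears the juvenile at roughly −20 dB, and the higher threshold
rejects that bleed-through while the wearer's calls sit far above it.

Bout assembly chains syllables while the silent gap is strictly below
350 ms (a gap of *at least* 350 ms ends the song) and keeps chains whose
span — first onset to last offset — is *at least* 400 ms; both boundaries
are closed to match the "at least" phrasing of the rules. A call counts as
practice-related iff its **onset** lies in a bout window; the call may
outlast the song. An introductory-note exclusion is not applied by
default: the rule has no operational definition in the source procedure,
so the literal pipeline is the reproducible default.

Segmentation quality is scored by one-to-one greedy onset matching within
a tolerance (10 ms in the test gate): precision = matched/predicted (zero
when nothing is predicted), recall = matched/truth. On default-condition
synthetic sessions the gate is precision ≥ 0.80 and recall ≥ 0.68 — the
quality thresholds used to accept per-bird segmentation networks in the
recording workflow this package mirrors. Recall below 1.0 on synthetic
sessions comes almost entirely from calls that overlap a syllable and merge
into a single envelope run.

## Interaction statistics

`call_ratio` divides in-song call onsets by the summed bout spans. The
denominator uses bout windows (first onset to last offset, gaps included);
an alternative reading — singing time excluding gaps — would change the
scale but not the trend structure, and the window reading matches the
definition of the attribution window.

`development_trend` is OLS of call ratio on age in days post-hatch
(scipy `linregress`), reporting slope, intercept, R², F (the squared slope
t), the two-sided slope p, and the slope's t-based confidence interval. A
constant response returns a zero slope with R² = 0; constant age is
reported as a singular fit rather than an error.

`learner_threshold(mean, se)` returns `mean + 1.96·se` rounded to one
decimal — the upper 95% normal confidence bound of untutored-bird song
similarity (the printed inputs 32.023 ± 4.44% give 40.7%). Classification
is strict: a bird is a good learner iff its similarity *exceeds* the
threshold; a tie is poor, because the threshold is an upper confidence
bound on "no learning". Similarity scores themselves are external inputs;
this package does not compute spectral similarity.

Post-call snippets start at the call **offset** by default (the rule
"directly after the call" does not anchor to onset or offset; the anchor is
a config option) and run 300 ms, clipped at the bout end (clipped snippets
are flagged short). The matched control applies the same within-bout
offset to the nearest-in-time call-free bout long enough to host it, with
seedable random tie-breaking.

## Intracellular statistics

Spikes are upward crossings of baseline + 15 mV, time-stamped at the
crossing sample, with a 1 ms refractory merge (the spike-time anchor is
otherwise unspecified; the crossing sample is reproducible and
sample-rate-independent to within one sample). The analysis window is the
call padded by 50 ms for delayed auditory responses; the silence window has
equal length and ends 50 ms before call onset so the two never overlap.

**Spiking precision.** The observed statistic D_obs is the mean absolute
latency difference over all spike pairs from *distinct* trials within the
window (within-trial pairs are excluded — they carry ISI information, not
stimulus locking). The null is built by 1000 independent per-trial uniform
circular shifts of the spike times within the window: this preserves
per-trial counts and ISI structure while destroying stimulus alignment. A
label-reassignment shuffle that keeps absolute spike times cannot destroy
time-locking and was therefore rejected; a per-trial ISI-permutation
shuffle is available behind `shuffle_method="isi"`. The cell is responsive
when D_obs falls below the null's 5th percentile (one-sided — "more precise
than chance"; a two-sided option exists), and the reported score is
`(mean(null) − D_obs)/sd(null)`, approximately 0 under the null and
positive for precise cells. Cells with fewer than two spiking trials
return an absent result, never zero. The same statistic applied to the
silence window provides each cell's baseline precision.

**Subthreshold extraction.** Every maximal run of samples at or above the
threshold level is replaced, from the last sub-level sample before it to
the first sub-level sample after it, by linear interpolation between those
anchors; overlapping cuts merge into one segment because they form one
maximal run. Runs touching a trace boundary are filled from the single
available anchor and flagged. The clipped trace provably never exceeds the
threshold level outside flagged boundary segments.

**Correlation and Δ subthreshold.** Zero-lag Pearson correlation is
computed for every unordered trial pair within the window and averaged;
zero-variance traces are skipped with the pair count reported.
Δ subthreshold is the per-trial difference of window means
(analysis − silence), averaged over trials. Because the analysis window
includes the 50 ms pad, a boxcar deflection spanning only the call is
diluted by duration/(duration + 50 ms) in the estimate.

**Perturbation responsiveness.** Per perturbed rendition, Δspikes is the
epoch count minus the mean epoch count of unperturbed renditions. The
control distribution is built leave-one-out over the unperturbed
renditions (each against the mean of the others) — the procedure text says
only that the control is "the difference during unperturbed renditions";
leave-one-out is the construction that uses every rendition symmetrically
without reusing the tested value. The confidence interval is control mean
± 1.96 control SD; perfectly stereotyped renditions give a degenerate
[0, 0] interval, so any nonzero Δ is flagged, and zero is not — matching
the adult reference behavior (Δ = 0 ± 0). Subthreshold flags require an
externally supplied adult maximum |Δ| (mV); that value belongs to a
reference dataset and is deliberately a required config input, not a
default.

## Extracellular statistics

QC keeps a unit iff ISI-violation index ≤ 0.25 AND amplitude cutoff < 0.3
AND presence ratio > 0.90; a missing metric excludes with reason
`missing_metric`. The printed inclusion sentence reads "isi > 0.25", which
as written would *keep* poorly isolated units; the standard reading
(exclude above 0.25) is the default and the literal one is available
behind `qc_isi_literal` with a warning. Spontaneous rate is measured over
inter-stimulus silence (stimulus windows plus pad excised from spikes and
time base); QC-passing units are classed projection iff that rate is
≤ 2 Hz (boundary inclusive, per the stated rule). The PSTH conserves
counts exactly (its bins partition the window). The population summary
reuses the intracellular windows, firing-rate and precision machinery on
stimulus-aligned spike trains under the playback schedule (one call every
1.5 s, 60+ trials).

## Statistical wrappers

Rank-sum comparisons are exact by enumeration when the combined sample is
≤ 20 and tie-free, and midrank/normal-approximate otherwise; constant
pooled data returns p = 1 with a warning. Fisher's 2×2 test is the
two-sided exact hypergeometric sum. The nested mixed model
`response ~ 1 + condition + (1 | outer) + (1 | outer:inner)` is fitted by
maximum likelihood with statsmodels MixedLM (random intercept for the
outer group, a variance component for inner-nested-in-outer), reporting
the Wald two-sided p for the condition effect and the three variance
components. Optimization falls back from L-BFGS to CG to Powell on
ill-conditioned Hessians. A singular nesting — one observation per inner
group — makes the inner component unidentifiable; the fit falls back to
the outer-only model with a warning and a `fallback` flag. No
multiple-testing correction is applied anywhere; p values are reported
unadjusted. On the 4-bird × 5-cell × 10-observation null design the Wald
test's type-I error measures ≈ 0.05 (the acceptance suite asserts
[0.03, 0.08] over 1000 replicates).

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes with known ground
truth, emulating the *statistical* structure the analyses assume — not
realistic zebra finch acoustics or biophysics.

**Audio.** Syllables are 1–8 kHz band-limited noise bursts and calls short
harmonic stacks, both with 5 ms cosine ramps (spectral realism is
irrelevant to an envelope segmenter; ramps avoid clicks). Box-channel
syllable RMS is 0.25, call RMS 0.30 on the backpack and half that on the
box; the backpack renders juvenile sounds at −20 dB, emulating its bias
toward the wearer. The noise floor is Gaussian with RMS 0.005. Sessions
place bouts by a Poisson process (default 4/min) with ≥ 0.5 s separation
so the assembly rule keeps them distinct; syllable durations ~N(90, 20) ms
and gaps ~N(80, 20) ms truncated to [20, 300] ms; female call onsets
follow an inhomogeneous Poisson process — the in-song rate
`max(0, base + slope·(age − age0))` inside bout windows (default base
0.5 Hz) and a low out-of-song rate (0.02 Hz) elsewhere. The development
generator emits event tables without rendering audio; the statistical
structure is identical and the trend suites stay cheap. The tutor motif is
rendered at the printed durations, gaps and pitches as tone complexes.

**Intracellular trials.** Each trial is baseline (−70 mV) + a shared
stimulus-locked component + private noise + spikes, at a 20 kHz default
digitization (the recording hardware's rate is not part of the procedure
description; 20 kHz resolves 2 ms-wide spikes comfortably). Private noise
is an exponentially correlated (Ornstein–Uhlenbeck) process, correlation
time 10 ms, matching smooth membrane-potential fluctuations. The shared
component is one fixed smooth waveform per seed, normalized to exactly
unit sample SD inside the stimulus window and scaled to carry a fraction ρ
of the in-window subthreshold variance; the private noise is likewise
rescaled so its in-window sample SD is exact. Both normalizations exist
for the same reason: ρ is defined on in-window sample variances, making
the expected zero-lag pairwise correlation equal ρ without a
finite-window bias (an OU process's sample variance over a 150 ms window
systematically underestimates its stationary variance). Locked spikes are
Poisson-many per trial at template latencies jittered by σ (default 2 ms);
the template latencies fall inside one short burst span (default 30 ms) —
an evoked response is a latency-concentrated burst, and a template
scattered across the whole window would emulate unlocked multi-event
firing instead. Spike waveforms are Gaussian bumps of height ≥ 45 mV
(the ≥ 30 mV inclusion rule guarantees 15 mV threshold detection is
exhaustive), with a 2 ms minimum separation so ground-truth counts match
detected counts exactly.

**Singing perturbations.** Unperturbed renditions share one smooth motif
pattern (SD 3.5–5 mV, clipped to ±10 mV so the pattern itself never
crosses spike threshold) plus fixed template spike latencies; perturbed
renditions add a boxcar deflection and/or an exact number of extra spikes
at fixed latencies inside the call epoch. Note that a large deflection can
legitimately push the pattern over threshold and add further spikes — the
`extra_spikes`-exact guarantees hold at zero deflection.

**Populations.** Projection-class units draw spontaneous rates from
[0.3, 1.8] Hz, interneurons [3, 12] Hz; playback responses are a rate gain
inside the call + 50 ms window plus optional locked spikes at per-unit
fixed latencies. QC metrics are drawn in the passing range, with named
per-unit failures forced across their thresholds on request.

Every generator is deterministic under a fixed seed. What passing tests on
these generators show is that the *computations* are correct and calibrated
under the assumed statistical structure; they do not show robustness to
real-data pathologies the generators omit — cage noise transients,
overlapping vocalizations beyond simple superposition, electrode drift,
bridge-balance artifacts, spike-waveform variability, or non-stationary
firing rates.

## Problem sizes in the verification suites

The calibration suites use: 200 null cells and 100 locked-cell simulations
(15 trials each, 1000 permutations) for the permutation test; four
33-trial sets (2112 pairs) for shared-fraction recovery; 100 replicate
birds × 20 ages (600 s sessions) for trend-CI coverage and 200 sessions
for call-ratio bias; three 60 s rendered sessions for the segmentation
gate; and 1000 null + 200 effect datasets (4 × 5 × 10 nested design) for
the mixed model. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping the full suite around a minute of
compute.

## Known limitations

- The envelope segmenter has no spectral discrimination: any loud sound in
  band is an "event". Channel attribution (box vs backpack) is the only
  mechanism separating juvenile from female vocalizations.
- Song-similarity scoring is consumed, never computed.
- The precision null's exact original shuffle construction is not restated
  in the procedure text; two defensible constructions are provided and
  neither is asserted as the original.
- Wald p values from ML mixed models are mildly anticonservative in very
  small designs; the calibration suite covers the design sizes used here,
  not arbitrary ones.
- The adult maximum |Δ subthreshold| reference is not shipped; analyses
  that need it must supply the value from their own adult dataset.
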