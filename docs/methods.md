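# Methods

This note documents the generative model, the analysis procedures, the
parameter choices that matter, and what the synthetic validation does and
does not establish about real data.

## Synthetic sessions

### Stimuli

Locally sparse noise on a 14 (elevation) × 22 (azimuth) grid of 5° squares;
grid cell centres run from azimuth 2.5°–107.5° and elevation −32.5°–+32.5°,
so both task locations (BR at (36°, −18°), TL at (93°, 18°)) fall inside the
grid. A new pattern appears every 0.3 s. Per pattern the number of
simultaneous squares is drawn as 6 + Binomial(4, 0.425), i.e. mean 7.7 with
support {6..10} and 2.5/97.5 percentiles at 6 and 10. Placement is greedy
rejection sampling: candidate cells not within the 3 s same-location
refractory are visited in random order and accepted when ≥25° (centre to
centre) from every square already placed in the pattern, restarting up to 40
times if the target count is not reached. Infeasible separation/count
combinations are rejected up front by a deterministic packing bound. Polarity
(black/white) is assigned uniformly per square.

### Trials and behaviour

Blocks alternate BR, TL, BR. Each trial is a delay drawn from
3 s + Exponential(mean 9 s) followed by a 1.6 s grating, then 1 s of
post-trial time. (The generative rule implies a mean delay of 12 s.) Catch
trials are converted from no-go trials only after at least ten go trials
since the previous catch or the block switch; because outcomes do not exist
at generation time, go trials stand in for "rewarded" trials in the spacing
rule — under the default 85% hit rate the two notions almost coincide.

The behavioural profile is parameterised per block type as focal or divided
(default: focal in BR blocks, divided in TL blocks, the configuration used
for the neural analyses). Defaults: hit rate 0.85, FA rate 0.15, go reaction
times Normal(0.50 s, 0.10 s) truncated to [0.20, 1.55] s. Catch trials in
focal blocks are missed with probability 0.55 and otherwise answered with
reaction times shifted +0.60 s; in divided blocks they behave like go trials
(miss 0.10). A 2% rate of pre-onset spout hits exercises the reaction-time
exclusion rule.

Running is an alternating bout process: stationary epochs of exponential
mean 5 s (speed ≈ 0) and running epochs of mean 8 s with a per-bout speed
drawn uniformly from 2–15 cm/s, giving both states ample occupancy and
frequent onsets after ≥1 s of stillness. Pupil position jitters smoothly
(SD ≈ 1.5°) with occasional >10° saccade excursions, and the eye-image
correlation statistic carries rare closure artifacts, so the validity
pipeline has real work to do.

### Neurons

Each neuron has a rotated-Gaussian RF of a single polarity (ON or OFF),
σ_major uniform 5–8°, aspect 1–1.6, and response amplitude uniform 0.4–0.8
ΔF/F per event at the RF centre. Every polarity-matched square contributes an
impulse of Gaussian-weighted drive, scaled by the attentional gain of the
block the square falls in and by the running gain when speed ≥ 1 cm/s at
onset. The attentional gain applies only in focally attended blocks and only
to neurons whose true two-sigma ellipse overlaps the attended disk; divided
blocks apply no gain. This makes the noiseless algebra exact: a gain *g*
yields an index of (g − 1)/(g + 1) for attended-location neurons.

Impulses are convolved with a single-exponential calcium kernel (decay
0.6 s, GCaMP6f-like; amplitude 1 ΔF/F per unit drive — a one-parameter
kernel keeps recovery analytic). Fluorescence is
F = F₀(t)·(1 + ΔF/F) + noise, with F₀(t) a slow sinusoid (amplitude 5%,
period 600 s) plus a linear trend (6% over the session) on a per-neuron base
of 80–120 a.u., additive Gaussian noise of SD 0.08·F₀ base, and rectification
at 0. The drift timescale is chosen as slow photobleaching-type drift, long
relative to the 155 s F₀ chunks.

Neuron identities are positional and persist across sessions generated for
the same cohort, standing in for cross-day cell matching.

## Analysis

* **F₀ / ΔF/F₀.** Chunks of 2000 frames every 500 frames; within each chunk
  the mode of a diffusion-KDE density (DCT-based, plug-in bandwidth by
  fixed-point iteration, 2¹² grid over the padded data range; Silverman
  fallback if the fixed point fails). The plug-in functionals are evaluated
  on the first 512 DCT coefficients — higher frequencies of a 2000-sample
  histogram are noise and do not move the bandwidth. Cubic spline through the
  chunk modes, constant extrapolation beyond the first/last chunk centres.
  The padded-range grid makes the estimator exactly translation-covariant,
  hence F₀(F + c) = F₀(F) + c.
* **Running speed.** Savitzky–Golay, window = nearest odd frame count
  spanning 500 ms (7 frames at 12.85 Hz), polynomial order 3 (preserves bout
  shape).
* **Validity.** Eye-closure frames: image correlation below the median by
  more than 5.5 SD. RF analyses additionally exclude frames with >10° pupil
  deviation in either axis. The two criteria are independent and
  order-free.
* **RF mapping.** Event positions are shifted by the concurrent pupil
  deviation and snapped to the nearest grid cell; events on invalid frames
  are dropped. The onset response is the mean ΔF/F over 7 frames (~0–0.5 s)
  from the onset frame minus the median over the 6 preceding frames
  (~470 ms). Subfields: per location and polarity (≥3 repetitions), a
  two-sided Wilcoxon rank-sum of that location's responses against the
  pooled responses of all other locations of the same polarity (vectorised
  tie-corrected normal approximation), Šidák-corrected over the tested
  family (≤308 per polarity); mask = corrected p < 0.05 AND positive median.
  Cells with both ON and OFF subfields are excluded from fitting. The
  rotated-Gaussian fit runs on the outside-mean-subtracted median map,
  initialised from masked-map moments, bounded (centre within grid ±10°,
  σ ∈ [1°, 60°]); σ at the bound or non-convergence marks the fit failed.
  σ_major ≥ σ_minor is enforced by swapping, with the angle wrapped to
  (−π/2, π/2].
* **Ellipse–disk distance.** D = s − r, where s is the distance from the
  disk centre to the nearest point of the two-sigma ellipse boundary
  (dense sampling + bounded 1-D refinement), negated when the disk centre
  lies inside the ellipse. The negation makes D ≤ 0 equivalent to
  overlap/containment/tangency in every configuration, including a disk
  strictly containing its centre inside a large ellipse; the brute-force
  reference sampler uses the identical convention.
* **Response samples.** Per RF repetition, ΔF/F summed over the 7-frame
  window [peak − 1, peak + 5] minus 7 × the pre-onset baseline median; the
  peak offset is fixed per neuron from the maximum-response (RF-centre)
  stimulus. Indices (R_A − R_B)/(R_A + R_B) use per-condition means
  (with equal repetition counts, sums and means give the same index; means
  are robust to small imbalances). An index is undefined when either
  condition has fewer than 5 samples or the denominator is ≤ 0
  (net-negative responders are excluded). Bootstrap significance: both
  sides resampled with replacement (default 10,000 replicates; the session
  pipeline uses 2,000 for throughput), one-sided violation fraction doubled
  for two-sided reporting. Per-neuron bootstrap seeds are spawned
  deterministically from the session seed.
* **Reliability splits.** Halves are defined per stimulus location by onset
  order (odd counts put the extra onset in the first half). Within-block:
  eq.-(b) indices for each half of blocks 1 and 3, with R_out the first
  (block 1) or second (block 3) half of block 2 — the block-2 halves control
  for slow time-dependent changes. Between-block: R_in from the second half
  of block 1 and the first half of block 3, R_out from the first/second half
  of block 2. Running reliability compares the running index computed within
  block 1 vs block 3.
* **Hierarchical statistics.** Bootstrap replicates resample animals with
  replacement, then units within each drawn animal (same count as observed
  by default; configurable); percentile CIs. The paired test randomly flips
  each drawn pair's order inside every replicate and counts replicates at
  least as extreme as the observed statistic, two-sided by absolute value.
  Permutation tests enumerate all arrangements when there are ≤10⁵ of them.
  BH adjustment delegates to the standard step-up implementation.

## Validation experiments and problem sizes

The recovery experiments (in `attnrun.recovery`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: 200 neurons ×
3 × 18 trials for gain recovery; 100 neurons × 600 s passive mapping for RF
recovery; 500 null neurons for the familywise error rate; 500 null datasets
for each test-calibration check (bootstrap 2,000 replicates, hierarchical
test 1,000); 100 seeds × 450 trials (≈10 catch trials per block, the regime
the classification is designed for) for the focal-classification rate; and
200 neurons × 3 × 36 trials for the reliability analyses, where the longer
blocks give each half-block enough repetitions that measurement noise does
not attenuate the half-to-half correlations. Reliability experiments draw
per-neuron attentional gains uniformly from 1.2–2.5 (resampled per block for
the null variant) and running gains from 1.2–3.0, since reliability is only
measurable when the modulated quantity varies across neurons.

## What passing does and does not show

The generator reproduces the task's timing, stimulus constraints and
state-dependent gain structure with known ground truth, so the validation
demonstrates that the analysis chain is correct and calibrated: it recovers
multiplicative gains through the full pipeline (baseline estimation, RF
detection, window extraction), holds nominal false-positive rates, and
dissociates stable from unstable modulation. It does not emulate several
properties of real recordings — neuropil contamination, correlated
population variability, non-exponential indicator dynamics, eye-position
statistics tied to behaviour, or drifting RFs — so passing here does not by
itself certify performance on those fronts.

## Known limitations

* The forward model applies gains at event onset only; a state change inside
  a response window is not fractionally weighted (windows are 0.5 s versus
  multi-second bouts, so the effect is small but visible as a ≈+0.01–0.02
  bias of the recovered running index).
* Because stimulation is continuous, tonic evoked activity leaks into the
  chunk-mode F₀, and it leaks slightly more in high-gain blocks; dividing by
  a differentially inflated F₀ attenuates the recovered attention index by
  up to ≈0.03 depending on the population's amplitudes. Real recordings with
  sparser firing sit closer to the analytic value.
* The rank-sum reference ("all other locations of the same polarity")
  slightly deflates sensitivity for neurons whose RF spans many cells, since
  the reference pool then contains driven samples.
* `fit_pupil_ellipse` consumes binary masks; video segmentation upstream of
  the mask is out of scope.
* The hierarchical bootstrap draws as many units per resampled animal as
  observed; `n_units` exposes the alternative but no guidance is offered.
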