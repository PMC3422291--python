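# Methods

## Scope

`tfsldecode` implements an EEG preference-decoding chain: epoched
multichannel trials → band-pass filtering → time-delay embedding →
synchronization likelihood (SL) per electrode pair, time window and band →
per-electrode TFSL features → F-ratio ranking → sequential forward
selection (SFS) wrapped around a small Levenberg–Marquardt-trained network
→ pooled (CGM) / per-participant (PAM) evaluation, temporal decoding
profiles and quasi-randomization chance estimation.  A synthetic generator
with known class-dependent coupling provides ground truth for every stage.

## Preprocessing

* Re-referencing subtracts the average of two mastoid channels sample-wise
  and drops them.
* Band-pass filtering uses a 10th-order Butterworth prototype
  (second-order sections; the realized band-pass has 20 poles), applied
  forward–backward by default.  Zero-phase filtering is deliberate: the
  50 ms feature windows are interpreted as post-onset latencies and a
  causal filter's group delay would shift them.  A causal single-pass
  option (`zero_phase=False`) is retained.
* Epochs run 1 s from each face onset plus a *tail* of
  max<sub>bands</sub> (m−1)·L = 175 samples at 512 Hz, so embedding
  vectors anchored anywhere inside the analysis second are complete; the
  delta band (span 175 samples) would otherwise have no valid anchors in
  late windows.
* The 20-window grid uses boundaries round(k·0.05·fs) with half-open
  intervals: at 512 Hz, alternating 26/25-sample windows that tile
  [0, 512) exactly.  Indexing is 0-based and half-open throughout.
* Labelling: a final choice of face 1 labels that trial's face-1 epoch
  *chosen* and its face-2 epoch *not chosen*, and vice versa.  No baseline
  correction is applied; the SL recurrence construction is invariant to
  amplitude offset and scale per channel, so it would be inert anyway.

## Synchronization likelihood

Per band, each channel is embedded with the band's lag L and dimension m
(delta 25/8, theta 21/7, alpha 14/6, beta 6/8, gamma-1 5/5, gamma-2 3/6 —
lag shrinking with frequency so a vector spans a few cycles).  At each
anchor (samples 0, 25, …, 475 by default; one per 50 ms window):

1. Candidates are all embedded vectors of the epoch (tail included) at
   `candidate_shift` spacing.  Candidates within the Theiler window —
   (m−1)·L samples of the anchor, anchor included — are excluded to keep
   trivially autocorrelated neighbours out of the recurrence sets.
2. The critical distance ε is the ⌈p_ref·N⌉-th order statistic of the
   Euclidean distances from the anchor state to the N valid candidates
   (p_ref = 0.1), i.e. the smallest radius capturing a fraction p_ref of
   them.  Ties are included in the recurrence set, so |R| ≥ ⌈p_ref·N⌉.
3. The directed SL is |R_x ∩ R_y| / |R_x|; the reported pair value is the
   mean of the two directions (features are undirected).
4. The per-electrode feature is the mean pair SL over the electrode's
   n−1 partners; with the default one-anchor-per-window layout window k
   takes anchor k's value, and if a reconfiguration puts several anchors
   into one window their values are averaged.

The hot path vectorizes this per anchor: one distance matrix per channel,
ε by partition, boolean recurrence masks, and pair intersection counts as
a mask–mask matrix product.  A brute-force O(N²) implementation with
explicit sets reproduces it bit-for-bit in the test suite.

### Independence baseline and its limits

For exchangeable signals (white noise), fixing the recurrence fraction at
p_ref per anchor makes the expected SL between independent channels equal
p_ref up to the ceiling in ⌈p_ref·N⌉ (measured: 0.1017 ± 0.003 at N ≈ 370).
This is the property the estimator's interpretation rests on, and it is
what the acceptance baseline (`independence_baseline`) measures.

Band-pass-filtered noise on a 1 s epoch is *not* exchangeable: two
independent same-band signals both recur preferentially at lags where the
oscillatory phase realigns with the anchor (≈ every cycle, decaying over
the coherence time ≈ fs/bandwidth).  Since both recurrence combs are
anchored at the same time point, their intersection is enriched and the
mean SL between independent filtered channels sits well above p_ref
(≈ 0.18–0.33 depending on band and Theiler width; for the alpha band the
bias only vanishes for candidates ≳ 300 samples from the anchor, more than
a 1 s epoch can spare).  No affordable Theiler window removes it, so the
package treats filtered-noise SL as a *relative* quantity: class contrasts
and F-ratios are unaffected (both classes share the bias), but absolute SL
values in band-filtered data should not be read against the 0.1 baseline.
`independence_baseline(filtered=True)` exposes the biased variant for
inspection.

## Synthetic data

The generator emulates the recording conditions the pipeline targets:
64 channels (configurable) at 512 Hz, 1 s epochs plus the 175-sample
embedding tail, two classes.

* Background: independent spectrally shaped Gaussian noise per channel
  (FFT-filtered to a 1/f<sup>α</sup> power spectrum, α = 1 by default),
  unit RMS.  Independence across channels keeps non-effect pairs at the
  estimator's baseline.
* Effect: per chosen trial, one shared band-limited Gaussian driver
  realization (unit RMS) is additively mixed with coefficient κ into the
  effect electrodes, only inside the effect windows, with 10 ms cosine
  ramps at the window edges to avoid spectral splatter.  κ = 1 therefore
  means driver amplitude ≈ background RMS ("strong" coupling).  A shared
  additive driver creates generalized synchronization detectable by SL
  without committing to a specific nonlinear map.  Not-chosen trials
  receive no driver (a reduced κ is configurable).
* Regimes: a fixed electrode set shared by all participants (the pooled
  CGM story), or an independent random set per participant
  (`effect_electrodes=<int>`, the idiosyncratic PAM story).
* Labels realize exactly round(n·class_balance) chosen trials per
  participant, shuffled; generation is bit-reproducible from (config,
  seed), and driver draws are burned for no-driver trials so the noise
  background is identical across κ settings of the same seed.

What the generator does **not** emulate: volume conduction and a forward
model (no spatially correlated background), ocular/muscle artifacts,
event-related potentials, or realistic 1/f deviations.  Passing tests
therefore show the *pipeline* recovers known coupling under clean
conditions; they do not certify performance on real recordings.

## F-ratio and profiles

FR = [(μ₁−μ̄)² + (μ₂−μ̄)²] / [(s₁²+s₂²)/2] with unbiased within-class
variances and sample variance (denominator 1) over the two class means —
the "population" convention is available and halves every score without
changing ranks.  Both-zero within-variance with separated means returns
+inf with a warning.  Ranking is descending with ties broken by feature-id
order (stable argsort), so results are reproducible.  Temporal profiles
average the top-300 F-ratios either cumulatively (windows 1..k; 384
features at the first step in the full configuration) or per window; when
fewer than k features exist all are averaged (with a warning).  Scalp maps
average F-ratios over bands and a window range per electrode.

## Decoder

Two-layer perceptron: 16 tan-sigmoid hidden units, linear outputs, one-hot
targets, MSE loss.  Levenberg–Marquardt: solve (JᵀJ + λI)δ = −Jᵀr with the
analytic Jacobian; λ starts at 1e−3, ÷10 on an accepted step, ×10 on a
rejected one, abort above 1e10; stop at MSE ≤ 1e−5 or 100 accepted epochs.
Inputs are z-scored with training-set statistics stored on the model
(SL features are bounded but standardization stabilizes LM; toggleable).
Weights initialize uniformly in ±1/√fan-in from the seed, so training is
deterministic given (data, seed).  The output layer defaults to one unit
per class (2); a fixed width of 4 is available, surplus units trained
toward zero and ignored at prediction.  Prediction is argmax over the
class units, exact ties to the first class.

When a validation set is supplied, training tracks validation MSE per
accepted epoch, stops after 6 consecutive increases, and restores the
best-validation weights — the validation partition's role in the 60/20/20
protocol.

## Selection and evaluation protocols

Per repetition of the decoding protocol: a fresh stratified 60/20/20
split; F-ratio ranking on the training partition only; SFS adds features
in rank order, retraining the decoder after each addition, and stops when
the selection score fails to improve for `patience` consecutive additions
(default 1, literal "stop at first non-improvement"); the best-scoring
prefix is kept and its accuracy on the untouched test partition is
reported.  The selection score defaults to the *validation* accuracy:
scoring selection on the test partition leaks information into the
reported accuracy, so the leaky variant is available explicitly as
`scoring="test"` but is not the default.  SFS is re-run in every
repetition rather than once per dataset, keeping each repetition's test
partition untouched by any selection step.

CGM pools all trials into one decoder and reports SD across repetitions;
PAM runs the whole protocol per participant and reports the mean and SD
across participants.  Participants below a minimum trial count are
skipped with a warning.

Quasi-randomization chance: per run, flip the labels of a uniformly
random half of the trials seen during training (train + validation
partitions, so early stopping cannot re-import label information), rank
and select top-k features under the flipped labels, train, and score the
untouched test partition against the true labels.  Flipping half the
labels destroys the class signal in expectation, so the mean over runs
estimates the decoder's operational chance level; flipping all labels
inverts the decision rule and serves as a symmetry check.

## Numerical and degenerate-input choices

* Distances are Euclidean; ε uses `np.partition` (exact order statistic).
* Anchors must coincide with candidate positions (anchor_shift a multiple
  of candidate_shift), else rejected.
* SL values are clamped to [0, 1]; the SL matrix diagonal is exactly 1.
* Stratified splits keep class ratios within ±1 trial; a class too small
  for a split part is named in the error.  k-fold with k equal to the
  trial count degrades to leave-one-out.
* Single-repetition evaluations report SD = 0.

## Problem sizes

The test suite and acceptance script run desk-scale configurations chosen
to preserve the structure of the full 64-channel problem: 16 channels /
200 trials for the chance and recovery experiments, 6–8 channels for
profile and scope experiments, 2 trials at the full 64-channel montage for
the feature-count check, and 20 noise realizations × 20 anchors for the
baseline.  These sizes are the package's standing demonstration
conditions; the algorithms themselves have no special-casing by size.

## Known limitations

* Absolute SL in band-filtered data is biased above p_ref on 1 s epochs
  (see above); only contrasts are interpretable.
* The per-electrode aggregation (mean over partners) is one of several
  defensible reductions of pair SL to electrode features.
* LM training is exact-Jacobian and dense: fine for dozens of selected
  features, not intended for thousands.
* The generator's shared-driver coupling is additive; strongly nonlinear
  generalized synchronization is represented only insofar as SL detects
  state-space recurrence overlap.
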