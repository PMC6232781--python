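# Methods

This document describes the model and procedure implemented by `headbci`, the
rationale for every default parameter, the design and limits of the synthetic
data generator, and the numerical choices made along the way.

## 1. Problem and experimental protocol

A participant wearing a 32-channel EEG cap and a head-mounted gyroscope makes
self-paced head rotations from center to the left or right, holding still
between movements. The analysis goal is single-trial prediction: given one
250 ms window of EEG that ends at least 188 ms *before* a rotation starts,
classify it as preceding a left rotation, preceding a right rotation, or
preceding no rotation.

The per-session procedure is:

1. record blocks of continuous EEG (512 Hz) and yaw velocity (128 Hz);
2. detect rotation onsets and directions from the gyroscope;
3. clean the EEG and bring it onto the 128 Hz analysis grid;
4. cut labeled windows, balance the classes, split the data;
5. train a per-participant network three times; report test accuracy against
   a binomial chance bound;
6. replay the held-out stream frame by frame through the fitted network and
   average the probability traces around the held-out onsets;
7. compute the pre-onset left-minus-right voltage topography.

## 2. Onset detection (`headbci.imu`)

* **Threshold** — 3× the standard deviation of a stationary segment of the
  velocity trace. With `stationary_segment="auto"` the quietest 2 s chunk of
  the recording is used, which the generator guarantees exists (the first
  ~3 s of every block are movement-free). A segment with zero variance or
  shorter than the sustain window is rejected as an error rather than
  producing a meaningless threshold.
* **Sustain rule** — velocity must exceed the threshold for a full 125 ms
  window; the onset is the first sample of that window and the offset the
  first sample of the first fully sub-threshold window. This rejects brief
  noise spikes while costing no onset latency (the onset is placed at the
  *start* of the sustained excursion).
* **Direction** — the sign of velocity at onset (right positive).
* **Center-outward filtering** — integrated yaw position at each onset, with a
  5° tolerance, separates rotations launched from center (scored) from return
  movements and chained rotations (excluded from scoring, but still masked for
  no-rotation sampling and frame labeling).

With the default kinematics the detector recovers planted onsets with a 95th
percentile error below 2 IMU frames (≈ 16 ms), which the test suite asserts.

## 3. Preprocessing (`headbci.preprocess`)

* **Band-pass 0.75–8 Hz**, zero-phase (forward–backward 4th-order
  Butterworth), applied at the native 512 Hz. The pre-movement signature is a
  slow ramp, so the band keeps the low-frequency content while removing drift
  (high-pass) and oscillatory/muscle activity (low-pass). The 8 Hz edge also
  serves as the anti-alias filter for the decimation that follows.
* **Downsampling to 128 Hz** by polyphase resampling, aligning the EEG with
  the IMU frame grid: one frame = 7.8125 ms.
* **Rejection threshold 80 units** — an epoch is discarded if any sample on
  any channel has absolute amplitude strictly above 80. Rejection is a
  *selection* decision: the continuous record is never modified, so the
  streaming stage sees every frame.

Zero-phase filtering is non-causal: it smears the planted ramp backwards in
time by more than the 1 s onset-locked analysis window (the high-pass edge at
0.75 Hz rings with a ~1.3 s period). Consequences for interpretation are
discussed in §7.

## 4. Windows, balancing, split (`headbci.epochs`)

* **Rotation windows** — 7 windows of 250 ms per rotation, start offsets
  evenly spaced so the union spans exactly [−488, −188] ms relative to onset;
  the middle window is centered at −338 ms. At 128 Hz a window is 32 frames ×
  32 channels = **1024 features**, flattened channel-major.
* **No-rotation windows** — sampled uniformly over the eligible start-frame
  grid; a start is eligible only if the window overlaps no detected movement
  (scored or not) and ends ≥ 1000 ms before every subsequent onset. By default
  14 no-rotation windows are sampled per rotation so that balancing never
  starves the "none" class. If the request cannot be met the sampler raises
  instead of silently relaxing the clearance.
* **Balancing** — all three classes are undersampled to min(n_left, n_right).
* **Split** — 72 % train / 18 % validation / 10 % test. The test set is one
  contiguous stream at the end of the last block (4 minutes of a 40-minute
  default session) so that streaming evaluation uses genuinely unseen,
  temporally separate data. All seven windows of a rotation share a group id
  and always land in the same partition; groups straddling the test boundary
  are dropped entirely. Train/validation assignment is randomized at the group
  level within each block.

## 5. Classifier (`headbci.model`)

A dense MLP: 1024 → 512 → 256 → 6 → 3.

* Hidden activations ReLU; 10 % inverted dropout on the first two hidden
  layers; L2 penalty 1e-4 on all weights; He initialization.
* **Output layer: three independent sigmoids**, not a softmax. The training
  loss is categorical cross-entropy computed on the sigmoid activations
  normalized inside the loss (p_k = a_k / Σa). Inference reports the *raw*
  sigmoid activations, which need not sum to one — a deliberate property for
  streaming, where a window far from anything seen in training can have all
  three probabilities low.
* Adam (lr 0.001, β₁ 0.9, β₂ 0.999), 150 epochs, batch size 150. Inputs are
  standardized per feature with training-set statistics (the same affine map
  at train and inference, so a single streaming window is well defined).
* Parameter count: (1024·512+512) + (512·256+256) + (256·6+6) + (6·3+3) =
  **657,691**.
* Each participant is fitted **three times** with different seeds; accuracy is
  reported per repetition with mean and standard deviation.

The network is implemented directly in NumPy. Gradient correctness is attested
behaviorally in the test suite: loss decreases, separable data is learned to
high accuracy, pure noise stays at chance, and training is bit-reproducible
per seed.

**Chance bound** — for a balanced test set of n trials and c classes, the
chance level is the smallest k with BinomialCDF(k; n, 1/c) ≥ 0.95, reported as
k/n. A random classifier exceeds this accuracy with probability ≤ 0.05. For
n = 330, c = 3 the bound is 124/330 ≈ 37.6 %, i.e. 38 %.

## 6. Streaming and topography (`headbci.streaming`, `headbci.erp`)

The fitted network is slid across the continuous test stream in 250 ms windows
advanced one frame at a time — one probability triple every 7.8125 ms; a
240 s stream yields 30,689 positions. Probabilities are indexed at the window
*center*; the 125 ms availability delay of a live system is carried as
metadata, never silently shifted. Traces are averaged time-locked to detected
onsets (mean ± sd over events, per direction).

Pre-onset ERPs average the 1000 ms before each scored onset, baselined on the
first three frames of that second. The lateralization map is the
left-minus-right per-electrode mean with equal event counts per side (seeded
subsampling), averaged within and then across participants so each participant
weighs equally.

## 7. Synthetic generator: design, calibration, realism

`headbci.synth` plants a known signature so the pipeline's conclusions can be
checked against ground truth:

* **Schedule** — onsets separated by a reserved quiet interval (2 s minimum
  gap + the full out-and-back movement) plus an exponential margin targeting
  6 rotations/min; directions are a fair coin.
* **IMU** — raised-cosine velocity pulses (outward at onset, return pulse of
  opposite sign after a 400 ms hold), peak 200 deg/s over 300 ms (~30°
  amplitude), plus 0.3 deg/s gyro noise. These are brisk but plausible head
  turns; the steep initial slope is what allows ≤ 2-frame onset recovery.
* **EEG** — pink (1/f) background noise, sd 6 units per channel; per event a
  linear ramp from 0 at onset−450 ms to −25 units at onset (decaying over the
  rotation) weighted over fronto-central sites (Cz maximum), plus a
  lateralized component of half the ramp amplitude whose hemispheric sign
  flips with direction; optional 3 Hz artifact bursts (peak 225 units) that
  the 80-unit rejection must catch.

Amplitude calibration was prescribed as part of the design, not tuned to test
outcomes: the planted signal-to-noise was set so that a *linear* reference
classifier (multinomial logistic regression) decodes the balanced window
classes at ≈ 0.98 — i.e. clearly above chance with headroom below the
rejection threshold (worst-case clean amplitude ≈ 43 < 80). The suite compares
the network against this independent oracle rather than against a tuned
constant.

Known limitations:

* The planted ramp is deterministic and identical across events; real
  readiness potentials vary in amplitude, latency and topography from trial
  to trial.
* Pink noise is spatially independent across channels; real EEG has strong
  spatial correlation (volume conduction), which would make both the
  classification problem and the topography statistics harder.
* The zero-phase filter makes information about an upcoming movement available
  earlier than any causal system could have it; the streaming tests therefore
  assert the *location of the P(none) dip* (inside the trained window band,
  roughly −0.55 to −0.15 s) rather than the first detectable deviation.
* The generator's "no-rotation" periods are genuinely stationary; real
  recordings contain postural drift, blinks and swallows that the rejection
  threshold only partially captures.

## 8. Problem sizes and runtimes

Defaults reproduce the full protocol geometry: 2 blocks × 20 min, ~120 rotations per
session, a 4-minute test stream, ~330 balanced test windows, 150 training
epochs × 3 repetitions. On one CPU that full configuration takes on the order
of 10–15 minutes per participant, dominated by training.

The test suite uses reduced but honest sizes: 200–600 s blocks, 20–60 training
epochs, 3 repetitions, and 10-seed pools for the negative controls (no planted
signal; no planted lateralization). The full suite runs in roughly 8 minutes
on one CPU; `scripts/acceptance.py` takes about one minute.

## 9. Numerical choices

* All randomness flows through `numpy.random.SeedSequence([seed, crc32(name)])`
  substreams, so stages are independently reproducible and insensitive to
  call order.
* Weights are float32 (BLAS speed); losses and metrics accumulate in float64.
* Sigmoids use `scipy.special.expit` (no overflow); the normalized-sigmoid
  cross-entropy clips activations to [1e-9, 1−1e-9].
* `chance_threshold` uses `scipy.stats.binom.ppf` with explicit CDF guards
  against edge rounding, and the test suite checks it against a brute-force
  CDF summation for every n ≤ 500 and c ∈ {2, 3, 4}.
* Sessions, epoch datasets and model checkpoints are stored as HDF5 plus
  TSV/JSON sidecars — self-describing, portable, and diff-friendly where
  text is feasible.
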