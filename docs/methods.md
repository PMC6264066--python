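# Methods

## Problem and approach

Children with ADHD move differently from typically developing peers —
more frequent and more intense fine and gross motor activity — and these
differences are measurable with wrist- and ankle-worn tri-axial
accelerometers during a normal school day.  `kinemap` implements an
end-to-end method that turns raw 10 Hz tri-axial recordings into an
objective subject-level score: the signal is decomposed relative to the
local gravity direction, encoded into orientation-invariant 28×28 binary
"acceleration images", classified image-by-image with a small CNN, and
aggregated into one decision per child.

## Signal model and decomposition

A body-worn accelerometer measures gravity plus movement acceleration in
sensor coordinates.  The gravity component for sample *i* is estimated by a
centered moving average over N + 1 = 51 samples (5.1 s at 10 Hz with
N = 50) — slow enough to track posture changes, long enough to average out
voluntary movement.  Movement acceleration is the raw sample minus this
estimate; it is then split into a vertical component (orthogonal projection
onto the gravity estimate, `a_v = (a_m·g/|g|²) g`) and the horizontal
residual `a_h = a_m − a_v`.  Only the two magnitudes |a_v| and |a_h|,
normalised by |g|, feed the encoder, which makes the representation
invariant to how the sensor was strapped on: a rigid rotation of the raw
series leaves the images bit-identical (asserted in the tests).

Numerical/edge choices:

* The first and last N/2 samples of each contiguous segment have no full
  filter window and are marked invalid — no padding, no truncated windows —
  so no image window ever rests on a biased gravity estimate.
* Timestamp gaps larger than 2 sample periods (sensor removed) split the
  recording into independently processed segments.
* A gravity-estimate norm below 0.1 g (free fall, corrupt data) marks the
  sample invalid rather than risking division by a near-zero norm.
* All internal math is in units of g; m/s² input is divided by 9.80665 at
  read time.

## Acceleration images

A 51-sample sliding window advancing by 25 samples (2.5 s) is encoded by
binning each sample at

    index = floor(1 + 9 · min(3, ratio)),   ratio = |a_v|/|g| or |a_h|/|g|

giving 1-based bins 1..28: one g of movement spans nine bins and everything
at or above 3 g lands in the saturation bin 28.  The pixel at
(row = horizontal bin, column = vertical bin) is set to 1; repeated hits
stay 1, so the image is a binary occupancy map of the window's intensity
signature.  A count-accumulating variant exists behind a non-default flag
for experimentation.  Binning uses the magnitude |a_v|, so upward and
downward accelerations share bins.  Window centers are anchored at the first index with full
window-plus-gravity support and advance on a fixed 25-sample grid.

## Classifier

The per-image classifier is a small CNN: three 3×3 same-padding
convolution blocks (8 → 16 → 32 channels, each with batch normalisation
and ReLU, 2×2/2 max-pooling after the first two), a fully connected layer
from 7·7·32 = 1568 features to 2 logits, and a softmax.  Class order is
fixed (index 0 = ADHD, 1 = control).  It is implemented directly in numpy
(im2col convolutions, float32 throughout): the network has ≈20k parameters
and binary 28×28 inputs, so CPU mini-batch SGD is entirely adequate, and
keeping the numerics in one place makes seeded runs bit-reproducible —
build, train and predict are deterministic functions of the seed.

Training defaults: SGD with momentum 0.9, learning rate 0.01, batch size
128, 10 epochs, no class reweighting (inverse-frequency weighting is
available behind a flag).  Per-image labels inherit the participant's
group.  Experiments in this package typically run 2–3 epochs: the training
loss on the synthetic cohorts plateaus within the first two epochs, and
the subject-level statistics are insensitive to further passes.

## Subject-level statistics

* **Frame counting** — disjoint runs of n = 20 consecutive images
  (52.5 s); a frame is positive when ≥ th images were classified
  ADHD-like.  Sweeping th = 1..20 gives each participant a vector of
  positive-frame *fractions* (fractions rather than raw counts, for
  comparability across session lengths; counts are available via flag).
  Group differences per threshold are tested with a pooled-variance
  two-sample t-test (Welch behind a flag; the test is unpaired because the
  decision statistic is defined per participant).  Perfectly separated
  groups (zero variance, different means) report the limiting p = 0;
  literally identical groups report p = 1.
* **Combined likelihood** — `cl = Σ_j (p_j(ADHD) − p_j(control))`
  over a participant's images, equal to `2·Σ p_ADHD − J` by the
  complement rule.  The participant is classified ADHD when cl > 0; the
  exact tie cl = 0 goes to control, the conservative choice for a
  screening statistic.  Image-level argmax ties likewise break to control.

## Evaluation schemas

* **Leave-one-participant-out**: one model per held-out child, trained on
  all other participants' images; the held-out child's id never appears in
  the training set (audited in the report).  The threshold-sweep test
  reuses the per-image labels from these same held-out predictions.
* **Temporal 4-fold**: each session is cut into 4 equal consecutive blocks
  (1.5 h of a 6 h school day); fold f holds out block f of *every*
  participant and trains on the rest.  Because every child contributes
  training data, this bounds generalisation optimistically.  The harness
  rotates all four blocks (true 4-fold); a `single_split` flag reproduces
  the one fixed consecutive train/validation split reading instead, using
  the last block.
* **Medicated transfer**: a single model trained on non-medicated ADHD +
  controls scores the medicated children, tabulating (id, SNAP score, cl,
  classified-as) to gauge how far medication shifts movement toward the
  control pattern.

All randomness (weight init, batch order, simulation) flows from one run
seed through `numpy.random.SeedSequence`, recorded in every report.

## Synthetic cohort

The study data behind the published results were never deposited, so the
package ships a generator whose defaults emulate the recording conditions:
10 Hz tri-axial sessions composed of

* a unit-norm gravity direction drifting as a small-step random walk
  (0.02 rad/s) — posture changes and strap creep;
* movement bursts: exponentially damped sinusoids (1–4 Hz, decay 0.2–0.6 s)
  with uniformly random 3-D direction, arriving as a Poisson process;
* white Gaussian noise (σ = 0.02 g).

The group contrast is purely kinematic.  Controls emit ~6 bursts/min with
log-normal peak amplitudes of median 0.45 g (mass below 0.8 g); ADHD-like
participants at full effect emit ~12/min with median 1.8 g (mass in the
1.3–2.8 g high-intensity region reported for ADHD movement).  A scalar
`effect_size` ∈ [0, 1] interpolates the ADHD parameters from the control
values (0 ⇒ the groups are generatively identical) to the full contrast;
medicated-group parameters sit 60% of the way back toward control by
default.  Gravity drift and noise never differ between groups, so a
classifier cannot succeed through orientation artifacts — and because the
encoding is rotation-invariant, rotating one group's raw data changes
nothing (asserted in the tests).

What the generator does *not* model: activity schedules (lessons vs
breaks), periodic gait, diurnal structure, sensor saturation, or any
biomechanical account of ADHD movement.  Passing the recovery experiments
therefore shows that the pipeline detects intensity/rate differences of
the configured kind — not that it would achieve the same numbers on real
school-day recordings.

## Experiment sizes

The packaged experiments use cohort sizes chosen to make the recovery and
calibration properties measurable with comfortable margins while keeping
a full run in the minutes range on one CPU core:

* strong-effect recovery: 8 ADHD/control pairs, 30-minute sessions
  (≈716 images per child), 3 training epochs — leave-one-out subject
  accuracy and the threshold sweep are evaluated on these 16 subjects;
* null calibration (chance band): 8 pairs, 10-minute sessions, 2 epochs;
* null sweep uniformity: 20 replicate cohorts of 3 pairs, 8-minute
  sessions, 2 epochs; the mid-threshold (th = 10) p-value per replicate is
  tested against uniformity with a Kolmogorov–Smirnov test.

At the null, leave-one-out subject accuracy is noisy and can sit below
0.5: holding out one child leaves the training classes imbalanced, which
biases the summed per-image scores of the held-out child toward the
opposite class.  At the 16-subject sizes above the measured accuracy stays
within the binomial chance band [0.25, 0.75]; with very small cohorts and
very short sessions the inversion can dominate, which is why the chance
band experiment uses the full 8-pair cohort.

## Known limitations

* The CNN is intentionally minimal; no augmentation, architecture search
  or GPU path.  Training cost grows linearly with images × epochs.
* Wrist and ankle are modelled and evaluated independently; there is no
  sensor fusion and no synchronisation across devices.
* The vertical magnitude loses the up/down sign; a signed-bin encoding
  would double the vertical information and is left as future work.
* Published subject-level outcome tables allow exact verification of the
  metric arithmetic, but the headline real-data results cannot be
  regenerated from signals because the recordings are unavailable; all
  signal-level claims are validated on the synthetic cohort only.
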