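# Methods

## The model

`boluseg` performs unsupervised segmentation of swallowed-bolus material and
post-swallow residue in videofluoroscopy (VFSS) frames by reconstruction-based
anomaly detection. A convolutional autoencoder f_theta is trained only on
frames that contain no bolus, minimising a reconstruction loss over the
training set; at inference, structures the model never saw — bolus, residue —
reconstruct poorly, and the per-pixel error map, thresholded, becomes a binary
segmentation.

The central design element is **positional encoding as input channels**. A
plain convolutional autoencoder is translation-equivariant: it learns what
tissue looks like, not where it belongs, and so tends to reconstruct a bolus
whose appearance resembles anatomy seen elsewhere during training. Appending
two fixed sinusoidal channels

    PE(x, y) = [ sin(2*pi*x / W), cos(2*pi*y / H) ]

to the three image channels (v(x, y) in R^5) lets the model learn the
*location-conditioned* appearance mu(x, y). If a test frame carries an
anomaly I'(x0, y0) = mu(x0, y0) + Delta, the location-aware model predicts
mu(x0, y0) and the reconstruction error grows like ||Delta||^2, whereas the
location-blind model can reconstruct any appearance that is globally
familiar and may miss the anomaly entirely. Two consequences are testable
and tested: error grows monotonically with the deviation magnitude, and the
PE model beats its no-PE twin precisely on anomalies whose appearance is
copied from elsewhere in the frame ("transplanted" anomalies).

Because one sine/cosine period spans the full image, the encoding is not
injective — two columns can share a sin value. This is accepted as-is; it
has not been an obstacle in practice and keeping the natural [-1, 1] range
avoids introducing unstated rescalings.

## Architecture

Encoder: three blocks of [3x3 conv -> batch norm -> ReLU], with dropout
(rate 0.1) in the first block only, each followed by 2x2 max pooling; widths
64/128/256 at full scale. Decoder: per level, a kernel-2 stride-2 transpose
convolution, concatenation of the encoder feature map at the matching
resolution (skip connection), then a 3x3 merge convolution with batch norm
and ReLU; head is a 3x3 convolution to 3 channels with sigmoid, so outputs
lie in (0, 1). The decoder schedule (256->128 merge 384->128; 128->64 merge
192->64; 64->64 merge 128->64) keeps the default network at 1.18 M trainable
parameters, under the 1.71 M budget the family is designed to respect.
Inputs must have spatial size divisible by 8 (three pooling stages); the
no-PE ablation differs only in the first convolution (3 vs 5 input
channels, exactly 2*64*3*3 = 1152 parameters).

The network and its training loop are implemented directly on numpy in
channel-last layout: im2col + GEMM convolutions, hand-written backward
passes, Adam, and a reduce-on-plateau scheduler. Everything is float32 and
bit-reproducible given a seed; a finite-difference gradient check guards the
backward passes indirectly through the descent and reproducibility tests.

## Loss

L_total = L_MSE + lambda * L_edge with lambda = 0.05 by default.
L_MSE is the mean squared pixel difference. L_edge compares forward
finite-difference gradients of target and reconstruction along both spatial
axes and averages their absolute differences; it preserves sharp anatomical
boundaries and is blind to constant intensity offsets. Both terms are
normalised by element count so lambda is comparable across image sizes (at a
fixed size this is a constant rescale absorbed into lambda).

## Training protocol

Adam (beta = 0.9/0.999, no weight decay), initial learning rate 0.01, batch
size 16, 100 epochs at full scale. A seeded 10% of the *training* frames is
held out to monitor a plateau scheduler that halves the learning rate after
10 epochs without improvement; the weights of the lowest monitored-loss
epoch are kept. Augmentation is Gaussian noise only (sigma 0.02, "light"
perturbation of local detail), applied to the image channels of the input
while the target stays clean — a denoising objective that discourages the
identity shortcut the skip connections would otherwise allow. The positional
channels are never noised: they encode coordinates, not appearance.
Geometric augmentations (flips, rotations) are deliberately excluded and a
guard test enforces this: they would decouple image content from the fixed
positional encoding and are known to break detection.

## Segmentation

The error map is the per-pixel mean over the three image channels of the
absolute input-reconstruction difference. The threshold is adaptive:
tau = k x (pooled mean error over a seeded 10% calibration subset of the
evaluation frames), with multiplier k = 1 by default. Pooling is restricted
to the region of interest so border pixels do not bias tau; whether the
original procedure pooled over all pixels or ROI pixels is not documented,
so a flag allows either. Masks are (error > tau) AND ROI; an optional
minimum-component-area filter (8-connectivity) is provided but off by
default. Calibration frames are excluded from evaluation. The ROI is
geometric: the left, right and top margins (default 10% each) are excluded,
the bottom edge never — VFSS framing leaves gaps between those borders and
the head/neck anatomy.

## Evaluation

Accuracy, sensitivity, specificity, IoU and Dice are computed per frame from
pixel confusion counts inside the ROI, then averaged over frames (frame-level
values are what paired tests and frame-set confidence intervals require;
pixel pooling would erase them). A frame where a metric's denominator is
zero (e.g. IoU with empty prediction and empty truth) is excluded from that
metric's aggregate and counted. 95% confidence intervals use a seeded
percentile bootstrap, 1000 resamples with replacement at the original sample
size. Method comparisons use a two-sided paired t-test on per-frame values;
zero variance of the differences is reported explicitly rather than
producing an undefined statistic.

## The phantom generator

Clinical VFSS data are private, so the package ships a generator that
realises the statistical structure the method relies on, with exact ground
truth:

* **Background**: frames are drawn from N(mu(x, y), sigma^2) — a fixed
  smooth mean field (sum of Gaussian intensity bumps over a base level,
  redrawn until at least 0.2 intensity contrast exists so location carries
  information) plus isotropic per-pixel Gaussian noise and a small rigid
  jitter of the structures (±1 px) standing in for physiologic motion the
  detector must tolerate. The covariance is modelled as isotropic because
  the anomaly-detection argument uses only means and a deviation norm.
  Grayscale anatomy is replicated across three channels. By default the
  field lives on a torus (periodic=True) and jitter is a circular shift, so
  the background world is exactly translation-symmetric. Each blob's
  amplitude is additionally scaled per frame by a factor U(1 - a, 1)
  (default a = 0.5), emulating cross-subject anatomy and exposure
  variability: a bright smooth region is then a plausible local appearance
  anywhere, while its *expected* location stays informative. Layout modes
  "scatter" and "hybrid" go further and redraw (some) blob centers every
  frame within a structure zone, for experiments that need
  location-conditioned statistics not inferable from a single frame.
* **Noise level**: the default per-pixel sigma is 0.005, deliberately small
  relative to both the denoising-augmentation sigma (0.02) and anomaly
  contrasts (>= 0.15). The anomaly-detection argument presumes the deviation
  dominates the background reconstruction error; if the frame noise sits in
  the training *targets* at a level above the augmentation noise, the
  loss-optimal autoencoder simply copies its input through the skip
  connections (copy loss sigma_aug^2 < predict-the-mean loss sigma_f^2) and
  the error map measures input noise rather than anomaly structure. Keeping
  sigma_f < sigma_aug makes the optimal denoiser weight the learned
  location-conditioned mean (Wiener weight sigma_f^2/(sigma_f^2+sigma_aug^2)
  ~ 0.06), which is the regime the method is about.
* **Anomalies**: ellipses, either *additive* (intensity offset Delta,
  bolus-like contrast; Delta = 0 gives a null anomaly for false-positive
  control) or *transplanted* (mean-field appearance copied from a disjoint
  source ellipse — globally familiar, spatially inconsistent). Transplant
  sources must differ from their destination by at least 0.15 mean absolute
  field contrast: a transplant between equal-intensity regions would be a
  null anomaly with no signal to detect. Masks are exact by construction;
  in additive mode only mask pixels change (pre-clipping).

What the phantom does **not** emulate: radiographically realistic anatomy
(vertebrae, mandible shading), contrast-agent texture, temporal correlation
between frames, scatter or detector artifacts. Passing phantom tests
demonstrates that the mechanism works when the modelling assumptions hold;
it does not certify clinical performance.

## Desk-scale benchmark

The acceptance benchmark runs the ablation at 64x64 pixels: 200 training
frames, 40 test frames (10 clean, 30 with one transplanted ellipse of
semi-axes 7x5), 30 epochs, network widths scaled to (16, 32, 64). These
sizes keep a two-model training run in minutes on one CPU core while
preserving the full-scale architecture shape, loss, optimiser, scheduler and
thresholding. The expected qualitative outcomes are the directional ones:
PE mean IoU above no-PE mean IoU, and median in-anomaly error strictly
increasing over additive deltas {0.1, 0.2, 0.4}.

Two benchmark conditions differ from the library defaults, both for reasons
of scale rather than preference:

* **Circular padding (with the periodic phantom).** Zero padding leaks
  absolute position into deep features; at 64x64 the bottleneck path's
  receptive field spans most of the frame, so a "no-PE" network trained on a
  fixed scene can localise itself from the borders and memorise the
  location-conditioned mean — erasing the very contrast the ablation
  measures. On a toroidal phantom with circular convolutions the world is
  exactly translation-symmetric (verified: the no-PE network commutes with
  pooling-aligned shifts to machine precision), so absolute position reaches
  the model only through the sin/cos channels. Full-scale images have
  border-blind interiors and do not need this control.
* **Threshold multiplier k = 2 and a 20-px minimum component area.**
  Anomalies cover only ~3% of calibration pixels at this scale, so tau at
  1x the pooled mean sits inside the bulk of the background error
  distribution (~p75-80) and flags a large background fraction; 2x places
  tau near the background p99 while staying well under the in-anomaly error
  level. The component filter (anomalies are ~110 px; noise false positives
  nearly isolated) is the targeted-postprocessing step, inert in library
  defaults.

## Numerical and design choices

* Pixel indexing is 0-based; x is the column (paired with W), y the row
  (paired with H).
* Resize interpolation is bilinear without an antialias prefilter;
  normalization is per-frame min-max (a constant frame maps to zeros).
* The border crop removes maximal contiguous border rows/columns whose mean
  intensity is at most `threshold x max intensity` (relative, default 0.02);
  a fully black frame is an error, not an empty crop.
* Max-pool backward routes ties to the first maximum in scan order
  (deterministic); batch-norm uses eps 1e-5, momentum 0.1.
* The calibration split, training validation split, weight initialisation,
  dropout, noise augmentation, phantom sampling and bootstrap all consume
  seeded generators derived from a single run seed by fixed small offsets.

## Known limitations

* The ablation endpoint is noisy at desk scale: with ~36 evaluated frames
  and one training run per variant, the IoU gap between the PE model and
  its no-PE twin fluctuates across benchmark seeds by roughly +/-0.05 —
  the same order as the gap itself. The robust signatures at this scale are
  the error-level ones (higher in-anomaly reconstruction error for the PE
  model; clean frames reconstructing better than anomaly pixels; error
  growing with the deviation magnitude). Resolving the IoU-level gap the
  way a clinical study can (hundreds of test frames) is out of reach of a
  minutes-long CPU benchmark.
* A position-blind convolutional model is not as blind as the idealised
  theory assumes: zero padding leaks absolute position, and any fixed scene
  can be completed modulo translation from relative geometry. The benchmark
  controls the first (circular padding on a toroidal phantom) and blunts
  the second (per-frame amplitude variability), but relative-context cues
  cannot be fully removed from a single-layout world.
* Pure-numpy training is CPU-bound; full-scale 256x256 training is possible
  but slow, and the package is tuned for desk-scale experimentation and
  method validation.
* The fixed positional encoding assumes a consistent field of view; applying
  a trained model to a differently framed acquisition requires retraining
  (cheap, since no annotations are needed).
* Thresholding is global per run; no temporal smoothing or per-frame
  adaptive thresholds are provided.
* FLOPs are not reported: a meaningful count depends on convolution
  implementation details, and the package does not claim any particular
  inference-speed figure.
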