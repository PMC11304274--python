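# Methods

This note documents the models, numerical choices and limitations of the
`pureshift` package: a simulator of chunk-undersampled interferogram
pure-shift NMR data, a squeeze-and-excitation (SE) residual convolutional
network that recovers artifact-free spectra from undersampled ones, an
iterative-soft-thresholding (IST-S) compressed-sensing baseline, and the
evaluation statistics used to compare them.

## Signal model

Interferogram-mode pure-shift acquisition assembles a free induction decay
(FID) chunk by chunk: increment *c* of the pseudo-2D experiment contributes
the time interval `[c·L_c, (c+1)·L_c)` dwell points of the decoupled signal
(`L_c` = chunk length in complex points).  For ideal singlets the
concatenation is exactly a sum of damped complex exponentials,

    s(t_k) = Σ_j A_j · exp(i(2π f_j t_k + φ_j)) · exp(−π λ_j t_k),
    t_k = k / sw,

with amplitude `A_j`, offset `f_j` (Hz), zero-order phase `φ_j` and full
Lorentzian linewidth at half height `λ_j` (Hz); the decay rate is `π λ_j`
so that the absorption-mode line has FWHH = `λ_j` (verified in the test
suite against the discrete Fourier transform).  J-coupling evolution within
chunks (the source of chunk sidebands in real interferogram data) is not
simulated: labels are ideal singlet spectra, and the artifact class the
network learns to remove is chunk undersampling.

Non-uniform sampling (NUS) omits whole chunks.  `apply_nus` zeroes every
sample outside the sampled chunks; the spectrum of the chunk-zeroed FID is
the network input.  Schedules draw chunks uniformly at random without
replacement, always including chunk 0, which anchors the overall intensity
scale (the scheduler of the reference experiments is not published; this is
the package's choice).  Noise is i.i.d. complex Gaussian in the time domain
applied to inputs only; labels are noiseless.

### Chunk geometry

The default geometry is **93 chunks x 64 complex points, zero-filled to
8192**.  93 is the smallest chunk count that reconciles all four quoted NUS
levels at once — 5/93 = 5.4 %, 7/93 = 7.5 %, 15/93 = 16.1 %, 23/93 =
24.7 % — and reproduces the acceleration factor 93/15 ≈ 6.2 (a brute-force
search over 50–200 chunks, included in the tests, finds 93 and its
multiples only).

### Peak-set distribution (simulator defaults)

| parameter | default | rationale |
|---|---|---|
| peaks per spectrum | uniform 3–25 | crowded-to-sparse small molecules |
| frequency | uniform over central 90 % of window, ≥ 2 bins apart | avoids edge wrap and unresolvable coincidences |
| amplitude | log-uniform on [0.02, 1] | 50x dynamic range, matching the hardest reported regime |
| linewidth | uniform 1–6 Hz | typical 1H solution linewidths at the 0.49 Hz/bin default resolution |
| phase | 0 | spectra are assumed phase-corrected |
| noise σ | uniform [0, 0.05] x max FID point | noise-robust training range |

Spectra are the real part of the centered DFT, each independently scaled to
unit maximum absolute value; the scale factor is retained for
de-normalization.

## Network

The recovery network maps a length-N real spectrum to a length-N real
spectrum.  Its building unit is the CBLD block: convolution → batch
normalization → leaky rectifier (slope 0.01) → dropout (rate 0.1).  The
stack is

* entry CBLD, 1 → C channels, kernel 9;
* six residual blocks, each CBLD(C→C, kernel 21) → SE gate → CBLD(C→C,
  kernel 21) with an identity skip added around the block;
* output block: 1x1 convolution (C→1) + batch normalization, with no
  activation or dropout.

All convolutions are stride 1 with 'same' padding, so the feature-map
length stays N everywhere.  The SE gate is global average pooling over the
length axis, a bottleneck pair of dense maps C → C/r → C (ReLU between,
sigmoid after, r = 2) and per-channel rescaling by the resulting scalars.
Setting `use_se=False` yields the ablation variant (non-SE-PSNet) with the
identical stack minus the gates, which removes exactly
`6·(2C²/r + C/r + C)` parameters.

At the reference size (N = 8192, C = 32) the architecture has 266,051
learnable scalars (1.01 MB at 4 bytes each) and costs 2.12 billion
multiply-adds per forward pass by the convolution convention
`N·C_in·C_out·K`; SE terms add ~0.0003 % and are excluded from the headline
count.  Both numbers are computed by layer enumeration, cross-checked
against a closed form in the tests.

The network engine is written in NumPy with hand-derived backward passes
(convolutions run as K shifted GEMMs on a channels-last layout).  Every
layer's gradient is verified against central finite differences in float64
in the test suite.  Dropout placement inside every CBLD block, the
variance-scaling fan-in initialization, and inference-mode batch
normalization via exponential running statistics (momentum 0.1) are
standard choices; none of them is pinned down by the published description.

## Training

Supervised pairs (spectrum of the noisy chunk-undersampled FID, spectrum of
the clean fully sampled FID) are fit by mean squared error with
adaptive-moment gradient descent (Adam).  The published account does not
state loss, optimizer, batch size or epochs; the package defaults are MSE,
Adam at learning rate 1e-3, batch 64, 100 epochs, a 90/10 train/validation
split, and model selection by lowest validation loss.  Training is fully
reproducible from one seed (data order, dropout, initialization).

Because the final batch normalization initially forces a unit-scale output
while unit-max-normalized spectra have a much smaller RMS, the default
initialization spends many epochs shrinking the output scale.  The
training-quality experiments therefore initialize the output-block
batch-norm gain at 0.05 — a small-gain variant of standard residual
batch-norm initialization — which reaches the same converged loss in a
fraction of the epochs (both paths were measured to converge to the same
plateau).

The M-to-S option draws several undersampled inputs with pairwise distinct
schedules (optionally mixing NUS levels) for one shared ideal label,
improving generalization across sampling conditions.

### CPU fast profile

The full-scale study conditions (N = 8192, C = 32, 4000 pairs, ~20 min on a
desktop GPU) are impractical for a single-CPU NumPy run, so the package
defines a scaled-down profile used by its own training-quality tests:
93 chunks x 8 complex points zero-filled to N = 1024 at 500 Hz sweep
(identical 0.49 Hz/bin resolution and 16 ms chunk duration), C = 16
channels, 3–10 peaks of 1–4 Hz linewidth per spectrum, 512 training pairs,
batch 32, learning rate 3e-3, 30 epochs (the validation loss plateaus well
before that under the small-gain output initialization).  All
chunk-sampling arithmetic (93 chunks; keep 5/7/15/23) is unchanged.

Results under this profile demonstrate the method end to end at reduced
problem size; they do not certify full-scale performance.  The quantitative
ceiling of the scaled profile sits below the full-scale one — fewer
parameters and training pairs, and proportionally wider peaks — and the
dominant residual error is a systematic shrinkage of weak and mid-height
peaks, the usual bias of an MSE-trained denoiser at limited capacity.  In
particular, the scaled profile should not be expected to reproduce every
full-scale quantitative finding (such as the exact peak-intensity
correlation values, or the margin between the SE and non-SE variants); the
training-quality tests compute and assert those statistics so the gap is
measured rather than assumed.

## IST-S baseline

Iterative soft thresholding with data consistency: starting from the
chunk-zeroed FID, each iteration Fourier transforms the estimate,
soft-thresholds the complex spectrum's magnitude (phase preserved) at
`τ_k = 0.99^k · max|initial spectrum|`, inverse transforms, and overwrites
the sampled chunks with the measured data; 500 iterations by default.  The
iteration runs on the measured grid — zero filling is applied only for the
final display spectrum — so a fully sampled input passes through
unchanged.  The published caption fixes "500 iterations and the threshold
value of 0.99"; interpreting 0.99 as the geometric decay ratio of the
threshold level, initialized at the maximum spectral magnitude, is this
package's reading (standard decreasing-threshold IST practice).  Whether
the original thresholds the real spectrum or the complex magnitude is not
stated; magnitude thresholding preserves the phase structure of partially
sampled data and is used here.

## Evaluation

* **RMSD** between unit-max normalized spectra (full-spectrum by default; a
  peak-region variant restricts to ±5 bins around reference peaks).
* **Peak picking**: local maxima above 1 % of the maximum, ≥ 2 bins apart.
* **Matching**: greedy nearest-first one-to-one matching within ±2 bins;
  unmatched reference peaks are false negatives, surplus reconstructed
  peaks false positives.
* **R²**: squared Pearson correlation of matched peak heights; an integral
  variant correlates ±5-bin window sums.  Fewer than two matches flags the
  statistic as undefined rather than fabricating a value.
* For synthetic data, `r2_at_true_peaks` reads intensities at the known
  ground-truth line positions (maximum within ±2 bins), which is immune to
  the spurious local maxima that truncation ringing adds to picked peak
  lists.
* Multi-trial runs report mean and sample standard deviation per metric
  (20 trials by default).

The picking threshold, matching tolerance and integral window are not
published; the defaults above are exposed in every API.

## Known limitations

* Chunk sidebands from J-modulation within chunks are not simulated; the
  concatenated-sinusoid model covers undersampling artifacts only.
* Phase errors, baseline distortions, solvent signals and temperature
  drifts of real spectra are absent from the generator, so synthetic-test
  performance bounds real-data performance from above.
* The ppm axis, referencing, and spectrometer raw formats are out of scope
  (axes are in Hz; JCAMP-DX import covers the plain AFFN dialect only).
* Reconstruction operates line-by-line on 1D spectra; multi-dimensional
  data would require an outer loop not provided here.
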