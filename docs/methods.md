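# Methods

## Signal model and labels

A recording is a set of synchronized, equally long channels at a common
rate (nominally 100 Hz): IMU channels, knee stretch channels, sEMG channels
(natively 2000 Hz, decimated to the common grid), plus a foot-pressure
channel used only for labelling. `downsample_channel` applies a zero-phase
8th-order Butterworth low-pass at 80% of the output Nyquist before keeping
every factor-th sample; Butterworth (rather than a Chebyshev design) keeps
the DC gain exactly 1, so constant signals pass unchanged. An RMS-envelope
alternative for sEMG (`emg_envelope`: rectify, 50 ms RMS window, decimate)
is provided since either convention is common for surface EMG.

`derive_phase_labels` smooths the pressure with a centered moving average
whose window *shrinks at the edges* (no fabricated samples), marks strict
local maxima subject to a minimum peak distance and prominence
(`scipy.signal.find_peaks`), and interpolates the phase linearly 0→100
between consecutive maxima. Samples before the first and after the last
marked peak have no stride context and are flagged invalid rather than
extrapolated. Defaults — smoothing window 15 samples, minimum peak distance
50 samples (0.5 s at 100 Hz), prominence 10% of the smoothed signal's range
— assume treadmill strides of ≥ 0.8 s; all three are exposed as parameters.

Phase is encoded as (sin, cos) of 2πp/100 and decoded with atan2 (negative
angles wrapped by +2π). Encoded labels always lie on the unit circle;
predictions are unconstrained and only their angle is used. The zero vector
has no angle and is rejected explicitly.

`make_windows` cuts M×L sliding windows whose label is the phase at the
window's **last** sample — the causal choice, matching what a real-time
controller can know. Windows whose final sample is unlabelled are dropped.

## Architecture

`ModelConfig` defaults to the full-size configuration: embedding d = 768,
12 heads, 6 encoder layers, patch length 10, FFN expansion 4d; the
synthetic experiments use reduced instances (see below). Choices where the
design was genuinely open:

* **Attention scaling.** The per-head width is d/h and scores are scaled
  by √(d/h), the standard multi-head convention; a literal d_k = d scaling
  is dimensionally awkward once heads are concatenated, but is available
  via `scale_by_full_d` for comparison. Both paths are checked against the
  scalar oracle.
* **Weight sharing.** The patch projection (W_t, b_t) and positional table
  P_t are shared across channels (the channel-independent convention of
  patch time-series transformers), while the prepended tokens are
  per-channel (`per_channel_tokens`, default on). Channel identity must
  survive weight sharing for the cross-attention weights to be
  interpretable as channel importance; sharing everything *including* the
  token would make channels indistinguishable up to content.
* **Positional encoding** is a learnable (L/P_l + 1)×d table (no sinusoidal
  formula is assumed); row 0 belongs to the channel token.
* **Encoder wiring** is post-norm, exactly `LayerNorm(x + MultiHead(x))`
  then `LayerNorm(a + FFN(a))` with GELU in the FFN.
* **Cross-attention fusion** is a single multi-head dot-product attention
  with query T′W_Q and keys/values from the channel tokens, followed by an
  output projection; no residual or FFN block is added after it.
* **Prediction head**: one hidden layer of width d with GELU, then a linear
  2-unit output with no activation — targets lie on the unit circle but
  predictions are deliberately unconstrained.
* **Dropout** 0.1 on attention weights, FFN hidden activations and the head
  hidden layer during training; evaluation mode is deterministic.
* **Initialization**: truncated normal (σ = 0.02, clipped at ±2σ) for
  tokens and tables, uniform fan-in for linear maps; fully seeded.

The networks run on `gaitphase.autodiff`, a compact reverse-mode tape over
numpy float64 arrays (broadcast-aware elementwise ops, batched matmul,
softmax, GELU, LayerNorm, stride-1 conv1d + average pooling for the
baselines). Every operator is gradient-checked against central finite
differences in the test suite, and the attention stack is additionally
checked against an independent nested-loop scalar implementation.

## Interpretation

* `channel_weights`: per window, the cross-attention softmax rows of T′
  over channels are averaged over heads (arithmetic mean; per-head values
  retained behind `head_reduction="per-head"`), then averaged over windows
  with the standard deviation as dispersion. Weights are computed on the
  evaluation split to avoid training-set attention artifacts.
* `attention_scope`: arithmetic mean of the captured encoder self-attention
  matrices over a layer/head set, default the last three layers × last six
  heads (clipped to the model's depth/width). A convex combination of
  stochastic rows is stochastic, which the tests assert.
* `select_top_channels`: rank by mean weight within modality, exact ties
  broken by lexicographic channel name (deterministic and
  order-invariant). `build_fused_source_specs` emits the four fused
  16-channel configurations: top 8 IMU + top 8 EMG; both stretch + top 14
  EMG; both stretch + top 14 IMU; both stretch + top 7 IMU + top 7 EMG.

## Training and evaluation

Defaults follow the reference protocol: Adam, batch 32, learning rate
4e-6, 200 epochs, 7:3 split. The split is **chronological** by default:
with stride-1 windows a random split would place near-duplicate windows
(99% sample overlap) on both sides; the chronological split additionally
drops ceil((L−1)/stride) windows after the boundary so no evaluation
window overlaps a training window in time. A plain random mode remains
available. Channels are z-scored with training-partition statistics
(stored in the checkpoint); no learning-rate schedule or early stopping.
Per-bin R² on the wrapped scale can be negative in the boundary bins; no
circular correction is applied, deliberately.

Baselines: the CNN is a dual-branch stack (parallel kernel-3 and kernel-7
branches of conv→ReLU→average-pool blocks, features concatenated); LSTM
and GRU stack 4 recurrent blocks of hidden width 128 with a linear head on
the last hidden state; the hybrids feed 3 conv blocks into 3 recurrent
blocks. All share the M×L → ℝ² forward contract and training loop.

## Synthetic generator

`generate_recording` emulates the *shape* of treadmill gait data with
known ground truth: per-stride phase ramps (stride lengths perturbed
uniformly by ±jitter·mean), kinematic channels as first+second harmonics
of the phase, EMG channels as rectified white noise gated by smooth
circular burst envelopes (defaults: one burst near 40% emulating push-off,
one near 90% emulating swing), a stretch channel as a smooth periodic
flexion ramp, pure-noise channels carrying no phase information, and a
foot-pressure pulse `exp(4(cos θ − 1))` whose maxima fall exactly on
stride-boundary samples. `snr` is the signal-RMS to noise-std ratio;
snr = 0 means no added noise. Default conditions: 20 strides of mean 100
samples (1 s at 100 Hz, a typical cadence), 5% jitter.

What it does **not** emulate: biomechanically validated waveforms,
inter-subject variability, sensor drift and motion artifacts, EMG
crosstalk, or asynchronous sampling. Passing tests therefore demonstrate
that the pipeline, architecture and attribution machinery behave correctly
on stride-periodic signals with known truth — not clinical-grade accuracy
on human recordings.

## Canonical experiments (gaitphase.experiments)

Problem sizes were chosen to be comfortably tractable on one CPU:

* **Phase recovery**: reduced transformer (d = 64, 2 layers, 4 heads,
  patch 10, no dropout), 21 noiseless strides → 2001 stride-1 windows,
  chronological 7:3 split, Adam lr 1e-3, batch 64, 15 epochs. The check is
  pooled RMSE < 5 phase units over the interior bins (post-stance +
  pre-swing); boundary bins are excluded because the plain-difference
  metric inflates them by construction.
* **Channel attribution**: 6 channels (2 kinematic + 1 stretch informative,
  3 pure noise), 14 strides → 1301 windows, the same reduced model,
  10 epochs, 10 training seeds. The informative channels' mean
  cross-attention weight should exceed the noise channels' in ≥ 9/10
  seeds. Two failure modes observed during design are worth recording:
  an *under-trained* model prefers noise channels (their encoded tokens
  are nearly input-independent, which suits an early near-constant
  predictor), and a heavily over-parameterized model on very few windows
  can memorize noise. Attribution is therefore meaningful only at
  convergence, which the chosen budget reaches reliably.
* **Baseline smoke runs**: reduced widths (hidden 32, 8 conv channels),
  151 windows, 3 epochs — enough to verify that every family strictly
  reduces its training loss from initialization.

## Numerical notes and degenerate inputs

* Attention softmax is computed with max-subtraction; rows are validated
  as stochastic to 1e−6 in the forward traces.
* LayerNorm uses ε = 1e−5 inside the square root.
* Non-finite activations raise immediately with the failing stage named;
  a non-finite training loss aborts with the epoch index.
* A phase bin with fewer than two evaluation samples reports NaN metrics
  rather than a fabricated value; R² is undefined (error) for a constant
  target.
* Channel series shorter than the window, zero-length datasets, empty
  channel lists, unknown modalities/families, and non-integer decimation
  factors are all rejected with specific messages.

## Known limitations

* The synthetic task is much easier than human gait; reported synthetic
  RMSEs say nothing quantitative about performance on real recordings.
* The full-size configuration (d = 768, 6 layers) is impractical to train
  in this numpy engine; it is validated structurally (shapes, oracle
  equivalence) rather than end-to-end.
* Stride segmentation is peak-based only; no heel-strike/toe-off event
  classifiers are provided.
* The engine is single-threaded beyond BLAS; no GPU path exists.
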