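# Methods

## The model

`trfdecode` estimates linear stimulus-response models between a speech
envelope and multichannel EEG,

    Y_hat = X W,

where `X` is the regressor augmented with time-lagged copies of each channel
(lags and channels combined into one column dimension) and `W` is the
spatio-temporal kernel.  A **forward** model (temporal response function)
predicts each EEG channel from the attended-speech envelope with lags
0..+500 ms — the stimulus precedes the response.  A **backward** model
(decoder) reconstructs the envelope from all EEG channels with lags
−500..0 ms in the same sign convention — the response trails the stimulus.
At the study scale (66 channels, 33 lags at 64 Hz) a backward decoder has
2,178 free parameters against 33 per channel for the forward model, which is
why the two directions respond so differently to regularization.

Edges are zero padded: the lagged design keeps one row per target sample, and
lags that reach outside a trial contribute zeros.  Trials are lagged
independently, so no information crosses trial boundaries.  There is no
intercept term; all inputs are z-normalized with training-fold statistics
(the equations carry no bias term, and normalized signals have near-zero
mean).

## Estimators

All schemes minimize the residual sum of squares plus a scheme-specific
penalty and, except the elastic net, are closed forms in the sufficient
statistics `Cxx = X^T X`, `Cxy = X^T Y`:

| scheme     | solution                                   | parameter range |
|------------|--------------------------------------------|-----------------|
| ols        | `Cxx^{-1} Cxy` (Cholesky, condition-checked) | —             |
| ridge      | `(Cxx + λI)^{-1} Cxy`                      | (0, ∞)          |
| lra        | invert only the leading eigenspace covering a fraction λ of the eigenvalue mass | (0, 1] |
| shrinkage  | `((1−λ)Cxx + λνI)^{-1} Cxy`, ν = trace/d   | [0, 1]          |
| tikhonov   | `(Cxx + λM)^{-1} Cxy`, `M = D^T D` first-difference roughness penalty | (0, ∞) |
| elasticnet | coordinate descent on `1/(2N)‖Y−XW‖² + λ[(1−α)‖W‖²/2 + α‖W‖₁]` | λ ∈ (0, ∞), α ∈ (0, 1] |

Ridge and shrinkage flatten the eigenvalue spectrum smoothly (ridge shifts it
up, shrinkage pulls it toward its mean), LRA truncates it, Tikhonov penalizes
kernel roughness, the elastic net adds sparsity.  λ values are **not**
comparable across schemes; each is tuned on its own path:

- geometric, `λ_n = 10⁻⁶ · 1.848ⁿ`, n = 0..53 (54 values spanning 10⁻⁶ to
  ≈1.4·10⁸) for penalties on (0, ∞);
- log-sigmoid, `logit(λ) ← logit(λ) + 0.475` from 10⁻⁶, 41 values in (0, 1),
  for LRA/shrinkage.

The Tikhonov penalty matrix spans the full combined channel·lag dimension by
default, so with a multichannel regressor the kernel endpoints of adjacent
channels leak into one another; a block-diagonal per-channel variant is
available (`per_channel=True`).  Numerical choices: solvers use symmetric
Cholesky factorizations, never explicit inverses; OLS refuses systems whose
estimated condition number exceeds 10¹²; LRA clamps eigenvalues below
10⁻¹²·max to zero before inversion; coordinate descent declares convergence
when the largest coefficient change falls below 10⁻⁶ (10,000-iteration cap,
non-convergence carries a warning, never silent success); elastic-net warm
starts along the path change iteration counts only.

The elastic-net solver internally rescales columns to unit RMS (no
centering) and maps coefficients back; its λ therefore matches the stated
objective exactly on standardized inputs.  The documented asymmetry stands:
all closed-form schemes consume covariances, the elastic net alone needs the
raw design.

## Preprocessing

EEG chain, fixed order: (1) line-noise removal by convolution with a boxcar
of `fs / line_freq` samples (non-integer length realized by interpolating the
two flanking integer-length boxcars; zero at the line frequency and its
harmonics); (2) FFT resampling to 64 Hz by spectral truncation; (3) linear
detrend; (4) causal 4th-order 0.1 Hz Butterworth high-pass — forward pass
only, group delay ≈2.7 samples at 1 Hz falling below 0.7 above 2 Hz; (5)
ocular-artifact removal by joint decorrelation: blink samples flagged where
z-scored 1–30 Hz EOG exceeds 4, generalized eigenproblem `R_A v = λ R v`
solved in the whitened space of `R` (whitening keeps principal components
above 10⁻⁹·max), components with eigenvalue above 80% of the maximum
regressed out (typically one or two); (6) common-average reference; (7)
1–9 Hz zero-phase windowed-sinc FIR (type I, order 128, shifted by its group
delay); (8) z-normalization with training-fold statistics only.

Audio chain: 31-band 4th-order gammatone filterbank, ERB-spaced centers over
80–8000 Hz; per-band Hilbert magnitude compressed with a 0.3 power law;
bands summed; FFT-resampled to 64 Hz; 9 Hz zero-phase low-pass.  Envelope
normalization uses the attended-stream training statistics.

## Cross-validation

10 outer folds over trials (seeded permutation, sizes within one trial).
Inner loop: leave-one-training-fold-out (9 inner folds).  For every λ on the
path a model is fit per inner fold and scored by the Pearson correlation
between its prediction/reconstruction and the validation fold (channel mean
for forward models).  The λ maximizing the mean validation correlation is
selected — smallest such λ on ties, since validation curves are flat over a
broad region — and the inner-fold models at λ* are averaged element-wise
into the model evaluated on the held-out fold.  Models are always fit to the
attended envelope.  Normalization statistics come from the outer fold's
training trials and are reused across its inner folds.

At full scale the engine works on lagged sufficient statistics: per-trial
raw lagged Gram matrices plus prefix-sum correction terms, from which the
covariances of the z-normalized design are reconstructed exactly for any
training statistics (verified against explicit design matrices to machine
precision in the tests).  Ridge, shrinkage, LRA and OLS share one
eigendecomposition per inner fold, so sweeping λ costs two matrix-vector
products per value; Tikhonov re-factorizes per λ and the elastic net
consumes raw designs — both are practical at forward-model scale and slow
(but exact) for 2,178-dimensional backward problems.

## Attention decoding and metrics

Decisions are made on windows of 1–30 s stepped in 1 s increments within
trials; the stated window length includes the 0.5 s kernel, so correlations
are computed over the window minus the rows whose lag history leaves it.
Backward: decision value = r(reconstruction, envelope A) − r(reconstruction,
envelope B); ties classify as A with a logged flag.  Forward: each envelope
predicts all 66 channels, giving 132 correlation features per window; a
linear soft-margin SVM (C = 1) trained on the outer fold's training-trial
features supplies the decision value.

ROC curves sweep the signed decision value over midpoint thresholds (plus
sentinels, so (0,0) and (1,1) are always present) and record the fraction of
segments at or above each threshold.  The Wolpaw rate,
`V[log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))]` bits/min, assumes every
segment is classified; the decision rate is `V = 60/segment length`, i.e.
non-overlapping decisions.  The Nykopp rate sweeps a threshold on the
decision magnitude, builds the empirical confusion matrix over retained
segments and maximizes the empirical mutual information; `V` stays the
attempted rate (a `scale_v_by_fraction` option is exposed).  With few
retained segments the empirical maximum is optimistically biased — the
label-permutation test bounds this bias rather than pretending it away — and
for strongly asymmetric confusion matrices Nykopp ≥ Wolpaw is not a
mathematical identity, so it is asserted on synthetic runs, not enforced at
runtime.  Correlations are Fisher-z transformed and accuracies arcsine
transformed before averaging in summary tables.

The noise floor randomizes Fourier phases (conjugate-symmetric, magnitudes
preserved exactly; one shared phase draw across channels so the spatial
covariance survives) of the audio for forward models or the EEG for backward
models, recomputes the regression accuracy with the trained model frozen,
and reports the central 95% interval over 100 randomizations.

## The synthetic scenario

The generator emulates a two-talker listening experiment *after*
preprocessing — i.e. the 64 Hz, 1–9 Hz band signals the models actually
consume.  Defaults: 60 trials of 50 s at 64 Hz, 66 channels, balanced
attended-stream labels.  Envelopes are 1–9 Hz band-passed noise, half-wave
rectified and 9 Hz low-passed (nonnegative, envelope-like spectra).  The
planted kernel is a Gaussian-windowed 4 Hz burst centred at 150 ms (within
the canonical latency range of cortical envelope tracking) with a smooth
random topography; attention is gain modulation, attended:unattended = 2:1.
Background noise mixes 24 pink-noise sources into all channels plus 1% white
sensor noise, then band-passes the sum 1–9 Hz with the same zero-phase FIR
as the real pipeline.  Band-limiting is what makes the lagged EEG covariance
severely ill-conditioned — the property of real filtered EEG that makes
backward-model regularization matter; without it OLS and ridge are
indistinguishable.

The default SNR (signal = kernel-filtered envelope sum, noise = total
background, both in-band) is −25 dB, calibrated once against the operating
regime the toolbox targets: backward regularized reconstruction accuracy
r ≈ 0.3 with OLS at roughly half that, and 30 s decoding accuracy near
ceiling for the regularized decoder.  (At −30 dB the regularized decoder sits
at ≈92% and the margin over the 90% recovery threshold becomes seed-
dependent; −25 dB keeps parameter recovery robustly demonstrable.)  What the simulator does **not** emulate:
real EEG nonstationarity and artifacts, inter-subject variability,
reverberant acoustics, attention switches within trials, and any nonlinear
envelope-response coupling.  Passing tests therefore demonstrate correctness
of the estimation/decoding machinery under the stated generative
assumptions, not performance on recorded data.

## Problem sizes in the shipped checks

The test suite exercises unit-level properties at small sizes and one
full-scale backward run (60×50 s, 66 channels, ridge vs OLS on a 14-step
geometric path with ratio 1.848⁴ spanning the same 10⁻⁶..10⁸ range as the
54-step default; the coarser grid only affects how finely the flat validation
plateau is sampled).  The acceptance script repeats that run from scratch and
also fits a single-channel high-SNR forward scenario for kernel recovery.

## Known limitations

- The causal high-pass contract "group delay < 2 samples at all frequencies
  ≥ 1 Hz" is not met by a 4th-order 0.1 Hz Butterworth at 64 Hz: the true
  delay is 2.675 samples at exactly 1 Hz, dropping below 2 around 1.16 Hz.
  The filter is implemented as specified and the measured curve is exposed
  via `butter_group_delay`.
- Full-scale Tikhonov and elastic-net backward fits are supported but slow
  (no shared eigenbasis / raw-design coordinate descent respectively).
- The EDF/BDF reader imports whatever montage the file declares; picking the
  EOG bipolar pairs is the caller's responsibility (`--veog/--heog`).
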