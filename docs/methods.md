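# Methods

## Pipeline

One trial (channels × samples at sampling rate fs) passes through:

1. **Normalization.** Each channel is affinely mapped onto [−1, +1]
   (`minmax_normalize`). Scope is per channel per trial by default — the
   alternative, one map per channel over the whole recording, is available
   (`normalization="recording"`), and normalization can be switched off.
   Per-trial scope avoids leaking amplitude information between trials.
2. **Decomposition.** Masking EMD (default) or plain EMD, first K = 3
   IMFs per channel.
3. **Features.** Per IMF: energy, five morphological measures, fuzzy
   approximate entropy, seven Burg AR coefficients → 14 numbers per IMF,
   concatenated over IMFs and channels in a fixed, named layout.
4. **Classification.** Feed-forward network trained by back-propagation,
   one-hot ±1 targets, label = argmax output unit.
5. **Evaluation.** Stratified 70/30 train/test split (seeded), confusion
   matrix, accuracy, error rate. All randomness derives from one root seed
   split into named per-stage streams, so reports regenerate
   byte-identically.

## Empirical mode decomposition

Sifting subtracts the mean of the upper/lower extrema envelopes until the
Cauchy criterion SD = Σ(h_prev−h_new)² / Σh_prev² < `sd_tol` or
`max_sifts` iterations. Choices where the procedure itself is
underdetermined:

* **Envelopes**: natural cubic splines through the extrema; the two
  extrema nearest each signal end are mirrored about the boundary sample
  before fitting, the least-artifact common treatment of spline end
  swings. Spline overshoot means upper ≥ lower is not guaranteed
  pointwise, and nothing relies on it.
* **Plateaus** of equal samples yield one extremum at the midpoint index
  (floored for even lengths).
* **Stopping defaults**: `sd_tol = 0.2`, `max_sifts = 100` (the classical
  sifting defaults), `max_imfs = 10`; decomposition of a residue stops
  when it has fewer than two maxima or two minima.

Whatever the stopping parameters, IMFs + residue telescope back to the
input exactly; the tests assert 1e−10 relative reconstruction error.

## Hilbert spectral analysis

The analytic signal is the DFT construction (negative bins zeroed,
positive doubled, DC/Nyquist kept), so its real part is the input exactly.
Instantaneous frequency is the unwrapped-phase derivative via central
differences (one-sided at the ends). Conventions: zero-amplitude samples
get frequency 0 (phase undefined); negative instantaneous frequencies —
phase slips at low-amplitude samples — are kept in the trace but clamped
to 0 wherever a nonnegative frequency is required (mask weighting). All
closed-form tolerance checks use the central 80% of samples, excluding
boundary Gibbs effects.

## Masking EMD

Mask parameters come from the Hilbert trace of the plain first IMF:

* amplitude `a_z = 1.6 · mean(a)`. The 1.6 coefficient is treated as a
  fixed constant of the method (`MASK_AMPLITUDE_COEF`); no attempt is made
  to optimize it.
* frequency `f_z = Σ a·f² / Σ a·f`, the amplitude-weighted mean
  instantaneous frequency. This is the standard masking-frequency
  estimator; it weights the mask toward the scale that carries the
  signal's energy, and reduces to f exactly for a constant-frequency
  trace.
* waveform: sine with phase 0; the phase is exposed should a caller want
  a cosine mask.

`y = (IMF1[x+z] + IMF1[x−z]) / 2`; only the *first* IMFs of the two
shifted signals are paired — deeper IMFs come from recursion on the
residue, with the mask re-estimated at every level (default) or applied at
the first level only (`mask_levels="first"`). Degenerate cases degrade
gracefully: an all-zero amplitude trace gives a zero mask (exactly plain
EMD — asserted in tests), an estimated f_z at or above Nyquist is clamped
to 0.45·fs with a warning, and loss of extrema in a masked signal falls
back to the plain IMF with a logged notice.

## Features

* **Energy** E = Σ h(n)².
* **Morphological**: AA = max|x| (peak absolute amplitude — the literal
  definition; a `aa_as_area` flag switches to Σ|x| for users who prefer an
  area reading), PA and NA the positive/negative parts of the sum,
  TT = PA + NA and TAA = PA + |NA| (exact identities, asserted on random
  inputs).
* **Fuzzy approximate entropy**: templates are the sliding windows of
  length m with their own mean removed; pair distance is Chebyshev; the
  similarity degree of a pair is the fuzzy membership exp(−dⁿ/r); each
  template's degree is its mean similarity to all other templates;
  Φᵐ is the mean log degree and FAP = Φᵐ − Φᵐ⁺¹. Defaults m = 2,
  n = 2, r = 0.2·SD(signal) (relative mode). A constant signal scores
  exactly 0. Under amplitude scaling with relative r the value changes
  smoothly but is *not* invariant (d² and r scale differently); no
  invariance is claimed. The vectorized implementation is pinned to an
  independent brute-force double-loop reference at 1e−12 on all short
  signals in the suite. An alternative normalization of the similarity
  degree by a constant count rather than by the membership sum admits no
  consistent reading and is not implemented.
* **AR coefficients**: Burg's method (statsmodels), order 7 by default,
  mean removed, sign convention X(t) = Σ a(i)X(t−i) + e(t) — verified by
  simulate-and-recover tests (AR(2) truth ±0.03 at n = 20 000).

Features are computed **per IMF** (first K = 3 per channel). Where a
decomposition yields fewer IMFs the remaining slots are zero; a channel
whose decomposition fails entirely is zero-filled with a logged warning.
A `method="raw"` mode computes the same families on the raw channel.

## Network

Architecture default: one hidden layer of 10 units, tansig everywhere,
one-hot targets in {−1, +1} matching the tansig range. Weights and biases
initialize uniform(−0.5, +0.5) under the training seed. Training is
full-batch: the per-sample steepest-descent steps are accumulated over an
epoch and applied once — deterministic and consistent with stopping on the
epoch MSE against the error goal (default 10⁻², configurable through the
Table-style experiment axes: error goal, transfer function, normalization
on/off). An online (per-sample) mode exists behind a flag. Default
learning rate α = 10⁻³ for the summed batch step; divergence (non-finite
values) raises an error naming the epoch. The −2 factor in the output
sensitivity makes the assembled quantity the exact gradient of the summed
squared error; the tests verify this against central finite differences at
1e−5 relative tolerance across architectures and transfer functions.

Before the network, each feature column is affinely rescaled onto [−1, +1]
using the *training* split's extremes (test columns get the same map;
constant columns map to 0). Raw energies span orders of magnitude and
would saturate a sigmoidal layer; fitting the map on the training split
only keeps the test set untouched by training.

## Synthetic data

`gen_signal` renders sums of tones, AM tones, linear chirps, intermittent
gated bursts and AR background noise, keeping every component's
ground-truth trace for oracle comparisons. Bursts are rectangular-gated
tones with 10-sample raised-cosine edges (avoiding envelope ringing
unrelated to mode mixing), placed randomly without overlap to a target
duty fraction. AR noise filters unit-variance Gaussian innovations through
the AR recursion, discards a 10×-order burn-in, and is rescaled so its
sample standard deviation equals the requested amplitude.

`gen_mi_trials` emulates the structure of a 4-class motor-imagery
experiment: each class sets the amplitudes of a mu-band tone (10 Hz ± 1 Hz
jitter per trial; band 8–12 Hz) and a beta-band tone (22 ± 1 Hz; band
18–26 Hz) over AR(1) noise (coefficient 0.9, std 0.5 — a lowpass-heavy
background). Channels share the class tones with ±20% gain variation over
independent noise; channel count is a free parameter (default 3). Phases
are random per trial; label balance is exact; everything is bit-identical
under the seed.

Study conditions used by the tests: the *strong-effect* table
[[2.0, 0.5], [0.5, 2.0], [2.0, 2.0], [0.5, 0.5]] (mu, beta amplitude per
class) and the *null* table of identical rows. The end-to-end checks use
100 trials (25 per class), 3 channels, 3 s at 250 Hz: the strong-effect
set must classify at ≥ 95% held out, the null set must stay at chance
(95% binomial interval containing 1/4).

What this generator does **not** emulate: volume conduction and electrode
geometry, event-related (de)synchronization time courses, 1/f spectra
beyond AR(1), ocular/muscle artifacts, non-stationarity across a session.
Passing tests therefore demonstrate correctness of the algorithms and
sensitivity to band-power class structure — not performance on real EEG.

## Known limitations

* EMD boundary effects remain visible in the outer ~10% of samples;
  all quantitative oracles deliberately exclude them.
* The mask-frequency estimate degrades when IMF1 is noise-dominated; the
  Nyquist clamp and zero-mask fallback keep the decomposition defined but
  not necessarily better than plain EMD there.
* Mu (10 Hz) and beta (22 Hz) tones of comparable amplitude sit within one
  octave-ish scale ratio, so the first IMF carries whichever band
  dominates a trial rather than always the beta band; the classifier
  compensates because AR and entropy features encode the dominant
  frequency, but per-IMF band attribution should not be assumed.
* Plain steepest descent with a fixed rate: no momentum or adaptive
  schedule; convergence on hard problems (e.g. XOR in online mode) is
  seed- and rate-sensitive.
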