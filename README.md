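# memdbci

Masking empirical mode decomposition (masking EMD) feature extraction and a
from-scratch feed-forward back-propagation neural network (FFBPNN) for
motor-imagery EEG classification — with a seeded synthetic trial generator,
so the entire chain is testable on any machine without external recordings.

## Who this is for

Brain–computer-interface and EEG signal-processing researchers who want a
transparent, fully tested reference implementation of the masking-EMD
classification pipeline: min–max normalization → masking EMD → per-IMF
features (energy, morphology, fuzzy approximate entropy, AR coefficients) →
back-propagation network → confusion-matrix evaluation.

## The method

**EMD** decomposes a signal x(n) into intrinsic mode functions (IMFs) by
sifting: subtract the mean of the cubic-spline envelopes through the maxima
and minima until the Cauchy criterion SD = Σ(h_prev−h_new)²/Σh_prev² < 0.2
is met, then repeat on the residue. Intermittent oscillations cause *mode
mixing* — one IMF carrying widely different timescales.

**Masking EMD** mitigates this by a masking sinusoid z(n) built from the
Hilbert statistics of the plain first IMF, with instantaneous amplitude
a(i) and frequency f(i):

```
a_z = (1.6 / N) · Σᵢ a(i)
f_z = Σᵢ a(i) f(i)² / Σᵢ a(i) f(i)          (amplitude-weighted mean frequency)
z(n) = a_z · sin(2π f_z n / fs)
y(n) = (IMF1[x + z] + IMF1[x − z]) / 2       (the mask cancels in the average)
```

**Features** per IMF: energy E = Σ|h(n)|²; morphological AA = max|x|,
PA = Σ½(x+|x|), NA = Σ½(x−|x|), TT = PA+NA, TAA = PA+|NA|; fuzzy
approximate entropy FAP(m,n,r,N) = Φᵐ − Φᵐ⁺¹ with fuzzy membership
exp(−dᵢⱼⁿ/r) of Chebyshev template distances; and order-7 Burg AR
coefficients of X(t) = Σ a(i)X(t−i) + e(t).

**Classifier**: a feed-forward network trained by back-propagation of
sensitivities,

```
aⁿ⁺¹ = fⁿ⁺¹(Wⁿ⁺¹ aⁿ + bⁿ⁺¹)
s^L  = −2 F^L(x^L)(t − a),   sⁿ = Fⁿ(xⁿ)(Wⁿ⁺¹)ᵀ sⁿ⁺¹
Wⁿ ← Wⁿ − α sⁿ (aⁿ⁻¹)ᵀ,      bⁿ ← bⁿ − α sⁿ
```

with purelin / logsig / tansig transfer functions and an MSE error goal as
the stopping rule. Gradients are verified against finite differences in
the test suite.

## Worked example

```python
import numpy as np
from memdbci.synth import gen_signal, gen_mi_trials, ComponentSpec, STRONG_EFFECT
from memdbci.emd import Signal, extract_imf
from memdbci.memd import memd_extract_imf
from memdbci.evaluate import run_pipeline, PipelineConfig

# 1) mode mixing: a 2 Hz tone with intermittent 25 Hz bursts
gs = gen_signal([ComponentSpec("tone", 1.0, 2.0),
                 ComponentSpec("intermittent_burst", 0.4, 25.0, burst_duty=0.25)],
                n=2000, fs=250.0, seed=0)
burst = gs.traces[1]                       # ground-truth burst component
plain, _ = extract_imf(gs.samples)
masked, mask = memd_extract_imf(Signal(gs.samples, 250.0))
print(round(np.corrcoef(plain, burst)[0, 1], 3),
      round(np.corrcoef(masked, burst)[0, 1], 3),
      round(mask.a_z, 2), round(mask.f_z, 1))
# 0.231 0.914 1.12 17.7

# 2) end-to-end classification of 100 synthetic 4-class motor-imagery trials
data = gen_mi_trials(25, 4, class_effect=STRONG_EFFECT, seed=42)
report = run_pipeline(PipelineConfig(seed=1), data)
print(report["accuracy"], report["stopped_by"], report["epochs_run"])
# 1.0 goal 104
```

The first block shows the point of the mask: plain EMD's first IMF
correlates 0.23 with the true intermittent burst (it mixes the 2 Hz tone
in), while the masked IMF reaches 0.91; the mask parameters (amplitude
1.12, frequency 17.7 Hz) were estimated from the data. The second block
runs the full pipeline — normalization, masking EMD, all four feature
families, network training to the 10⁻² MSE goal (reached after 104
epochs) — and classifies all 30 held-out trials correctly.

The same stages are scriptable from a shell:

```
memdbci simulate --trials-per-class 25 --classes 4 --out trials/
memdbci extract  --in trials/ --out features.csv --imfs 3 --method memd
memdbci train    --features features.csv --model model.json
memdbci evaluate --data trials/ --report out/
```

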