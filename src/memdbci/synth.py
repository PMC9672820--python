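"""Seeded synthetic test signals and motor-imagery-like trial sets.

Every downstream stage (decomposition, feature extraction, classification)
is exercised on signals generated here, so no external recordings are
needed. Two levels:

* :func:`gen_signal` renders a sum of elementary components — tones,
  AM tones, linear chirps, intermittent gated bursts (the classic
  mode-mixing provocation), and autoregressive colored noise — and keeps
  each component's ground-truth trace so decomposition quality can be
  measured by correlation against truth.
* :func:`gen_mi_trials` builds labeled multi-channel trial sets emulating
  the structure of a motor-imagery EEG experiment: each class modulates
  the amplitudes of a mu-band (~10 Hz) and a beta-band (~22 Hz)
  oscillation riding on AR background noise. Label balance is exact.

Everything is deterministic under the seed: the same arguments and seed
give bit-identical output.

These are statistical stand-ins, not forward-modeled EEG: no electrode
geometry, no artifacts, no 1/f spectrum beyond what the AR noise gives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .exceptions import InvalidSpecError, TooShortSignalError

__all__ = [
    "ComponentSpec",
    "GeneratedSignal",
    "TrialSet",
    "gen_signal",
    "gen_mi_trials",
]

_KINDS = {"tone", "am_tone", "chirp", "intermittent_burst", "ar_noise"}


@dataclass
class ComponentSpec:
    """One additive component of a synthetic signal.

    ``frequency`` is a scalar in Hz for tones and bursts, a ``(f0, f1)``
    pair for chirps, and unused for ``ar_noise``. For ``ar_noise`` the
    ``amplitude`` is the target sample standard deviation after filtering.
    """

    kind: str
    amplitude: float = 1.0
    frequency: float | tuple[float, float] | None = None
    phase: float = 0.0
    mod_freq: float = 1.0  # am_tone: modulation frequency, Hz
    mod_depth: float = 0.5  # am_tone: modulation depth in [0, 1]
    burst_duty: float | None = None  # intermittent_burst: on-fraction
    burst_len: float = 0.4  # intermittent_burst: single burst length, s
    ar_coeffs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidSpecError(f"unknown component kind {self.kind!r}")
        if self.amplitude < 0:
            raise InvalidSpecError("amplitude must be >= 0")
        if self.kind == "intermittent_burst":
            if self.burst_duty is None or not (0 < self.burst_duty <= 1):
                raise InvalidSpecError("burst_duty must be in (0, 1]")
        if self.kind == "ar_noise" and not self.ar_coeffs:
            raise InvalidSpecError("ar_noise needs ar_coeffs")

    def max_frequency(self) -> float:
        if self.kind == "ar_noise":
            return 0.0
        if self.frequency is None:
            raise InvalidSpecError(f"{self.kind} component needs a frequency")
        if isinstance(self.frequency, tuple):
            return max(self.frequency)
        return float(self.frequency)


@dataclass
class GeneratedSignal:
    """Mixed samples plus the ground-truth trace of every component."""

    samples: np.ndarray
    fs: float
    traces: list[np.ndarray]
    specs: list[ComponentSpec]


@dataclass
class TrialSet:
    """Labeled multi-channel trials sharing one sampling rate.

    ``trials[i]`` is a channels x samples matrix; ``labels[i]`` is its
    integer class in ``0..K-1``. ``meta`` records the generator arguments
    and seed so any set can be regenerated bit-identically.
    """

    trials: list[np.ndarray]
    labels: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def __len__(self) -> int:
        return len(self.trials)


def _raised_cosine_gate(n: int, starts: np.ndarray, length: int, edge: int = 10) -> np.ndarray:
    """0/1 gate with half-Hann ramps of ``edge`` samples at burst edges."""
    gate = np.zeros(n)
    edge = min(edge, length // 2)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, edge + 1) / (edge + 1)))
    for s in starts:
        e = min(s + length, n)
        gate[s:e] = 1.0
        gate[s : s + edge] = ramp[: e - s]
        if e - s >= edge:
            gate[e - edge : e] = ramp[::-1][: edge]
    return gate


def _render(spec: ComponentSpec, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    if spec.kind == "tone":
        return spec.amplitude * np.sin(2 * np.pi * spec.frequency * t + spec.phase)
    if spec.kind == "am_tone":
        env = 1.0 + spec.mod_depth * np.sin(2 * np.pi * spec.mod_freq * t)
        return spec.amplitude * env * np.sin(2 * np.pi * spec.frequency * t + spec.phase)
    if spec.kind == "chirp":
        f0, f1 = spec.frequency
        # linear instantaneous frequency f0 -> f1 over the record
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) * t**2 / t[-1])
        return spec.amplitude * np.sin(phase + spec.phase)
    if spec.kind == "intermittent_burst":
        length = max(2, int(round(spec.burst_len * fs)))
        n_bursts = max(1, int(round(spec.burst_duty * n / length)))
        # rejection-sample non-overlapping starts (margin one burst length)
        starts: list[int] = []
        for _ in range(1000):
            if len(starts) == n_bursts:
                break
            c = int(rng.integers(0, max(1, n - length)))
            if all(abs(c - s) >= 2 * length for s in starts):
                starts.append(c)
        gate = _raised_cosine_gate(n, np.array(sorted(starts)), length)
        return spec.amplitude * gate * np.sin(2 * np.pi * spec.frequency * t + spec.phase)
    if spec.kind == "ar_noise":
        order = len(spec.ar_coeffs)
        burn = 10 * order
        e = rng.standard_normal(n + burn)
        a = np.concatenate(([1.0], -np.asarray(spec.ar_coeffs)))
        y = lfilter([1.0], a, e)[burn:]
        sd = y.std()
        if sd > 0:
            y = y / sd * spec.amplitude
        return y
    raise InvalidSpecError(spec.kind)  # pragma: no cover


def gen_signal(
    components: list[ComponentSpec], n: int, fs: float, seed: int
) -> GeneratedSignal:
    """Render and sum ``components`` into one ``n``-sample signal at ``fs`` Hz.

    Each stochastic component draws from its own child stream of ``seed``,
    so adding a component does not perturb the others' realizations.
    """
    if n < 16:
        raise TooShortSignalError(f"need n >= 16, got {n}")
    for spec in components:
        if spec.max_frequency() >= fs / 2:
            raise InvalidSpecError(
                f"component frequency {spec.max_frequency()} Hz >= Nyquist ({fs / 2} Hz)"
            )
    streams = np.random.SeedSequence(seed).spawn(max(len(components), 1))
    traces = [
        _render(spec, n, fs, np.random.default_rng(ss))
        for spec, ss in zip(components, streams)
    ]
    samples = np.sum(traces, axis=0) if traces else np.zeros(n)
    return GeneratedSignal(samples=samples, fs=float(fs), traces=traces, specs=list(components))


# class-conditional (mu, beta) tone amplitudes: the study conditions for the
# strong-effect and null-effect synthetic experiments
STRONG_EFFECT = np.array([[2.0, 0.5], [0.5, 2.0], [2.0, 2.0], [0.5, 0.5]])
NULL_EFFECT = np.ones((4, 2))

MU_FREQ = 10.0  # Hz, center of the mu band (8-12 Hz)
BETA_FREQ = 22.0  # Hz, center of the beta band (18-26 Hz)


def gen_mi_trials(
    n_trials_per_class: int,
    n_classes: int = 4,
    n_channels: int = 3,
    fs: float = 250.0,
    duration: float = 3.0,
    class_effect: np.ndarray | None = None,
    noise_ar: tuple[float, ...] = (0.9,),
    noise_std: float = 0.5,
    seed: int = 0,
    freq_jitter: float = 1.0,
) -> TrialSet:
    """Generate a balanced labeled motor-imagery-like trial set.

    ``class_effect`` is a K x 2 table of (mu, beta) tone amplitudes per
    class; identical rows give a null set on which any classifier can only
    reach chance. Tone frequencies are jittered per trial by up to
    ``freq_jitter`` Hz within their band and phases are random, so trials
    of one class are realizations, not copies. Channels of one trial share
    the class tones (with small amplitude variation) over independent AR
    noise.
    """
    if n_classes < 2:
        raise InvalidSpecError("need at least 2 classes")
    if class_effect is None:
        class_effect = STRONG_EFFECT[:n_classes]
    class_effect = np.asarray(class_effect, dtype=float)
    if class_effect.shape[0] != n_classes:
        raise InvalidSpecError(
            f"class_effect has {class_effect.shape[0]} rows for {n_classes} classes"
        )
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trials: list[np.ndarray] = []
    labels: list[int] = []
    for k in range(n_classes):
        mu_amp, beta_amp = class_effect[k]
        for _ in range(n_trials_per_class):
            f_mu = MU_FREQ + rng.uniform(-freq_jitter, freq_jitter)
            f_beta = BETA_FREQ + rng.uniform(-freq_jitter, freq_jitter)
            ph_mu, ph_beta = rng.uniform(0, 2 * np.pi, size=2)
            trial = np.empty((n_channels, n))
            for c in range(n_channels):
                gain = rng.uniform(0.8, 1.2)
                comp = [
                    ComponentSpec("tone", gain * mu_amp, f_mu, phase=ph_mu),
                    ComponentSpec("tone", gain * beta_amp, f_beta, phase=ph_beta),
                    ComponentSpec("ar_noise", noise_std, ar_coeffs=tuple(noise_ar)),
                ]
                gs = gen_signal(comp, n, fs, seed=int(rng.integers(2**31)))
                trial[c] = gs.samples
            trials.append(trial)
            labels.append(k)
    # shuffle trial order so classes are interleaved as in a real session
    perm = rng.permutation(len(trials))
    trials = [trials[i] for i in perm]
    labels_arr = np.asarray(labels)[perm]
    meta = {
        "n_trials_per_class": n_trials_per_class,
        "n_classes": n_classes,
        "n_channels": n_channels,
        "fs": fs,
        "duration": duration,
        "class_effect": class_effect.tolist(),
        "noise_ar": list(noise_ar),
        "noise_std": noise_std,
        "seed": seed,
        "freq_jitter": freq_jitter,
    }
    return TrialSet(trials=trials, labels=labels_arr, fs=float(fs), meta=meta)
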