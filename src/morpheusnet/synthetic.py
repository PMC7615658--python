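"""Synthetic single-channel EEG with stage-dependent spectra and Markov hypnograms.

The generator reproduces the spectral signatures sleep scorers rely on —
alpha in relaxed wake, theta in N1, spindle bursts and K-complexes in N2,
high-amplitude slow delta in N3, low-amplitude mixed-frequency activity in
REM — on top of a 1/f broadband background.  Stage sequences come from a
first-order Markov chain with strongly diagonal transitions, so epoch
context carries real information for a sequence learner, as it does in a
night of human sleep.

This is a band-power caricature, not a physiological simulation: it has no
artifacts, no EMG contamination, no inter-subject electrode variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import EPOCH_SAMPLES, N_CLASSES, STAGE_NAMES, TARGET_FS, EpochedRecording


@dataclass
class Oscillation:
    """A narrow-band component: center frequency, band width, amplitude (µV)."""

    freq: float
    bandwidth: float
    amplitude: float
    burst_len_s: tuple[float, float] | None = None  # None = tonic
    burst_rate_per_epoch: float = 0.0

    def __post_init__(self):
        if not 0 < self.freq < TARGET_FS / 2:
            raise ValueError(f"frequency {self.freq} outside (0, {TARGET_FS / 2}) Hz")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class StageSignalModel:
    """Per-stage oscillatory components plus broadband background."""

    components: dict[str, list[Oscillation]]
    noise_exponent: dict[str, float]
    noise_amplitude: dict[str, float]  # µV rms of the broadband background
    amplitude_scale: float = 1.0

    def __post_init__(self):
        for table in (self.components, self.noise_exponent, self.noise_amplitude):
            if sorted(table) != sorted(STAGE_NAMES):
                raise ValueError("stage model must define exactly the 5 AASM stages")


def default_stage_models() -> StageSignalModel:
    """Packaged stage signatures (amplitudes in µV, frequencies in Hz)."""
    c = {
        "W": [Oscillation(10.0, 2.0, 12.0)],  # alpha
        "N1": [Oscillation(6.0, 1.5, 18.0)],  # theta
        "N2": [
            Oscillation(6.0, 1.5, 16.0),  # theta background
            Oscillation(13.5, 1.5, 30.0, burst_len_s=(0.5, 1.0), burst_rate_per_epoch=4.0),  # spindles
            Oscillation(0.8, 0.4, 60.0, burst_len_s=(0.8, 1.2), burst_rate_per_epoch=1.0),  # K-complex
        ],
        "N3": [Oscillation(1.0, 0.8, 80.0)],  # slow delta
        "REM": [Oscillation(4.5, 1.5, 8.0), Oscillation(20.0, 4.0, 4.0)],  # mixed low-amp
    }
    noise_exp = {"W": 0.8, "N1": 1.0, "N2": 1.0, "N3": 1.3, "REM": 1.0}
    noise_amp = {"W": 14.0, "N1": 8.0, "N2": 8.0, "N3": 10.0, "REM": 7.0}
    return StageSignalModel(c, noise_exp, noise_amp)


@dataclass
class TransitionModel:
    """Initial distribution and 5x5 row-stochastic matrix at 30-s resolution."""

    initial: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.initial.shape != (N_CLASSES,) or self.matrix.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("transition model must be over the 5 stages")
        if np.any(self.initial < 0) or np.any(self.matrix < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.initial.sum() - 1) > 1e-9 or np.any(np.abs(self.matrix.sum(1) - 1) > 1e-9):
            raise ValueError("initial distribution and matrix rows must sum to 1")


def default_transition_model() -> TransitionModel:
    """Strongly diagonal chain (self-transition >= 0.85) resembling real
    hypnogram bout structure: W->N1->N2->{N3, REM} with occasional arousals."""
    m = np.array(
        [
            # W     N1    N2    N3    REM
            [0.88, 0.10, 0.02, 0.00, 0.00],  # W
            [0.05, 0.85, 0.09, 0.00, 0.01],  # N1
            [0.01, 0.03, 0.88, 0.05, 0.03],  # N2
            [0.01, 0.00, 0.07, 0.91, 0.01],  # N3
            [0.02, 0.03, 0.04, 0.00, 0.91],  # REM
        ]
    )
    init = np.array([0.6, 0.3, 0.1, 0.0, 0.0])
    return TransitionModel(init, m)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, unit rms."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / TARGET_FS)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / (x.std() + 1e-12)


def generate_epoch(stage: int, model: StageSignalModel, seed: int) -> np.ndarray:
    """One 30-s, 100-Hz epoch (3000x1 µV) for a stage; deterministic in seed."""
    name = STAGE_NAMES[int(stage)]
    rng = np.random.default_rng(seed)
    t = np.arange(EPOCH_SAMPLES) / TARGET_FS
    x = model.noise_amplitude[name] * _pink_noise(rng, EPOCH_SAMPLES, model.noise_exponent[name])
    for osc in model.components[name]:
        f = osc.freq + rng.uniform(-0.5, 0.5) * osc.bandwidth
        phase = rng.uniform(0, 2 * np.pi)
        wave = osc.amplitude * np.sin(2 * np.pi * f * t + phase)
        if osc.burst_len_s is None:
            x += wave
        else:
            n_bursts = rng.poisson(osc.burst_rate_per_epoch)
            env = np.zeros(EPOCH_SAMPLES)
            for _ in range(n_bursts):
                dur = rng.uniform(*osc.burst_len_s)
                n = int(dur * TARGET_FS)
                start = rng.integers(0, max(1, EPOCH_SAMPLES - n))
                env[start : start + n] = np.maximum(env[start : start + n], np.hanning(n))
            x += wave * env
    return (model.amplitude_scale * x).astype(np.float32)[:, None]


def generate_hypnogram(n_epochs: int, tm: TransitionModel, seed: int) -> np.ndarray:
    """Markov-sampled stage sequence; deterministic given the seed."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_epochs, dtype=np.int64)
    labels[0] = rng.choice(N_CLASSES, p=tm.initial)
    for i in range(1, n_epochs):
        labels[i] = rng.choice(N_CLASSES, p=tm.matrix[labels[i - 1]])
    return labels


def generate_recording(
    n_epochs: int,
    seed: int,
    model: StageSignalModel | None = None,
    tm: TransitionModel | None = None,
    subject_id: str = "S000",
) -> EpochedRecording:
    """One subject: a Markov hypnogram and an epoch per label."""
    model = model or default_stage_models()
    tm = tm or default_transition_model()
    ss = np.random.SeedSequence(seed)
    hyp_seed, epoch_entropy = ss.spawn(2)
    labels = generate_hypnogram(n_epochs, tm, hyp_seed.generate_state(1)[0] % (2**31))
    epoch_seeds = epoch_entropy.generate_state(n_epochs) % (2**31)
    epochs = np.stack(
        [generate_epoch(lab, model, int(s)) for lab, s in zip(labels, epoch_seeds)]
    )
    return EpochedRecording(epochs, labels, subject_id=subject_id, channel="synthetic Fpz-Cz")


def generate_dataset(
    n_subjects: int,
    epochs_per_subject: int,
    seed: int,
    model: StageSignalModel | None = None,
    tm: TransitionModel | None = None,
) -> list[EpochedRecording]:
    """Independent subjects with ids S000... from one master seed."""
    if n_subjects < 1 or epochs_per_subject < 1:
        raise ValueError("counts must be positive")
    subject_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    return [
        generate_recording(
            epochs_per_subject, int(s), model=model, tm=tm, subject_id=f"S{i:03d}"
        )
        for i, s in enumerate(subject_seeds)
    ]
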