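"""Polysomnography I/O: EDF recordings, hypnograms, epoching and label maps.

The pipeline's in-memory contract is fixed: 30-second epochs at 100 Hz
(3000 samples, one EEG channel) with five AASM stage labels
W=0, N1=1, N2=2, N3=3, REM=4.  Recordings scored under the older
R&K standard are mapped onto this vocabulary, merging N4 into N3.

Reading uses :mod:`mne`; writing uses a small built-in EDF encoder
(16-bit, one-second data records) sufficient for single-channel fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

EPOCH_LEN_S = 30
TARGET_FS = 100
EPOCH_SAMPLES = EPOCH_LEN_S * TARGET_FS  # 3000

#: integer codes of the five AASM stages
STAGES = {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4}
STAGE_NAMES = ["W", "N1", "N2", "N3", "REM"]
N_CLASSES = 5

#: sentinel returned by map_labels for epochs to drop
EXCLUDE = -1

# R&K six-stage vocabulary -> AASM five-stage codes; N4 merges into N3.
_RK_MAP = {
    "WAKE": STAGES["W"],
    "W": STAGES["W"],
    "N1": STAGES["N1"],
    "N2": STAGES["N2"],
    "N3": STAGES["N3"],
    "N4": STAGES["N3"],
    "REM": STAGES["REM"],
    "R": STAGES["REM"],
    "S1": STAGES["N1"],
    "S2": STAGES["N2"],
    "S3": STAGES["N3"],
    "S4": STAGES["N3"],
}
_AASM_MAP = {
    "W": STAGES["W"],
    "WAKE": STAGES["W"],
    "N1": STAGES["N1"],
    "N2": STAGES["N2"],
    "N3": STAGES["N3"],
    "REM": STAGES["REM"],
    "R": STAGES["REM"],
}
_EXCLUDE_SET = {"MOVEMENT", "UNKNOWN", "UNSCORED", "?", "ARTIFACT"}

# Sleep-EDF style annotation strings normalised to the bare stage token.
_ANNOTATION_PREFIXES = ("SLEEP STAGE ", "STAGE ")


@dataclass
class RawRecording:
    """A single EEG channel with its native rate and stage annotations."""

    signal: np.ndarray  # (n_samples,), µV
    fs: float
    channel: str
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        onsets = [a[0] for a in self.annotations]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("annotation onsets must be non-decreasing")


@dataclass
class EpochedRecording:
    """Stack of labelled 30-s, 100-Hz single-channel epochs."""

    epochs: np.ndarray  # (n_epochs, 3000, 1), µV
    labels: np.ndarray  # (n_epochs,), codes 0-4
    subject_id: str = ""
    channel: str = ""
    epoch_len_s: int = EPOCH_LEN_S
    fs: int = TARGET_FS

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim == 2:
            self.epochs = self.epochs[:, :, None]
        if self.epochs.shape[1] != self.epoch_len_s * self.fs:
            raise ValueError(
                f"epochs have {self.epochs.shape[1]} samples, expected "
                f"{self.epoch_len_s * self.fs}"
            )
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels and epochs length mismatch")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError("labels outside the 5 AASM classes")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


def map_labels(raw_label: str, scheme: str = "RK") -> int:
    """Map a hypnogram label string to a stage code or :data:`EXCLUDE`.

    ``scheme='RK'`` merges N4 (equivalently S4) into N3; ``scheme='AASM'``
    is the identity on the five stages.  MOVEMENT/UNKNOWN/unscored labels
    map to :data:`EXCLUDE`.
    """
    token = raw_label.strip().upper()
    for pref in _ANNOTATION_PREFIXES:
        if token.startswith(pref):
            token = token[len(pref) :].strip()
    if token in _EXCLUDE_SET:
        return EXCLUDE
    table = {"RK": _RK_MAP, "AASM": _AASM_MAP}.get(scheme.upper())
    if table is None:
        raise ValueError(f"unknown labelling scheme {scheme!r}")
    if token not in table:
        raise ValueError(f"unrecognized stage label {raw_label!r} under scheme {scheme}")
    return table[token]


def resample_signal(rec: RawRecording, target_fs: float) -> RawRecording:
    """Polyphase resampling to ``target_fs``; identity when rates match."""
    if target_fs <= 0:
        raise ValueError(f"target rate must be positive, got {target_fs}")
    if rec.fs == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = resample_poly(rec.signal, frac.numerator, frac.denominator)
    n_expected = round(len(rec.signal) * target_fs / rec.fs)
    out = out[:n_expected]
    if len(out) < n_expected:
        out = np.pad(out, (0, n_expected - len(out)))
    return RawRecording(out, target_fs, rec.channel, rec.annotations)


def _label_at(annotations, t: float) -> str | None:
    """Annotation label covering time t; an annotation starting at t wins."""
    hit = None
    for onset, duration, label in annotations:
        if onset == t:
            return label
        if onset <= t < onset + duration:
            hit = label
    return hit


def segment_epochs(
    rec: RawRecording,
    hypnogram: list[tuple[float, float, str]] | None = None,
    scheme: str = "RK",
    subject_id: str = "",
) -> EpochedRecording:
    """Cut a 100-Hz recording into labelled non-overlapping 30-s epochs.

    Each epoch takes the label of the annotation covering its onset;
    a trailing partial window is dropped and excluded labels are removed.
    """
    if rec.fs != TARGET_FS:
        raise ValueError(f"expected a {TARGET_FS}-Hz recording, got {rec.fs} Hz; resample first")
    annotations = hypnogram if hypnogram is not None else rec.annotations
    if not annotations:
        raise ValueError("empty hypnogram: no stage annotations to label epochs with")
    n_epochs = len(rec.signal) // EPOCH_SAMPLES
    if n_epochs == 0:
        raise ValueError("signal shorter than one 30-s epoch")
    epochs, labels = [], []
    for i in range(n_epochs):
        raw = _label_at(annotations, i * EPOCH_LEN_S)
        if raw is None:
            continue
        code = map_labels(raw, scheme)
        if code == EXCLUDE:
            continue
        epochs.append(rec.signal[i * EPOCH_SAMPLES : (i + 1) * EPOCH_SAMPLES])
        labels.append(code)
    if not epochs:
        raise ValueError("no scorable epochs after exclusion")
    return EpochedRecording(
        np.stack(epochs)[:, :, None], np.array(labels), subject_id=subject_id, channel=rec.channel
    )


def trim_evaluation_window(rec: EpochedRecording, mode: str = "none") -> EpochedRecording:
    """Restrict a recording to the evaluation window around sleep.

    ``pm30`` keeps from 30 min before the first non-wake epoch to 30 min
    after the last; ``in_bed`` keeps first to last non-wake epoch
    inclusive; ``none`` is the identity.
    """
    if mode == "none":
        return rec
    if mode not in ("pm30", "in_bed"):
        raise ValueError(f"unknown trim mode {mode!r}")
    non_wake = np.flatnonzero(rec.labels != STAGES["W"])
    if len(non_wake) == 0:
        raise ValueError("recording is all wake; cannot trim to the sleep period")
    first, last = int(non_wake[0]), int(non_wake[-1])
    if mode == "pm30":
        margin = (30 * 60) // rec.epoch_len_s  # 60 epochs
        lo, hi = max(0, first - margin), min(rec.n_epochs, last + margin + 1)
    else:
        lo, hi = first, last + 1
    return EpochedRecording(
        rec.epochs[lo:hi], rec.labels[lo:hi], subject_id=rec.subject_id, channel=rec.channel
    )


# ---------------------------------------------------------------------------
# EDF reading (mne) and a minimal EDF writer
# ---------------------------------------------------------------------------

def read_psg_edf(path: str | Path, channel: str) -> RawRecording:
    """Read one EEG channel (case-insensitive match) from an EDF/EDF+ file."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface a format error
        raise ValueError(f"could not parse {path} as EDF: {exc}") from exc
    match = [ch for ch in raw.ch_names if ch.lower() == channel.lower()]
    if not match:
        raise KeyError(
            f"channel {channel!r} not in {path.name}; available: {', '.join(raw.ch_names)}"
        )
    raw = raw.pick(match).load_data(verbose="error")
    # mne scales EEG channels to volts; the pipeline works in µV
    signal = raw.get_data()[0] * 1e6
    annotations = [
        (float(on), float(du), str(de))
        for on, du, de in zip(raw.annotations.onset, raw.annotations.duration, raw.annotations.description)
    ]
    return RawRecording(signal, float(raw.info["sfreq"]), match[0], annotations)


def write_edf(path: str | Path, signal: np.ndarray, fs: int, channel: str = "EEG Fpz-Cz") -> None:
    """Write a single-channel EDF file (16-bit, 1-s records, physical µV).

    The signal length must be a whole number of seconds.  Intended for
    fixtures and synthetic recordings; not a general-purpose EDF+ encoder.
    """
    signal = np.asarray(signal, dtype=np.float64)
    fs = int(fs)
    if len(signal) % fs:
        raise ValueError("signal length must be a whole number of 1-s records")
    n_records = len(signal) // fs
    phys_max = max(1.0, float(np.abs(signal).max()) * 1.000001)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    def f(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate 01-JAN-2000 X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 + 256), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),
            f("1", 4),
            # per-signal fields
            f(channel, 16),
            f("", 80),
            f("uV", 8),
            f(f"{phys_min:.6g}", 8),
            f(f"{phys_max:.6g}", 8),
            f(str(dig_min), 8),
            f(str(dig_max), 8),
            f("", 80),
            f(str(fs), 8),
            f("", 32),
        ]
    )
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((signal - phys_min) * scale + dig_min).astype("<i2")
    Path(path).write_bytes(header + digital.tobytes())


def write_hypnogram_csv(path: str | Path, labels: np.ndarray) -> None:
    """One stage name per line, one line per 30-s epoch."""
    Path(path).write_text("\n".join(STAGE_NAMES[int(c)] for c in labels) + "\n")


def read_hypnogram_csv(path: str | Path) -> list[tuple[float, float, str]]:
    """Read a one-label-per-30-s hypnogram into annotation triples."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty hypnogram file: {path}")
    return [(i * EPOCH_LEN_S, float(EPOCH_LEN_S), lab) for i, lab in enumerate(lines)]


def save_epoched(rec: EpochedRecording, path: str | Path) -> None:
    """Persist epochs + labels as npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), epochs=rec.epochs, labels=rec.labels)
    meta = {
        "subject_id": rec.subject_id,
        "channel": rec.channel,
        "epoch_len_s": rec.epoch_len_s,
        "fs": rec.fs,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epoched(path: str | Path) -> EpochedRecording:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        epochs, labels = z["epochs"], z["labels"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochedRecording(epochs, labels, subject_id=meta["subject_id"], channel=meta["channel"])
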