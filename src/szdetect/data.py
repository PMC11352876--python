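"""Reading Bonn-format EEG segments and generating synthetic look-alike datasets.

A Bonn segment is a plain ASCII file with one amplitude value per line
(4097 samples at 173.61 Hz in the published recordings).  Class labels are
inferred from the set directory: ``E`` holds seizure activity, ``D`` holds
seizure-free intracranial recordings, and the remaining sets load as
unlabeled.

The synthetic generator emits single-channel segments with the same
geometry: a pink-noise background plus a 10 Hz rhythmic component for the
non-seizure class, and the same background plus biphasic spike-wave bursts
and an elevated 20-30 Hz band-limited component for the seizure class.  It
exists so every downstream stage of the pipeline can be exercised without
the original recordings.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DataNotFoundError, FormatError

__all__ = [
    "SEIZURE",
    "NON_SEIZURE",
    "UNLABELED",
    "BONN_FS",
    "BONN_SEGMENT_LENGTH",
    "EEGRecord",
    "SignalDataset",
    "SynthConfig",
    "read_bonn_segment",
    "load_dataset",
    "synth_dataset",
    "serialize_segment",
    "save_dataset",
    "load_saved_dataset",
]

SEIZURE = "seizure"
NON_SEIZURE = "non_seizure"
UNLABELED = "unlabeled"

#: Sampling rate (Hz) of the published Bonn recordings.
BONN_FS = 173.61
#: Samples per published Bonn segment.
BONN_SEGMENT_LENGTH = 4097

#: Set-directory -> class label map.  Sets A-C load as unlabeled.
SET_LABELS = {"E": SEIZURE, "D": NON_SEIZURE}

VALID_LABELS = frozenset({SEIZURE, NON_SEIZURE, UNLABELED})


@dataclass
class EEGRecord:
    """One fixed-rate single-channel EEG segment with a class label.

    Parameters
    ----------
    samples
        Real-valued amplitude sequence (µV).  Must be non-empty and finite.
    fs
        Sampling rate in Hz, strictly positive.
    label
        One of ``"seizure"``, ``"non_seizure"`` or ``"unlabeled"``.
    source_id
        Origin string: a file path or ``"synthetic:<seed>:<index>"``.
    """

    samples: np.ndarray
    fs: float
    label: str = UNLABELED
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ConfigurationError("EEGRecord requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("EEGRecord samples must all be finite")
        if not (self.fs > 0):
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in VALID_LABELS:
            raise ConfigurationError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    def replace(self, **changes) -> "EEGRecord":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass
class SignalDataset:
    """An ordered collection of :class:`EEGRecord` sharing one sampling rate."""

    records: list[EEGRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        rates = {r.fs for r in self.records}
        if len(rates) > 1:
            raise ConfigurationError(f"records mix sampling rates: {sorted(rates)}")

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records))

    @property
    def fs(self) -> float | None:
        return self.records[0].fs if self.records else None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices: Iterable[int]) -> "SignalDataset":
        return SignalDataset([self.records[i] for i in indices])


@dataclass
class SynthConfig:
    """Configuration for the synthetic Bonn-mimicking generator.

    ``seizure_beta_gain`` multiplies the amplitude of the seizure class's
    20-30 Hz band-limited component relative to the background scale;
    values above 1 give the seizure class strictly larger mean beta-band
    power than the non-seizure class.
    """

    n_per_class: int = 100
    n_samples: int = BONN_SEGMENT_LENGTH
    fs: float = BONN_FS
    seizure_beta_gain: float = 4.0
    spike_rate: float = 3.0
    noise_scale: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if self.n_samples < 64:
            raise ConfigurationError("n_samples must be >= 64")
        if not (self.fs > 0):
            raise ConfigurationError("fs must be positive")
        if self.seizure_beta_gain < 1:
            raise ConfigurationError("seizure_beta_gain must be >= 1")
        if self.spike_rate < 0:
            raise ConfigurationError("spike_rate must be >= 0")
        if not (self.noise_scale > 0):
            raise ConfigurationError("noise_scale must be positive")


def read_bonn_segment(path: str | Path) -> EEGRecord:
    """Parse one Bonn ASCII segment file into an :class:`EEGRecord`.

    One numeric value per line; integers and floats are both accepted and
    surrounding whitespace is ignored.  The label is inferred from the
    parent directory name (``E`` -> seizure, ``D`` -> non-seizure,
    otherwise unlabeled).

    Raises
    ------
    DataNotFoundError
        If the file does not exist.
    FormatError
        If the file is empty or contains a non-numeric line (the message
        names the offending line number).
    """
    path = Path(path)
    if not path.is_file():
        raise DataNotFoundError(f"no such segment file: {path}")
    values: list[float] = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {text!r} on line {lineno}"
                ) from None
    if not values:
        raise FormatError(f"{path}: empty segment file")
    label = SET_LABELS.get(path.parent.name.upper(), UNLABELED)
    return EEGRecord(np.array(values), fs=BONN_FS, label=label, source_id=str(path))


def load_dataset(root: str | Path, sets: Sequence[str]) -> SignalDataset:
    """Load every parseable segment from the requested Bonn set directories.

    ``root`` must contain one subdirectory per requested set letter.  Files
    within each set directory are read in sorted order so datasets are
    reproducible across filesystems.
    """
    root = Path(root)
    records: list[EEGRecord] = []
    for set_name in sets:
        set_dir = root / set_name
        if not set_dir.is_dir():
            raise DataNotFoundError(f"set directory {set_name!r} not found under {root}")
        for path in sorted(p for p in set_dir.iterdir() if p.is_file()):
            records.append(read_bonn_segment(path))
    return SignalDataset(records)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f ("pink") noise of length ``n``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    # 1/sqrt(f) amplitude shaping; leave DC untouched at the first bin scale.
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero] / freqs[nonzero][0])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-variance noise band-limited to [low, high] Hz via an FFT mask."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():  # degenerate fs; keep at least one bin
        mask[np.argmin(np.abs(freqs - 0.5 * (low + high)))] = True
    x = np.fft.irfft(spec * mask, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_wave(rng: np.random.Generator, n: int, fs: float, rate: float) -> np.ndarray:
    """Biphasic spike-wave bursts: a seeded impulse train convolved with a
    spike kernel followed by a slower half-wave."""
    expected = rate * n / fs
    n_spikes = int(rng.poisson(expected)) if expected > 0 else 0
    train = np.zeros(n)
    if n_spikes:
        idx = rng.integers(0, n, size=n_spikes)
        amps = rng.uniform(0.8, 1.2, size=n_spikes)
        np.add.at(train, idx, amps)
    # Biphasic spike (~70 ms) followed by a slow wave (~200 ms).
    t_spike = np.arange(int(0.07 * fs)) / fs
    spike = np.sin(2 * np.pi * t_spike / 0.07) * np.exp(-t_spike / 0.03)
    t_wave = np.arange(int(0.2 * fs)) / fs
    wave = -0.5 * np.sin(np.pi * t_wave / 0.2)
    kernel = np.concatenate([spike, wave])
    out = np.convolve(train, kernel)[:n]
    return out


def _synth_record(
    rng: np.random.Generator, config: SynthConfig, label: str, index: int
) -> EEGRecord:
    n, fs, scale = config.n_samples, config.fs, config.noise_scale
    x = _pink_noise(rng, n) * scale
    if label == NON_SEIZURE:
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.8, 1.2) * scale
        t = np.arange(n) / fs
        x = x + amp * np.sin(2 * np.pi * 10.0 * t + phase)
    else:
        beta_high = min(30.0, 0.45 * fs)
        beta_low = min(20.0, 0.8 * beta_high)
        x = x + config.seizure_beta_gain * scale * _band_noise(rng, n, fs, beta_low, beta_high)
        x = x + 5.0 * scale * _spike_wave(rng, n, fs, config.spike_rate)
    return EEGRecord(x, fs=fs, label=label, source_id=f"synthetic:{config.seed}:{index}")


def synth_dataset(config: SynthConfig) -> SignalDataset:
    """Generate ``2 * n_per_class`` synthetic records (non-seizure first).

    Deterministic for a fixed ``config.seed``: all randomness flows through
    one ``numpy`` generator seeded from the config.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    index = 0
    for _ in range(config.n_per_class):
        records.append(_synth_record(rng, config, NON_SEIZURE, index))
        index += 1
    for _ in range(config.n_per_class):
        records.append(_synth_record(rng, config, SEIZURE, index))
        index += 1
    return SignalDataset(records)


def serialize_segment(record: EEGRecord) -> str:
    """Render a record back to the Bonn one-value-per-line dialect.

    Uses the shortest round-tripping decimal representation, so parsing the
    output reproduces the sample values exactly; integral values render
    without a decimal point, matching the public dataset files.
    """
    lines = []
    for v in record.samples:
        f = float(v)
        lines.append(str(int(f)) if f.is_integer() else repr(f))
    return "\n".join(lines) + "\n"


def save_dataset(ds: SignalDataset, root: str | Path) -> Path:
    """Write a dataset as a directory of ASCII segments plus a TSV manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest_lines = ["file\tsource_id\tlabel\tfs"]
    for i, rec in enumerate(ds.records):
        name = f"rec_{i:05d}.txt"
        (root / name).write_text(serialize_segment(rec), encoding="ascii")
        manifest_lines.append(f"{name}\t{rec.source_id}\t{rec.label}\t{rec.fs!r}")
    manifest = root / "manifest.tsv"
    manifest.write_text("\n".join(manifest_lines) + "\n", encoding="utf-8")
    return manifest


def load_saved_dataset(root: str | Path) -> SignalDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    root = Path(root)
    manifest = root / "manifest.tsv"
    if not manifest.is_file():
        raise DataNotFoundError(f"no manifest.tsv under {root}")
    records = []
    lines = manifest.read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{manifest}: malformed row on line {lineno}")
        name, source_id, label, fs = parts
        rec = read_bonn_segment(root / name)
        records.append(rec.replace(source_id=source_id, label=label, fs=float(fs)))
    return SignalDataset(records)
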