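"""Random data augmentation: label-preserving variants of EEG segments.

Three elementary transforms — multiplicative amplitude scaling, circular
time shift, and width (duration) warping — plus their amplitude+width
combination.  :func:`augment_dataset` draws transforms and parameters from
a seeded generator and records full provenance for every variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import resample

from .data import EEGRecord, SignalDataset
from .errors import ConfigurationError

__all__ = [
    "AugmentConfig",
    "Provenance",
    "AugmentedDataset",
    "rda_amplitude",
    "rda_shift",
    "rda_width",
    "augment_dataset",
    "export_provenance",
]

TRANSFORMS = ("amplitude", "shift", "width", "combined")


@dataclass
class AugmentConfig:
    """Parameter ranges and draw budget for random data augmentation.

    ``factor`` variants are drawn per input record.  When ``combo_prob`` is
    None the transform is chosen uniformly among the four kinds; otherwise
    the combined transform is drawn with that probability and the three
    elementary transforms share the remainder equally.
    """

    amp_range: tuple[float, float] = (0.5, 1.0)
    shift_frac: float = 0.1
    width_range: tuple[float, float] = (0.9, 1.1)
    combo_prob: float | None = None
    factor: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.amp_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid amp_range {self.amp_range}")
        if not (0 <= self.shift_frac <= 0.5):
            raise ConfigurationError(f"shift_frac must be in [0, 0.5], got {self.shift_frac}")
        wlo, whi = self.width_range
        if not (0 < wlo <= whi):
            raise ConfigurationError(f"invalid width_range {self.width_range}")
        if self.combo_prob is not None and not (0 <= self.combo_prob <= 1):
            raise ConfigurationError("combo_prob must lie in [0, 1]")
        if self.factor < 0:
            raise ConfigurationError("factor must be >= 0")


@dataclass
class Provenance:
    """Origin of one augmented variant."""

    source_id: str
    transform: str
    parameters: dict
    output_id: str


@dataclass
class AugmentedDataset:
    """Originals followed by variants, with per-variant provenance."""

    records: list[EEGRecord] = field(default_factory=list)
    provenance: list[Provenance] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def as_signal_dataset(self) -> SignalDataset:
        return SignalDataset(list(self.records))


def rda_amplitude(record: EEGRecord, s: float) -> EEGRecord:
    """Scale every sample by ``s > 0``; label preserved."""
    if not (s > 0):
        raise ConfigurationError(f"amplitude factor must be positive, got {s}")
    return record.replace(samples=record.samples * s)


def rda_shift(record: EEGRecord, k: int) -> EEGRecord:
    """Circularly shift the record by ``k`` samples (positive = rightward).

    The multiset of sample values is unchanged, so amplitude statistics are
    exactly preserved.
    """
    n = len(record)
    if abs(int(k)) >= n:
        raise ConfigurationError(f"|shift| must be < record length {n}, got {k}")
    return record.replace(samples=np.roll(record.samples, int(k)))


def rda_width(record: EEGRecord, w: float) -> EEGRecord:
    """Warp the record's width by factor ``w`` at constant output length.

    The signal is band-limited resampled to ``round(n * w)`` samples
    (stretching its duration by ``w``, hence dividing instantaneous
    frequencies by ``w``); the result is center-cropped (``w > 1``) or
    reflection-padded at the edges (``w < 1``) back to the original length.
    """
    if not (w > 0):
        raise ConfigurationError(f"width factor must be positive, got {w}")
    n = len(record)
    m = max(2, int(round(n * w)))
    warped = resample(record.samples, m) if m != n else record.samples.copy()
    if m > n:
        start = (m - n) // 2
        out = warped[start:start + n]
    elif m < n:
        deficit = n - m
        left = deficit // 2
        right = deficit - left
        out = np.pad(warped, (left, right), mode="reflect")
    else:
        out = warped
    return record.replace(samples=out)


def _apply_variant(
    record: EEGRecord, rng: np.random.Generator, config: AugmentConfig
) -> tuple[EEGRecord, str, dict]:
    if config.combo_prob is None:
        transform = TRANSFORMS[rng.integers(len(TRANSFORMS))]
    else:
        if rng.random() < config.combo_prob:
            transform = "combined"
        else:
            transform = TRANSFORMS[rng.integers(3)]
    n = len(record)
    if transform == "amplitude":
        s = float(rng.uniform(*config.amp_range))
        return rda_amplitude(record, s), transform, {"s": s}
    if transform == "shift":
        kmax = int(np.floor(config.shift_frac * n))
        k = int(rng.integers(-kmax, kmax + 1)) if kmax > 0 else 0
        return rda_shift(record, k), transform, {"k": k}
    if transform == "width":
        w = float(rng.uniform(*config.width_range))
        return rda_width(record, w), transform, {"w": w}
    s = float(rng.uniform(*config.amp_range))
    w = float(rng.uniform(*config.width_range))
    return rda_width(rda_amplitude(record, s), w), transform, {"s": s, "w": w}


def augment_dataset(ds: SignalDataset, config: AugmentConfig) -> AugmentedDataset:
    """Draw ``config.factor`` seeded variants per record.

    The output holds the originals in input order followed by the variants
    in input order; every variant keeps its source's label, so the per-class
    ratio of the variant set equals the input ratio exactly.
    """
    if len(ds) == 0:
        raise ConfigurationError("cannot augment an empty dataset")
    rng = np.random.default_rng(config.seed)
    records = list(ds.records)
    provenance: list[Provenance] = []
    variants: list[EEGRecord] = []
    for rec in ds.records:
        for j in range(config.factor):
            variant, transform, params = _apply_variant(rec, rng, config)
            output_id = f"{rec.source_id}|aug{j}:{transform}"
            variants.append(variant.replace(source_id=output_id))
            provenance.append(Provenance(rec.source_id, transform, params, output_id))
    return AugmentedDataset(records + variants, provenance)


def export_provenance(aug: AugmentedDataset, path: str | Path) -> Path:
    """Write provenance as a TSV table (source_id, transform, parameters, output_id)."""
    path = Path(path)
    lines = ["source_id\ttransform\tparameters\toutput_id"]
    for p in aug.provenance:
        params = ";".join(f"{k}={v!r}" for k, v in sorted(p.parameters.items()))
        lines.append(f"{p.source_id}\t{p.transform}\t{params}\t{p.output_id}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
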