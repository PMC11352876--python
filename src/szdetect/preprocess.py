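"""Band-pass / median filtering and a rational-dilation wavelet filter bank.

The wavelet analysis splits a segment into ``levels`` detail bands plus one
approximation band whose band edges follow a geometric progression with
rational ratio ``p/q`` (dilation ``q/p > 1``).  The bank is built directly
in the DFT domain from power-complementary raised-cosine crossovers, which
makes it a tight frame: subband energies sum to the signal energy and
analysis followed by synthesis reconstructs the input to machine precision
for any input length.  Subbands are kept at full rate; the ``s`` parameter
sharpens the crossover transitions (larger ``s`` -> narrower transitions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter as _nd_median
from scipy.signal import butter, sosfiltfilt

from .data import EEGRecord
from .errors import ConfigurationError, ConsistencyError
from . import data as _data

__all__ = [
    "FilterSpec",
    "RADWTParams",
    "SubbandDecomposition",
    "bandpass_filter",
    "median_filter",
    "radwt_forward",
    "radwt_inverse",
    "reconstruct_band",
    "max_feasible_levels",
    "save_decomposition",
    "load_decomposition",
]


@dataclass
class FilterSpec:
    """Specification of a preprocessing filter.

    ``kind`` selects either the zero-phase IIR band-pass (``bandpass_iir``)
    or the running-median smoother (``median``); fields irrelevant to the
    chosen kind are ignored.
    """

    low_hz: float = 0.5
    high_hz: float = 40.0
    order: int = 4
    kind: str = "bandpass_iir"
    median_window: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass_iir", "median"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        if self.kind == "bandpass_iir":
            if not (0 < self.low_hz < self.high_hz):
                raise ConfigurationError(
                    f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
                )
            if self.order < 1:
                raise ConfigurationError("filter order must be >= 1")
        else:
            if self.median_window < 3 or self.median_window % 2 == 0:
                raise ConfigurationError("median_window must be odd and >= 3")


@dataclass
class RADWTParams:
    """Rational-dilation parameters: dilation q/p > 1 across ``levels`` scales."""

    p: int = 2
    q: int = 3
    s: int = 1
    levels: int = 4

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ConfigurationError("p must be >= 1")
        if self.q <= self.p:
            raise ConfigurationError("q must exceed p (dilation q/p > 1)")
        if self.s < 1:
            raise ConfigurationError("s must be >= 1")
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")

    @property
    def dilation(self) -> float:
        return self.q / self.p


@dataclass
class SubbandDecomposition:
    """Per-scale subband signals from :func:`radwt_forward`.

    ``subbands[0]`` is the approximation (lowest) band; ``subbands[1:]``
    are detail bands ordered from low to high frequency.  Every subband is
    stored at the original rate, so ``len(subbands) == levels + 1`` and each
    has ``original_length`` samples.
    """

    subbands: list[np.ndarray]
    params: RADWTParams
    original_length: int
    fs: float

    def __post_init__(self) -> None:
        self.subbands = [np.asarray(b, dtype=float) for b in self.subbands]
        if len(self.subbands) != self.params.levels + 1:
            raise ConsistencyError(
                f"expected {self.params.levels + 1} subbands, got {len(self.subbands)}"
            )

    def energies(self) -> np.ndarray:
        """Energy (sum of squares) per subband."""
        return np.array([float(np.sum(b * b)) for b in self.subbands])


def bandpass_filter(record: EEGRecord, spec: FilterSpec) -> EEGRecord:
    """Zero-phase Butterworth band-pass of a record.

    Applied forward-backward (``sosfiltfilt``) with reflected edge padding,
    so the output has zero phase distortion, the same length, and the
    record's label / sampling rate are preserved.
    """
    if spec.kind != "bandpass_iir":
        raise ConfigurationError("bandpass_filter requires a bandpass_iir FilterSpec")
    nyq = record.fs / 2.0
    if spec.high_hz >= nyq:
        raise ConfigurationError(
            f"high_hz {spec.high_hz} must be below Nyquist {nyq} at fs={record.fs}"
        )
    sos = butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                 fs=record.fs, output="sos")
    filtered = sosfiltfilt(sos, record.samples, padtype="even")
    return record.replace(samples=filtered)


def median_filter(record: EEGRecord, window: int) -> EEGRecord:
    """Running-median smoothing with a centered odd window.

    Edges are handled with reflected padding; length, label and fs are
    preserved.
    """
    if window % 2 == 0 or window < 3:
        raise ConfigurationError(f"median window must be odd and >= 3, got {window}")
    if window > len(record):
        raise ConfigurationError(
            f"median window {window} exceeds record length {len(record)}"
        )
    smoothed = _nd_median(record.samples, size=window, mode="reflect")
    return record.replace(samples=smoothed)


def _band_edges(fs: float, params: RADWTParams) -> np.ndarray:
    """Crossover frequencies, highest first: fN*(p/q)^k for k=1..levels."""
    nyq = fs / 2.0
    ratio = params.p / params.q
    return nyq * ratio ** np.arange(1, params.levels + 1)


def max_feasible_levels(n: int, fs: float, params: RADWTParams) -> int:
    """Largest level count whose lowest crossover still clears the first
    positive DFT bin for a length-``n`` signal."""
    df = fs / n
    ratio = params.p / params.q
    nyq = fs / 2.0
    levels = 0
    edge = nyq * ratio
    while levels < 64:
        hw = edge * (1.0 - ratio) / (8.0 * params.s)
        if edge - hw <= 2 * df:
            break
        levels += 1
        edge *= ratio
    return levels


def _analysis_windows(n: int, fs: float, params: RADWTParams) -> np.ndarray:
    """Power-complementary amplitude windows, shape (levels+1, n//2+1).

    Band 0 is the approximation; bands are separated by raised-cosine
    crossovers of half-width ``edge * (1 - p/q) / (8 s)`` centered on each
    geometric band edge, so the squared windows sum to exactly 1 at every
    frequency bin.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    edges = _band_edges(fs, params)  # highest crossover first
    ratio = params.p / params.q
    n_bands = params.levels + 1

    # theta ramps 0 -> pi/2 across each crossover's transition band.
    thetas = []
    for edge in edges:
        hw = edge * (1.0 - ratio) / (8.0 * params.s)
        x = np.clip((freqs - (edge - hw)) / (2.0 * hw), 0.0, 1.0)
        thetas.append(x * (np.pi / 2.0))

    windows = np.empty((n_bands, freqs.size))
    # Band index b: 0 = approximation (below edges[-1]); b = levels = top band.
    # For band b the lower crossover is edges[levels-b] (sin side) and the
    # upper crossover is edges[levels-b-1] (cos side).
    for b in range(n_bands):
        w = np.ones(freqs.size)
        if b > 0:
            w = w * np.sin(thetas[params.levels - b])
        if b < params.levels:
            w = w * np.cos(thetas[params.levels - b - 1])
        windows[b] = w
    return windows


def radwt_forward(record: EEGRecord, params: RADWTParams) -> SubbandDecomposition:
    """Analyze a record into ``levels + 1`` tight-frame subband signals.

    Raises
    ------
    ConfigurationError
        If the record is too short for the requested level count; the
        message states the maximum feasible level count.
    """
    n = len(record)
    feasible = max_feasible_levels(n, record.fs, params)
    if params.levels > feasible:
        raise ConfigurationError(
            f"{params.levels} levels infeasible for length {n} at fs={record.fs}; "
            f"maximum feasible levels is {feasible}"
        )
    spectrum = np.fft.rfft(record.samples)
    windows = _analysis_windows(n, record.fs, params)
    subbands = [np.fft.irfft(w * spectrum, n) for w in windows]
    return SubbandDecomposition(subbands, params, original_length=n, fs=record.fs)


def radwt_inverse(decomp: SubbandDecomposition) -> EEGRecord:
    """Synthesize the original signal from a decomposition.

    Each subband contributes ``irfft(H_b * rfft(y_b))``; because the
    windows are power complementary the contributions sum back to the
    original signal.
    """
    n = decomp.original_length
    for i, band in enumerate(decomp.subbands):
        if band.shape != (n,):
            raise ConsistencyError(
                f"subband {i} has length {band.shape}, expected ({n},)"
            )
    windows = _analysis_windows(n, decomp.fs, decomp.params)
    total = np.zeros(n // 2 + 1, dtype=complex)
    for w, band in zip(windows, decomp.subbands):
        total += w * np.fft.rfft(band)
    samples = np.fft.irfft(total, n)
    return EEGRecord(samples, fs=decomp.fs, label=_data.UNLABELED, source_id="radwt_inverse")


def reconstruct_band(decomp: SubbandDecomposition, band: int) -> np.ndarray:
    """Additive contribution of one subband to the reconstruction."""
    if not 0 <= band < len(decomp.subbands):
        raise ConfigurationError(f"band index {band} out of range")
    n = decomp.original_length
    w = _analysis_windows(n, decomp.fs, decomp.params)[band]
    return np.fft.irfft(w * np.fft.rfft(decomp.subbands[band]), n)


def save_decomposition(decomp: SubbandDecomposition, root: str | Path) -> Path:
    """Write a decomposition as per-band numeric files plus a JSON manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    names = []
    for i, band in enumerate(decomp.subbands):
        name = f"band_{i:02d}.txt"
        np.savetxt(root / name, band, fmt="%.17g")
        names.append(name)
    manifest = {
        "p": decomp.params.p,
        "q": decomp.params.q,
        "s": decomp.params.s,
        "levels": decomp.params.levels,
        "original_length": decomp.original_length,
        "fs": decomp.fs,
        "bands": names,
    }
    path = root / "decomposition.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path


def load_decomposition(root: str | Path) -> SubbandDecomposition:
    root = Path(root)
    manifest = json.loads((root / "decomposition.json").read_text(encoding="utf-8"))
    params = RADWTParams(p=manifest["p"], q=manifest["q"], s=manifest["s"],
                         levels=manifest["levels"])
    subbands = [np.loadtxt(root / name) for name in manifest["bands"]]
    return SubbandDecomposition(subbands, params,
                                original_length=manifest["original_length"],
                                fs=manifest["fs"])
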