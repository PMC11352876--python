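"""End-to-end orchestration of the three classification variants.

Stage order: load/generate -> band-pass -> median -> wavelet-bank
round-trip -> stratified 70/30 split -> (optional) augmentation of the
training side -> windowed statistical features (plus fuzzy C-means
selection/membership features for the fcm variant) -> hyperparameter
search with the variant's optimizer over cross-validated fitness ->
final training -> held-out metric report.

Augmentation happens after the split by default so variants can never leak
across the train/test boundary; ``paper_ordering=True`` reproduces the
augment-before-split sequence for comparison.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import augment as _augment
from . import fuzzyfeat as _ff
from . import lstm as _lstm
from . import metrics as _metrics
from . import optim as _optim
from . import preprocess as _pre
from .data import (
    NON_SEIZURE,
    SEIZURE,
    EEGRecord,
    SignalDataset,
    SynthConfig,
    load_dataset,
    synth_dataset,
)
from .errors import ConfigurationError, ConsistencyError

__all__ = [
    "METHODS",
    "FCM_PS_LSTM",
    "PS_LSTM",
    "PO_LSTM",
    "OptimBudget",
    "FeatureSettings",
    "RunConfig",
    "RunResult",
    "CompareResult",
    "run_method",
    "compare_bda_arda",
    "render_compare_table",
]

FCM_PS_LSTM = "fcm_ps_lstm"
PS_LSTM = "ps_lstm"
PO_LSTM = "po_lstm"
METHODS = (FCM_PS_LSTM, PS_LSTM, PO_LSTM)

#: Cross-validation folds used during tuning, per method.
METHOD_CV_FOLDS = {FCM_PS_LSTM: 10, PS_LSTM: 10, PO_LSTM: 5}


@dataclass
class OptimBudget:
    """Population size and iteration count for the hyperparameter search."""

    population: int = 5
    iterations: int = 10

    def __post_init__(self) -> None:
        if self.population < 2 or self.iterations < 1:
            raise ConfigurationError("budget needs population >= 2 and iterations >= 1")


@dataclass
class FeatureSettings:
    win: int = 256
    overlap_frac: float = 0.5
    select_k: int = 5
    fcm: _ff.FCMConfig = field(default_factory=_ff.FCMConfig)


@dataclass
class RunConfig:
    """Full configuration of one end-to-end run."""

    method: str = PS_LSTM
    synth: SynthConfig | None = field(default_factory=SynthConfig)
    bonn_dir: str | None = None
    bonn_sets: tuple[str, ...] = ("D", "E")
    bandpass: _pre.FilterSpec = field(default_factory=_pre.FilterSpec)
    median_window: int = 5
    radwt: _pre.RADWTParams | None = field(default_factory=_pre.RADWTParams)
    augment: _augment.AugmentConfig | None = None
    features: FeatureSettings = field(default_factory=FeatureSettings)
    budget: OptimBudget = field(default_factory=OptimBudget)
    cv_folds: int | None = None
    train_fraction: float = 0.7
    lstm: _lstm.LSTMConfig = field(default_factory=lambda: _lstm.LSTMConfig(epochs=10))
    space: _optim.SearchSpace = field(default_factory=_optim.SearchSpace)
    paper_ordering: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (0 < self.train_fraction < 1):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.cv_folds is not None and self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.synth is None and self.bonn_dir is None:
            raise ConfigurationError("a data source (synth or bonn_dir) is required")

    def folds(self) -> int:
        return self.cv_folds if self.cv_folds is not None else METHOD_CV_FOLDS[self.method]


@dataclass
class RunResult:
    method: str
    best_params: dict
    optimizer_history: list[float]
    test_report: _metrics.MetricsReport
    confusion: _metrics.ConfusionMatrix
    n_train: int
    n_test: int
    cv_folds: int
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "best_params": self.best_params,
            "optimizer_history": self.optimizer_history,
            "test_metrics": self.test_report.as_dict(),
            "confusion": dataclasses.asdict(self.confusion),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


@dataclass
class CompareResult:
    bda: RunResult
    arda: RunResult

    @property
    def delta(self) -> dict[str, float]:
        b = self.bda.test_report.as_dict()
        a = self.arda.test_report.as_dict()
        return {k: a[k] - b[k] for k in b}


def _derived_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0])


def _load_records(config: RunConfig) -> list[EEGRecord]:
    if config.bonn_dir is not None:
        ds = load_dataset(config.bonn_dir, config.bonn_sets)
    else:
        ds = synth_dataset(config.synth)
    records = [r for r in ds.records if r.label in (SEIZURE, NON_SEIZURE)]
    labels = {r.label for r in records}
    if len(labels) < 2:
        raise ConfigurationError("dataset must contain both seizure and non-seizure records")
    return records


def _preprocess(records: list[EEGRecord], config: RunConfig) -> list[EEGRecord]:
    out = []
    for rec in records:
        r = _pre.bandpass_filter(rec, config.bandpass)
        r = _pre.median_filter(r, config.median_window)
        if config.radwt is not None:
            decomp = _pre.radwt_forward(r, config.radwt)
            rebuilt = _pre.radwt_inverse(decomp)
            r = r.replace(samples=rebuilt.samples)
        out.append(r)
    return out


def _stratified_split(
    records: list[EEGRecord], train_fraction: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in (NON_SEIZURE, SEIZURE):
        idx = [i for i, r in enumerate(records) if r.label == label]
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[j] for j in perm[:n_train])
        test_idx.extend(idx[j] for j in perm[n_train:])
    return sorted(train_idx), sorted(test_idx)


def _root_id(source_id: str) -> str:
    return source_id.split("|aug", 1)[0]


def _check_leakage(train: list[EEGRecord], test: list[EEGRecord]) -> None:
    train_roots = {_root_id(r.source_id) for r in train}
    test_roots = {_root_id(r.source_id) for r in test}
    overlap = train_roots & test_roots
    if overlap:
        raise ConsistencyError(
            f"train/test leakage: {len(overlap)} shared source records, e.g. "
            f"{sorted(overlap)[:3]}"
        )


def _sequence_features(
    records: list[EEGRecord], settings: FeatureSettings
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-record sequences of window feature vectors, plus 0/1 labels."""
    sequences = []
    labels = []
    for rec in records:
        windows = _ff.window_segments(rec, settings.win, settings.overlap_frac)
        seq = np.stack([_ff.stat_features(w).as_array() for w in windows])
        sequences.append(seq)
        labels.append(1 if rec.label == SEIZURE else 0)
    return sequences, np.asarray(labels, dtype=int)


def _fcm_transform(
    train_seqs: list[np.ndarray],
    test_seqs: list[np.ndarray],
    settings: FeatureSettings,
) -> tuple[list[np.ndarray], list[np.ndarray], dict]:
    """Fit FCM on training windows; select top-k columns and append
    membership degrees to every window of both sides."""
    stacked = np.vstack(train_seqs)
    result = _ff.fcm_fit(stacked, settings.fcm)
    scores = _ff.feature_scores(result, stacked)
    k = min(settings.select_k, stacked.shape[1])
    top = np.sort(np.argsort(-scores, kind="stable")[:k])

    def apply(seqs: list[np.ndarray]) -> list[np.ndarray]:
        out = []
        for seq in seqs:
            u = _ff.fcm_memberships(seq, result)
            out.append(np.hstack([seq[:, top], u]))
        return out

    info = {
        "selected_columns": [_ff.FEATURE_NAMES[i] for i in top],
        "scores": scores.tolist(),
    }
    return apply(train_seqs), apply(test_seqs), info


def _standardize(
    train_seqs: list[np.ndarray], test_seqs: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    stacked = np.vstack(train_seqs)
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    x_train = np.stack([(s - mu) / sd for s in train_seqs])
    x_test = np.stack([(s - mu) / sd for s in test_seqs])
    return x_train, x_test


def run_method(config: RunConfig, progress: Callable[[str], None] | None = None) -> RunResult:
    """Execute one full classification run and report held-out metrics."""

    def log(msg: str) -> None:
        if progress is not None:
            progress(msg)

    log("loading data")
    records = _load_records(config)
    log(f"preprocessing {len(records)} records")
    records = _preprocess(records, config)

    split_rng = np.random.default_rng(_derived_seed(config.seed, 1))
    if config.paper_ordering and config.augment is not None:
        # Augment-before-split ordering: variants are treated as free-standing
        # records, so near-duplicates may straddle the split.
        aug = _augment.augment_dataset(SignalDataset(records), config.augment)
        records = list(aug.records)
        train_idx, test_idx = _stratified_split(records, config.train_fraction, split_rng)
        train_records = [records[i] for i in train_idx]
        test_records = [records[i] for i in test_idx]
    else:
        train_idx, test_idx = _stratified_split(records, config.train_fraction, split_rng)
        train_records = [records[i] for i in train_idx]
        test_records = [records[i] for i in test_idx]
        if config.augment is not None and config.augment.factor > 0:
            log("augmenting training side")
            aug = _augment.augment_dataset(SignalDataset(train_records), config.augment)
            train_records = list(aug.records)
        _check_leakage(train_records, test_records)

    log("extracting features")
    train_seqs, y_train = _sequence_features(train_records, config.features)
    test_seqs, y_test = _sequence_features(test_records, config.features)
    if config.method == FCM_PS_LSTM:
        train_seqs, test_seqs, _ = _fcm_transform(train_seqs, test_seqs, config.features)
    x_train, x_test = _standardize(train_seqs, test_seqs)

    folds = config.folds()
    fitness_seed = _derived_seed(config.seed, 2)

    def objective(position: np.ndarray) -> float:
        return _lstm.cv_fitness(position, config.space, (x_train, y_train), folds,
                                fitness_seed, base_config=config.lstm)

    log(f"tuning hyperparameters ({config.method}, {folds}-fold)")
    opt_seed = _derived_seed(config.seed, 3)
    bounds = config.space.bounds()
    if config.method == PO_LSTM:
        opt = _optim.po_optimize(objective, bounds, n_agents=config.budget.population,
                                 max_iter=config.budget.iterations, seed=opt_seed)
    else:
        opt = _optim.pso_optimize(objective, bounds, n=config.budget.population,
                                  max_iter=config.budget.iterations, seed=opt_seed)

    best = config.space.decode(opt.best_position)
    log(f"final training with {best}")
    final_config = dataclasses.replace(
        config.lstm,
        hidden_units=best["hidden_units"],
        learning_rate=best["learning_rate"],
        dropout=best["dropout"],
        seed=_derived_seed(config.seed, 4),
    )
    model, _ = _lstm.train((x_train, y_train), final_config)
    pred, _ = _lstm.predict(model, x_test)
    y_pred_labels = np.where(pred == 1, SEIZURE, NON_SEIZURE)
    y_true_labels = np.where(y_test == 1, SEIZURE, NON_SEIZURE)
    cm = _metrics.confusion(y_true_labels, y_pred_labels)
    report = _metrics.compute_metrics(cm)
    return RunResult(
        method=config.method,
        best_params=best,
        optimizer_history=[float(v) for v in opt.history],
        test_report=report,
        confusion=cm,
        n_train=len(train_records),
        n_test=len(test_records),
        cv_folds=folds,
        train_ids=[r.source_id for r in train_records],
        test_ids=[r.source_id for r in test_records],
        seed=config.seed,
    )


def compare_bda_arda(config: RunConfig, progress: Callable[[str], None] | None = None) -> CompareResult:
    """Run the configured method once without and once with augmentation.

    Both runs share the seed, so the stratified split — drawn before any
    augmentation — is identical and the two test-side record sets match.
    """
    if config.augment is None:
        raise ConfigurationError("compare_bda_arda requires an AugmentConfig")
    if config.paper_ordering:
        raise ConfigurationError("compare_bda_arda requires the leak-free ordering")
    bda_config = dataclasses.replace(config, augment=None)
    bda = run_method(bda_config, progress)
    arda = run_method(config, progress)
    if bda.test_ids != arda.test_ids:
        raise ConsistencyError("BDA and ARDA runs diverged on the test-side records")
    return CompareResult(bda=bda, arda=arda)


def render_compare_table(result: CompareResult, decimals: int = 2) -> str:
    """TSV with exactly two rows (BDA, ARDA) and the nine metric columns."""
    header = "condition\t" + "\t".join(_metrics.METRIC_ORDER)
    rows = [header]
    for name, res in (("BDA", result.bda), ("ARDA", result.arda)):
        values = res.test_report.as_dict()
        rows.append(name + "\t" + "\t".join(
            f"{values[m]:.{decimals}f}" for m in _metrics.METRIC_ORDER
        ))
    return "\n".join(rows) + "\n"
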