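"""The 1-D CNN AMSA regressor: architecture, training, CV and grid search.

The estimator maps a two-channel differential ECG signal (length
floor(L/2)-1, 499 for 4-s / 250 Hz segments) to a single AMSA value.  The
network has N + 1 convolutional feature-extraction blocks followed by
fully connected layers:

* blocks 1..N: conv(width W, C channels, stride 1, same padding) ->
  batch-norm -> leaky ReLU -> max-pool(kernel 2, stride 2, ceil mode), so
  the temporal length after block n is ceil(len / 2^n);
* block N+1: conv -> batch-norm -> leaky ReLU -> *global* max-pool ->
  dropout, yielding C features;
* fully connected layers (default widths 64, 32, 1) with leaky-ReLU
  between them and a linear scalar output.

Training minimises MSE with Adam (learning rate 1e-3).  Conv weights use
Xavier-normal init, dense weights uniform [-0.1, 0.1].  Both members of
every corrupted/uncorrupted segment pair enter training with the shared
true-AMSA label; optional augmentation multiplies the training set by 8
via the negate/reverse/swap group.  Predictions are clipped at 0 (labels
are non-negative but the MSE fit is unconstrained).

The module follows the model/results idiom: build
:class:`AmsaCnnRegressor` from segment pairs, call :meth:`fit`, and work
with the returned :class:`AmsaCnnResults`.  Thin functional wrappers
(:func:`build_model`, :func:`train`, :func:`predict_amsa`,
:func:`cross_validate`, :func:`grid_search`) expose the same operations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _nn
from .core import EcgSegment, SegmentPair
from .evaluation import MetricsReport, compute_metrics
from .exceptions import ConfigurationError, InvalidInputError
from .features import TwoChannelInput, augment, difference_transform

logger = logging.getLogger("amsanet.model")

_ALLOWED_CHANNELS = (4, 8, 16, 32, 64)


@dataclass(frozen=True)
class CnnConfig:
    """Architecture hyperparameters (grid-search optima as defaults)."""

    kernel_width: int = 11
    n_pooled_blocks: int = 5
    channels: int = 32
    leaky_slope: float = 0.01
    dropout: float = 0.5
    fc_sizes: tuple[int, ...] = (64, 32, 1)

    def validate(self, input_length: int | None = None) -> None:
        if self.kernel_width % 2 == 0 or not (3 <= self.kernel_width <= 11):
            raise ConfigurationError("kernel_width must be odd and in [3, 11]")
        if not (1 <= self.n_pooled_blocks <= 7):
            raise ConfigurationError("n_pooled_blocks must be in [1, 7]")
        if self.channels not in _ALLOWED_CHANNELS:
            raise ConfigurationError(f"channels must be one of {_ALLOWED_CHANNELS}")
        if not self.fc_sizes or self.fc_sizes[-1] != 1:
            raise ConfigurationError("fc_sizes must end in a single output unit")
        if input_length is not None and input_length < 2 ** self.n_pooled_blocks:
            raise ConfigurationError(
                f"input length {input_length} shorter than 2^N = "
                f"{2 ** self.n_pooled_blocks}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol.

    The published protocol is batch 1024 / 50 epochs; the package default
    is the desk-scale 256 / 30 which trains the default architecture on a
    few thousand synthetic pairs in minutes on one CPU.
    """

    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 30
    init_range: tuple[float, float] = (-0.1, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("lr, batch_size and epochs must be positive")


FULL_SCALE_TRAIN = TrainConfig(batch_size=1024, epochs=50)


def _build_network(cfg: CnnConfig, input_length: int,
                   rng: np.random.Generator,
                   init_range: tuple[float, float] = (-0.1, 0.1),
                   dtype=np.float32) -> _nn.Network:
    cfg.validate(input_length)
    layers: list[_nn.Layer] = []
    c_in = 2
    for _ in range(cfg.n_pooled_blocks):
        layers += [
            _nn.Conv1d(c_in, cfg.channels, cfg.kernel_width, rng, dtype=dtype),
            _nn.BatchNorm1d(cfg.channels, dtype=dtype),
            _nn.LeakyReLU(cfg.leaky_slope),
            _nn.MaxPool1d(),
        ]
        c_in = cfg.channels
    layers += [
        _nn.Conv1d(c_in, cfg.channels, cfg.kernel_width, rng, dtype=dtype),
        _nn.BatchNorm1d(cfg.channels, dtype=dtype),
        _nn.LeakyReLU(cfg.leaky_slope),
        _nn.GlobalMaxPool(),
        _nn.Dropout(cfg.dropout, rng),
    ]
    n_in = cfg.channels
    for i, n_out in enumerate(cfg.fc_sizes):
        layers.append(_nn.Dense(n_in, n_out, rng, init_range=init_range, dtype=dtype))
        if i < len(cfg.fc_sizes) - 1:
            layers.append(_nn.LeakyReLU(cfg.leaky_slope))
        n_in = n_out
    return _nn.Network(layers)


class AmsaEstimator:
    """A (possibly untrained) CNN AMSA estimator bound to an input length."""

    def __init__(self, cfg: CnnConfig, input_length: int, seed: int = 0,
                 init_range: tuple[float, float] = (-0.1, 0.1)) -> None:
        self.cfg = cfg
        self.input_length = int(input_length)
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        self.network = _build_network(cfg, input_length, self._rng, init_range)
        self.history: list[float] = []

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters()

    def predict_inputs(self, inputs: Sequence[TwoChannelInput]) -> np.ndarray:
        """Non-negative AMSA predictions for prepared two-channel inputs."""
        x = np.stack([xi.as_array() for xi in inputs]).astype(np.float32)
        if x.shape[2] != self.input_length:
            raise InvalidInputError(
                f"input length {x.shape[2]} != trained length {self.input_length}")
        out = self.network.forward(x, training=False)[:, 0]
        return np.maximum(out.astype(float), 0.0)

    def predict_segment(self, segment: EcgSegment) -> float:
        return float(self.predict_inputs([difference_transform(segment)])[0])

    def save(self, path: str | Path) -> Path:
        """Checkpoint: weights + running stats + embedded config (npz)."""
        path = Path(path)
        meta = json.dumps({"cfg": asdict(self.cfg), "input_length": self.input_length,
                           "seed": self.seed, "history": self.history})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.network.state_arrays())
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "AmsaEstimator":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["cfg"]
            cfg_d["fc_sizes"] = tuple(cfg_d["fc_sizes"])
            cfg = CnnConfig(**cfg_d)
            est = cls(cfg, meta["input_length"], seed=meta["seed"])
            est.network.load_state({k: data[k] for k in data.files if k != "__meta__"})
            est.history = list(meta["history"])
        return est


def _pairs_to_training_arrays(
    pairs: Sequence[SegmentPair], use_augment: bool
) -> tuple[np.ndarray, np.ndarray]:
    xs: list[np.ndarray] = []
    ys: list[float] = []
    for pair in pairs:
        for seg in (pair.corrupted, pair.uncorrupted):
            base = difference_transform(seg)
            variants = [base] + (augment(base) if use_augment else [])
            for v in variants:
                xs.append(v.as_array())
                ys.append(pair.amsa_true)
    return np.stack(xs).astype(np.float32), np.asarray(ys, dtype=np.float32)


def build_model(cfg: CnnConfig, input_length: int, seed: int = 0) -> AmsaEstimator:
    """Construct an untrained estimator for the given input length."""
    return AmsaEstimator(cfg, input_length, seed=seed)


def train(
    model: AmsaEstimator,
    pairs: Sequence[SegmentPair],
    tcfg: TrainConfig = TrainConfig(),
    augment: bool = True,
) -> AmsaEstimator:
    """Fit the estimator on segment pairs (both members share the label)."""
    tcfg.validate()
    if not pairs:
        raise InvalidInputError("empty training set")
    x, y = _pairs_to_training_arrays(pairs, use_augment=augment)
    if x.shape[2] != model.input_length:
        raise InvalidInputError(
            f"pair input length {x.shape[2]} != model length {model.input_length}")
    rng = np.random.default_rng(tcfg.seed + 1)
    logger.info("training on %d samples (%d pairs, augment=%s), %d epochs",
                x.shape[0], len(pairs), augment, tcfg.epochs)
    model.history = _nn.train_mse(model.network, x, y, rng, lr=tcfg.lr,
                                  batch_size=tcfg.batch_size, epochs=tcfg.epochs)
    return model


def predict_amsa(model: AmsaEstimator, segment: EcgSegment) -> float:
    """AMSA prediction (mV.Hz, clipped at 0) for one segment."""
    return model.predict_segment(segment)


def evaluate_on_pairs(model: AmsaEstimator, pairs: Sequence[SegmentPair]) -> MetricsReport:
    """Metrics of the model's corrupted-member predictions vs the true labels."""
    inputs = [difference_transform(p.corrupted) for p in pairs]
    preds = model.predict_inputs(inputs)
    truths = np.array([p.amsa_true for p in pairs])
    return compute_metrics(preds, truths)


def _subject_folds(pairs: Sequence[SegmentPair], k: int, seed: int) -> list[list[int]]:
    subjects = sorted({p.subject_id for p in pairs})
    if len(subjects) < k:
        raise InvalidInputError(f"need >= {k} subjects for {k}-fold CV, "
                                f"got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    fold_of = {s: i % k for i, s in enumerate(order)}
    folds: list[list[int]] = [[] for _ in range(k)]
    for idx, p in enumerate(pairs):
        folds[fold_of[p.subject_id]].append(idx)
    return folds


def cross_validate(
    pairs: Sequence[SegmentPair],
    cfg: CnnConfig = CnnConfig(),
    tcfg: TrainConfig = TrainConfig(),
    k: int = 5,
    augment: bool = True,
) -> list[MetricsReport]:
    """Subject-grouped k-fold cross-validation (no subject crosses folds).

    Overall performance is conventionally reported as the average of the
    per-fold metrics.
    """
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    folds = _subject_folds(pairs, k, tcfg.seed)
    input_length = difference_transform(pairs[0].corrupted).length
    reports = []
    for fold_i, val_idx in enumerate(folds):
        train_pairs = [p for j, p in enumerate(pairs)
                       if j not in set(val_idx)]
        val_pairs = [pairs[j] for j in val_idx]
        est = AmsaEstimator(cfg, input_length, seed=tcfg.seed + fold_i)
        train(est, train_pairs, tcfg, augment=augment)
        reports.append(evaluate_on_pairs(est, val_pairs))
    return reports


DEFAULT_GRID = {"kernel_width": (3, 5, 7, 9, 11),
                "n_pooled_blocks": (1, 2, 3, 4, 5, 6, 7),
                "channels": (4, 8, 16, 32, 64)}


def grid_search(
    pairs: Sequence[SegmentPair],
    grid: dict[str, Iterable[int]] = DEFAULT_GRID,
    tcfg: TrainConfig = TrainConfig(),
    val_pairs: Sequence[SegmentPair] | None = None,
    base_cfg: CnnConfig = CnnConfig(),
    augment: bool = False,
) -> tuple[CnnConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search selected by validation MAE.

    With ``val_pairs`` given, each combination trains once on ``pairs``
    and scores on the fixed validation set (the desk-scale protocol);
    otherwise a subject-grouped 2-fold CV on ``pairs`` is used.
    Combinations invalid for the input length are skipped with a warning.
    Ties break toward the smaller parameter count.
    """
    input_length = difference_transform(pairs[0].corrupted).length
    rows = []
    for w in grid.get("kernel_width", (base_cfg.kernel_width,)):
        for n in grid.get("n_pooled_blocks", (base_cfg.n_pooled_blocks,)):
            for c in grid.get("channels", (base_cfg.channels,)):
                cfg = replace(base_cfg, kernel_width=w, n_pooled_blocks=n, channels=c)
                try:
                    cfg.validate(input_length)
                except ConfigurationError as exc:
                    logger.warning("skipping W=%d N=%d C=%d: %s", w, n, c, exc)
                    continue
                if val_pairs is not None:
                    est = AmsaEstimator(cfg, input_length, seed=tcfg.seed)
                    train(est, pairs, tcfg, augment=augment)
                    mae = evaluate_on_pairs(est, val_pairs).mae
                    n_params = est.n_parameters
                else:
                    reports = cross_validate(pairs, cfg, tcfg, k=2, augment=augment)
                    mae = float(np.mean([r.mae for r in reports]))
                    n_params = AmsaEstimator(cfg, input_length).n_parameters
                rows.append({"kernel_width": w, "n_pooled_blocks": n, "channels": c,
                             "val_mae": mae, "n_parameters": n_params})
    if not rows:
        raise InvalidInputError("grid contained no valid combination")
    table = pd.DataFrame(rows).sort_values(["val_mae", "n_parameters"],
                                           ignore_index=True)
    best = table.iloc[0]
    best_cfg = replace(base_cfg, kernel_width=int(best.kernel_width),
                       n_pooled_blocks=int(best.n_pooled_blocks),
                       channels=int(best.channels))
    return best_cfg, table


class AmsaCnnRegressor:
    """Model object: segment pairs plus architecture/training configuration.

    Examples
    --------
    >>> model = AmsaCnnRegressor(train_pairs)          # doctest: +SKIP
    >>> res = model.fit()                              # doctest: +SKIP
    >>> res.predict_amsa(some_segment)                 # doctest: +SKIP
    """

    def __init__(self, pairs: Sequence[SegmentPair],
                 cnn: CnnConfig = CnnConfig(),
                 training: TrainConfig = TrainConfig()) -> None:
        if not pairs:
            raise InvalidInputError("AmsaCnnRegressor needs at least one segment pair")
        self.pairs = list(pairs)
        self.cnn = cnn
        self.training = training
        self.input_length = difference_transform(self.pairs[0].corrupted).length
        cnn.validate(self.input_length)

    @classmethod
    def from_dataset(cls, splits: dict[str, list[SegmentPair]],
                     cnn: CnnConfig = CnnConfig(),
                     training: TrainConfig = TrainConfig()) -> "AmsaCnnRegressor":
        """Build from a ``build_dataset``-style dict, training on its 'train' split."""
        return cls(splits["train"], cnn=cnn, training=training)

    def fit(self, augment: bool = True) -> "AmsaCnnResults":
        est = AmsaEstimator(self.cnn, self.input_length, seed=self.training.seed,
                            init_range=self.training.init_range)
        train(est, self.pairs, self.training, augment=augment)
        return AmsaCnnResults(self, est)


class AmsaCnnResults:
    """Fitted-estimator results: parameters, history, prediction, summary."""

    def __init__(self, model: AmsaCnnRegressor, estimator: AmsaEstimator) -> None:
        self.model = model
        self.estimator = estimator
        self.history = estimator.history

    def predict_amsa(self, segment: EcgSegment) -> float:
        return self.estimator.predict_segment(segment)

    def predict(self, pairs: Sequence[SegmentPair]) -> np.ndarray:
        inputs = [difference_transform(p.corrupted) for p in pairs]
        return self.estimator.predict_inputs(inputs)

    def metrics(self, pairs: Sequence[SegmentPair]) -> MetricsReport:
        return evaluate_on_pairs(self.estimator, pairs)

    def save(self, path: str | Path) -> Path:
        return self.estimator.save(path)

    def summary(self) -> str:
        cfg, tcfg = self.model.cnn, self.model.training
        lines = [
            "AMSA 1D-CNN regression results",
            "=" * 46,
            f"{'input length':<28}{self.model.input_length}",
            f"{'conv blocks (pooled + 1)':<28}{cfg.n_pooled_blocks} + 1",
            f"{'kernel width W':<28}{cfg.kernel_width}",
            f"{'channels C':<28}{cfg.channels}",
            f"{'fully connected':<28}{cfg.fc_sizes}",
            f"{'parameters':<28}{self.estimator.n_parameters}",
            f"{'training pairs':<28}{len(self.model.pairs)}",
            f"{'epochs x batch':<28}{tcfg.epochs} x {tcfg.batch_size}",
            f"{'final training MSE':<28}"
            f"{self.history[-1]:.4f} (mV.Hz)^2" if self.history else
            f"{'final training MSE':<28}n/a",
            "=" * 46,
        ]
        return "\n".join(lines)
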