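"""Training, evaluation and augmentation benchmarking protocol.

The protocol: stratified random 70/15/15 train/validation/test splits,
repeated ``n_folds`` times with per-fold seeds (Monte-Carlo cross-
validation), a fresh classifier per fold, Adam training with on-the-fly
augmentation (every training volume re-augmented with freshly drawn
parameters each epoch; validation and test volumes are never augmented),
and one of two stopping regimes:

* ``early_stopping`` — halt once validation accuracy has not improved for
  ``patience_epochs`` epochs (default 50) and restore the best-validation
  weights;
* ``fixed_epochs`` — run exactly ``fixed_epochs`` epochs (default 150) and
  keep the final weights.

``run_benchmark`` trains every named augmentation strategy on identical
per-fold splits and identical weight initializations (paired comparison)
and reports mean ± sd test accuracy per strategy plus the delta against the
no-augmentation baseline in percentage units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, augment
from .cnn import Adam, CNN3D, CNNSpec, bce_with_logits, build_model, predict_proba
from .volumes import LabelledDataset

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class TrainConfig:
    """Optimization and protocol settings.

    Reference values: Adam with learning rate 1e-5, batch size 16, early
    stopping with patience 50 (capped at ``max_epochs``) or a fixed run of
    150 epochs. ``intensity_mode`` optionally rescales each volume by its
    maximum before training (no rescaling by default).
    """

    learning_rate: float = 1e-5
    batch_size: int = 16
    stopping_mode: str = "early_stopping"
    patience_epochs: int = 50
    max_epochs: int = 500
    fixed_epochs: int = 150
    augmentation: Optional[AugmentationConfig] = None
    intensity_mode: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.stopping_mode not in ("early_stopping", "fixed_epochs"):
            raise ValueError("stopping_mode must be 'early_stopping' or 'fixed_epochs'")
        if self.intensity_mode not in ("none", "divide_by_max"):
            raise ValueError("intensity_mode must be 'none' or 'divide_by_max'")


@dataclass
class FoldResult:
    fold_id: int = 0
    train_accuracy: float = float("nan")
    val_accuracy: float = float("nan")
    test_accuracy: float = float("nan")
    epochs_run: int = 0
    best_epoch: int = 0
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("train_accuracy", "val_accuracy", "test_accuracy"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.best_epoch > self.epochs_run:
            raise ValueError("best_epoch cannot exceed epochs_run")


class EarlyStopping:
    """Track validation accuracy; stop ``patience`` epochs after the last improvement.

    Improvement means strictly greater than the running best. Epochs are
    1-indexed; with the last improvement at epoch e, ``should_stop`` first
    becomes true after epoch e + patience.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, val_accuracy: float) -> bool:
        """Register one epoch's validation accuracy; True if it improved."""
        self.epoch += 1
        if val_accuracy > self.best:
            self.best = val_accuracy
            self.best_epoch = self.epoch
            return True
        return False

    @property
    def should_stop(self) -> bool:
        return self.epoch - self.best_epoch >= self.patience


def _largest_remainder(total: int, fractions: Sequence[float]) -> np.ndarray:
    quotas = np.asarray(fractions, dtype=float) * total
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    shortfall = total - int(base.sum())
    order = np.argsort(-remainder, kind="stable")
    base[order[:shortfall]] += 1
    return base


def split_dataset(
    dataset: LabelledDataset,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LabelledDataset, LabelledDataset, LabelledDataset]:
    """Stratified random train/validation/test split.

    Global subset sizes come from largest-remainder rounding of
    ``n * fraction`` (1112 subjects at 70/15/15 give 778/167/167); within
    each class the same rounding is used, adjusted so both the per-class
    totals and the global subset sizes are met exactly. Deterministic given
    the generator state.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if rng is None:
        rng = np.random.default_rng(0)
    labels = dataset.labels
    classes = np.unique(labels)
    for c in classes:
        if (labels == c).sum() < 3:
            raise ValueError(
                f"stratification error: class {c} has fewer than 3 subjects"
            )
    n = len(dataset)
    col_targets = _largest_remainder(n, fractions)

    class_counts = np.array([(labels == c).sum() for c in classes])
    quotas = class_counts[:, None] * col_targets[None, :] / n
    alloc = np.floor(quotas).astype(int)
    remainder = quotas - alloc
    row_deficit = class_counts - alloc.sum(axis=1)
    col_deficit = col_targets - alloc.sum(axis=0)
    cells = sorted(
        ((ci, si) for ci in range(len(classes)) for si in range(3)),
        key=lambda cs: -remainder[cs],
    )
    while row_deficit.sum() > 0:
        progressed = False
        for ci, si in cells:
            if row_deficit[ci] > 0 and col_deficit[si] > 0:
                alloc[ci, si] += 1
                row_deficit[ci] -= 1
                col_deficit[si] -= 1
                progressed = True
        if not progressed:  # cannot happen with consistent deficits
            raise RuntimeError("split allocation failed")

    subsets: list[list[int]] = [[], [], []]
    for ci, c in enumerate(classes):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        start = 0
        for si in range(3):
            take = alloc[ci, si]
            subsets[si].extend(idx[start : start + take].tolist())
            start += take
    return tuple(dataset.subset(sorted(s)) for s in subsets)  # type: ignore[return-value]


def _prepare_arrays(subset: LabelledDataset, intensity_mode: str):
    X, y = subset.to_arrays()
    if intensity_mode == "divide_by_max":
        maxima = X.reshape(X.shape[0], -1).max(axis=1)
        maxima[maxima <= 0] = 1.0
        X = X / maxima[:, None, None, None]
    return X, y


def _batch_accuracy_logits(model: CNN3D, X: np.ndarray, y: np.ndarray, batch_size: int):
    losses, correct = 0.0, 0
    for start in range(0, len(y), batch_size):
        z = model.forward_logits(X[start : start + batch_size], train=False)
        loss, _ = bce_with_logits(z, y[start : start + batch_size])
        losses += loss * len(z)
        correct += int(((z >= 0).astype(int) == y[start : start + batch_size]).sum())
    return losses / len(y), correct / len(y)


def train_model(
    train: LabelledDataset,
    val: LabelledDataset,
    model: CNN3D,
    config: TrainConfig,
    seed: Optional[int] = None,
) -> tuple[CNN3D, FoldResult]:
    """Train one model on one split under the configured stopping regime.

    Training volumes are re-augmented with fresh random parameters every
    epoch when an augmentation strategy is configured; validation volumes
    are never augmented. Deterministic given (model seed, config, seed).
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    if len(val) == 0:
        raise ValueError("validation set is empty")
    seed = config.seed if seed is None else int(seed)
    shuffle_seq, aug_seq = np.random.SeedSequence(seed).spawn(2)
    shuffle_rng = np.random.default_rng(shuffle_seq)
    aug_rng = np.random.default_rng(aug_seq)

    Xtr, ytr = _prepare_arrays(train, config.intensity_mode)
    Xval, yval = _prepare_arrays(val, config.intensity_mode)

    optimizer = Adam(model, config.learning_rate)
    early = config.stopping_mode == "early_stopping"
    cap = config.max_epochs if early else config.fixed_epochs
    stopper = EarlyStopping(config.patience_epochs) if early else None
    aug_cfg = config.augmentation

    history: dict[str, list[float]] = {
        "loss": [],
        "train_accuracy": [],
        "val_loss": [],
        "val_accuracy": [],
    }
    best_weights = None
    epochs_run = 0
    for epoch in range(cap):
        perm = shuffle_rng.permutation(len(ytr))
        loss_sum, correct = 0.0, 0
        for start in range(0, len(perm), config.batch_size):
            bidx = perm[start : start + config.batch_size]
            xb = Xtr[bidx]
            if aug_cfg is not None:
                xb = np.stack([augment(x, aug_cfg, aug_rng) for x in xb])
            yb = ytr[bidx]
            logits = model.forward_logits(xb, train=True)
            loss, dlogits = bce_with_logits(logits, yb)
            model.backward(dlogits)
            optimizer.step()
            loss_sum += loss * len(bidx)
            correct += int(((logits >= 0).astype(int) == yb).sum())
        val_loss, val_acc = _batch_accuracy_logits(model, Xval, yval, config.batch_size)
        history["loss"].append(loss_sum / len(ytr))
        history["train_accuracy"].append(correct / len(ytr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        epochs_run = epoch + 1
        if early:
            if stopper.update(val_acc):
                best_weights = model.get_weights()
            if stopper.should_stop:
                break

    if early and best_weights is not None:
        model.set_weights(best_weights)
        best_epoch = stopper.best_epoch
    else:
        best_epoch = epochs_run
    model.history = history
    result = FoldResult(
        fold_id=0,
        train_accuracy=history["train_accuracy"][best_epoch - 1],
        val_accuracy=history["val_accuracy"][best_epoch - 1],
        epochs_run=epochs_run,
        best_epoch=best_epoch,
        history=history,
    )
    return model, result


def evaluate(model: CNN3D, test: LabelledDataset, intensity_mode: str = "none") -> float:
    """Fraction of correct threshold-0.5 classifications on a held-out set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    X, y = _prepare_arrays(test, intensity_mode)
    probs = predict_proba(model, X)
    return float(((probs >= 0.5).astype(int) == y).mean())


def cross_validate(
    dataset: LabelledDataset,
    config: TrainConfig,
    n_folds: int = 10,
    model_spec: Optional[CNNSpec] = None,
) -> list[FoldResult]:
    """Repeated stratified 70/15/15 splits, one fresh model per fold.

    Fold f uses seed ``config.seed + f`` for its split, its weight
    initialization and its training stream, so results are reproducible and
    splits are shared across strategies that differ only in augmentation.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if model_spec is None:
        model_spec = CNNSpec(input_shape=dataset.volumes[0].shape + (1,))
    results = []
    for fold in range(n_folds):
        fold_seed = config.seed + fold
        train, val, test = split_dataset(dataset, rng=np.random.default_rng(fold_seed))
        model = build_model(model_spec, seed=fold_seed)
        model, fr = train_model(train, val, model, config, seed=fold_seed)
        fr.fold_id = fold
        fr.test_accuracy = evaluate(model, test, config.intensity_mode)
        results.append(fr)
    return results


@dataclass
class BenchmarkResult:
    """Per-strategy fold results with paired splits across strategies."""

    folds: dict[str, list[FoldResult]]
    baseline: str = "none"

    def __post_init__(self) -> None:
        if self.baseline not in self.folds:
            raise ValueError(f"baseline strategy {self.baseline!r} missing")
        n = {name: len(f) for name, f in self.folds.items()}
        if len(set(n.values())) != 1:
            raise ValueError(f"strategies have unequal fold counts: {n}")

    def test_accuracies(self, name: str) -> np.ndarray:
        return np.array([f.test_accuracy for f in self.folds[name]])

    def mean_accuracy(self, name: str) -> float:
        return float(self.test_accuracies(name).mean())

    def sd_accuracy(self, name: str) -> float:
        acc = self.test_accuracies(name)
        return float(acc.std(ddof=1)) if len(acc) > 1 else 0.0

    def delta_pct(self, name: str, reference: Optional[str] = None) -> float:
        """Mean test-accuracy difference vs the reference, in percentage units."""
        reference = self.baseline if reference is None else reference
        return 100.0 * (self.mean_accuracy(name) - self.mean_accuracy(reference))


def run_benchmark(
    dataset: LabelledDataset,
    strategies: dict[str, Optional[AugmentationConfig]],
    config: TrainConfig,
    n_folds: int = 10,
    model_spec: Optional[CNNSpec] = None,
) -> BenchmarkResult:
    """Cross-validate every augmentation strategy on identical fold splits.

    ``strategies`` maps a name to an AugmentationConfig (or None for no
    augmentation) and must contain the baseline entry ``"none"``. Combined
    strategies are expressed as a single config with several families
    enabled.
    """
    if "none" not in strategies:
        raise ValueError("strategies must include the 'none' baseline")
    folds = {}
    for name, aug in strategies.items():
        cfg = replace(config, augmentation=aug)
        folds[name] = cross_validate(dataset, cfg, n_folds=n_folds, model_spec=model_spec)
    return BenchmarkResult(folds=folds)


def summarize(result: BenchmarkResult) -> pd.DataFrame:
    """Per-strategy mean, sd (over folds, n-1 denominator) and delta vs baseline.

    Deltas are reported in percentage units rounded to one decimal; the
    unrounded mean and sd columns are kept for downstream use.
    """
    rows = []
    for name in result.folds:
        rows.append(
            {
                "strategy": name,
                "n_folds": len(result.folds[name]),
                "mean_test_accuracy": result.mean_accuracy(name),
                "sd_test_accuracy": result.sd_accuracy(name),
                "delta_pct": round(result.delta_pct(name), 1),
            }
        )
    return pd.DataFrame(rows)
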