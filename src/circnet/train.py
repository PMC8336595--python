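"""Model optimization, grouped cross-validation and evaluation metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .features import FeatConfig, build_batch
from .io import Dataset, GeneRecord
from .model import ModelConfig, ModelParams, forward, init_params, loss, loss_graph

__all__ = [
    "TrainConfig",
    "MetricReport",
    "AMSGrad",
    "train",
    "grouped_kfold",
    "evaluate",
    "rank_auc",
    "predict_scores",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and training-loop settings (defaults = published values)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    amsgrad: bool = True
    batch_size: int = 64
    lambda_l2: float = 1e-3
    max_epochs: int = 100
    patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1/beta2 must be in (0,1)")


class AMSGrad:
    """AMSGrad variant of Adam: keeps the elementwise max of second moments."""

    def __init__(self, params: ModelParams, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, amsgrad: bool = True, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.amsgrad = amsgrad
        self.m = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.vhat = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[k], self.v[k], out=self.vhat[k])
                denom = np.sqrt(self.vhat[k]) + self.eps
            else:
                mhat = self.m[k] / (1 - self.b1 ** self.t)
                vhat = self.v[k] / (1 - self.b2 ** self.t)
                self.params.arrays[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                continue
            self.params.arrays[k] -= self.lr * self.m[k] / denom


def _group_key(rec: GeneRecord) -> str:
    return rec.group_id if rec.group_id is not None else rec.id


def _split_by_group(records: list[GeneRecord], fraction: float, rng: np.random.Generator):
    """Group-aware split; returns (major, minor) with ~fraction in minor."""
    groups: dict[str, list[GeneRecord]] = {}
    for rec in records:
        groups.setdefault(_group_key(rec), []).append(rec)
    keys = sorted(groups)
    rng.shuffle(keys)
    target = int(round(fraction * len(records)))
    minor, count = [], 0
    for key in keys:
        if count >= target:
            break
        minor.extend(groups[key])
        count += len(groups[key])
    minor_ids = {r.id for r in minor}
    major = [r for r in records if r.id not in minor_ids]
    return major, minor


def _iter_batches(records: list[GeneRecord], batch_size: int, rng: np.random.Generator | None):
    order = np.arange(len(records))
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, len(records), batch_size):
        yield [records[int(i)] for i in order[start : start + batch_size]]


def predict_scores(records: list[GeneRecord], params: ModelParams, cfg: ModelConfig,
                   batch_size: int = 64, return_maps: bool = False):
    """Score records in order; optionally collect per-record attention maps."""
    feat = FeatConfig(L=cfg.L, K=cfg.K)
    scores, maps = [], []
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        res = forward(build_batch(chunk, feat), params, cfg)
        scores.extend(res.scores.tolist())
        if return_maps:
            maps.extend(res.maps)
    scores = np.asarray(scores)
    return (scores, maps) if return_maps else scores


def train(dataset: Dataset | list[GeneRecord], model_config: ModelConfig,
          train_config: TrainConfig) -> tuple[ModelParams, list[dict]]:
    """Optimize with AMSGrad and early stopping on validation loss.

    Returns the parameters at the best validation loss and a per-epoch log.
    Fully reproducible for a fixed seed.
    """
    records = list(dataset.records if isinstance(dataset, Dataset) else dataset)
    records = [r for r in records if r.label is not None]
    labels = {r.label for r in records}
    if labels != {0, 1}:
        raise ValueError("training requires at least one record of each class")
    rng = np.random.default_rng(train_config.seed)
    params = init_params(model_config, seed=train_config.seed)
    if train_config.max_epochs == 0:
        return params, []
    train_recs, val_recs = _split_by_group(records, train_config.val_fraction, rng)
    if not val_recs or not train_recs:
        train_recs, val_recs = records, records
    feat = FeatConfig(L=model_config.L, K=model_config.K)
    opt = AMSGrad(params, lr=train_config.learning_rate, beta1=train_config.beta1,
                  beta2=train_config.beta2, amsgrad=train_config.amsgrad)
    best_loss, best_params, best_epoch = np.inf, params.copy(), -1
    log: list[dict] = []
    for epoch in range(train_config.max_epochs):
        epoch_losses = []
        for chunk in _iter_batches(train_recs, train_config.batch_size, rng):
            batch = build_batch(chunk, feat)
            tensors = params.as_tensors()
            from .model import _forward_graph  # local import avoids cycle at module load

            result = _forward_graph(batch, tensors, model_config)
            obj = loss_graph(result, batch.labels, train_config.lambda_l2)
            obj.backward()
            grads = {k: t.grad for k, t in tensors.items() if t.grad is not None}
            opt.step(grads)
            epoch_losses.append(float(obj.data))
        val_scores = predict_scores(val_recs, params, model_config, train_config.batch_size)
        val_y = np.array([r.label for r in val_recs])
        val_loss = loss(val_scores, val_y, params, train_config.lambda_l2)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_accuracy": float(np.mean((val_scores > 0.5) == val_y)),
        }
        log.append(entry)
        if val_loss < best_loss - 1e-9:
            best_loss, best_params, best_epoch = val_loss, params.copy(), epoch
        elif epoch - best_epoch >= train_config.patience:
            break
    return best_params, log


def grouped_kfold(records: list[GeneRecord], k: int, seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """k-fold splits that never separate records sharing a group_id.

    Returns ``k`` pairs of (train_ids, test_ids). Records without a group are
    their own singleton group. Fold sizes are balanced greedily by record
    count at group granularity.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(_group_key(rec), []).append(rec.id)
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} groups for {k} folds")
    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)
    # largest-first greedy balancing; shuffle breaks ties deterministically
    keys.sort(key=lambda g: -len(groups[g]))
    folds: list[list[str]] = [[] for _ in range(k)]
    for key in keys:
        smallest = min(range(k), key=lambda f: len(folds[f]))
        folds[smallest].extend(groups[key])
    all_ids = {r.id for r in records}
    splits = []
    for f in range(k):
        test = sorted(folds[f])
        train = sorted(all_ids - set(test))
        splits.append((train, test))
    return splits


@dataclass
class MetricReport:
    """Binary-classification metrics plus the confusion counts behind them."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    auc: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate_rates: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f1": self.f1, "mcc": self.mcc, "auc": self.auc,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


def rank_auc(y_true, scores) -> float:
    """ROC AUC via the Mann-Whitney rank statistic; ties count one half."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    r_pos = ranks[y_true == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(y_true, scores, threshold: float = 0.5) -> MetricReport:
    """Compute the full metric panel at a score threshold.

    Rates with a zero denominator are reported as 0 and recorded in
    ``degenerate_rates``.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must align")
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    degenerate = []

    def rate(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    acc = rate(tp + tn, tp + fp + fn + tn, "accuracy")
    prec = rate(tp, tp + fp, "precision")
    sens = rate(tp, tp + fn, "sensitivity")
    spec = rate(tn, tn + fp, "specificity")
    f1 = rate(2 * prec * sens, prec + sens, "f1") if (prec + sens) > 0 else _flag(degenerate, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else _flag(degenerate, "mcc")
    auc = rank_auc(y_true, scores)
    return MetricReport(
        accuracy=float(acc), precision=float(prec), sensitivity=float(sens),
        specificity=float(spec), f1=float(f1), mcc=float(mcc), auc=auc,
        tp=tp, fp=fp, fn=fn, tn=tn, degenerate_rates=degenerate,
    )


def _flag(degenerate: list[str], name: str) -> float:
    degenerate.append(name)
    return 0.0


def aggregate_reports(reports: list[MetricReport]) -> dict[str, tuple[float, float]]:
    """Mean and standard deviation per metric over cross-validation folds."""
    out = {}
    for key in ("accuracy", "precision", "sensitivity", "specificity", "f1", "mcc", "auc"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        out[key] = (float(vals.mean()), float(vals.std()))
    return out
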