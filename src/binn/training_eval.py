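"""Data preparation, the training regime, and k-fold evaluation.

Quantitative matrices are samples x proteins, possibly with missing
values (a protein not detected in a sample).  Preparation imputes missing
entries as 0 and standardizes each protein to mean 0 / variance 1, with
the scaler fit on a chosen sample subset (the training fold by default,
or the whole dataset for strict replication of whole-dataset scaling).

Training minimizes the cross-entropy of the averaged multi-head
prediction with Adam, an L2 weight penalty, a reduce-on-plateau learning
rate and early stopping.  When no validation subset is supplied
(interpretation mode: the model is fitted on the complete dataset before
attribution), the plateau/stopping monitor is the training loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, average_precision_score,
                             confusion_matrix, precision_recall_fscore_support,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .network import BinnModel, build_model
from .pathway_graph import LayeredSpec

logger = logging.getLogger(__name__)

__all__ = ["QuantDataset", "TrainConfig", "TrainResult", "EvalReport",
           "filter_min_per_group", "prepare", "train", "kfold_evaluate",
           "classification_metrics"]


# ---------------------------------------------------------------------------
# QuantDataset
# ---------------------------------------------------------------------------


@dataclass
class QuantDataset:
    """A samples x proteins abundance matrix with class labels.

    ``matrix`` holds abundances with NaN for missing (undetected) values;
    ``labels`` is indexed like the matrix rows.  ``detected`` exposes the
    observed/missing mask.  After :func:`prepare`, missing entries are
    exactly 0 and each protein is standardized on the fitting partition.
    """

    matrix: pd.DataFrame
    labels: pd.Series
    prepared: bool = False

    def __post_init__(self):
        self.labels = self.labels.reindex(self.matrix.index)
        if self.labels.isna().any():
            missing = self.labels[self.labels.isna()].index.tolist()
            raise ValueError(f"samples without a class label: {missing[:5]}")
        self._detected = ~self.matrix.isna()

    @property
    def detected(self) -> pd.DataFrame:
        return self._detected

    @property
    def proteins(self) -> list:
        return list(self.matrix.columns)

    @property
    def classes(self) -> list:
        return sorted(self.labels.unique())

    def y_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[v] for v in self.labels], dtype=int)

    def to_input(self, spec: LayeredSpec) -> np.ndarray:
        """Matrix restricted and ordered to the spec's input layer."""
        missing = [p for p in spec.proteins if p not in self.matrix.columns]
        if missing:
            raise KeyError(f"dataset lacks spec proteins: {missing[:5]}")
        return self.matrix[spec.proteins].to_numpy(dtype=float)

    def subset(self, idx) -> "QuantDataset":
        sub = QuantDataset(self.matrix.iloc[idx].copy(),
                           self.labels.iloc[idx].copy(),
                           prepared=self.prepared)
        sub._detected = self._detected.iloc[idx]
        return sub

    @classmethod
    def from_tsv(cls, matrix_path, design_path, sample_col: str | int = 0,
                 group_col: str | int = 1) -> "QuantDataset":
        """Read a quant matrix TSV (first column sample id, header row =
        protein ids) and a design TSV (sample, group columns)."""
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        if isinstance(sample_col, int):
            sample_col = design.columns[sample_col]
        if isinstance(group_col, int):
            group_col = design.columns[group_col]
        labels = design.set_index(sample_col)[group_col]
        return cls(mat, labels.reindex(mat.index))


def filter_min_per_group(data: QuantDataset, min_n: int = 3) -> QuantDataset:
    """Drop proteins detected in fewer than ``min_n`` samples in any group."""
    if len(data.classes) < 2:
        raise ValueError("filtering requires at least two groups")
    counts = data.detected.groupby(data.labels).sum()
    keep = (counts >= min_n).all(axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_min_per_group: dropped %d of %d proteins",
                    dropped, len(keep))
    if not keep.any():
        raise ValueError("every protein fails the per-group detection minimum")
    out = QuantDataset(data.matrix.loc[:, keep].copy(), data.labels.copy(),
                       prepared=data.prepared)
    return out


def prepare(data: QuantDataset, fit_on=None) -> QuantDataset:
    """Impute missing values as 0, then standardize each protein.

    Mean and SD are estimated on ``fit_on`` (an index array over samples;
    default: all samples, replicating whole-dataset scaling) and applied to
    the full matrix, so a held-out fold keeps honest leakage semantics.
    Zero-variance proteins become all-zero after centering.
    """
    filled = data.matrix.fillna(0.0)
    fit = filled if fit_on is None else filled.iloc[np.asarray(fit_on)]
    if len(fit) == 0:
        raise ValueError("fit_on selects no samples")
    mu = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    out = QuantDataset((filled - mu) / sd, data.labels.copy(), prepared=True)
    out._detected = data.detected.copy()
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyperparameters of the training regime.

    Defaults follow the regime used for DIA plasma cohorts: Adam at an
    initial learning rate of 1e-3 (1e-2 suits shallow targeted panels),
    L2 weight decay of 1e-3, cross-entropy loss, reduce-on-plateau
    scheduling and early stopping, k = 3 stratified folds.
    """

    lr0: float = 1e-3
    weight_decay: float = 1e-3
    max_epochs: int = 1000
    batch_size: int | None = 32          # None = full batch
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    min_lr: float = 1e-6
    early_stop_patience: int = 20
    k: int = 3
    p_drop: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0 or self.weight_decay < 0 or self.min_lr <= 0:
            raise ValueError("rates must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class TrainResult:
    model: BinnModel
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    stopped_epoch: int | None = None

    def curves_frame(self) -> pd.DataFrame:
        d = {"epoch": np.arange(len(self.train_loss)),
             "train_loss": self.train_loss, "lr": self.lr}
        if self.val_loss:
            d["val_loss"] = self.val_loss
        return pd.DataFrame(d)


def _onehot(y_idx: np.ndarray, c_out: int) -> np.ndarray:
    if c_out == 1:
        return y_idx.reshape(-1, 1).astype(float)
    out = np.zeros((len(y_idx), c_out))
    out[np.arange(len(y_idx)), y_idx] = 1.0
    return out


class _Adam:
    def __init__(self, params, lr, weight_decay):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            if self.wd and (k.startswith("W") or k.startswith("U")):
                g = g + self.wd * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: BinnModel, data: QuantDataset, cfg: TrainConfig,
          validation: QuantDataset | None = None) -> TrainResult:
    """Fit a model in place; returns the model plus loss curves.

    ``data`` (and ``validation``) must already be prepared; the monitored
    loss is the validation loss when a validation subset is supplied and
    the training loss otherwise.
    """
    if not data.prepared:
        raise ValueError("run prepare() before training")
    X = data.to_input(model.spec)
    y = _onehot(data.y_indices(), model.c_out)
    if model.c_out > 1 and len(data.classes) != model.c_out:
        raise ValueError("number of classes does not match the model outputs")
    Xv = yv = None
    if validation is not None:
        Xv = validation.to_input(model.spec)
        yv = _onehot(validation.y_indices(), model.c_out)

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.lr0, cfg.weight_decay)
    result = TrainResult(model=model)
    best = np.inf
    best_params = None
    plateau_wait = stop_wait = 0
    n = X.shape[0]

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        bs = cfg.batch_size or n
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            loss, grads = model.loss_and_grads(X[idx], y[idx], training=True,
                                               rng=rng)
            opt.step(model.params, grads)
            model.apply_masks()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        result.train_loss.append(train_loss)
        result.lr.append(opt.lr)
        if validation is not None:
            vloss, _ = model.loss_and_grads(Xv, yv, training=False)
            result.val_loss.append(float(vloss))
            monitored = float(vloss)
        else:
            # plateau/stopping watch the deterministic eval-mode training
            # loss, not the dropout-noisy running loss of the batches
            mloss, _ = model.loss_and_grads(X, y, training=False)
            monitored = float(mloss)

        if monitored < best - 1e-6:
            best = monitored
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_running = {k: v.copy() for k, v in model.running.items()}
            plateau_wait = stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait > cfg.plateau_patience and opt.lr > cfg.min_lr:
                opt.lr = max(opt.lr * cfg.plateau_factor, cfg.min_lr)
                plateau_wait = 0
            if stop_wait > cfg.early_stop_patience:
                result.stopped_epoch = epoch
                break

    if best_params is not None:
        model.params = best_params
        model.running = best_running
        model.apply_masks()
    model.fitted = True
    return result


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def classification_metrics(y_true: np.ndarray, proba: np.ndarray,
                           classes: list) -> dict:
    """Standard metrics from true class indices and class probabilities.

    ``proba`` has one column per class; the harness works for any scorer
    that can produce calibrated or uncalibrated class scores.
    """
    y_pred = proba.argmax(axis=1)
    c = len(classes)
    if c == 2:
        roc = roc_auc_score(y_true, proba[:, 1])
        pr = average_precision_score(y_true, proba[:, 1])
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", zero_division=0)
    else:
        roc = roc_auc_score(y_true, proba, multi_class="ovr", average="macro")
        pr = float(np.mean([
            average_precision_score((y_true == k).astype(int), proba[:, k])
            for k in range(c)]))
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(c),
                          normalize="true")
    per_class = precision_recall_fscore_support(
        y_true, y_pred, labels=np.arange(c), zero_division=0)
    return {
        "roc_auc": float(roc), "pr_auc": float(pr),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(prec), "recall": float(rec), "f1": float(f1),
        "per_class": {str(classes[k]): {"precision": float(per_class[0][k]),
                                        "recall": float(per_class[1][k]),
                                        "f1": float(per_class[2][k])}
                      for k in range(c)},
        "confusion_normalized": cm.tolist(),
    }


@dataclass
class EvalReport:
    """Per-fold metrics with mean and SD summaries."""

    folds: list
    classes: list

    _SCALARS = ("roc_auc", "pr_auc", "accuracy", "precision", "recall", "f1")

    def summary(self) -> dict:
        out = {}
        for key in self._SCALARS:
            vals = np.array([f[key] for f in self.folds])
            out[key] = {"mean": float(vals.mean()), "sd": float(vals.std()),
                        "ci95_halfwidth": float(1.96 * vals.std()
                                                / np.sqrt(len(vals)))}
        cms = np.array([f["confusion_normalized"] for f in self.folds])
        out["confusion_normalized_mean"] = cms.mean(axis=0).tolist()
        return out

    def to_json(self, path=None) -> str:
        doc = {"classes": [str(c) for c in self.classes],
               "folds": self.folds, "summary": self.summary()}
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def kfold_evaluate(spec: LayeredSpec, data: QuantDataset, cfg: TrainConfig,
                   *, paper_scaling: bool = False) -> EvalReport:
    """Stratified k-fold cross-validation with a fresh model per fold.

    The scaler is fit on each training fold by default;
    ``paper_scaling=True`` standardizes on the whole dataset instead
    (whole-cohort scaling, comparable across folds but with mild leakage).
    """
    y_idx = data.y_indices()
    counts = np.bincount(y_idx)
    if cfg.k > counts.min():
        raise ValueError(
            f"k={cfg.k} exceeds the smallest class count ({counts.min()}); "
            "a class would be absent from a fold")
    skf = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
    folds = []
    for fold_i, (tr, te) in enumerate(skf.split(data.matrix, y_idx)):
        fit_on = None if paper_scaling else tr
        prepared = prepare(data, fit_on=fit_on)
        d_tr, d_te = prepared.subset(tr), prepared.subset(te)
        model = build_model(spec, p_drop=cfg.p_drop,
                            seed=cfg.seed * 1000 + fold_i)
        res = train(model, d_tr, cfg, validation=d_te)
        proba = model.predict_proba(d_te.to_input(spec))
        m = classification_metrics(y_idx[te], proba, data.classes)
        m["fold"] = fold_i
        m["train_loss"] = res.train_loss
        m["val_loss"] = res.val_loss
        folds.append(m)
    return EvalReport(folds=folds, classes=data.classes)
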