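"""Balanced, cross-validated training and evaluation of the classifiers.

Protocol: the cohort is first class-balanced by down-sampling the
majority class to the minority count (uniform, seeded, minority fully
retained). Stratified 10-fold cross-validation then tests every subject
exactly once; within each training fold an inner stratified 10% split is
carved out for early stopping, and covariate min-max scaling is refit on
the training fold only — neither the test fold nor the inner validation
data ever influences fitting or scaling. Training uses Adam on binary
cross-entropy with an L2 weight penalty (default 0.01), batch size 8, at
most 100 epochs, and early stopping with patience 10 on validation
accuracy, restoring the best-validation epoch's weights.

Per-fold metrics are accuracy, precision, recall, F1 and rank-based AUC
(tie-corrected); a single-class test fold leaves AUC missing and
degenerate precision/recall denominators yield 0 with a logged warning.
Reporting writes per-fold and summary CSVs, a mean-metric heatmap across
(architecture, covariate-mode) pairs, and a per-fold AUC plot for the
best model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .models import Classifier, ModelSpec, build_model, N_COVARIATES
from .phenotype import CovariateScaler, COVARIATE_NAMES

__all__ = ["TrainConfig", "FoldResult", "MetricsTable", "EarlyStopper",
           "downsample_balance", "kfold_split", "train_model", "evaluate",
           "cross_validate", "standardize_feature_maps"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    optimizer: str = "adam"
    loss: str = "binary_cross_entropy"
    learning_rate: float = 1e-3
    l2_strength: float = 0.01
    k_folds: int = 10
    val_fraction: float = 0.1
    downsample_seed: int = 0
    split_seed: int = 0
    train_seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.k_folds < 2:
            raise ValueError(f"k_folds must be >= 2, got {self.k_folds}")
        if not self.patience < self.max_epochs:
            raise ValueError(f"patience ({self.patience}) must be < max_epochs "
                             f"({self.max_epochs})")
        if self.optimizer != "adam":
            raise ValueError(f"only the adam optimizer is provided, got {self.optimizer!r}")
        if self.loss != "binary_cross_entropy":
            raise ValueError(f"only binary cross-entropy is provided, got {self.loss!r}")


@dataclass
class FoldResult:
    fold_index: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    n_train: int
    n_test: int
    best_epoch: int


@dataclass
class MetricsTable:
    """Per-fold results plus mean/std aggregation, as tidy DataFrames."""

    folds: pd.DataFrame      # model, covariates, fold, metrics, sizes, best_epoch
    summary: pd.DataFrame    # model, covariates, metric, mean, std

    def mean(self, arch: str, use_covariates: bool, metric: str) -> float:
        s = self.summary
        row = s[(s["model"] == arch) & (s["covariates"] == use_covariates)
                & (s["metric"] == metric)]
        return float(row["mean"].iloc[0])


def downsample_balance(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a class-balanced subset: min(n0, n1) subjects per class.

    The minority class is fully retained; the majority subset is drawn
    uniformly without replacement. Indices come back sorted.
    """
    labels = np.asarray(labels)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present to balance by down-sampling")
    n = min(len(idx0), len(idx1))
    rng = np.random.default_rng(seed)
    take0 = idx0 if len(idx0) == n else rng.choice(idx0, size=n, replace=False)
    take1 = idx1 if len(idx1) == n else rng.choice(idx1, size=n, replace=False)
    return np.sort(np.concatenate([take0, take1]))


def kfold_split(n: int, k: int, labels: np.ndarray, seed: int
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled k-fold partition of ``range(n)``."""
    if k > n:
        raise ValueError(f"cannot split n={n} subjects into k={k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(n), np.asarray(labels))]


class EarlyStopper:
    """Patience-based stopping on a maximised validation metric.

    ``update`` returns True when the metric has not strictly improved for
    ``patience`` consecutive epochs; ``best_epoch`` identifies the weights
    to restore.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.stall = 0

    def update(self, epoch: int, value: float) -> bool:
        if value > self.best:
            self.best, self.best_epoch, self.stall = value, epoch, 0
            return False
        self.stall += 1
        return self.stall >= self.patience


def _bce_and_dlogit(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    return float(loss), (p - y) / len(y)


def train_model(model: Classifier, X: np.ndarray, covariates: np.ndarray | None,
                y: np.ndarray, config: TrainConfig) -> dict:
    """Train in place; restore the best-validation-accuracy weights.

    An inner stratified ``val_fraction`` split of the training data feeds
    early stopping. Returns a history dict with per-epoch train/validation
    loss and accuracy plus ``best_epoch`` (1-based).
    """
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    idx = np.arange(len(y))
    # stratified inner split needs >= 1 subject per class on both sides
    n_val = int(np.clip(round(config.val_fraction * len(y)), 2, len(y) - 2))
    tr_idx, va_idx = train_test_split(idx, test_size=n_val,
                                      stratify=y, random_state=config.train_seed % (2 ** 31))
    cov = covariates

    def _sub(indices):
        return (X[indices], None if cov is None else cov[indices], y[indices])

    Xtr, ctr, ytr = _sub(tr_idx)
    Xva, cva, yva = _sub(va_idx)

    params = model.params()
    weight_params = [p for p in params if p.is_weight]
    opt = nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([41, config.train_seed]))

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    stopper = EarlyStopper(config.patience)
    best_weights = model.get_weights()
    lam = config.l2_strength

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(ytr))
        for start in range(0, len(ytr), config.batch_size):
            b = order[start:start + config.batch_size]
            opt.zero_grad()
            p = model.forward(Xtr[b], None if ctr is None else ctr[b], train=True)
            _, dlogit = _bce_and_dlogit(p, ytr[b])
            model.backward(dlogit)
            if lam > 0:
                for wp in weight_params:
                    wp.grad += 2.0 * lam * wp.value
            opt.step()

        p_tr = model.forward(Xtr, ctr, train=False)
        p_va = model.forward(Xva, cva, train=False)
        tr_loss, _ = _bce_and_dlogit(p_tr, ytr)
        va_loss, _ = _bce_and_dlogit(p_va, yva)
        va_acc = float(np.mean((p_va >= 0.5) == yva))
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(float(np.mean((p_tr >= 0.5) == ytr)))
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)

        improved_epoch = stopper.best_epoch
        stop = stopper.update(epoch, va_acc)
        if stopper.best_epoch != improved_epoch or epoch == 1:
            best_weights = model.get_weights()
        if stop:
            break

    model.set_weights(best_weights)
    history["best_epoch"] = stopper.best_epoch
    return history


def evaluate(model: Classifier, X: np.ndarray, covariates: np.ndarray | None,
             y: np.ndarray, threshold: float = 0.5) -> dict:
    """Threshold metrics plus tie-corrected rank AUC on one test set.

    AUC is missing (None) when the test set holds a single class;
    degenerate precision/recall denominators yield 0 with a warning.
    """
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("test set must be non-empty")
    p = model.forward(X, covariates, train=False)
    yhat = (p >= threshold).astype(int)

    precision = skm.precision_score(y, yhat, zero_division=0)
    recall = skm.recall_score(y, yhat, zero_division=0)
    if (yhat == 1).sum() == 0 or (y == 1).sum() == 0:
        logger.warning("degenerate precision/recall denominator; reporting 0")
    auc = None
    if len(np.unique(y)) == 2:
        auc = float(skm.roc_auc_score(y, p))
    else:
        logger.warning("single-class test set; AUC undefined, recorded as missing")
    return dict(
        accuracy=float(skm.accuracy_score(y, yhat)),
        precision=float(precision),
        recall=float(recall),
        f1=float(skm.f1_score(y, yhat, zero_division=0)),
        auc=auc,
        probabilities=p,
    )


def _covariate_matrix(scaled: pd.DataFrame) -> np.ndarray:
    return scaled[list(COVARIATE_NAMES)].to_numpy(dtype=np.float64)


def standardize_feature_maps(train_maps: np.ndarray, *others: np.ndarray):
    """Per-feature z-scoring of (N, slices, features) stacks.

    A frozen backbone emits features of arbitrary scale, so the training
    harness standardises each feature column to zero mean / unit variance
    — statistics fit on the training subjects only, applied unchanged to
    held-out subjects. Column-wise affine maps keep padded-slice rows
    identical within a subject.
    """
    mu = train_maps.mean(axis=(0, 1))
    sd = train_maps.std(axis=(0, 1))
    sd = np.where(sd < 1e-12, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train_maps, *others))


def cross_validate(feature_maps: np.ndarray, attrs: pd.DataFrame, labels: np.ndarray,
                   model_specs: list[ModelSpec], config: TrainConfig,
                   out_dir: str | Path | None = None) -> MetricsTable:
    """Full protocol for each requested (architecture, covariate-mode).

    ``feature_maps`` is (N, slices, features); ``attrs`` holds the *raw*
    attribute columns (age, gender, handedness, full4_iq, ld_or_odd) so
    scaling can be refit inside each training fold. Artifacts (CSVs,
    heatmap, per-fold AUC plot, run manifest) are written when ``out_dir``
    is given.
    """
    feature_maps = np.asarray(feature_maps, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    keep = downsample_balance(labels, config.downsample_seed)
    X = feature_maps[keep]
    y = labels[keep]
    attrs = attrs.iloc[keep].reset_index(drop=True)
    folds = kfold_split(len(y), config.k_folds, y, config.split_seed)

    rows = []
    for spec in model_specs:
        for fold_i, (tr, te) in enumerate(folds):
            Xtr, Xte = standardize_feature_maps(X[tr], X[te])
            cov_tr = cov_te = None
            if spec.use_covariates:
                scaler = CovariateScaler().fit(attrs.iloc[tr])
                cov_tr = _covariate_matrix(scaler.transform(attrs.iloc[tr]))
                cov_te = _covariate_matrix(scaler.transform(attrs.iloc[te]))
            model = build_model(
                ModelSpec(**{**asdict(spec), "init_seed": spec.init_seed + fold_i}),
                feature_maps.shape[1:],
                N_COVARIATES if spec.use_covariates else 0,
            )
            try:
                history = train_model(model, Xtr, cov_tr, y[tr], config)
            except ValueError as exc:
                raise ValueError(f"fold {fold_i} ({spec.arch}): {exc}") from exc
            m = evaluate(model, Xte, cov_te, y[te])
            rows.append(dict(model=spec.arch, covariates=spec.use_covariates,
                             fold=fold_i, accuracy=m["accuracy"], precision=m["precision"],
                             recall=m["recall"], f1=m["f1"], auc=m["auc"],
                             n_train=len(tr), n_test=len(te),
                             best_epoch=history["best_epoch"]))
            logger.info("%s cov=%s fold %d: acc=%.3f auc=%s", spec.arch,
                        spec.use_covariates, fold_i, m["accuracy"],
                        "NA" if m["auc"] is None else f"{m['auc']:.3f}")

    folds_df = pd.DataFrame(rows)
    agg = []
    for (arch, use_cov), grp in folds_df.groupby(["model", "covariates"], sort=False):
        for metric in METRIC_NAMES:
            vals = grp[metric].dropna().astype(float)
            agg.append(dict(model=arch, covariates=use_cov, metric=metric,
                            mean=float(vals.mean()), std=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0))
    table = MetricsTable(folds=folds_df, summary=pd.DataFrame(agg))

    if out_dir is not None:
        _write_artifacts(table, config, model_specs, Path(out_dir))
    return table


def _write_artifacts(table: MetricsTable, config: TrainConfig,
                     model_specs: list[ModelSpec], out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    table.folds.to_csv(out_dir / "folds.csv", index=False)
    table.summary.to_csv(out_dir / "summary.csv", index=False)

    # mean-metric heatmap over (model, covariate-mode) rows
    piv = table.summary.pivot_table(index=["model", "covariates"], columns="metric",
                                    values="mean")[list(METRIC_NAMES)]
    fig, ax = plt.subplots(figsize=(7, 1.0 + 0.6 * len(piv)))
    im = ax.imshow(piv.to_numpy(), vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(piv.columns)), piv.columns)
    ax.set_yticks(range(len(piv)),
                  [f"{m} (+cov)" if c else m for m, c in piv.index])
    for i in range(piv.shape[0]):
        for j in range(piv.shape[1]):
            ax.text(j, i, f"{piv.iat[i, j]:.2f}", ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax, label="mean over folds")
    ax.set_title("10-fold cross-validation, mean metrics")
    fig.tight_layout()
    fig.savefig(out_dir / "heatmap.png", dpi=120)
    plt.close(fig)

    # per-fold AUC for the best model by mean AUC
    sm = table.summary
    aucs = sm[sm["metric"] == "auc"].sort_values("mean", ascending=False)
    best_arch, best_cov = aucs.iloc[0]["model"], bool(aucs.iloc[0]["covariates"])
    sel = table.folds[(table.folds["model"] == best_arch)
                      & (table.folds["covariates"] == best_cov)]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(sel["fold"], sel["auc"], marker="o")
    ax.axhline(float(aucs.iloc[0]["mean"]), ls="--", color="gray", label="mean")
    ax.set_xlabel("fold")
    ax.set_ylabel("AUC")
    ax.set_ylim(0, 1.05)
    ax.set_title(f"per-fold AUC, {best_arch}{' + covariates' if best_cov else ''}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "auc_per_fold.png", dpi=120)
    plt.close(fig)

    manifest = dict(
        config=asdict(config),
        models=[{**asdict(s), "hidden_sizes": list(s.trunk_sizes)} for s in model_specs],
        seeds=dict(downsample=config.downsample_seed, split=config.split_seed,
                   train=config.train_seed),
    )
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
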