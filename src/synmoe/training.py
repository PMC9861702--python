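"""Losses, the multi-task objective, order-augmented training with early
stopping, five-fold cross-validation, and the ablation-variant harness.

The objective is the weighted sum of per-task losses: mean squared error
(weight 1) for each synergy-score regression and label-smoothing
cross-entropy (weight 10) for the two classification tasks.  Training
records are order-augmented — every pair appears in both <x, y> and <y, x>
orientation — and test-time predictions average the two orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .data_model import CombinationSample, Dataset, FeatureStore
from .network import (ExpertSpec, ModelConfig, PredictionBundle, SynergyMoE,
                      TaskSpec, default_experts, default_tasks)
from .nn import Adam, log_softmax

LOG_FLOOR = 1e-12  # probability floor before taking logarithms


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 1000
    patience: int = 100
    smoothing_eps: float = 0.1
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 <= self.smoothing_eps < 1.0:
            raise ValueError("smoothing_eps must be in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def sce_loss(probs, true_class: int, eps: float = 0.1) -> float:
    """Label-smoothing cross-entropy on one probability vector.

    The true class keeps weight (1 - eps); each other class receives weight
    eps.  With eps = 0 this is plain cross-entropy.  Probabilities are
    floored at 1e-12 before the logarithm.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"eps must be in [0, 1), got {eps}")
    p = np.maximum(np.asarray(probs, dtype=float), LOG_FLOOR)
    logp = np.log(p)
    weights = np.full(p.shape[-1], eps)
    weights[true_class] = 1.0 - eps
    return float(-(weights * logp).sum())


def total_loss(bundle: PredictionBundle, sample: CombinationSample,
               tasks: list[TaskSpec], eps: float = 0.1) -> float:
    """Weighted multi-task loss for a single sample:
    sum of loss_weight * (squared error | SCE) over the task roster."""
    total = 0.0
    for task in tasks:
        if task.kind == "regression":
            if task.name not in bundle.regression:
                raise KeyError(f"bundle missing regression output {task.name!r}")
            err = bundle.regression[task.name] - sample.scores[task.name]
            total += task.loss_weight * err * err
        else:
            if task.name not in bundle.classification:
                raise KeyError(f"bundle missing classification output {task.name!r}")
            label = sample.synergy_label if task.name == "synergy" else sample.ddi_label
            total += task.loss_weight * sce_loss(
                bundle.classification[task.name], label, eps)
    return total


def _sce_from_logits(logits: Tensor, labels: np.ndarray, eps: float) -> Tensor:
    """Batch-mean SCE computed from logits via log-softmax (stable path)."""
    logp = log_softmax(logits, axis=1)
    n, k = logits.data.shape
    weights = np.full((n, k), eps)
    weights[np.arange(n), labels.astype(int)] = 1.0 - eps
    return -(logp * Tensor(weights)).sum() * (1.0 / n)


def _batch_loss(outputs: dict[str, Tensor], targets: dict[str, np.ndarray],
                tasks, eps: float) -> Tensor:
    """Differentiable batch objective; per-batch reduction is the sample mean."""
    loss = None
    for task in tasks:
        y = targets[task.name]
        if task.kind == "regression":
            pred = outputs[task.name].reshape(-1)
            term = ((pred - Tensor(y)) ** 2.0).mean() * task.loss_weight
        else:
            term = _sce_from_logits(outputs[task.name], y, eps) * task.loss_weight
        loss = term if loss is None else loss + term
    return loss


# --------------------------------------------------------------------------
# data plumbing
# --------------------------------------------------------------------------

def augment_orders(samples: list[CombinationSample]) -> list[CombinationSample]:
    """Emit every sample in both drug orders with identical targets."""
    out = []
    for s in samples:
        out.append(s)
        out.append(s.swapped())
    return out


@dataclass
class FoldAssignment:
    """A k-fold partition with per-iteration train/val/test roles.

    In iteration i, fold i is the test set, fold (i + 1) mod k the
    validation set, and the remaining k - 2 folds the training set; each
    sample is tested exactly once across the k iterations.
    """

    fold_id: np.ndarray
    k: int

    def roles(self, iteration: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not 0 <= iteration < self.k:
            raise ValueError(f"iteration must be in [0, {self.k})")
        test = np.flatnonzero(self.fold_id == iteration)
        val = np.flatnonzero(self.fold_id == (iteration + 1) % self.k)
        train = np.flatnonzero(~np.isin(self.fold_id, [iteration, (iteration + 1) % self.k]))
        return train, val, test


def make_folds(n: int, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Shuffle n samples into k near-equal folds (sizes differ by <= 1)."""
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        fold_id[chunk] = fold
    return FoldAssignment(fold_id=fold_id, k=k)


def _design_matrices(samples: list[CombinationSample], store: FeatureStore,
                     tasks) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    dx = np.stack([store.drug(s.drug_x) for s in samples])
    dy = np.stack([store.drug(s.drug_y) for s in samples])
    cr = np.stack([store.cell(s.cell_line) for s in samples])
    targets = {}
    for task in tasks:
        if task.kind == "regression":
            targets[task.name] = np.array([s.scores[task.name] for s in samples])
        elif task.name == "synergy":
            targets[task.name] = np.array([s.synergy_label for s in samples])
        else:
            targets[task.name] = np.array([s.ddi_label for s in samples])
    return dx, dy, cr, targets


def _symmetrized_outputs(model: SynergyMoE, dx, dy, cr, batch_size: int = 512,
                         ) -> dict[str, np.ndarray]:
    """Eval-mode forward averaged over both drug orders, in batches."""
    model.eval()
    n = dx.shape[0]
    chunks: dict[str, list[np.ndarray]] = {}
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        fwd = model.forward(dx[lo:hi], dy[lo:hi], cr[lo:hi])
        bwd = model.forward(dy[lo:hi], dx[lo:hi], cr[lo:hi])
        for name in fwd:
            avg = 0.5 * (fwd[name].data + bwd[name].data)
            chunks.setdefault(name, []).append(avg)
    return {name: np.concatenate(parts) for name, parts in chunks.items()}


def _np_total_loss(outputs: dict[str, np.ndarray], targets: dict[str, np.ndarray],
                   tasks, eps: float) -> float:
    """Batch-mean objective from raw (symmetrized) outputs, pure numpy."""
    total = 0.0
    for task in tasks:
        y = targets[task.name]
        out = outputs[task.name]
        if task.kind == "regression":
            total += task.loss_weight * float(np.mean((out.ravel() - y) ** 2))
        else:
            z = out - out.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            p = np.maximum(p, LOG_FLOOR)
            n, k = p.shape
            w = np.full((n, k), eps)
            w[np.arange(n), y.astype(int)] = 1.0 - eps
            total += task.loss_weight * float(-(w * np.log(p)).sum() / n)
    return total


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

class EarlyStopper:
    """Track the best validation loss; signal a stop after `patience` epochs
    without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = math.inf
        self.best_epoch = -1

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch; returns True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


def train_model(dataset: Dataset, model_config: ModelConfig,
                train_config: TrainConfig,
                split: tuple[np.ndarray, np.ndarray],
                verbose: bool = False) -> tuple[SynergyMoE, pd.DataFrame]:
    """Train on the given (train, val) index split.

    Mini-batches are drawn from the order-augmented training records with a
    fresh shuffle each epoch (reseeded from the master seed).  Validation
    loss uses un-augmented, order-averaged eval-mode predictions; the
    returned model carries the parameters of the best-validation epoch.
    """
    train_idx, val_idx = split
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation splits must be non-empty")
    same_split = (len(train_idx) == len(val_idx)
                  and np.array_equal(np.sort(train_idx), np.sort(val_idx)))
    if np.intersect1d(train_idx, val_idx).size and not same_split:
        # identical splits are allowed on purpose: a single-batch overfit run
        # monitors the very samples it trains on
        raise ValueError("train and validation splits overlap")

    tasks = model_config.tasks
    train_samples = augment_orders([dataset.samples[i] for i in train_idx])
    dx_tr, dy_tr, cr_tr, tg_tr = _design_matrices(train_samples, dataset.store, tasks)
    val_samples = [dataset.samples[i] for i in val_idx]
    dx_va, dy_va, cr_va, tg_va = _design_matrices(val_samples, dataset.store, tasks)

    model = SynergyMoE(model_config)
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    stopper = EarlyStopper(train_config.patience)
    n_train = dx_tr.shape[0]
    bs = train_config.batch_size
    history = []
    best_params: dict[str, np.ndarray] | None = None
    best_buffers: dict[str, np.ndarray] | None = None

    for epoch in range(train_config.max_epochs):
        model.train()
        rng = np.random.default_rng(
            np.random.SeedSequence((train_config.seed, epoch)))
        perm = rng.permutation(n_train)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n_train, bs):
            idx = perm[lo:lo + bs]
            outputs = model.forward(dx_tr[idx], dy_tr[idx], cr_tr[idx])
            loss = _batch_loss(outputs, {k: v[idx] for k, v in tg_tr.items()},
                               tasks, train_config.smoothing_eps)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1

        val_outputs = _symmetrized_outputs(model, dx_va, dy_va, cr_va)
        val_loss = _np_total_loss(val_outputs, tg_va, tasks,
                                  train_config.smoothing_eps)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                        "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:4d}  train {epoch_loss / n_batches:10.4f}  "
                  f"val {val_loss:10.4f}")
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_params = {k: p.data.copy() for k, p in model.named_parameters()}
            best_buffers = {k: b.copy() for k, b in model.named_buffers()}
        if stop:
            break

    # restore the best-validation parameters
    params = dict(model.named_parameters())
    for k, v in best_params.items():
        params[k].data = v
    from .network import _buffer_owners
    owners = _buffer_owners(model)
    for k, v in best_buffers.items():
        owner, attr = owners[k]
        setattr(owner, attr, v)
    model.eval()
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = stopper.best_epoch
    hist.attrs["best_val_loss"] = stopper.best_loss
    return model, hist


def predict_symmetrized(model: SynergyMoE, samples: list[CombinationSample],
                        store: FeatureStore) -> list[PredictionBundle]:
    """Order-averaged eval-mode predictions: mean of the <x, y> and <y, x>
    forward passes per task (probabilities averaged after softmax)."""
    dx, dy, cr, _ = _design_matrices(samples, store, model.config.tasks)
    fwd = model.predict_bundles(dx, dy, cr)
    bwd = model.predict_bundles(dy, dx, cr)
    bundles = []
    for a, b in zip(fwd, bwd):
        reg = {t: 0.5 * (a.regression[t] + b.regression[t]) for t in a.regression}
        cls = {t: (0.5 * (a.classification[t][0] + b.classification[t][0]),
                   0.5 * (a.classification[t][1] + b.classification[t][1]))
               for t in a.classification}
        bundles.append(PredictionBundle(regression=reg, classification=cls))
    return bundles


# --------------------------------------------------------------------------
# ablation / variant harness
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    name: str
    task_subset: tuple[str, ...]
    expert_kinds: tuple[str, ...] = ("dense", "bi_additive", "bi_interaction")
    share_one_gate: bool = False


_TASK_PRESETS: dict[str, VariantSpec] = {
    # task-transfer ablations; the synergy classification task is always kept
    "onlyDDS": VariantSpec("onlyDDS", ("synergy",)),
    "Loewe": VariantSpec("Loewe", ("loewe", "synergy")),
    "removeLoewe": VariantSpec("removeLoewe", ("zip", "bliss", "hsa", "s", "synergy")),
    "REG": VariantSpec("REG", ("loewe", "bliss", "zip", "hsa", "s", "synergy")),
    "DDI": VariantSpec("DDI", ("ddi", "synergy")),
    "full": VariantSpec("full", ("loewe", "bliss", "zip", "hsa", "s",
                                 "synergy", "ddi")),
    "onegate": VariantSpec("onegate", ("loewe", "bliss", "zip", "hsa", "s",
                                       "synergy", "ddi"), share_one_gate=True),
}
_TASK_PRESETS["nonLoewe"] = _TASK_PRESETS["removeLoewe"]

_EXPERT_NAME = {"DCE": "dense", "BAE": "bi_additive", "BIE": "bi_interaction"}

TOTAL_EXPERTS = 6  # the expert budget is fixed; it splits evenly across kinds


def _expert_counts(kinds: tuple[str, ...]) -> dict[str, int]:
    per = TOTAL_EXPERTS // len(kinds)
    return {k: per for k in kinds}


def build_variant(name: str, *, p_d: int = 541, p_c: int = 927,
                  expert_widths: tuple[int, ...] = (4096, 2048),
                  **config_overrides) -> tuple[ModelConfig, tuple[TaskSpec, ...]]:
    """Instantiate a named ablation preset.

    Task presets: onlyDDS, Loewe, removeLoewe (alias nonLoewe), REG, DDI,
    full, onegate.  Expert presets: DCE / BAE / BIE (six experts of one
    kind), pairwise combos like "DCE+BAE" (three each), and "all" (2+2+2).
    """
    all_tasks = {t.name: t for t in default_tasks()}
    if name in _TASK_PRESETS:
        spec = _TASK_PRESETS[name]
        kinds = spec.expert_kinds
        share = spec.share_one_gate
        task_names = spec.task_subset
    else:
        parts = name.replace(" ", "").split("+")
        if name == "all":
            kinds = ("dense", "bi_additive", "bi_interaction")
        elif all(p in _EXPERT_NAME for p in parts):
            kinds = tuple(_EXPERT_NAME[p] for p in parts)
        else:
            raise KeyError(
                f"unknown variant {name!r}; presets: "
                f"{sorted(_TASK_PRESETS) + sorted(_EXPERT_NAME) + ['all']} "
                "and '+'-joined expert combos")
        share = False
        task_names = tuple(t.name for t in default_tasks())
    tasks = tuple(all_tasks[t] for t in task_names)
    experts = default_experts(layer_widths=tuple(expert_widths),
                              counts=_expert_counts(kinds))
    cfg = ModelConfig(p_d=p_d, p_c=p_c, experts=experts, tasks=tasks,
                      share_one_gate=share, **config_overrides)
    return cfg, tasks


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def cross_validate(dataset: Dataset, model_config: ModelConfig,
                   train_config: TrainConfig, k: int = 5,
                   verbose: bool = False):
    """Five-fold protocol: per iteration 3 folds train, 1 validation (early
    stopping), 1 test; every sample is tested exactly once.  Returns
    (per-fold EvaluationReports, aggregate report, fold assignment)."""
    from .evaluation import aggregate_cv, evaluate_model

    folds = make_folds(len(dataset), k=k, seed=train_config.seed)
    reports = []
    for it in range(k):
        train_idx, val_idx, test_idx = folds.roles(it)
        model, _ = train_model(dataset, model_config, train_config,
                               (train_idx, val_idx), verbose=verbose)
        reports.append(evaluate_model(model, dataset, test_idx))
    return reports, aggregate_cv(reports), folds
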