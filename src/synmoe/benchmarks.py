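"""Desk-scale end-to-end benchmark protocols.

These runs exercise the full pipeline (cohort generation, training with
early stopping, order-averaged evaluation) at sizes chosen to finish in
minutes on one CPU:

* ``learning_sanity_run`` — a 2,000-sample cohort with low score noise and a
  reduced architecture (expert widths {64, 32}, latent d = 32).  The reduced
  runs use a learning rate of 1e-3: with ~5,000 optimizer steps available at
  this scale, the full-scale default of 1e-4 cannot traverse the parameter
  distance that tens of thousands of steps cover on the real cohort.
* ``overfit_run`` — an 8-sample, single-batch cohort that a small model must
  memorize; training and validation deliberately alias so early stopping
  monitors the fit itself.
"""

from __future__ import annotations

import numpy as np

from .data_model import REGRESSION_TASKS
from .evaluation import EvaluationReport, evaluate_model
from .network import ModelConfig, default_experts
from .synthetic import SimConfig, generate_dataset
from .training import TrainConfig, make_folds, train_model

LOW_NOISE = {t: 1.0 for t in REGRESSION_TASKS}


def learning_sanity_run(seed: int = 11):
    """Train the reduced model on a fresh synthetic cohort; returns
    (held-out EvaluationReport, history)."""
    sim = SimConfig(n_samples=2000, noise_sd=dict(LOW_NOISE),
                    replicate_prob=0.0, seed=seed)
    dataset = generate_dataset(sim)
    model_cfg = ModelConfig.reduced(seed=seed)
    train_cfg = TrainConfig(max_epochs=200, patience=100, learning_rate=1e-3,
                            seed=seed)
    folds = make_folds(len(dataset), k=5, seed=seed)
    train_idx, val_idx, test_idx = folds.roles(0)
    model, history = train_model(dataset, model_cfg, train_cfg,
                                 (train_idx, val_idx))
    report = evaluate_model(model, dataset, test_idx)
    return report, history


def overfit_run(seed: int = 7):
    """Memorize a single 8-sample batch; returns the training-loss history."""
    sim = SimConfig(n_drugs=12, n_cells=4, p_d=16, p_c=8, n_samples=8,
                    latent_dim=8, replicate_prob=0.0, seed=seed)
    dataset = generate_dataset(sim)
    model_cfg = ModelConfig(
        p_d=16, p_c=8, experts=default_experts(layer_widths=(16, 8)),
        gate_hidden=16, tower_widths=(8, 8), dropout_rate=0.0, seed=seed)
    train_cfg = TrainConfig(max_epochs=300, patience=50, learning_rate=3e-3,
                            batch_size=8, seed=seed)
    idx = np.arange(len(dataset))
    _, history = train_model(dataset, model_cfg, train_cfg, (idx, idx))
    return history
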