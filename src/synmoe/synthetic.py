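"""In-silico cohort generator.

Emulates the statistical structure of curated drug-combination screens:

* drugs and cell lines live in a low-dimensional latent space; observed
  descriptor/expression features are a noisy linear read-out of it,
* each of the five synergy scores is a symmetric function of the two drug
  embeddings and the cell embedding, built from a task-shared component
  (inducing positive cross-score correlation) plus a task-specific one,
* synergy scores are symmetric under drug swap, with score noise tied to the
  unordered (pair, cell, replicate) key so regeneration is reproducible,
* DDI labels are pair-level (cell-line independent),
* the Loewe-analog intercept is calibrated so that roughly 1 sample in 16 is
  synergistic at the labeling threshold, mirroring the ~1:15 class imbalance
  of the real cohort; the DDI positive rate defaults to ~7.3% for the same
  reason.

Every stream of randomness descends from one master seed through a
hierarchical ``SeedSequence``, so entities, score functions and sampling are
independently reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    REGRESSION_TASKS,
    CombinationSample,
    Dataset,
    FeatureStore,
    ValidationError,
    assign_synergy_label,
)

__all__ = ["SimConfig", "GroundTruth", "generate_entities",
           "generate_task_targets", "generate_dataset"]


def _default_shared() -> dict[str, float]:
    # the S score is the outlier, weakly tied to the others
    return {"loewe": 0.8, "bliss": 0.9, "zip": 0.85, "hsa": 0.9, "s": 0.3}


def _default_specific() -> dict[str, float]:
    return {"loewe": 0.4, "bliss": 0.3, "zip": 0.35, "hsa": 0.3, "s": 0.9}


def _default_noise() -> dict[str, float]:
    return {t: 3.0 for t in REGRESSION_TASKS}


@dataclass
class SimConfig:
    """Cohort-generation settings.

    Dimensions default to desk scale (p_d=64, p_c=32, latent_dim=8) so the
    full pipeline runs in seconds; the full-scale dims (541 descriptors, 927
    genes) are plain config options.
    """

    n_drugs: int = 60
    n_cells: int = 10
    p_d: int = 64
    p_c: int = 32
    n_samples: int = 4000
    latent_dim: int = 8
    task_shared_weight: dict[str, float] = field(default_factory=_default_shared)
    task_specific_weight: dict[str, float] = field(default_factory=_default_specific)
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    # score_scale sets the dispersion of the generated scores: with unit-ish
    # latent functions it yields sd ≈ 9, matching a cohort whose Loewe mean
    # is ≈ -9 when ~1/16 of samples clear the +5 synergy threshold
    score_scale: float = 5.0
    feature_noise_sd: float = 0.05
    synergy_threshold: float = 5.0
    target_positive_rate: float = 1.0 / 16.0
    ddi_positive_rate: float = 0.073
    replicate_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_cells", "p_d", "p_c", "n_samples", "latent_dim"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("target_positive_rate", "ddi_positive_rate"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.replicate_prob <= 1.0:
            raise ValidationError("replicate_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generative parameters behind a synthetic cohort."""

    drug_embeddings: dict[str, np.ndarray]
    cell_embeddings: dict[str, np.ndarray]
    task_functions: dict[str, dict[str, np.ndarray]]  # task -> coefficient vectors
    shared_function: dict[str, np.ndarray]
    intercepts: dict[str, float]
    ddi_pair_set: set[tuple[str, str]]
    noise_entropy: int  # root entropy of the per-triple noise stream

    def to_json(self) -> str:
        def enc(d):
            return {k: np.asarray(v).tolist() for k, v in d.items()}
        return json.dumps({
            "drug_embeddings": enc(self.drug_embeddings),
            "cell_embeddings": enc(self.cell_embeddings),
            "task_functions": {t: enc(f) for t, f in self.task_functions.items()},
            "shared_function": enc(self.shared_function),
            "intercepts": self.intercepts,
            "ddi_pairs": sorted(map(list, self.ddi_pair_set)),
            "noise_entropy": self.noise_entropy,
        }, indent=1)


def _drug_id(i: int) -> str:
    return f"drug_{i:04d}"


def _cell_id(i: int) -> str:
    return f"cell_{i:03d}"


def _function_coeffs(rng: np.random.Generator, latent_dim: int) -> dict[str, np.ndarray]:
    scale = 1.0 / np.sqrt(latent_dim)
    return {
        "u": rng.normal(0.0, scale, latent_dim),  # weights on ex * ey
        "v": rng.normal(0.0, scale, latent_dim),  # weights on ex + ey
        "w": rng.normal(0.0, scale, latent_dim),  # weights on (ex + ey) * ec
    }


def _symmetric_value(coeffs: dict[str, np.ndarray], ex, ey, ec) -> np.ndarray:
    """u.(ex*ey) + v.(ex+ey) + w.((ex+ey)*ec) — symmetric in (ex, ey)."""
    s = ex + ey
    return (ex * ey) @ coeffs["u"] + s @ coeffs["v"] + (s * ec) @ coeffs["w"]


def generate_entities(config: SimConfig) -> tuple[FeatureStore, GroundTruth]:
    """Draw latent embeddings, feature read-outs, score functions, DDI pairs."""
    root = np.random.SeedSequence(config.seed)
    ent_seq, fn_seq, ddi_seq, noise_seq = root.spawn(4)
    rng = np.random.default_rng(ent_seq)
    L = config.latent_dim

    drug_emb = rng.standard_normal((config.n_drugs, L))
    cell_emb = rng.standard_normal((config.n_cells, L))
    A_d = rng.normal(0.0, 1.0 / np.sqrt(L), (L, config.p_d))
    A_c = rng.normal(0.0, 1.0 / np.sqrt(L), (L, config.p_c))
    drug_feat = drug_emb @ A_d + config.feature_noise_sd * rng.standard_normal(
        (config.n_drugs, config.p_d))
    cell_feat = cell_emb @ A_c + config.feature_noise_sd * rng.standard_normal(
        (config.n_cells, config.p_c))

    store = FeatureStore(
        drug_features={_drug_id(i): drug_feat[i] for i in range(config.n_drugs)},
        cell_features={_cell_id(i): cell_feat[i] for i in range(config.n_cells)},
    )

    fn_rng = np.random.default_rng(fn_seq)
    shared = _function_coeffs(fn_rng, L)
    task_fns = {t: _function_coeffs(fn_rng, L) for t in REGRESSION_TASKS}

    # adverse interactions are chemistry-driven, not random: a pair is adverse
    # when a symmetric latent interaction score lands in the top fraction
    # (ddi_positive_rate) over all pairs, so the label is learnable from the
    # drug features, pair-level, and cell-line independent
    ddi_rng = np.random.default_rng(ddi_seq)
    ddi_coeffs = _function_coeffs(ddi_rng, L)
    pair_idx = list(itertools.combinations(range(config.n_drugs), 2))
    pair_scores = np.array([
        float((drug_emb[i] * drug_emb[j]) @ ddi_coeffs["u"]
              + (drug_emb[i] + drug_emb[j]) @ ddi_coeffs["v"])
        for i, j in pair_idx])
    cut = np.quantile(pair_scores, 1.0 - config.ddi_positive_rate)
    ddi_pairs = {
        (_drug_id(i), _drug_id(j))
        for (i, j), s in zip(pair_idx, pair_scores) if s > cut
    }

    truth = GroundTruth(
        drug_embeddings={_drug_id(i): drug_emb[i] for i in range(config.n_drugs)},
        cell_embeddings={_cell_id(i): cell_emb[i] for i in range(config.n_cells)},
        task_functions=task_fns,
        shared_function=shared,
        intercepts={t: 0.0 for t in REGRESSION_TASKS},
        ddi_pair_set=ddi_pairs,
        noise_entropy=int(noise_seq.generate_state(1, np.uint32)[0]),
    )
    return store, truth


def _triple_noise(truth: GroundTruth, x: str, y: str, c: str,
                  config: SimConfig, replicate: int) -> dict[str, float]:
    """Score noise keyed to the unordered (pair, cell, replicate) triple."""
    lo, hi = sorted((x, y))
    key = (truth.noise_entropy,
           int(lo.rsplit("_", 1)[1]), int(hi.rsplit("_", 1)[1]),
           int(c.rsplit("_", 1)[1]), replicate)
    rng = np.random.default_rng(np.random.SeedSequence(key))
    draws = rng.standard_normal(len(REGRESSION_TASKS))
    return {t: float(config.noise_sd[t] * draws[i])
            for i, t in enumerate(REGRESSION_TASKS)}


def generate_task_targets(x: str, y: str, c: str, truth: GroundTruth,
                          config: SimConfig, replicate: int = 0) -> dict[str, float]:
    """Five synergy-score analogs for one (drug x, drug y, cell line) triple.

    score_t = intercept_t + scale * (shared_w_t * f + specific_w_t * g_t) + noise_t
    with f and g_t symmetric in the two drug embeddings; swapping the drugs
    reproduces the identical scores, noise included.
    """
    try:
        ex, ey = truth.drug_embeddings[x], truth.drug_embeddings[y]
        ec = truth.cell_embeddings[c]
    except KeyError as exc:
        raise KeyError(f"id not in ground truth: {exc.args[0]!r}") from None
    f = _symmetric_value(truth.shared_function, ex, ey, ec)
    noise = _triple_noise(truth, x, y, c, config, replicate)
    out = {}
    for t in REGRESSION_TASKS:
        g = _symmetric_value(truth.task_functions[t], ex, ey, ec)
        out[t] = float(truth.intercepts[t]
                       + config.score_scale * (config.task_shared_weight[t] * f
                                               + config.task_specific_weight[t] * g)
                       + noise[t])
    return out


def generate_dataset(config: SimConfig) -> Dataset:
    """Draw a full cohort; ``dataset.truth`` carries the generative parameters.

    Triples are sampled without replacement over (unordered pair, cell line);
    a replicate row with independent noise is appended with probability
    ``replicate_prob`` per triple.  Before labeling, the Loewe-analog
    intercept is shifted so the fraction of base rows above the synergy
    threshold approximates ``target_positive_rate``.
    """
    store, truth = generate_entities(config)
    pairs = list(itertools.combinations(range(config.n_drugs), 2))
    capacity = len(pairs) * config.n_cells
    if config.n_samples > capacity:
        raise ValidationError(
            f"n_samples={config.n_samples} exceeds the {capacity} distinct "
            "(pair, cell) triples; increase n_drugs or n_cells")
    sample_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 2 ** 20 + 7)))
    chosen = sample_rng.choice(capacity, size=config.n_samples, replace=False)
    triples = [(pairs[k // config.n_cells], k % config.n_cells) for k in chosen]

    base_scores = []
    for (i, j), ci in triples:
        base_scores.append(generate_task_targets(
            _drug_id(i), _drug_id(j), _cell_id(ci), truth, config, replicate=0))

    # calibrate the Loewe-analog intercept to the target positive rate
    raw_loewe = np.array([s["loewe"] for s in base_scores])
    q = float(np.quantile(raw_loewe, 1.0 - config.target_positive_rate))
    truth.intercepts["loewe"] = config.synergy_threshold - q
    for s in base_scores:
        s["loewe"] += truth.intercepts["loewe"]

    replicate_draws = sample_rng.random(config.n_samples)
    samples: list[CombinationSample] = []
    for idx, ((i, j), ci) in enumerate(triples):
        x, y, c = _drug_id(i), _drug_id(j), _cell_id(ci)
        ddi = int((x, y) in truth.ddi_pair_set)
        rows = [base_scores[idx]]
        if replicate_draws[idx] < config.replicate_prob:
            rows.append(generate_task_targets(x, y, c, truth, config, replicate=1))
        for scores in rows:
            samples.append(CombinationSample(
                drug_x=x, drug_y=y, cell_line=c, scores=dict(scores),
                synergy_label=assign_synergy_label(scores["loewe"],
                                                   config.synergy_threshold),
                ddi_label=ddi))
    return Dataset(samples=samples, store=store, truth=truth)
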