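"""The multi-task mixture-of-experts computation graph.

Three components:

* **Hybrid ensemble layer** — M expert subnetworks of three kinds, each
  mapping the raw (dx, dy, cr) features to a shared d-dimensional latent:

  - *dense*: two layers on the concatenation [dx, dy, cr],
  - *bi-additive*: two two-layer towers on [dx, cr] and [dy, cr], summed
    elementwise ("or"-style interaction),
  - *bi-interaction*: the same double tower, but the tower outputs a and b
    are combined as Layer_add(a + b) + Layer_prod(a ⊙ b), borrowing the
    bi-interaction pooling of neural factorization machines ("and"-style).

* **Task-specific fusion layer** — one gating network per task (or a single
  shared gate) producing softmax weights over the M expert latents; the
  fused representation is the weighted sum.

* **Prediction layer** — per-task towers: two layers plus a final linear
  map; regression towers emit one value, classification towers two logits
  whose softmax is the (negative, positive) probability pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, concat
from .data_model import REGRESSION_TASKS, CLASSIFICATION_TASKS
from .nn import Linear, MLPLayer, Module, softmax

EXPERT_KINDS = ("dense", "bi_additive", "bi_interaction")


@dataclass(frozen=True)
class LayerSpec:
    width: int
    use_activation: bool = True
    use_batchnorm: bool = True
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("layer width must be positive")


@dataclass(frozen=True)
class ExpertSpec:
    kind: str
    layer_widths: tuple[int, ...] = (4096, 2048)

    def __post_init__(self):
        if self.kind not in EXPERT_KINDS:
            raise ValueError(f"unknown expert kind {self.kind!r}; choices: {EXPERT_KINDS}")

    @property
    def output_dim(self) -> int:
        return self.layer_widths[-1]


@dataclass(frozen=True)
class TaskSpec:
    name: str
    kind: str  # "regression" | "classification"
    loss_weight: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.kind not in ("regression", "classification"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.loss_weight is None:
            # regression losses weigh 1, classification 10: class probabilities
            # live on [0,1] while synergy scores span tens of units
            object.__setattr__(self, "loss_weight",
                               10.0 if self.kind == "classification" else 1.0)


def default_tasks() -> tuple[TaskSpec, ...]:
    return tuple([TaskSpec(t, "regression") for t in REGRESSION_TASKS]
                 + [TaskSpec(t, "classification") for t in CLASSIFICATION_TASKS])


def default_experts(layer_widths: tuple[int, ...] = (4096, 2048),
                    counts: dict[str, int] | None = None) -> tuple[ExpertSpec, ...]:
    counts = counts or {k: 2 for k in EXPERT_KINDS}
    return tuple(ExpertSpec(kind, tuple(layer_widths))
                 for kind in EXPERT_KINDS for _ in range(counts.get(kind, 0)))


@dataclass
class ModelConfig:
    """Full architecture description; serializable into checkpoints."""

    p_d: int = 541
    p_c: int = 927
    experts: tuple[ExpertSpec, ...] = field(default_factory=default_experts)
    tasks: tuple[TaskSpec, ...] = field(default_factory=default_tasks)
    gate_hidden: int = 4096
    tower_widths: tuple[int, ...] = (2048, 2048)
    dropout_rate: float = 0.5
    share_one_gate: bool = False
    norm_before_activation: bool = False
    seed: int = 0

    def __post_init__(self):
        self.experts = tuple(e if isinstance(e, ExpertSpec) else ExpertSpec(**e)
                             for e in self.experts)
        self.tasks = tuple(t if isinstance(t, TaskSpec) else TaskSpec(**t)
                           for t in self.tasks)
        if not self.experts:
            raise ValueError("need at least one expert")
        if not self.tasks:
            raise ValueError("need at least one task")
        names = [t.name for t in self.tasks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate task names: {names}")
        dims = {e.output_dim for e in self.experts}
        if len(dims) > 1:
            raise ValueError(f"experts must share one output dim, got {sorted(dims)}")

    @property
    def n_experts(self) -> int:
        return len(self.experts)

    @property
    def latent_dim(self) -> int:
        return self.experts[0].output_dim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["experts"] = [asdict(e) for e in self.experts]
        d["tasks"] = [asdict(t) for t in self.tasks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["experts"] = tuple(ExpertSpec(kind=e["kind"],
                                        layer_widths=tuple(e["layer_widths"]))
                             for e in d["experts"])
        d["tasks"] = tuple(TaskSpec(**t) for t in d["tasks"])
        d["tower_widths"] = tuple(d["tower_widths"])
        return cls(**d)

    @classmethod
    def reduced(cls, p_d: int = 64, p_c: int = 32, **overrides) -> "ModelConfig":
        """Desk-scale preset: expert widths {64, 32}, d=32, narrow gates/towers."""
        defaults = dict(
            p_d=p_d, p_c=p_c,
            experts=default_experts(layer_widths=(64, 32)),
            gate_hidden=64, tower_widths=(32, 32), dropout_rate=0.1,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PredictionBundle:
    """Per-sample outputs: synergy-score predictions and class probabilities."""

    regression: dict[str, float]
    classification: dict[str, tuple[float, float]]  # (p_negative, p_positive)

    def __post_init__(self):
        for name, (p0, p1) in self.classification.items():
            if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
                raise ValueError(f"{name}: probabilities outside [0, 1]")
            if abs(p0 + p1 - 1.0) > 1e-6:
                raise ValueError(f"{name}: probability pair does not sum to 1")


def _two_layer_stack(n_in: int, widths: tuple[int, ...], rng, cfg: ModelConfig,
                     ) -> list[MLPLayer]:
    layers = []
    for w in widths:
        layers.append(MLPLayer(n_in, w, rng, dropout_rate=cfg.dropout_rate,
                               norm_before_activation=cfg.norm_before_activation))
        n_in = w
    return layers


def _run_stack(layers: list[MLPLayer], x: Tensor) -> Tensor:
    for layer in layers:
        x = layer(x)
    return x


class DenseExpert(Module):
    """Two layers on the concatenation [dx, dy, cr]."""

    def __init__(self, spec: ExpertSpec, cfg: ModelConfig, rng):
        super().__init__()
        self.layers = _two_layer_stack(2 * cfg.p_d + cfg.p_c, spec.layer_widths, rng, cfg)

    def forward(self, dx, dy, cr):
        return _run_stack(self.layers, concat([dx, dy, cr], axis=1))


class BiAdditiveExpert(Module):
    """Tower_x([dx, cr]) + Tower_y([dy, cr]), summed elementwise."""

    def __init__(self, spec: ExpertSpec, cfg: ModelConfig, rng):
        super().__init__()
        n_in = cfg.p_d + cfg.p_c
        self.tower_x = _two_layer_stack(n_in, spec.layer_widths, rng, cfg)
        self.tower_y = _two_layer_stack(n_in, spec.layer_widths, rng, cfg)

    def forward(self, dx, dy, cr):
        a = _run_stack(self.tower_x, concat([dx, cr], axis=1))
        b = _run_stack(self.tower_y, concat([dy, cr], axis=1))
        return a + b


class BiInteractionExpert(Module):
    """Layer_add(a + b) + Layer_prod(a ⊙ b) over the two tower outputs."""

    def __init__(self, spec: ExpertSpec, cfg: ModelConfig, rng):
        super().__init__()
        n_in = cfg.p_d + cfg.p_c
        d = spec.output_dim
        self.tower_x = _two_layer_stack(n_in, spec.layer_widths, rng, cfg)
        self.tower_y = _two_layer_stack(n_in, spec.layer_widths, rng, cfg)
        self.layer_add = MLPLayer(d, d, rng, dropout_rate=cfg.dropout_rate,
                                  norm_before_activation=cfg.norm_before_activation)
        self.layer_prod = MLPLayer(d, d, rng, dropout_rate=cfg.dropout_rate,
                                   norm_before_activation=cfg.norm_before_activation)

    def forward(self, dx, dy, cr):
        a = _run_stack(self.tower_x, concat([dx, cr], axis=1))
        b = _run_stack(self.tower_y, concat([dy, cr], axis=1))
        return self.layer_add(a + b) + self.layer_prod(a * b)


_EXPERT_CLASSES = {"dense": DenseExpert, "bi_additive": BiAdditiveExpert,
                   "bi_interaction": BiInteractionExpert}


class GateNetwork(Module):
    """Two-layer gate on [dx, dy, cr] with a softmax over the M experts.

    Gate layers are plain affine+ReLU — no dropout or batch norm — keeping
    the fusion weights noise-free.
    """

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.lin1 = Linear(2 * cfg.p_d + cfg.p_c, cfg.gate_hidden, rng)
        self.lin2 = Linear(cfg.gate_hidden, cfg.n_experts, rng)

    def forward(self, dx, dy, cr) -> Tensor:
        h = self.lin1(concat([dx, dy, cr], axis=1)).relu()
        return softmax(self.lin2(h), axis=1)


class PredictionTower(Module):
    """Two layers then a final plain linear map (1 output for regression,
    2 logits for classification)."""

    def __init__(self, task: TaskSpec, cfg: ModelConfig, rng):
        super().__init__()
        self.task = task
        self.layers = _two_layer_stack(cfg.latent_dim, cfg.tower_widths, rng, cfg)
        out_dim = 1 if task.kind == "regression" else 2
        self.head = Linear(cfg.tower_widths[-1], out_dim, rng)

    def forward(self, fused: Tensor) -> Tensor:
        return self.head(_run_stack(self.layers, fused))


def fuse(latents: list[Tensor], weights: Tensor) -> Tensor:
    """Weighted sum of the M expert latents; weights has shape (batch, M)."""
    if weights.data.shape[1] != len(latents):
        raise ValueError(
            f"got {len(latents)} latents but {weights.data.shape[1]} weights")
    d = latents[0].data.shape[1]
    for k, lat in enumerate(latents):
        if lat.data.shape[1] != d:
            raise ValueError(f"latent {k} has width {lat.data.shape[1]}, expected {d}")
    # column selection via one-hot matmul keeps the graph simple and exact
    total = None
    for k, lat in enumerate(latents):
        sel = np.zeros((len(latents), 1))
        sel[k, 0] = 1.0
        wk = weights @ Tensor(sel)  # (batch, 1)
        term = lat * wk
        total = term if total is None else total + term
    return total


class SynergyMoE(Module):
    """The full model: experts, per-task gates, per-task towers."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self.experts = [
            _EXPERT_CLASSES[spec.kind](spec, config, rng) for spec in config.experts
        ]
        # gates are kept in a list (unique modules) with a name index so that
        # a shared gate is registered — and optimized — exactly once
        if config.share_one_gate:
            self.gate_modules = [GateNetwork(config, rng)]
            self._gate_index = {t.name: 0 for t in config.tasks}
        else:
            self.gate_modules = [GateNetwork(config, rng) for _ in config.tasks]
            self._gate_index = {t.name: i for i, t in enumerate(config.tasks)}
        self.towers = {t.name: PredictionTower(t, config, rng) for t in config.tasks}

    # -- pieces exposed for inspection and tests --------------------------------
    def expert_latents(self, dx: Tensor, dy: Tensor, cr: Tensor) -> list[Tensor]:
        self._check_dims(dx, dy, cr)
        latents = [e(dx, dy, cr) for e in self.experts]
        d = self.config.latent_dim
        for k, lat in enumerate(latents):
            if lat.data.shape[1] != d:
                raise ValueError(f"expert {k} produced width {lat.data.shape[1]}, "
                                 f"expected {d}")
        return latents

    def gate_weights(self, task: str, dx: Tensor, dy: Tensor, cr: Tensor) -> Tensor:
        try:
            gate = self.gate_modules[self._gate_index[task]]
        except KeyError:
            raise KeyError(f"unknown task {task!r}; registered: "
                           f"{sorted(self._gate_index)}") from None
        return gate(dx, dy, cr)

    def _check_dims(self, dx, dy, cr):
        if dx.data.shape[1] != self.config.p_d or dy.data.shape[1] != self.config.p_d:
            raise ValueError(f"drug features must have width {self.config.p_d}")
        if cr.data.shape[1] != self.config.p_c:
            raise ValueError(f"cell features must have width {self.config.p_c}")

    # -- forward -----------------------------------------------------------------
    def forward(self, dx, dy, cr) -> dict[str, Tensor]:
        """Batch forward pass.

        Returns a map task name -> Tensor: shape (batch, 1) for regression,
        (batch, 2) logits for classification.
        """
        dx, dy, cr = Tensor._lift(dx), Tensor._lift(dy), Tensor._lift(cr)
        latents = self.expert_latents(dx, dy, cr)
        out = {}
        for task in self.config.tasks:
            w = self.gate_weights(task.name, dx, dy, cr)
            fused = fuse(latents, w)
            out[task.name] = self.towers[task.name](fused)
        return out

    def predict_bundles(self, dx: np.ndarray, dy: np.ndarray, cr: np.ndarray,
                        ) -> list[PredictionBundle]:
        """Eval-mode prediction for a batch of raw feature rows."""
        was_training = self.training
        self.eval()
        try:
            raw = self.forward(dx, dy, cr)
        finally:
            self.train(was_training)
        n = np.atleast_2d(dx).shape[0]
        bundles = []
        for i in range(n):
            reg, cls = {}, {}
            for task in self.config.tasks:
                if task.kind == "regression":
                    reg[task.name] = float(raw[task.name].data[i, 0])
                else:
                    z = raw[task.name].data[i]
                    z = z - z.max()
                    p = np.exp(z) / np.exp(z).sum()
                    cls[task.name] = (float(p[0]), float(p[1]))
            bundles.append(PredictionBundle(regression=reg, classification=cls))
        return bundles


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(model: SynergyMoE, path) -> None:
    """Single-archive checkpoint: parameters and buffers keyed by module
    path, with the model config embedded as JSON.  Reload is bit-exact."""
    arrays = {f"param/{k}": p.data for k, p in model.named_parameters()}
    arrays.update({f"buffer/{k}": b for k, b in model.named_buffers()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> SynergyMoE:
    with np.load(path) as archive:
        cfg = ModelConfig.from_dict(
            json.loads(archive["config_json"].tobytes().decode()))
        model = SynergyMoE(cfg)
        params = dict(model.named_parameters())
        for key in archive.files:
            if key.startswith("param/"):
                params[key[len("param/"):]].data = archive[key].copy()
        buffer_owners = _buffer_owners(model)
        for key in archive.files:
            if key.startswith("buffer/"):
                name = key[len("buffer/"):]
                owner, attr = buffer_owners[name]
                setattr(owner, attr, archive[key].copy())
    model.eval()
    return model


def _buffer_owners(module: Module, prefix: str = "") -> dict[str, tuple[Module, str]]:
    out = {}
    for name, value in vars(module).items():
        if isinstance(value, np.ndarray):
            out[f"{prefix}{name}"] = (module, name)
    for name, child in module._children():
        out.update(_buffer_owners(child, f"{prefix}{name}."))
    return out
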