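import numpy as np
import pytest

from synmoe.network import ModelConfig, SynergyMoE, default_experts
from synmoe.synthetic import SimConfig, generate_dataset

TINY_REG_NOISE = {t: 1.0 for t in ("loewe", "bliss", "zip", "hsa", "s")}


def tiny_model_config(**overrides) -> ModelConfig:
    defaults = dict(
        p_d=6, p_c=4,
        experts=default_experts(layer_widths=(8, 5)),
        gate_hidden=7, tower_widths=(6, 6), dropout_rate=0.5, seed=0,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture
def tiny_model() -> SynergyMoE:
    return SynergyMoE(tiny_model_config()).eval()


@pytest.fixture
def tiny_inputs():
    rng = np.random.default_rng(42)
    return (rng.normal(size=(3, 6)), rng.normal(size=(3, 6)),
            rng.normal(size=(3, 4)))


@pytest.fixture(scope="session")
def small_dataset():
    """~150-sample cohort for protocol tests: fast but structurally complete."""
    config = SimConfig(n_drugs=14, n_cells=4, p_d=10, p_c=6, n_samples=150,
                       latent_dim=4, replicate_prob=0.2, seed=123)
    return generate_dataset(config)


def random_small_model(rng: np.random.Generator) -> tuple[SynergyMoE, int]:
    """A random compact architecture for oracle-equivalence sweeps."""
    from synmoe.network import EXPERT_KINDS, ExpertSpec, TaskSpec

    p_d = int(rng.integers(2, 7))
    p_c = int(rng.integers(2, 6))
    d = int(rng.integers(2, 9))
    w1 = int(rng.integers(d, 17))
    experts = tuple(
        ExpertSpec(str(rng.choice(EXPERT_KINDS)), (w1, d))
        for _ in range(int(rng.integers(1, 5)))
    )
    names = ["loewe", "s", "synergy", "ddi"]
    kinds = ["regression", "regression", "classification", "classification"]
    n_tasks = int(rng.integers(1, 5))
    tasks = tuple(TaskSpec(n, k) for n, k in zip(names[:n_tasks], kinds[:n_tasks]))
    cfg = ModelConfig(
        p_d=p_d, p_c=p_c, experts=experts, tasks=tasks,
        gate_hidden=int(rng.integers(2, 9)),
        tower_widths=(int(rng.integers(2, 9)), int(rng.integers(2, 9))),
        dropout_rate=float(rng.choice([0.0, 0.3, 0.5])),
        share_one_gate=bool(rng.random() < 0.2),
        norm_before_activation=bool(rng.random() < 0.2),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    batch = int(rng.integers(1, 5))
    model = SynergyMoE(cfg)
    # randomize running statistics so eval-mode batch norm is non-trivial
    for _, buf in model.named_buffers():
        if buf.min() >= 0 and np.all(buf == 1.0):  # running_var
            buf += rng.random(buf.shape)
        else:
            buf += rng.normal(size=buf.shape) * 0.5
    return model.eval(), batch
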