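"""Independent step-by-step recomputation of the network's forward pass.

These helpers read raw parameter arrays off a model and rebuild every
operation with plain numpy, sharing no code path with the autodiff engine.
They cover eval mode (running statistics, no dropout), which is the
deterministic contract the model must satisfy.
"""

import numpy as np


def linear(lin, x):
    return x @ lin.W.data + lin.b.data


def batchnorm_eval(bn, h):
    xhat = (h - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
    return xhat * bn.gamma.data + bn.beta.data


def batchnorm_train(bn, h):
    mu = h.mean(axis=0)
    var = ((h - mu) ** 2).mean(axis=0)
    xhat = (h - mu) / np.sqrt(var + bn.eps)
    return xhat * bn.gamma.data + bn.beta.data


def mlp_layer(layer, x, mode="eval"):
    h = linear(layer.linear, x)
    bn = (batchnorm_eval if mode == "eval" else batchnorm_train)
    if layer.norm_before_activation:
        if layer.bn is not None:
            h = bn(layer.bn, h)
        if layer.use_activation:
            h = np.maximum(h, 0.0)
    else:
        if layer.use_activation:
            h = np.maximum(h, 0.0)
        if layer.bn is not None:
            h = bn(layer.bn, h)
    return h  # dropout is identity in eval mode


def stack(layers, x, mode="eval"):
    for layer in layers:
        x = mlp_layer(layer, x, mode)
    return x


def expert(exp, dx, dy, cr):
    kind = type(exp).__name__
    if kind == "DenseExpert":
        return stack(exp.layers, np.concatenate([dx, dy, cr], axis=1))
    a = stack(exp.tower_x, np.concatenate([dx, cr], axis=1))
    b = stack(exp.tower_y, np.concatenate([dy, cr], axis=1))
    if kind == "BiAdditiveExpert":
        return a + b
    if kind == "BiInteractionExpert":
        return mlp_layer(exp.layer_add, a + b) + mlp_layer(exp.layer_prod, a * b)
    raise AssertionError(f"unknown expert class {kind}")


def softmax(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def gate(g, dx, dy, cr):
    h = np.maximum(linear(g.lin1, np.concatenate([dx, dy, cr], axis=1)), 0.0)
    return softmax(linear(g.lin2, h))


def tower(t, fused):
    return linear(t.head, stack(t.layers, fused))


def forward(model, dx, dy, cr):
    """Full eval-mode forward pass, recomputed independently."""
    latents = [expert(e, dx, dy, cr) for e in model.experts]
    out = {}
    for task in model.config.tasks:
        w = gate(model.gate_modules[model._gate_index[task.name]], dx, dy, cr)
        fused = sum(w[:, k:k + 1] * latents[k] for k in range(len(latents)))
        out[task.name] = tower(model.towers[task.name], fused)
    return out
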