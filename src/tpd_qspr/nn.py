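"""Numpy implementation of the multi-task message-passing network.

The regressor is a directed-bond message-passing encoder (messages live on
directed bonds; a bond's update aggregates messages entering its source
atom, excluding its own reverse) followed by mean aggregation of atom
vectors into a molecular vector and a feed-forward multi-output head. ReLU
activations throughout. Training minimizes a masked mean-squared error in
which unobserved labels contribute neither loss nor gradient.

Forward and backward passes are written directly in numpy: parameters are a
flat dict of arrays, the backward pass mirrors the forward pass with
scatter/gather adjoints, and optimization is Adam under a linear-warmup /
exponential-decay learning-rate schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .graphs import BatchedGraph

Params = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Masked multi-task loss
# ---------------------------------------------------------------------------

def masked_mt_loss(preds: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over observed (mask-true) cells only.

    The gradient with respect to any masked prediction is exactly zero; an
    all-false mask yields loss 0.
    """
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if preds.shape != labels.shape or preds.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: preds {preds.shape}, labels {labels.shape}, mask {mask.shape}"
        )
    n_obs = int(mask.sum())
    if n_obs == 0:
        return 0.0
    diff = np.where(mask, preds - labels, 0.0)
    return float((diff * diff).sum() / n_obs)


def masked_mt_loss_grad(preds: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """d(masked_mt_loss)/d(preds); zero at masked cells."""
    mask = np.asarray(mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        return np.zeros_like(np.asarray(preds, dtype=np.float64))
    diff = np.where(mask, np.asarray(preds, float) - np.asarray(labels, float), 0.0)
    return 2.0 * diff / n_obs


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


def init_params(
    atom_dim: int,
    bond_dim: int,
    hidden: int,
    ffn_layers: int,
    n_tasks: int,
    rng: np.random.Generator,
) -> Params:
    p: Params = {
        "Wi": _glorot(rng, atom_dim + bond_dim, hidden),
        "bi": np.zeros(hidden, dtype=np.float32),
        "Wh": _glorot(rng, hidden, hidden),
        "bh": np.zeros(hidden, dtype=np.float32),
        "Wo": _glorot(rng, atom_dim + hidden, hidden),
        "bo": np.zeros(hidden, dtype=np.float32),
    }
    for k in range(ffn_layers):
        p[f"F{k}_W"] = _glorot(rng, hidden, hidden)
        p[f"F{k}_b"] = np.zeros(hidden, dtype=np.float32)
    p["Out_W"] = _glorot(rng, hidden, n_tasks)
    p["Out_b"] = np.zeros(n_tasks, dtype=np.float32)
    return p


def n_ffn_layers(params: Params) -> int:
    return sum(1 for k in params if k.endswith("_W") and k.startswith("F"))


def clone_params(params: Params) -> Params:
    return {k: v.copy() for k, v in params.items()}


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def _scatter_add(values: np.ndarray, index: np.ndarray, n_rows: int) -> np.ndarray:
    out = np.zeros((n_rows, values.shape[1]), dtype=values.dtype)
    np.add.at(out, index, values)
    return out


def forward(
    batch: BatchedGraph,
    params: Params,
    depth: int,
    want_cache: bool = False,
):
    """Run the encoder+head; returns (output (n_mols, n_tasks), cache)."""
    xa = batch.atom_features
    xb = batch.bond_features
    n_atoms = xa.shape[0]
    in0 = np.concatenate([xa[batch.src], xb], axis=1) if xb.shape[0] else \
        np.zeros((0, xa.shape[1] + xb.shape[1]), dtype=np.float32)
    z0 = in0 @ params["Wi"] + params["bi"]
    h = np.maximum(z0, 0.0)

    ms, zs, hs = [], [], [h]
    for _ in range(1, depth):
        a = _scatter_add(h, batch.dst, n_atoms)
        m = a[batch.src] - h[batch.rev]
        z = z0 + m @ params["Wh"] + params["bh"]
        h = np.maximum(z, 0.0)
        ms.append(m)
        zs.append(z)
        hs.append(h)

    a_fin = _scatter_add(h, batch.dst, n_atoms)
    cat_o = np.concatenate([xa, a_fin], axis=1)
    zo = cat_o @ params["Wo"] + params["bo"]
    ho = np.maximum(zo, 0.0)

    counts = batch.atoms_per_mol.astype(np.float32)
    mol = np.zeros((batch.n_mols, ho.shape[1]), dtype=ho.dtype)
    np.add.at(mol, batch.mol_index, ho)
    mol /= counts[:, None]

    acts = [mol]
    zf_list = []
    x = mol
    for k in range(n_ffn_layers(params)):
        zf = x @ params[f"F{k}_W"] + params[f"F{k}_b"]
        x = np.maximum(zf, 0.0)
        zf_list.append(zf)
        acts.append(x)
    out = x @ params["Out_W"] + params["Out_b"]

    cache = None
    if want_cache:
        cache = {
            "in0": in0, "z0": z0, "ms": ms, "zs": zs, "hs": hs,
            "cat_o": cat_o, "zo": zo, "ho": ho, "counts": counts,
            "acts": acts, "zf_list": zf_list, "batch": batch, "depth": depth,
        }
    return out.astype(np.float64), cache


def backward(dout: np.ndarray, params: Params, cache: Mapping) -> Params:
    """Adjoint of :func:`forward`; returns gradients keyed like params."""
    batch: BatchedGraph = cache["batch"]
    depth = cache["depth"]
    grads: Params = {}
    dout = dout.astype(params["Out_W"].dtype)

    # head
    x_last = cache["acts"][-1]
    grads["Out_W"] = x_last.T @ dout
    grads["Out_b"] = dout.sum(axis=0)
    dx = dout @ params["Out_W"].T
    for k in range(n_ffn_layers(params) - 1, -1, -1):
        dzf = dx * (cache["zf_list"][k] > 0)
        grads[f"F{k}_W"] = cache["acts"][k].T @ dzf
        grads[f"F{k}_b"] = dzf.sum(axis=0)
        dx = dzf @ params[f"F{k}_W"].T

    # mean aggregation
    dho = dx[batch.mol_index] / cache["counts"][batch.mol_index][:, None]
    dzo = dho * (cache["zo"] > 0)
    grads["Wo"] = cache["cat_o"].T @ dzo
    grads["bo"] = dzo.sum(axis=0)
    dcat_o = dzo @ params["Wo"].T
    da_fin = dcat_o[:, batch.atom_features.shape[1]:]

    # final bond->atom scatter
    dh = da_fin[batch.dst]

    grads["Wh"] = np.zeros_like(params["Wh"])
    grads["bh"] = np.zeros_like(params["bh"])
    n_atoms = batch.atom_features.shape[0]
    dz0_acc = np.zeros_like(cache["z0"])
    for t in range(depth - 2, -1, -1):
        z_t = cache["zs"][t]
        m_t = cache["ms"][t]
        dz = dh * (z_t > 0)
        dz0_acc += dz
        grads["Wh"] += m_t.T @ dz
        grads["bh"] += dz.sum(axis=0)
        dm = dz @ params["Wh"].T
        da = _scatter_add(dm, batch.src, n_atoms)
        dh = da[batch.dst] - dm[batch.rev]

    dz0 = dz0_acc + dh * (cache["z0"] > 0)
    grads["Wi"] = cache["in0"].T @ dz0
    grads["bi"] = dz0.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# Optimizer and schedule
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; state per parameter array."""

    def __init__(self, params: Params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= (lr * (self.m[k] / b1c) /
                          (np.sqrt(self.v[k] / b2c) + self.eps)).astype(params[k].dtype)


@dataclass(frozen=True)
class LRSchedule:
    """Linear warm-up from lr_init to lr_max, then exponential decay to
    lr_final at the last step."""

    lr_init: float
    lr_max: float
    lr_final: float
    warmup_steps: int
    total_steps: int

    def __post_init__(self) -> None:
        if self.lr_init > self.lr_max:
            raise ValueError("lr_init must be <= lr_max")
        if not 0 <= self.warmup_steps <= self.total_steps:
            raise ValueError("warmup_steps outside [0, total_steps]")

    def lr_at(self, step: int) -> float:
        """Learning rate at a global step (0-based; warmup end hits lr_max,
        the final step hits lr_final)."""
        if self.warmup_steps > 0 and step < self.warmup_steps:
            frac = step / self.warmup_steps
            return self.lr_init + (self.lr_max - self.lr_init) * frac
        decay_steps = self.total_steps - self.warmup_steps
        if decay_steps <= 0:
            return self.lr_max
        gamma = (self.lr_final / self.lr_max) ** (1.0 / decay_steps)
        return self.lr_max * gamma ** (step - self.warmup_steps)
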