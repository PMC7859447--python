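"""Unsupervised training and inference drivers.

Two modes share one objective (multi-scale local NCC + weighted diffusion
regularizer):

* population mode (:func:`train`) — iterate over ordered pairs of distinct
  volumes from a dataset, the regime the method is designed for;
* instance mode (:func:`instance_optimize`) — fit the network to a single
  pair from zero-initialization, the desk-scale surrogate used by the
  recovery experiments.

The optimizer is Adam with an initial learning rate that halves every 10
epochs (step decay).
"""

from __future__ import annotations

import csv
import dataclasses
import time

import numpy as np

from .losses import LossConfig, total_loss
from .network import EPRegNet, NetworkConfig
from .transform import field_to_voxels, warp_labels_nn

__all__ = ["TrainConfig", "lr_at_epoch", "Adam", "train",
           "instance_optimize", "register"]


@dataclasses.dataclass
class TrainConfig:
    """Optimization schedule and objective weights.

    epochs : number of passes over the pair set (population mode)
    iterations : optimization steps (instance mode)
    lr0 : initial Adam learning rate
    lr_halving_every : epochs between learning-rate halvings
    window / lam / eps : similarity window, smoothness weight, stabilizer
    seed : RNG seed for pair shuffling and network init
    """

    epochs: int = 300
    iterations: int = 200
    lr0: float = 2e-4
    lr_halving_every: int = 10
    window: int = 9
    lam: float = 1000.0
    eps: float = 1e-5
    seed: int = 0

    def loss_config(self) -> LossConfig:
        return LossConfig(window=self.window, lam=self.lam, eps=self.eps)


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: ``lr0 * 0.5 ** (epoch // halving_interval)``."""
    return cfg.lr0 * 0.5 ** (epoch // cfg.lr_halving_every)


class Adam:
    """Adam over a flat list of parameter tensors."""

    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - (self.lr * mhat
                               / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _check_finite(breakdown: dict, where: str):
    for name, val in breakdown.items():
        if not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite loss term '{name}' ({val}) at {where}; aborting")


def _step(net: EPRegNet, opt: Adam, fixed, moving, loss_cfg: LossConfig):
    opt.zero_grad()
    result = net.forward(fixed, moving)
    loss, breakdown = total_loss(fixed, moving, result.grids,
                                 result.aggregate, loss_cfg)
    loss.backward()
    opt.step()
    return breakdown


def _write_log(log_path, records):
    if log_path is None or not records:
        return
    with open(log_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
        writer.writeheader()
        writer.writerows(records)


def train(pairs, cfg: TrainConfig | None = None,
          net_config: NetworkConfig | None = None,
          log_path=None, checkpoint_path=None):
    """Population training over a sequence of (fixed, moving) arrays.

    ``pairs`` is a sequence of 2-tuples of preprocessed volumes sharing one
    shape.  Pairs are shuffled every epoch with the run seed.  Returns the
    network at its best observed epoch-mean loss, plus the log records.
    """
    cfg = cfg or TrainConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training pair set")
    shape = np.asarray(pairs[0][0]).shape
    for f, m in pairs:
        if np.asarray(f).shape != shape or np.asarray(m).shape != shape:
            raise ValueError("all volumes must share the configured shape")
    net_config = net_config or NetworkConfig(seed=cfg.seed)
    net = EPRegNet(net_config).train_mode(True)
    opt = Adam(net.params(), lr=cfg.lr0)
    loss_cfg = cfg.loss_config()
    rng = np.random.default_rng(cfg.seed)
    records = []
    best = (np.inf, None)
    t0 = time.time()
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for step, idx in enumerate(order):
            fixed, moving = pairs[idx]
            breakdown = _step(net, opt, np.asarray(fixed), np.asarray(moving),
                              loss_cfg)
            _check_finite(breakdown, f"epoch {epoch} step {step}")
            epoch_losses.append(breakdown["total"])
            records.append({"epoch": epoch, "step": step, "lr": opt.lr,
                            "walltime": time.time() - t0, **breakdown})
        mean_loss = float(np.mean(epoch_losses))
        if mean_loss < best[0]:
            best = (mean_loss, net.state_arrays())
            if checkpoint_path is not None:
                net.save(checkpoint_path)
    if best[1] is not None:  # restore best-loss weights
        for k, p in enumerate(net.params()):
            p.data = best[1][f"param_{k}"]
    _write_log(log_path, records)
    return net, records


def instance_optimize(fixed, moving, cfg: TrainConfig | None = None,
                      net_config: NetworkConfig | None = None,
                      log_path=None):
    """Fit the objective on a single pair from zero-initialization.

    The learning rate is held constant: the epoch-level halving schedule is
    a population-training device and a 200-step single-pair fit has no use
    for it.  Instance fitting tolerates (and needs) a much larger step size
    than population training, so callers typically pass ``lr0=1e-2``.
    Returns the trained network and the per-iteration loss records.
    """
    cfg = cfg or TrainConfig()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    net_config = net_config or NetworkConfig(seed=cfg.seed)
    net = EPRegNet(net_config).train_mode(True)
    opt = Adam(net.params(), lr=cfg.lr0)
    loss_cfg = cfg.loss_config()
    records = []
    t0 = time.time()
    for it in range(cfg.iterations):
        breakdown = _step(net, opt, fixed, moving, loss_cfg)
        _check_finite(breakdown, f"iteration {it}")
        records.append({"epoch": 0, "step": it, "lr": opt.lr,
                        "walltime": time.time() - t0, **breakdown})
    _write_log(log_path, records)
    return net, records


def register(fixed, moving, net: EPRegNet, moving_labels=None):
    """Single forward pass: warped volume, fields, optional warped labels."""
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    net.train_mode(False)
    result = net.forward(fixed, moving)
    out = {
        "warped": result.warped.data,
        "full_grid": result.full_grid.data,
        "aggregate_field": result.aggregate.data,
        "aggregate_field_vox": field_to_voxels(result.aggregate.data),
        "phis": {i: p.data for i, p in result.phis.items()},
        "grids": {i: g.data for i, g in result.grids.items()},
        "affine": result.affine.data,
    }
    if moving_labels is not None:
        arr = moving_labels.data if hasattr(moving_labels, "data") \
            else np.asarray(moving_labels)
        out["warped_labels"] = warp_labels_nn(arr, result.full_grid.data)
    net.train_mode(True)
    return out
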