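"""Target decomposition, masked losses and the training loop.

Targets are sparse: most (cell type, feature) combinations are unmeasured at
any locus.  Losses therefore average only over measured entries, and the
gradient with respect to any unmeasured prediction is exactly zero.

For the split-head model, per-locus supervision targets are the across-cell
mean M (computed over measured cells only) and the deviation D = t - M; the
combined loss is a * MSE(M) + (1 - a) * MSE(D) with a small a, so nearly all
of the training signal drives the cell-specific deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Tensor
from .model import Network

_EPS = 1e-12


@dataclass
class LossSpec:
    task: str = "qualitative"
    a_weight: float = 0.0002

    def __post_init__(self):
        if not 0.0 <= self.a_weight <= 1.0:
            raise ValueError("a_weight must lie in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 20
    initial_lr: float = 0.0001
    batch_size: int = 16
    emb_weight_decay: float = 1.0
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.initial_lr <= 0:
            raise ValueError("epochs >= 1 and initial_lr > 0 required")
        if self.emb_weight_decay < 0 or self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")


def compute_mpi(targets: np.ndarray, mask: np.ndarray) -> tuple:
    """Mean/deviation decomposition of a (cells x features) target matrix.

    M[k] is the mean target over measured cells for feature k (NaN if the
    feature has no measured cell, which excludes it from the loss);
    D[n, k] = t[n, k] - M[k] on measured entries, NaN elsewhere.  Measured
    deviations sum to zero per feature by construction.
    """
    targets = np.asarray(targets, float)
    mask = np.asarray(mask, bool)
    counts = mask.sum(axis=0).astype(float)
    filled = np.where(mask, targets, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(counts > 0, filled.sum(axis=0) / counts, np.nan)
    D = np.where(mask, targets - M[None, :], np.nan)
    return M, D


def masked_bce_loss(preds: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over measured entries only."""
    mask = np.asarray(mask, bool)
    n = mask.sum()
    if n == 0:
        raise ValueError("masked_bce_loss requires at least one measured entry")
    t = np.where(mask, np.asarray(targets, float), 0.0)
    m = mask.astype(float)
    eps = Tensor(_EPS)
    # unmeasured predictions are replaced by 0.5 before the log so that even
    # pathological values there cannot poison the loss; the substitution has
    # zero gradient with respect to the original predictions
    pm = preds * Tensor(m) + Tensor(0.5 * (1.0 - m))
    per = -(
        Tensor(t) * (pm + eps).log()
        + Tensor(1.0 - t) * (1.0 - pm + eps).log()
    )
    return (per * Tensor(m)).sum() * (1.0 / float(n))


def masked_mse_loss(preds: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    mask = np.asarray(mask, bool)
    n = mask.sum()
    if n == 0:
        raise ValueError("masked_mse_loss requires at least one measured entry")
    t = np.where(mask, np.asarray(targets, float), 0.0)
    diff = (preds - Tensor(t)) * Tensor(mask.astype(float))
    return (diff**2).sum() * (1.0 / float(n))


def split_mse_loss(
    M_pred: Tensor,
    D_pred: Tensor,
    targets: np.ndarray,
    mask: np.ndarray,
    spec: LossSpec | None = None,
) -> Tensor:
    """a * MSE(M) + (1 - a) * MSE(D) against the per-locus decomposition.

    M_pred: (B, F); D_pred: (B, N, F); targets/mask: (B, N, F).  MSE(M) runs
    over (locus, feature) pairs with >= 1 measured cell; MSE(D) over measured
    entries.
    """
    spec = spec or LossSpec(task="quantitative")
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("split_mse_loss requires at least one measured entry")
    targets = np.asarray(targets, float)
    if targets.ndim == 2:  # single locus
        targets, mask = targets[None], mask[None]
    Ms, Ds = [], []
    for b in range(targets.shape[0]):
        M, D = compute_mpi(targets[b], mask[b])
        Ms.append(M)
        Ds.append(D)
    M_true = np.stack(Ms)  # (B, F), NaN where no measured cell
    D_true = np.stack(Ds)  # (B, N, F), NaN where unmeasured
    feat_mask = ~np.isnan(M_true)
    a = spec.a_weight
    mse_m = masked_mse_loss(M_pred, np.nan_to_num(M_true), feat_mask)
    mse_d = masked_mse_loss(D_pred, np.nan_to_num(D_true), mask)
    return mse_m * a + mse_d * (1.0 - a)


def cosine_lr(step: int, total_steps: int, initial_lr: float) -> float:
    """Cosine annealing from initial_lr at step 0 to 0 at the final step."""
    if total_steps <= 1:
        return initial_lr
    return 0.5 * initial_lr * (1.0 + np.cos(np.pi * step / (total_steps - 1)))


def _batch_loss(net: Network, X, y, mask, loss_spec: LossSpec) -> Tensor:
    xt = Tensor(X)
    if net.config.head_variant == "split_MD":
        m, d = net.forward_split(xt)
        return split_mse_loss(m, d, y, mask, loss_spec)
    preds = net.forward(xt)
    if loss_spec.task == "qualitative":
        return masked_bce_loss(preds, np.nan_to_num(y), mask)
    return masked_mse_loss(preds, np.nan_to_num(y), mask)


def train(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    loss_spec: LossSpec | None = None,
    cfg: TrainConfig | None = None,
    X_val=None,
    y_val=None,
    mask_val=None,
    log=None,
) -> tuple:
    """Train `net` in place with Adam under a cosine-annealed learning rate.

    Returns (net, history); history is a list of per-epoch dicts with train
    loss, validation loss (if a validation set was given) and final lr.
    Deterministic given cfg.seed and the input order.  On a non-finite loss
    the last finite parameter state is restored and training stops.
    """
    loss_spec = loss_spec or LossSpec(task=net.config.task)
    cfg = cfg or TrainConfig()
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("training requires at least one measured target")
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    opt = Adam(net.parameters, lr=cfg.initial_lr)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    history = []
    step = 0
    snapshot = [p.data.copy() for p in net.parameters]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if not mask[idx].any():
                continue
            opt.lr = cosine_lr(step, total_steps, cfg.initial_lr)
            opt.zero_grad()
            loss = _batch_loss(net, X[idx], y[idx], mask[idx], loss_spec)
            val = float(loss.data)
            if not np.isfinite(val):
                for p, snap in zip(net.parameters, snapshot):
                    p.data[...] = snap
                history.append({"epoch": epoch, "train_loss": np.nan, "diverged": True})
                return net, history
            loss.backward()
            opt.step()
            if cfg.weight_decay > 0:
                # decoupled L2 on all weights: biases the fit toward compact
                # sequence detectors rather than per-window memorization
                for p in net.parameters:
                    if p is not net.cell_embedding:
                        p.data *= 1.0 - opt.lr * cfg.weight_decay
            if cfg.emb_weight_decay > 0:
                # decoupled L2 on the embedding matrix only: the random init
                # component decays away while directions the head actually
                # uses are maintained by the gradient, so cells with shared
                # regulatory behaviour end up with aligned embeddings
                net.cell_embedding.data *= 1.0 - opt.lr * cfg.emb_weight_decay
            epoch_losses.append(val)
            step += 1
        snapshot = [p.data.copy() for p in net.parameters]
        rec = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "lr": opt.lr}
        if X_val is not None and len(X_val):
            vloss = _batch_loss(net, X_val, y_val, np.asarray(mask_val, bool), loss_spec)
            rec["val_loss"] = float(vloss.data)
        history.append(rec)
        if log is not None:
            log(rec)
    return net, history
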