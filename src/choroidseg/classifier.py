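"""Training the patch classifier: focal loss, l2 regularization, Adam.

The on-line/off-line patch classes are imbalanced (about 1:11 on B-scan
grids), so the objective is the focal loss

    FL(p, l) = -alpha * l * (1-p)^gamma * ln p
               - (1-alpha) * (1-l) * p^gamma * ln(1-p)

which up-weights the rare positive class (alpha) and down-weights easy
examples (gamma), plus an l2 penalty (mu/2)*||theta||^2 over all trainable
weights.  Defaults alpha=0.9, gamma=2, mu=0.1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import ArchConfig, PatchCNN, softmax

log = logging.getLogger(__name__)

P_EPS = 1e-7


@dataclass
class Hyper:
    """Training hyperparameters (focal weights from the method's defaults)."""

    alpha: float = 0.9
    gamma: float = 2.0
    mu: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 10
    seed: int = 0
    width_scale: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0 or self.mu < 0:
            raise ValueError("gamma and mu must be nonnegative")


def focal_loss(p, l, alpha: float = 0.9, gamma: float = 2.0):
    """Elementwise focal loss; probabilities are clipped to [1e-7, 1-1e-7]."""
    p = np.asarray(p, dtype=np.float64)
    l = np.asarray(l, dtype=np.float64)
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, P_EPS, 1.0 - P_EPS)
    pos = -alpha * l * (1.0 - p) ** gamma * np.log(p)
    neg = -(1.0 - alpha) * (1.0 - l) * p**gamma * np.log(1.0 - p)
    out = pos + neg
    return float(out) if out.ndim == 0 else out


def _focal_grad_logits(logits: np.ndarray, labels: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    """d(mean FL)/d(logits) for a batch, via dFL/dp and the softmax Jacobian."""
    p = softmax(logits.astype(np.float64))[:, 1]
    p = np.clip(p, P_EPS, 1.0 - P_EPS)
    l = labels.astype(np.float64)
    if gamma == 0.0:
        dpos = -alpha * (1.0 / p)
        dneg = (1.0 - alpha) / (1.0 - p)
    else:
        dpos = -alpha * (-gamma * (1.0 - p) ** (gamma - 1.0) * np.log(p) + (1.0 - p) ** gamma / p)
        dneg = -(1.0 - alpha) * (
            gamma * p ** (gamma - 1.0) * np.log(1.0 - p) - p**gamma / (1.0 - p)
        )
    dldp = l * dpos + (1.0 - l) * dneg
    dp_dz1 = p * (1.0 - p)
    g = np.zeros_like(logits, dtype=np.float64)
    g[:, 1] = dldp * dp_dz1
    g[:, 0] = -dldp * dp_dz1
    return g / len(labels)


def objective(net: PatchCNN, patches: np.ndarray, labels: np.ndarray, hyper: Hyper) -> float:
    """J(theta) = mean focal loss over the batch + (mu/2)*||theta||_2^2."""
    if len(patches) == 0:
        raise ValueError("batch must be nonempty")
    p = net.predict_proba(patches)
    fl = focal_loss(p, labels, hyper.alpha, hyper.gamma)
    return float(np.mean(fl) + 0.5 * hyper.mu * net.param_vector_sq_norm())


class Adam:
    """Adaptive moment estimation over the network's parameter dictionaries.

    The l2 penalty is applied as decoupled weight decay (the AdamW form):
    feeding mu*theta through Adam's moment normalization lets the decay
    term dominate every small-gradient coordinate and the network never
    escapes its initialization, while the decoupled step keeps the penalty
    a plain shrinkage toward zero.
    """

    def __init__(self, net: PatchCNN, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(l.params[n]) for k, l, n in net.parameters()}
        self.v = {k: np.zeros_like(l.params[n]) for k, l, n in net.parameters()}

    def step(self, mu: float) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, layer, name in self.net.parameters():
            g = layer.grads[name].astype(layer.params[name].dtype)
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p = layer.params[name]
            if mu:
                p *= 1.0 - self.lr * mu  # decoupled l2 decay
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _eval_subsample(labels: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic index subsample containing both classes (epoch logging)."""
    n = len(labels)
    if n <= cap:
        return np.arange(n)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_pos = min(len(pos), max(1, cap // 4))
    idx = np.concatenate([pos[:n_pos], neg[: cap - n_pos]])
    return np.sort(idx)


def train(patches: np.ndarray, labels: np.ndarray, hyper: Hyper | None = None) -> PatchCNN:
    """Minimize the regularized focal objective with Adam.

    Deterministic given ``hyper.seed`` (weight init and batch shuffling both
    derive from it).  Logs the epoch objective and class-conditional
    accuracies.  ``epochs=0`` returns the seeded initialization unchanged.
    """
    hyper = hyper or Hyper()
    patches = np.asarray(patches, dtype=np.float32)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    for required in (0, 1):
        if required not in classes:
            raise ValueError(f"training set contains no class-{required} samples")

    net = PatchCNN(ArchConfig(width_scale=hyper.width_scale), seed=hyper.seed)
    opt = Adam(net, lr=hyper.learning_rate)
    rng = np.random.default_rng(hyper.seed + 1)
    n = len(patches)
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, hyper.batch_size):
            idx = order[s : s + hyper.batch_size]
            xb, yb = patches[idx], labels[idx]
            z = net.logits(xb, train=True)
            p = np.clip(softmax(z.astype(np.float64))[:, 1], P_EPS, 1 - P_EPS)
            losses.append(np.mean(focal_loss(p, yb, hyper.alpha, hyper.gamma)))
            net.backward(_focal_grad_logits(z, yb, hyper.alpha, hyper.gamma))
            opt.step(hyper.mu)
        # class-conditional accuracy on a fixed subsample (cheap epoch log)
        eval_idx = _eval_subsample(labels, cap=2048)
        p_all = net.predict_proba(patches[eval_idx])
        pred = (p_all >= 0.5).astype(int)
        sub = labels[eval_idx]
        acc_pos = float(np.mean(pred[sub == 1] == 1))
        acc_neg = float(np.mean(pred[sub == 0] == 0))
        log.info(
            "epoch %d: mean focal loss %.5f, acc(on-line)=%.3f acc(off-line)=%.3f",
            epoch + 1, float(np.mean(losses)), acc_pos, acc_neg,
        )
    return net


# ---- checkpoints ----------------------------------------------------------

def save_checkpoint(path, net: PatchCNN, hyper: Hyper) -> None:
    """Save weights plus the hyperparameter record in one .npz file."""
    path = Path(path)
    state = net.state_dict()
    state["__hyper__"] = np.frombuffer(json.dumps(asdict(hyper)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[PatchCNN, Hyper]:
    data = np.load(path)
    hyper = Hyper(**json.loads(bytes(data["__hyper__"]).decode()))
    net = PatchCNN(ArchConfig(width_scale=hyper.width_scale), seed=hyper.seed)
    net.load_state_dict({k: data[k] for k in data.files if k != "__hyper__"})
    return net, hyper
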