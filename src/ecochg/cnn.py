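"""Scalogram classifiers: a compact from-scratch CNN and an optional
transfer-learned AlexNet backbone.

The compact backbone is a small two-convolution network implemented in
numpy and trained with stochastic gradient descent with momentum.  It is
the default: it trains in minutes on a CPU, needs no downloaded weights,
and the synthetic detection task (a localized energy blob at the stimulus
frequency vs. unstructured noise) is well within its capacity.  The
``large-pretrained`` backbone reproduces the ImageNet-AlexNet transfer
setup when torch/torchvision are installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.special import expit

from .scalogram import Scalogram

__all__ = [
    "TrainConfig",
    "CompactCNN",
    "CVResult",
    "train_classifier",
    "predict",
    "kfold_cv",
]


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the transfer-learning protocol: mini-batch 8, at most
    25 epochs, learning rate 1e-4, momentum 0.9, 10-fold cross-validation.
    ``TrainConfig.compact()`` swaps in a from-scratch learning rate (0.05)
    suitable for a randomly initialized small network, which 1e-4 cannot
    move appreciably within 25 epochs.
    """

    batch_size: int = 8
    max_epochs: int = 25
    learning_rate: float = 1e-4
    momentum: float = 0.9
    folds: int = 10
    backbone: str = "compact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.backbone not in ("compact", "large-pretrained"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    @classmethod
    def compact(cls, **overrides) -> "TrainConfig":
        defaults = dict(learning_rate=0.05, backbone="compact")
        defaults.update(overrides)
        return cls(**defaults)


def _as_images(scalograms) -> np.ndarray:
    """Stack scalograms (objects or arrays) into (n, 224, 224, 3)."""
    imgs = [s.image if isinstance(s, Scalogram) else np.asarray(s) for s in scalograms]
    arr = np.stack(imgs).astype(np.float32)
    if arr.ndim != 4 or arr.shape[1:] != (224, 224, 3):
        raise ValueError(f"expected (n, 224, 224, 3) scalograms, got {arr.shape}")
    return arr


def _im2col(xp: np.ndarray) -> np.ndarray:
    """Padded input (B, C, H+2, W+2) -> column view (B, C*9, H*W)."""
    b, c, hp, wp = xp.shape
    h, w = hp - 2, wp - 2
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * 9, h * w)


def _col2im(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    b, c, h, w = shape
    d = dcols.reshape(b, c, 3, 3, h, w)
    dxp = np.zeros((b, c, h + 2, w + 2))
    for i in range(3):
        for j in range(3):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, i, j]
    return dxp[:, :, 1:-1, 1:-1]


def _pad(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))


class CompactCNN:
    """Two-convolution binary classifier for 224x224x3 scalograms.

    Input handling: channels averaged (they are replicated anyway), 8x8
    average-pooled to 28x28, standardized with training-set statistics.
    Architecture: conv3x3(8) - ReLU - maxpool2 - conv3x3(16) - ReLU -
    maxpool2 - dense(1) - sigmoid.  Trained on binary cross-entropy with
    SGD + momentum; deterministic for a fixed seed.
    """

    N_F1, N_F2 = 8, 16

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.mean_ = 0.0
        self.std_ = 1.0
        self.history_: list[dict] = []
        rng = np.random.default_rng(cfg.seed)
        f1, f2 = self.N_F1, self.N_F2
        self.W1 = rng.normal(0, np.sqrt(2.0 / 9), (f1, 1 * 9))
        self.b1 = np.zeros(f1)
        self.W2 = rng.normal(0, np.sqrt(2.0 / (f1 * 9)), (f2, f1 * 9))
        self.b2 = np.zeros(f2)
        self.Wf = rng.normal(0, np.sqrt(2.0 / (f2 * 49)), f2 * 49)
        self.bf = 0.0
        self._rng = rng
        self._vel = {k: np.zeros_like(getattr(self, k)) for k in ("W1", "b1", "W2", "b2", "Wf")}
        self._vel["bf"] = 0.0

    # -- input reduction ------------------------------------------------
    @staticmethod
    def pool_images(images: np.ndarray, chunk: int = 64) -> np.ndarray:
        """(n, 224, 224, 3) -> (n, 1, 28, 28) by channel mean + 8x8 avg pool."""
        out = np.empty((images.shape[0], 1, 28, 28))
        for i in range(0, images.shape[0], chunk):
            x = images[i:i + chunk].astype(np.float64).mean(axis=3)
            out[i:i + chunk, 0] = x.reshape(-1, 28, 8, 28, 8).mean(axis=(2, 4))
        return out

    # -- forward/backward ------------------------------------------------
    def _forward(self, x: np.ndarray, keep: bool = False):
        b = x.shape[0]
        cols1 = _im2col(_pad(x))
        z1 = (self.W1 @ cols1 + self.b1[:, None]).reshape(b, self.N_F1, 28, 28)
        a1 = np.maximum(z1, 0)
        p1 = a1.reshape(b, self.N_F1, 14, 2, 14, 2).max(axis=(3, 5))
        cols2 = _im2col(_pad(p1))
        z2 = (self.W2 @ cols2 + self.b2[:, None]).reshape(b, self.N_F2, 14, 14)
        a2 = np.maximum(z2, 0)
        p2 = a2.reshape(b, self.N_F2, 7, 2, 7, 2).max(axis=(3, 5))
        flat = p2.reshape(b, -1)
        logits = flat @ self.Wf + self.bf
        if keep:
            self._cache = (x, cols1, z1, a1, p1, cols2, z2, a2, p2, flat)
        return logits

    def _backward(self, dlogits: np.ndarray) -> dict:
        x, cols1, z1, a1, p1, cols2, z2, a2, p2, flat = self._cache
        b = x.shape[0]
        g = {}
        g["Wf"] = flat.T @ dlogits
        g["bf"] = dlogits.sum()
        dflat = np.outer(dlogits, self.Wf)
        dp2 = dflat.reshape(p2.shape)
        # route gradients to the pooled maxima (ties share, measure-zero case)
        a2r = a2.reshape(b, self.N_F2, 7, 2, 7, 2)
        mask2 = a2r == p2[:, :, :, None, :, None]
        da2 = (mask2 * dp2[:, :, :, None, :, None]).reshape(a2.shape)
        dz2 = da2 * (z2 > 0)
        dz2f = dz2.reshape(b, self.N_F2, -1)
        g["W2"] = np.einsum("bfp,bcp->fc", dz2f, cols2)
        g["b2"] = dz2f.sum(axis=(0, 2))
        dcols2 = np.einsum("fc,bfp->bcp", self.W2, dz2f)
        dp1 = _col2im(dcols2, (b, self.N_F1, 14, 14))
        a1r = a1.reshape(b, self.N_F1, 14, 2, 14, 2)
        mask1 = a1r == p1[:, :, :, None, :, None]
        da1 = (mask1 * dp1[:, :, :, None, :, None]).reshape(a1.shape)
        dz1 = da1 * (z1 > 0)
        dz1f = dz1.reshape(b, self.N_F1, -1)
        g["W1"] = np.einsum("bfp,bcp->fc", dz1f, cols1)
        g["b1"] = dz1f.sum(axis=(0, 2))
        return g

    # -- API --------------------------------------------------------------
    def fit(self, scalograms, labels) -> "CompactCNN":
        images = _as_images(scalograms)
        y = np.asarray(labels).astype(float)
        if y.min() == y.max():
            raise ValueError("both classes must be present for training")
        x = self.pool_images(images)
        self.mean_ = float(x.mean())
        self.std_ = float(x.std()) or 1.0
        x = (x - self.mean_) / self.std_
        n = x.shape[0]
        cfg = self.cfg
        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb, keep=True)
                # stable BCE: softplus(z) - y z
                losses.append(float(np.mean(np.logaddexp(0, logits) - yb * logits)))
                dlogits = (expit(logits) - yb) / len(idx)
                grads = self._backward(dlogits)
                for k, gk in grads.items():
                    self._vel[k] = cfg.momentum * self._vel[k] - cfg.learning_rate * gk
                    setattr(self, k, getattr(self, k) + self._vel[k])
            probs = self.predict_proba(scalograms=None, _pooled=x)
            acc = float(np.mean((probs >= 0.5) == (y == 1)))
            self.history_.append({"epoch": epoch + 1, "loss": float(np.mean(losses)), "train_accuracy": acc})
        return self

    def predict_proba(self, scalograms, _pooled: np.ndarray | None = None) -> np.ndarray:
        if _pooled is None:
            images = _as_images(scalograms)
            _pooled = (self.pool_images(images) - self.mean_) / self.std_
        probs = np.empty(_pooled.shape[0])
        for i in range(0, _pooled.shape[0], 256):
            logits = self._forward(_pooled[i:i + 256])
            probs[i:i + 256] = expit(logits)
        return probs


@dataclass
class CVResult:
    """Stratified k-fold cross-validation outcome."""

    fold_accuracy: list[float]
    fold_auc: list[float]
    pooled_auc: float
    final_model: object = None
    fold_assignments: np.ndarray = field(default_factory=lambda: np.array([], int))


def train_classifier(scalograms, labels, cfg: TrainConfig | None = None):
    """Train a binary scalogram classifier; returns the model handle."""
    cfg = cfg or TrainConfig.compact()
    if cfg.backbone == "compact":
        return CompactCNN(cfg).fit(scalograms, labels)
    return _train_pretrained(scalograms, labels, cfg)


def predict(model, scalograms) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and 0.5-threshold decisions for a trained model."""
    probs = model.predict_proba(scalograms)
    return probs, probs >= 0.5


def kfold_cv(scalograms, labels, cfg: TrainConfig | None = None) -> CVResult:
    """Stratified k-fold CV, then a final model retrained on everything.

    Per-fold accuracy and AUC flag overfitting; the pooled AUC concatenates
    all validation-fold predictions.  Deterministic for a fixed seed.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    cfg = cfg or TrainConfig.compact()
    y = np.asarray(labels).astype(int)
    if len(y) < cfg.folds:
        raise ValueError(f"need at least {cfg.folds} items for {cfg.folds}-fold CV")
    images = _as_images(scalograms)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    accs, aucs = [], []
    pooled_scores = np.empty(len(y))
    assignment = np.empty(len(y), int)
    for k, (tr, va) in enumerate(skf.split(images, y)):
        model = train_classifier(images[tr], y[tr], dc_replace(cfg, seed=cfg.seed + k + 1))
        probs, dec = predict(model, images[va])
        pooled_scores[va] = probs
        assignment[va] = k
        accs.append(float(np.mean(dec == (y[va] == 1))))
        aucs.append(
            float(roc_auc_score(y[va], probs)) if len(np.unique(y[va])) == 2 else np.nan
        )
    final = train_classifier(images, y, cfg)
    return CVResult(
        fold_accuracy=accs,
        fold_auc=aucs,
        pooled_auc=float(roc_auc_score(y, pooled_scores)),
        final_model=final,
        fold_assignments=assignment,
    )


def _train_pretrained(scalograms, labels, cfg: TrainConfig):
    """ImageNet-AlexNet transfer backbone (requires torch + torchvision).

    The final two classifier layers are replaced for binary output; the
    rest of the pretrained network is left as initialized.
    """
    try:
        import torch
        from torch import nn
        from torchvision import models
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "backbone 'large-pretrained' requires torch and torchvision; "
            "install them or use backbone='compact'"
        ) from exc

    torch.manual_seed(cfg.seed)
    images = _as_images(scalograms)
    y = torch.tensor(np.asarray(labels).astype(np.int64))
    x = torch.tensor(images.transpose(0, 3, 1, 2), dtype=torch.float32)
    model = models.alexnet(weights=models.AlexNet_Weights.IMAGENET1K_V1)
    model.classifier[4] = nn.Linear(4096, 1024)
    model.classifier[6] = nn.Linear(1024, 2)
    opt = torch.optim.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    loss_fn = nn.CrossEntropyLoss()
    ds = torch.utils.data.TensorDataset(x, y)
    loader = torch.utils.data.DataLoader(ds, batch_size=cfg.batch_size, shuffle=True)
    model.train()
    for _ in range(cfg.max_epochs):
        for xb, yb in loader:
            opt.zero_grad()
            loss = loss_fn(model(xb), yb)
            loss.backward()
            opt.step()
    model.eval()

    class _TorchWrapper:
        def __init__(self, net):
            self.net = net

        def predict_proba(self, scalograms) -> np.ndarray:
            imgs = _as_images(scalograms)
            with torch.no_grad():
                logits = self.net(
                    torch.tensor(imgs.transpose(0, 3, 1, 2), dtype=torch.float32)
                )
                return torch.softmax(logits, dim=1)[:, 1].numpy()

    return _TorchWrapper(model)
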