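"""Small convolutional feature extractor trained on surrogate labels.

The extractor is trained to classify organoid images by a surrogate task
(which line/family the organoid came from) and its penultimate 64-d
activations are then used as image features — the transfer-learning
recipe behind image-based phenotype mapping, scaled to a 3-conv-block
network that trains on a CPU in minutes.  Implemented directly in numpy
(im2col convolutions, Adam, softmax cross-entropy) so training is fully
deterministic for a fixed seed.

Architecture (input 1x64x64): [conv3x3-8, ReLU, maxpool2] ->
[conv3x3-16, ReLU, maxpool2] -> [conv3x3-32, ReLU, maxpool2] ->
global average pool -> fc 32->64, ReLU (penultimate) -> fc 64->K.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize


@dataclass
class CNNConfig:
    architecture: str = "small_cnn"   # or "resnet50" (needs a DL runtime)
    epochs: int = 20
    lr: float = 3e-3
    batch_size: int = 16
    resolution: int = 64
    val_fraction: float = 0.25
    seed: int = 0
    channels: tuple[int, int, int] = (8, 16, 32)
    penultimate_dim: int = 64


def _prep(images, resolution: int) -> np.ndarray:
    out = np.empty((len(images), 1, resolution, resolution), np.float64)
    for i, img in enumerate(images):
        x = 1.0 - np.asarray(img, np.float64)  # organoid becomes the bright phase
        if x.shape != (resolution, resolution):
            x = resize(x, (resolution, resolution), anti_aliasing=True)
        x = x - x.mean()
        x /= x.std() + 1e-6
        out[i, 0] = x
    return out


def _im2col(xp: np.ndarray) -> np.ndarray:
    """Padded input (N,C,H+2,W+2) -> columns (N, C*9, H*W) for 3x3 conv."""
    n, c, hp, wp = xp.shape
    h, w = hp - 2, wp - 2
    cols = np.empty((n, c, 9, h, w), xp.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di:di + h, dj:dj + w]
            k += 1
    return cols.reshape(n, c * 9, h * w)


class _Conv:
    def __init__(self, cin, cout, rng):
        scale = np.sqrt(2.0 / (cin * 9))
        self.W = rng.normal(0, scale, size=(cout, cin, 3, 3))
        self.b = np.zeros(cout)

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._cols = _im2col(xp)                       # (N, C*9, H*W)
        Wm = self.W.reshape(self.W.shape[0], -1)       # (F, C*9)
        out = np.einsum("fk,nkp->nfp", Wm, self._cols)
        out += self.b[None, :, None]
        self._shape = (n, c, h, w)
        return out.reshape(n, -1, h, w)

    def backward(self, dout):
        n, c, h, w = self._shape
        f = self.W.shape[0]
        dm = dout.reshape(n, f, h * w)
        self.dW = np.einsum("nfp,nkp->fk", dm, self._cols).reshape(self.W.shape) / n
        self.db = dm.sum(axis=(0, 2)) / n
        Wm = self.W.reshape(f, -1)
        dcols = np.einsum("fk,nfp->nkp", Wm, dm).reshape(n, c, 9, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2))
        k = 0
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, k]
                k += 1
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, d):
        return d * self._m


class _Pool2:
    """2x2 max pool (ties share gradient equally)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = (xr == out[:, :, :, None, :, None])
        self._counts = self._mask.sum(axis=(3, 5), keepdims=True)
        self._hw = (h, w)
        return out

    def backward(self, d):
        h, w = self._hw
        dr = (self._mask / self._counts) * d[:, :, :, None, :, None]
        n, c = dr.shape[:2]
        return dr.reshape(n, c, h, w)


class _Dense:
    def __init__(self, nin, nout, rng):
        self.W = rng.normal(0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.b = np.zeros(nout)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, d):
        self.dW = self._x.T @ d / len(d)
        self.db = d.mean(axis=0)
        return d @ self.W.T


class SmallCNN:
    """3-conv-block classifier with a 64-d penultimate embedding layer."""

    def __init__(self, n_classes: int, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.channels
        self.conv = [_Conv(1, c1, rng), _Conv(c1, c2, rng), _Conv(c2, c3, rng)]
        self.relu = [_ReLU(), _ReLU(), _ReLU()]
        self.pool = [_Pool2(), _Pool2(), _Pool2()]
        self.fc1 = _Dense(c3, config.penultimate_dim, rng)
        self.relu_fc = _ReLU()
        self.fc2 = _Dense(config.penultimate_dim, n_classes, rng)
        self.n_classes = n_classes
        self.history: list[dict] = []

    # -- forward ---------------------------------------------------------
    def _trunk(self, x):
        for cv, rl, pl in zip(self.conv, self.relu, self.pool):
            x = pl.forward(rl.forward(cv.forward(x)))
        self._gap_hw = x.shape[2] * x.shape[3]
        g = x.mean(axis=(2, 3))
        self._gap_shape = x.shape
        return g

    def forward(self, x):
        g = self._trunk(x)
        self._pen = self.relu_fc.forward(self.fc1.forward(g))
        return self.fc2.forward(self._pen)

    def features(self, images) -> np.ndarray:
        """Penultimate 64-d activations for a list/array of images."""
        x = _prep(images, self.config.resolution)
        out = []
        for i in range(0, len(x), 64):
            g = self._trunk(x[i:i + 64])
            out.append(self.relu_fc.forward(self.fc1.forward(g)))
        return np.vstack(out)

    def predict_proba(self, images) -> np.ndarray:
        x = _prep(images, self.config.resolution)
        out = []
        for i in range(0, len(x), 64):
            z = self.forward(x[i:i + 64])
            z = z - z.max(1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(1, keepdims=True))
        return np.vstack(out)

    # -- training --------------------------------------------------------
    def _param_tensors(self):
        layers = self.conv + [self.fc1, self.fc2]
        return [(ly, "W") for ly in layers] + [(ly, "b") for ly in layers]

    def _step(self, xb, yb, adam_state, lr, t):
        z = self.forward(xb)
        z = z - z.max(1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(1, keepdims=True)
        loss = -np.log(p[np.arange(len(yb)), yb] + 1e-12).mean()
        d = p.copy()
        d[np.arange(len(yb)), yb] -= 1.0

        d = self.fc2.backward(d)
        d = self.relu_fc.backward(d)
        d = self.fc1.backward(d)
        # undo global average pool
        n, c, h, w = self._gap_shape
        d = np.broadcast_to(d[:, :, None, None], (n, c, h, w)) / (h * w)
        for cv, rl, pl in zip(reversed(self.conv), reversed(self.relu),
                              reversed(self.pool)):
            d = cv.backward(rl.backward(pl.backward(d)))

        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (ly, name) in enumerate(self._param_tensors()):
            g = getattr(ly, "d" + name)
            m, v = adam_state[i]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p_ = getattr(ly, name)
            p_ -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def fit(self, images, labels) -> "SmallCNN":
        cfg = self.config
        x = _prep(images, cfg.resolution)
        classes, y = np.unique(labels, return_inverse=True)
        self.classes_ = classes
        if len(classes) < 2:
            raise ValueError("surrogate training needs >= 2 label classes")
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(x)
        order = rng.permutation(n)
        n_val = int(round(cfg.val_fraction * n))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        adam_state = [
            (np.zeros_like(getattr(ly, nm)), np.zeros_like(getattr(ly, nm)))
            for ly, nm in self._param_tensors()
        ]
        t = 0
        for epoch in range(cfg.epochs):
            perm = rng.permutation(tr_idx)
            losses = []
            for i in range(0, len(perm), cfg.batch_size):
                b = perm[i:i + cfg.batch_size]
                if len(b) < 2:
                    continue
                t += 1
                losses.append(self._step(x[b], y[b], adam_state, cfg.lr, t))
            rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if n_val:
                pv = self.predict_proba([images[i] for i in val_idx])
                rec["val_accuracy"] = float((pv.argmax(1) == y[val_idx]).mean())
            self.history.append(rec)
        return self

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for ly, nm in self._param_tensors():
            h.update(np.ascontiguousarray(getattr(ly, nm)).tobytes())
        return h.hexdigest()


def train_feature_extractor(images, surrogate_labels, config: CNNConfig | None = None):
    """Train the surrogate classifier and return it as a feature extractor.

    ``extractor.features(images)`` yields the penultimate activations;
    ``extractor.history`` carries the training curve (train loss and
    held-out surrogate accuracy per epoch).
    """
    cfg = config or CNNConfig()
    if cfg.architecture == "resnet50":
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "architecture='resnet50' requires a deep-learning runtime "
                "(torch); use architecture='small_cnn' instead") from exc
        raise NotImplementedError(
            "resnet50 fine-tuning is a config hook; only small_cnn ships here")
    if cfg.architecture != "small_cnn":
        raise ValueError(f"unknown architecture {cfg.architecture!r}")
    classes = np.unique(surrogate_labels)
    model = SmallCNN(len(classes), cfg)
    model.fit(images, surrogate_labels)
    return model
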