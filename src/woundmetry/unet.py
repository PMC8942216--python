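"""A compact U-Net-shaped segmenter implemented in NumPy.

Two resolution levels, skip connections, and two independent sigmoid output
channels (wound, splint-inner) trained with a soft dice loss.  Written
directly on numpy — convolutions via im2col, explicit backpropagation,
Adam updates — and sized for CPU training on small phantom crops (64-128
px); 352-px crops are supported but slower.

The class follows the fit/predict conventions of scikit-learn estimators:
hyperparameters in ``__init__``/``get_params``/``set_params``, learned
state on underscore attributes after :meth:`fit`.
"""

from __future__ import annotations

import json

import numpy as np

from .errors import ConfigurationError, InputError
from .segment import AugmentationConfig, ProbabilityMaps, augment_sample, dice_loss

__all__ = ["UNetSegmenter", "TrainConfig", "train_segmenter", "predict_maps"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) patch matrix with zero 'same' padding."""
    C, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    cols = np.empty((C, k, k, H, W), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, i : i + H, j : j + W]
    return cols.reshape(C * k * k, H * W)


def _col2im(cols: np.ndarray, C: int, H: int, W: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    p = k // 2
    cols = cols.reshape(C, k, k, H, W)
    xp = np.zeros((C, H + 2 * p, W + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, i : i + H, j : j + W] += cols[:, i, j]
    return xp[:, p : p + H, p : p + W]


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.b = np.zeros(cout)
        self.k = k
        self.cin = cin
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        C, H, W = x.shape
        cols = _im2col(x, self.k)
        y = (self.W @ cols + self.b[:, None]).reshape(-1, H, W)
        if keep:
            self._cols, self._shape = cols, (H, W)
        return y

    def backward(self, dy: np.ndarray, grads: dict, name: str) -> np.ndarray:
        H, W = self._shape
        dyf = dy.reshape(-1, H * W)
        grads[name + ".W"] += dyf @ self._cols.T
        grads[name + ".b"] += dyf.sum(axis=1)
        dcols = self.W.T @ dyf
        return _col2im(dcols, self.cin, H, W, self.k)


def _pool2(x: np.ndarray) -> np.ndarray:
    C, H, W = x.shape
    return x.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))


def _pool2_back(dy: np.ndarray) -> np.ndarray:
    C, H2, W2 = dy.shape
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_back(dy: np.ndarray) -> np.ndarray:
    C, H, W = dy.shape
    return dy.reshape(C, H // 2, 2, W // 2, 2).sum(axis=(2, 4))


class UNetSegmenter:
    """Two-level encoder-decoder with skip connections and sigmoid heads.

    Parameters
    ----------
    base_channels : width of the first encoder stage (doubles once).
    learning_rate : Adam step size.
    smooth : dice-loss smoothing constant.
    seed : seeds weight init, shuffling and augmentation draws.
    """

    _LAYERS = ("enc1a", "enc1b", "enc2", "bottleneck", "dec2", "dec1", "head")

    def __init__(
        self,
        base_channels: int = 8,
        learning_rate: float = 3e-3,
        smooth: float = 1.0,
        seed: int = 0,
    ):
        self.base_channels = base_channels
        self.learning_rate = learning_rate
        self.smooth = smooth
        self.seed = seed

    # -- sklearn-style parameter plumbing -------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "base_channels": self.base_channels,
            "learning_rate": self.learning_rate,
            "smooth": self.smooth,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "UNetSegmenter":
        for k, v in params.items():
            if k not in self.get_params():
                raise InputError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- network --------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        c = self.base_channels
        self.layers_ = {
            "enc1a": _Conv(3, c, 3, rng),
            "enc1b": _Conv(c, c, 3, rng),
            "enc2": _Conv(c, 2 * c, 3, rng),
            "bottleneck": _Conv(2 * c, 2 * c, 3, rng),
            "dec2": _Conv(4 * c, 2 * c, 3, rng),
            "dec1": _Conv(3 * c, c, 3, rng),
            "head": _Conv(c, 2, 1, rng),
        }

    @staticmethod
    def _prep(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3:
            raise InputError(f"expected an RGB image, got shape {img.shape}")
        if img.shape[0] % 4 or img.shape[1] % 4:
            raise InputError(
                f"image sides must be divisible by 4, got {img.shape[:2]}"
            )
        return (img / 255.0 - 0.5).transpose(2, 0, 1)

    def _forward(self, x: np.ndarray, keep: bool = True):
        L = self.layers_
        a1 = np.maximum(L["enc1a"].forward(x, keep), 0.0)
        a2 = np.maximum(L["enc1b"].forward(a1, keep), 0.0)
        p1 = _pool2(a2)
        a3 = np.maximum(L["enc2"].forward(p1, keep), 0.0)
        p2 = _pool2(a3)
        a4 = np.maximum(L["bottleneck"].forward(p2, keep), 0.0)
        c1 = np.concatenate([_up2(a4), a3], axis=0)
        a5 = np.maximum(L["dec2"].forward(c1, keep), 0.0)
        c2 = np.concatenate([_up2(a5), a2], axis=0)
        a6 = np.maximum(L["dec1"].forward(c2, keep), 0.0)
        z = L["head"].forward(a6, keep)
        p = 1.0 / (1.0 + np.exp(-z))
        cache = (a1, a2, a3, a4, a5, a6, p) if keep else None
        return p, cache

    def _backward(self, cache, target: np.ndarray, grads: dict) -> float:
        a1, a2, a3, a4, a5, a6, p = cache
        L = self.layers_
        c = self.base_channels
        K = p.shape[0]
        s = self.smooth
        loss = 0.0
        dp = np.empty_like(p)
        for k in range(K):
            t = target[k]
            inter = float((p[k] * t).sum())
            denom = float(p[k].sum() + t.sum())
            loss += 1.0 - (2.0 * inter + s) / (denom + s)
            dp[k] = -(2.0 * t * (denom + s) - (2.0 * inter + s)) / (denom + s) ** 2
        loss /= K
        dp /= K
        dz = dp * p * (1.0 - p)
        d6 = L["head"].backward(dz, grads, "head") * (a6 > 0)
        dc2 = L["dec1"].backward(d6, grads, "dec1")
        d5 = _up2_back(dc2[: 2 * c]) * (a5 > 0)
        da2_skip = dc2[2 * c :]
        dc1 = L["dec2"].backward(d5, grads, "dec2")
        d4 = _up2_back(dc1[: 2 * c]) * (a4 > 0)
        da3_skip = dc1[2 * c :]
        dp2 = L["bottleneck"].backward(d4, grads, "bottleneck")
        d3 = (_pool2_back(dp2) + da3_skip) * (a3 > 0)
        dp1 = L["enc2"].backward(d3, grads, "enc2")
        d2 = (_pool2_back(dp1) + da2_skip) * (a2 > 0)
        d1 = L["enc1b"].backward(d2, grads, "enc1b") * (a1 > 0)
        L["enc1a"].backward(d1, grads, "enc1a")
        return loss

    def _zero_grads(self) -> dict:
        grads = {}
        for name, layer in self.layers_.items():
            grads[name + ".W"] = np.zeros_like(layer.W)
            grads[name + ".b"] = np.zeros_like(layer.b)
        return grads

    # -- training -------------------------------------------------------
    def fit(
        self,
        train_samples: list[tuple[np.ndarray, np.ndarray]],
        val_samples: list[tuple[np.ndarray, np.ndarray]],
        epochs: int = 30,
        batch_size: int = 4,
        augmentation: AugmentationConfig | None = None,
    ) -> "UNetSegmenter":
        """Train on (image, masks) pairs; masks are ``(2, H, W)`` binary.

        Augmentation, when given, is redrawn for every sample at every
        epoch (on-the-fly).  Per-epoch train/validation loss and IoU are
        appended to ``history_``.
        """
        if not train_samples or not val_samples:
            raise ConfigurationError("need at least one training and one validation sample")
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        self._adam_m = {k: np.zeros_like(v) for k, v in self._param_dict().items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self._param_dict().items()}
        self._adam_t = 0
        self.history_ = []

        for epoch in range(epochs):
            order = rng.permutation(len(train_samples))
            losses = []
            for start in range(0, len(order), batch_size):
                batch = order[start : start + batch_size]
                grads = self._zero_grads()
                for i in batch:
                    image, masks = train_samples[i]
                    if augmentation is not None:
                        image, masks = augment_sample(image, masks, augmentation, rng)
                    x = self._prep(image)
                    _, cache = self._forward(x, keep=True)
                    losses.append(self._backward(cache, np.asarray(masks, float), grads))
                for k in grads:
                    grads[k] /= len(batch)
                self._adam_step(grads)
            tr_loss, tr_iou = self._evaluate(train_samples)
            va_loss, va_iou = self._evaluate(val_samples)
            self.history_.append(
                {
                    "epoch": epoch,
                    "train_loss": tr_loss,
                    "val_loss": va_loss,
                    "train_iou": tr_iou,
                    "val_iou": va_iou,
                }
            )
        return self

    def _param_dict(self) -> dict:
        out = {}
        for name, layer in self.layers_.items():
            out[name + ".W"] = layer.W
            out[name + ".b"] = layer.b
        return out

    def _adam_step(self, grads: dict, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        params = self._param_dict()
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1**self._adam_t)
            vhat = self._adam_v[k] / (1 - beta2**self._adam_t)
            params[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def _evaluate(self, samples) -> tuple[float, float]:
        losses, ious = [], []
        for image, masks in samples:
            p, _ = self._forward(self._prep(image), keep=False)
            t = np.asarray(masks, dtype=np.float64)
            losses.append(dice_loss(p, t, self.smooth))
            hard = p >= 0.5
            for k in range(p.shape[0]):
                union = np.logical_or(hard[k], t[k] > 0.5).sum()
                inter = np.logical_and(hard[k], t[k] > 0.5).sum()
                ious.append(1.0 if union == 0 else inter / union)
        return float(np.mean(losses)), float(np.mean(ious))

    # -- inference ------------------------------------------------------
    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-class scores in [0, 1], shape ``(2, H, W)``."""
        if not hasattr(self, "layers_"):
            raise ConfigurationError("model is not fitted")
        p, _ = self._forward(self._prep(image), keep=False)
        return p

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint weights + config + seed manifest to an .npz file."""
        arrays = {k: v for k, v in self._param_dict().items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        data = np.load(path)
        config = json.loads(bytes(data["__config__"]).decode())
        model = cls(**config)
        model._build(np.random.default_rng(config["seed"]))
        for name, layer in model.layers_.items():
            layer.W = data[name + ".W"]
            layer.b = data[name + ".b"]
        return model


from dataclasses import dataclass, field


@dataclass
class TrainConfig:
    """Training knobs with desk-scale defaults.

    The full-scale recipe (1000 epochs, batch size 4) is impractical on a
    laptop CPU; 30 epochs on small phantom crops trains in minutes and is
    the package default.
    """

    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 3e-3
    seed: int = 0
    base_channels: int = 8
    val_wounds: list[str] | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.base_channels < 1:
            raise ConfigurationError("epochs, batch_size, base_channels must be >= 1")


def train_segmenter(
    dataset: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    train_config: TrainConfig = TrainConfig(),
    augmentation_config: AugmentationConfig | None = None,
) -> UNetSegmenter:
    """Train the segmenter on (wound_id, image, wound_mask, splint_mask) tuples.

    The train/validation split is by whole wound series, never by frame:
    ``val_wounds`` names the held-out series (default: the lexicographically
    last wound id).  Overlapping or empty splits raise
    :class:`ConfigurationError`.
    """
    ids = sorted({wid for wid, *_ in dataset})
    if len(ids) < 2:
        raise ConfigurationError("need at least two wound series to split train/val")
    val_ids = set(train_config.val_wounds or [ids[-1]])
    if not val_ids or not val_ids.issubset(ids):
        raise ConfigurationError(f"validation wounds {sorted(val_ids)} not all in dataset")
    train_ids = set(ids) - val_ids
    if not train_ids:
        raise ConfigurationError("no training wounds left after the validation split")

    def pack(wids):
        return [
            (img, np.stack([np.asarray(w, float), np.asarray(s, float)]))
            for wid, img, w, s in dataset
            if wid in wids
        ]

    model = UNetSegmenter(
        base_channels=train_config.base_channels,
        learning_rate=train_config.learning_rate,
        seed=train_config.seed,
    )
    model.fit(
        pack(train_ids),
        pack(val_ids),
        epochs=train_config.epochs,
        batch_size=train_config.batch_size,
        augmentation=augmentation_config,
    )
    return model


def predict_maps(model: UNetSegmenter, crop: np.ndarray) -> ProbabilityMaps:
    """Run the model on a crop and scale per-class scores to 8-bit maps."""
    p = model.predict_proba(crop)
    as8 = np.clip(np.rint(p * 255.0), 0, 255).astype(np.uint8)
    return ProbabilityMaps(wound=as8[0], splint=as8[1])
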