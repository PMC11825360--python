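"""Encoder-decoder segmentation network, implemented in numpy.

The default architecture, ``lite_unet``, is a reduced-parameter U-Net: a
stride-2 average-pool stem, four encoder levels with a single 3x3
convolution each (base width 16), a mirrored decoder with skip connections,
and a 1x1 classification head over the seven mask classes.  Because the
network is fully convolutional it can segment any image whose side is a
multiple of 32 — in particular all three supported encoding sizes — while
being trained mostly on 256-pixel crops.

Everything (im2col convolutions, backprop, Adam) is hand-rolled on numpy:
the execution environment provides no deep-learning framework.  Training is
deterministic for a fixed seed; inference is pure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .encoding import EncodedImage
from .masks import N_CLASSES, SV_CLASSES, CLASS_NAMES, SegmentationMask

ARCHITECTURES = {
    # stem_pool, depth, base channels, convs per level
    "lite_unet": dict(stem_pool=2, depth=4, base=16, double_conv=False),
    "mini_unet": dict(stem_pool=2, depth=3, base=8, double_conv=False),
    "unet": dict(stem_pool=1, depth=4, base=64, double_conv=True),
}

#: class priority used when downsampling label maps: SV classes survive
#: 2x2 pooling even as single-pixel bands
_PRIORITY = np.array([0, 2, 3, 4, 5, 6, 1])  # BG < REF < DEL < INS < ...
_PRIORITY_INV = np.argsort(_PRIORITY)


def downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Class-preserving label downsampling (SV classes win inside a block)."""
    out = labels
    while factor > 1:
        h, w = out.shape
        pr = _PRIORITY[out].reshape(h // 2, 2, w // 2, 2)
        out = _PRIORITY_INV[pr.max(axis=(1, 3))]
        factor //= 2
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# layers (forward + backward)


def _conv_fwd(x, W, b):
    cin = x.shape[2]
    k = int(round((W.shape[0] / cin) ** 0.5))
    H, Wd = x.shape[:2]
    if k == 1:
        cols = x.reshape(H * Wd, cin)
    else:
        p = k // 2
        xp = np.pad(x, ((p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(0, 1))
        # win: (H, W, C, k, k) -> (H*W, C*k*k)
        cols = np.ascontiguousarray(win).reshape(H * Wd, cin * k * k)
    y = cols @ W + b
    return y.reshape(H, Wd, -1), (cols, x.shape, k)


def _conv_bwd(dy, W, cache):
    cols, xshape, k = cache
    H, Wd, cin = xshape
    cout = dy.shape[2]
    dyf = dy.reshape(-1, cout)
    dW = cols.T @ dyf
    db = dyf.sum(axis=0)
    if k == 1:
        dx = (dyf @ W.T).reshape(H, Wd, cin)
    else:
        # input gradient = convolution of dy with the flipped kernel
        Wb = W.reshape(cin, k, k, cout).transpose(3, 1, 2, 0)[:, ::-1, ::-1, :]
        Wb = np.ascontiguousarray(Wb).reshape(cout * k * k, cin)
        dx, _ = _conv_fwd(dy, Wb, np.zeros(cin, dtype=dy.dtype))
    return dx, dW, db


def _relu_fwd(x):
    m = x > 0
    return x * m, m


def _avgpool_fwd(x):
    h, w, c = x.shape
    return x.reshape(h // 2, 2, w // 2, 2, c).mean(axis=(1, 3)), (h, w)


def _avgpool_bwd(dy, cache):
    h, w = cache
    return np.repeat(np.repeat(dy, 2, axis=0), 2, axis=1) * 0.25


def _maxpool_fwd(x):
    h, w, c = x.shape
    xr = x.reshape(h // 2, 2, w // 2, 2, c)
    m = xr.max(axis=(1, 3))
    mask = xr == m[:, None, :, None, :]
    mask = mask / mask.sum(axis=(1, 3), keepdims=True)
    return m, (mask, (h, w, c))


def _maxpool_bwd(dy, cache):
    mask, (h, w, c) = cache
    return (mask * dy[:, None, :, None, :]).reshape(h, w, c)


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)


def _up2_bwd(dy):
    h, w, c = dy.shape
    return dy.reshape(h // 2, 2, w // 2, 2, c).sum(axis=(1, 3))


# ---------------------------------------------------------------------------
# model


@dataclass
class TrainingExample:
    """One simulated image with its ground-truth mask."""

    image: object  # EncodedImage or (S, S, 3) uint8 array
    truth_mask: SegmentationMask
    metadata: dict = field(default_factory=dict)

    @property
    def pixels(self) -> np.ndarray:
        if isinstance(self.image, EncodedImage):
            return self.image.pixels
        return np.asarray(self.image)


class SegmentationModel:
    """A trained (or freshly initialised) encoder-decoder segmenter."""

    def __init__(self, architecture: str = "lite_unet", seed: int = 0,
                 class_weights: Optional[np.ndarray] = None):
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}")
        self.architecture = architecture
        self.config = dict(ARCHITECTURES[architecture])
        self.class_weights = (np.ones(N_CLASSES, dtype=np.float32)
                              if class_weights is None
                              else np.asarray(class_weights, np.float32))
        self.params = {}
        self._init_params(np.random.default_rng(seed))

    # -- construction -------------------------------------------------------
    def _conv_names(self):
        cfg = self.config
        depth, base = cfg["depth"], cfg["base"]
        reps = 2 if cfg["double_conv"] else 1
        names = []  # (name, cin, cout, k)
        cin = 3
        enc_ch = []
        for d in range(depth):
            cout = base * (2 ** d)
            for r in range(reps):
                names.append((f"enc{d}_{r}", cin, cout, 3))
                cin = cout
            enc_ch.append(cout)
        for d in range(depth - 2, -1, -1):
            cout = enc_ch[d]
            cin = cin + enc_ch[d]  # upsampled + skip
            for r in range(reps):
                names.append((f"dec{d}_{r}", cin, cout, 3))
                cin = cout
        names.append(("head", cin, N_CLASSES, 1))
        return names

    def _init_params(self, rng):
        for name, cin, cout, k in self._conv_names():
            fan_in = cin * k * k
            self.params[f"{name}_W"] = (
                rng.standard_normal((fan_in, cout)).astype(np.float32)
                * np.sqrt(2.0 / fan_in))
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward -------------------------------------------------
    def _forward(self, pixels: np.ndarray, need_cache: bool):
        cfg = self.config
        depth = cfg["depth"]
        reps = 2 if cfg["double_conv"] else 1
        x = pixels.astype(np.float32) / 255.0
        cache = []

        def conv_relu(name, x):
            y, cc = _conv_fwd(x, self.params[f"{name}_W"],
                              self.params[f"{name}_b"])
            a, m = _relu_fwd(y)
            if need_cache:
                cache.append(("conv_relu", name, cc, m))
            return a

        if cfg["stem_pool"] == 2:
            x, pc = _avgpool_fwd(x)
            if need_cache:
                cache.append(("stem", None, pc, None))
        skips = []
        for d in range(depth):
            if d > 0:
                x, pc = _maxpool_fwd(x)
                if need_cache:
                    cache.append(("pool", None, pc, None))
            for r in range(reps):
                x = conv_relu(f"enc{d}_{r}", x)
            skips.append(x)
        for d in range(depth - 2, -1, -1):
            x = _up2(x)
            skip = skips[d]
            x = np.concatenate([x, skip], axis=2)
            if need_cache:
                cache.append(("up_concat", None, skip.shape[2], None))
            for r in range(reps):
                x = conv_relu(f"dec{d}_{r}", x)
        logits, cc = _conv_fwd(x, self.params["head_W"], self.params["head_b"])
        if need_cache:
            cache.append(("head", "head", cc, None))
        return logits, cache

    def _backward(self, dlogits, cache):
        grads = {}
        cfg = self.config
        depth = cfg["depth"]
        reps = 2 if cfg["double_conv"] else 1
        it = list(cache)

        def pop():
            return it.pop()

        kind, name, cc, _ = pop()
        assert kind == "head"
        dx, dW, db = _conv_bwd(dlogits, self.params["head_W"], cc)
        grads["head_W"], grads["head_b"] = dW, db

        dskips = {}
        for d in range(0, depth - 1):
            for r in range(reps - 1, -1, -1):
                kind, name, cc, m = pop()
                dx = dx * m
                dx, dW, db = _conv_bwd(dx, self.params[f"{name}_W"], cc)
                grads[f"{name}_W"], grads[f"{name}_b"] = dW, db
            kind, _, skip_ch, _ = pop()
            assert kind == "up_concat"
            dskips[d] = dx[:, :, dx.shape[2] - skip_ch:]
            dx = _up2_bwd(dx[:, :, :dx.shape[2] - skip_ch])

        for d in range(depth - 1, -1, -1):
            if d in dskips:
                dx = dx + dskips[d]
            for r in range(reps - 1, -1, -1):
                kind, name, cc, m = pop()
                dx = dx * m
                dx, dW, db = _conv_bwd(dx, self.params[f"{name}_W"], cc)
                grads[f"{name}_W"], grads[f"{name}_b"] = dW, db
            if d > 0:
                kind, _, pc, _ = pop()
                assert kind == "pool"
                dx = _maxpool_bwd(dx, pc)
        return grads

    # -- public API ---------------------------------------------------------
    def logits(self, pixels: np.ndarray) -> np.ndarray:
        s = pixels.shape[0]
        stride = self.config["stem_pool"] * 2 ** (self.config["depth"] - 1)
        if s % stride or pixels.shape[0] != pixels.shape[1]:
            raise ValueError(
                f"image side must be a multiple of {stride}, got {pixels.shape}")
        logits, _ = self._forward(pixels, need_cache=False)
        return logits

    def segment(self, image) -> SegmentationMask:
        """Per-pixel argmax mask; deterministic, no state mutation."""
        pixels = image.pixels if isinstance(image, EncodedImage) else np.asarray(image)
        logits = self.logits(pixels)
        labels = np.argmax(logits, axis=2).astype(np.uint8)
        stem = self.config["stem_pool"]
        if stem > 1:
            labels = np.repeat(np.repeat(labels, stem, axis=0), stem, axis=1)
        return SegmentationMask(labels=labels)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps({"architecture": self.architecture,
                           "class_weights": self.class_weights.tolist()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(architecture=meta["architecture"],
                        class_weights=np.array(meta["class_weights"]))
            for k in z.files:
                if k != "__meta__":
                    model.params[k] = z[k]
        return model


# ---------------------------------------------------------------------------
# training


DEFAULT_HYPERPARAMS = dict(
    lr=2e-3, epochs=6, patience=2, crop=256, val_fraction=0.1,
    # Background dominates ~99% of pixels and the rarest class bands are a
    # single pixel tall; a high weight cap keeps them in the loss
    weight_clip=150.0,
)


def _class_weights(examples, clip):
    counts = np.zeros(N_CLASSES, dtype=np.float64)
    for ex in examples:
        counts += np.bincount(ex.truth_mask.labels.ravel(), minlength=N_CLASSES)
    freq = counts / max(counts.sum(), 1)
    w = 1.0 / np.maximum(freq, 1e-6)
    w = np.minimum(w / w[w > 0].min(), clip)
    return (w / w.mean()).astype(np.float32)


def _loss_and_grad(model, pixels, labels_ds, weights):
    logits, cache = model._forward(pixels, need_cache=True)
    h, w, c = logits.shape
    lf = logits.reshape(-1, c)
    lf = lf - lf.max(axis=1, keepdims=True)
    e = np.exp(lf)
    p = e / e.sum(axis=1, keepdims=True)
    y = labels_ds.ravel()
    wpix = weights[y]
    n = wpix.sum()
    loss = float((-np.log(np.maximum(p[np.arange(y.size), y], 1e-9)) * wpix).sum() / n)
    dl = p
    dl[np.arange(y.size), y] -= 1.0
    dl *= (wpix / n)[:, None]
    grads = model._backward(dl.reshape(h, w, c).astype(np.float32), cache)
    return loss, grads


def _random_crop(rng, pixels, labels, crop):
    s = pixels.shape[0]
    if s <= crop:
        return pixels, labels
    sv = np.argwhere(np.isin(labels, SV_CLASSES))
    if len(sv):
        cy, cx = sv[rng.integers(len(sv))]
    else:
        cy, cx = rng.integers(s), rng.integers(s)
    jitter = crop // 4
    y0 = int(np.clip(cy - crop // 2 + rng.integers(-jitter, jitter + 1),
                     0, s - crop))
    x0 = int(np.clip(cx - crop // 2 + rng.integers(-jitter, jitter + 1),
                     0, s - crop))
    y0 = (y0 // 32) * 32
    x0 = (x0 // 32) * 32
    return pixels[y0:y0 + crop, x0:x0 + crop], labels[y0:y0 + crop, x0:x0 + crop]


def pixel_accuracy(model, examples) -> float:
    correct = total = 0
    for ex in examples:
        pred = model.segment(ex.pixels).labels
        truth = ex.truth_mask.labels
        correct += int((pred == truth).sum())
        total += truth.size
    return correct / max(total, 1)


def train_model(examples: List[TrainingExample], architecture: str = "lite_unet",
                hyperparams: Optional[dict] = None, seed: int = 0,
                verbose: bool = False):
    """Train a segmentation model on simulated examples.

    Raises ``ValueError`` when the training set is empty or an SV class is
    entirely absent.  Returns ``(model, history)`` where history records the
    per-epoch mean loss and held-out pixel accuracy.  Training is
    deterministic given (examples, hyperparams, seed).
    """
    if not examples:
        raise ValueError("empty training set")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    present = set()
    for ex in examples:
        present.update(np.unique(ex.truth_mask.labels).tolist())
    missing = [CLASS_NAMES[c] for c in SV_CLASSES if c not in present]
    if missing:
        raise ValueError(f"training set lacks SV classes: {', '.join(missing)}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    n_val = max(1, int(round(hp["val_fraction"] * len(examples)))) \
        if len(examples) > 1 else 0
    val = [examples[i] for i in order[:n_val]]
    train = [examples[i] for i in order[n_val:]] or list(examples)

    weights = _class_weights(train, hp["weight_clip"])
    model = SegmentationModel(architecture, seed=seed, class_weights=weights)
    stem = model.config["stem_pool"]

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history = []
    best_acc, best_params, bad_epochs = -1.0, None, 0

    for epoch in range(hp["epochs"]):
        idx = rng.permutation(len(train))
        losses = []
        for i in idx:
            ex = train[i]
            pix, lab = _random_crop(rng, ex.pixels, ex.truth_mask.labels,
                                    hp["crop"])
            lab_ds = downsample_labels(lab, stem)
            loss, grads = _loss_and_grad(model, pix, lab_ds, weights)
            losses.append(loss)
            t += 1
            lr_t = hp["lr"] * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
            for k, g in grads.items():
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                model.params[k] -= (lr_t * m_state[k]
                                    / (np.sqrt(v_state[k]) + eps)).astype(np.float32)
        acc = pixel_accuracy(model, val) if val else float("nan")
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_pixel_accuracy": acc})
        if verbose:
            print(f"epoch {epoch}: loss={np.mean(losses):.4f} val_acc={acc:.4f}")
        if val:
            if acc > best_acc:
                best_acc, bad_epochs = acc, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                bad_epochs += 1
                if bad_epochs > hp["patience"]:
                    break
    if best_params is not None:
        model.params = best_params
    return model, history
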