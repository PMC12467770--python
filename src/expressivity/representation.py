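"""Desk-scale image classifiers and layer-wise feature harvesting.

Two backbone families mirror the architectures whose representations the
expressivity analysis probes:

* ``conv`` — a small strided convolutional network trained end-to-end with
  binary cross-entropy, with a fully connected head (128 -> 64 -> 1, ReLU,
  dropout 0.3) on the globally average-pooled feature vector;
* ``transformer`` — a frozen ViT-style encoder (patch embedding, pre-LN
  blocks with multi-head self-attention, a class token) whose MLP head on
  the [CLS] representation is the only trainable part.

Feature taps at early/mid/final depth return one vector per image:
convolutional taps are reduced by global average pooling, transformer taps
return the class-token vector at that block. Extraction always runs in
evaluation mode (dropout off), so repeated calls are bit-identical.

Grayscale images are replicated to 3 channels and normalized with the
ImageNet channel statistics before entering either backbone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from ._nn import MLP, Adam, Conv2d, Param, relu
from .mine import FeatureMatrix

__all__ = [
    "BackboneConfig",
    "LayerTag",
    "TrainRunConfig",
    "build_backbone",
    "train_classifier",
    "extract_features",
    "predict_proba",
    "preprocess_images",
]

_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_STD = np.array([0.229, 0.224, 0.225])


def preprocess_images(images: np.ndarray) -> np.ndarray:
    """(n, H, W) grayscale in [0,1] -> (n, 3, H, W) ImageNet-normalized."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ValueError("expected a (n, H, W) grayscale stack")
    x = np.repeat(images[:, None, :, :], 3, axis=1)
    return (x - _IMAGENET_MEAN[:, None, None]) / _IMAGENET_STD[:, None, None]


@dataclass
class BackboneConfig:
    """Family and sizing of a classifier backbone.

    The defaults are the desk-scale variants used throughout the test
    suite (64x64 inputs); ``input_size=256`` with wider channel/embedding
    settings gives full-size counterparts. ``freeze_encoder`` applies to
    the transformer family, whose encoder is always kept frozen (the
    training loop fits only the head); an unfrozen transformer is not
    supported.
    """

    family: str = "conv"
    input_size: int = 64
    conv_channels: tuple[int, ...] = (16, 32, 64)
    conv_blocks: int = 1            # convs per stage (first strided, rest 1:1)
    conv_head: tuple[int, ...] = (128, 64)
    dropout: float = 0.3
    vit_embed_dim: int = 64
    vit_depth: int = 4
    vit_heads: int = 4
    vit_patch: int = 8
    vit_head: tuple[int, ...] = (128,)
    freeze_encoder: bool = True
    weights_path: str | None = None

    def __post_init__(self):
        if self.family not in ("conv", "transformer"):
            raise ValueError(f"unknown backbone family {self.family!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.family == "transformer":
            if self.input_size % self.vit_patch:
                raise ValueError("input_size must be divisible by vit_patch")
            if self.vit_embed_dim % self.vit_heads:
                raise ValueError("vit_embed_dim must be divisible by vit_heads")
            if not self.freeze_encoder:
                raise ValueError(
                    "transformer backbones are supported only with a frozen "
                    "encoder (head-only training)")


@dataclass(frozen=True)
class LayerTag:
    """A named tap into the forward pass.

    ``stage`` is 'early', 'mid' or 'final'; ``pooling`` is 'gap' for
    convolutional taps and 'cls' (class token) or 'tokens_mean' for
    transformer taps ('auto' picks the family default).
    """

    stage: str
    pooling: str = "auto"

    def __post_init__(self):
        if self.stage not in ("early", "mid", "final"):
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class TrainRunConfig:
    """Classifier optimization settings (binary cross-entropy throughout).

    The conv default learning rate 1e-3 suits from-scratch training of the
    desk-scale network; fine-tuning a pretrained full-size network would
    use 1e-4 (set explicitly). The head-only (transformer) schedule is a
    linear warmup followed by cosine decay.
    """

    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    schedule: str = "constant"          # or "warmup_cosine"
    warmup_frac: float = 0.05
    early_stop_patience: int | None = None  # epochs without val-AUROC gain

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE loss and its gradient wrt the logits."""
    z = logits.ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / z.size
    return loss, grad


# ---------------------------------------------------------------------------
# Convolutional backbone
# ---------------------------------------------------------------------------

class ConvBackbone:
    """Strided 3x3 conv stages -> GAP -> MLP head -> 1 logit."""

    family = "conv"

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
        chans = [3, *cfg.conv_channels]
        self.convs = []
        self.stage_of = []  # index of the stage each conv belongs to
        for s, (a, b) in enumerate(zip(chans[:-1], chans[1:])):
            self.convs.append(Conv2d(rng, a, b, stride=2))
            self.stage_of.append(s)
            for _ in range(cfg.conv_blocks - 1):
                self.convs.append(Conv2d(rng, b, b, stride=1))
                self.stage_of.append(s)
        self.head = MLP(rng, cfg.conv_channels[-1], cfg.conv_head, 1,
                        activation="relu", init="he", dropout=cfg.dropout)
        self._relu_masks = None
        self._gap_hw = None

    # -- parameters ---------------------------------------------------------
    def params(self):
        return [p for c in self.convs for p in c.params()] + self.head.params()

    def trainable_params(self):
        return self.params()

    def state(self):
        return [p.value.copy() for p in self.params()]

    def load_state(self, state):
        for p, v in zip(self.params(), state):
            p.value[...] = v

    # -- forward / backward -------------------------------------------------
    def _stages(self, x, cache):
        outs = []
        masks = []
        h = x
        for conv in self.convs:
            z = conv.forward(h, cache=cache)
            mask = z > 0.0
            h = z * mask
            outs.append(h)
            masks.append(mask)
        return outs, masks

    def forward_train(self, x, rng):
        outs, self._relu_masks = self._stages(x, cache=True)
        h = outs[-1]
        self._gap_hw = h.shape[2] * h.shape[3]
        pooled = h.mean(axis=(2, 3))
        return self.head.forward(pooled, train=True, rng=rng)

    def backward(self, gl):
        g = self.head.backward(gl)
        n, c = g.shape
        h = self._relu_masks[-1].shape
        gsp = np.broadcast_to(g[:, :, None, None] / self._gap_hw,
                              (n, c, h[2], h[3])).copy()
        for conv, mask in zip(reversed(self.convs), reversed(self._relu_masks)):
            gsp = conv.backward(gsp * mask)
        return gsp

    # -- inference ----------------------------------------------------------
    def predict_logits(self, x, batch=256):
        out = []
        for s in range(0, x.shape[0], batch):
            outs, _ = self._stages(x[s:s + batch], cache=False)
            pooled = outs[-1].mean(axis=(2, 3))
            out.append(self.head.forward(pooled, train=False, cache=False).ravel())
        return np.concatenate(out)

    def available_tags(self):
        return ["early", "mid", "final"]

    def features(self, x, tag: LayerTag, batch=256):
        n_stages = len(self.cfg.conv_channels)
        stage = {"early": 0,
                 "mid": max(1, n_stages // 2),
                 "final": n_stages - 1}[tag.stage]
        conv_idx = max(i for i, s in enumerate(self.stage_of) if s == stage)
        if tag.pooling not in ("auto", "gap"):
            raise ValueError(f"conv taps support 'gap' pooling, not {tag.pooling!r}")
        out = []
        for s in range(0, x.shape[0], batch):
            outs, _ = self._stages(x[s:s + batch], cache=False)
            out.append(outs[conv_idx].mean(axis=(2, 3)))
        return np.vstack(out)


# ---------------------------------------------------------------------------
# Frozen transformer backbone
# ---------------------------------------------------------------------------

def _layernorm(x, g, b, eps=1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def _gelu(x):
    return 0.5 * x * (1.0 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x ** 3)))


def _softmax(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class ViTBackbone:
    """Frozen pre-LN ViT encoder + trainable MLP head on the class token.

    Encoder weights are randomly initialized (seeded) unless a weights
    file is supplied; they never receive gradients. Class-token vectors
    from the frozen encoder are cached per image stack, so head training
    pays the encoder forward cost once.
    """

    family = "transformer"

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x717]))
        D, P = cfg.vit_embed_dim, cfg.vit_patch
        n_patch = (cfg.input_size // P) ** 2
        s = 0.02
        w = {"patch": rng.normal(0, s, (P * P * 3, D)),
             "patch_b": np.zeros(D),
             "cls": rng.normal(0, s, (1, 1, D)),
             "pos": rng.normal(0, s, (1, n_patch + 1, D)),
             "ln_f": (np.ones(D), np.zeros(D))}
        blocks = []
        for _ in range(cfg.vit_depth):
            blocks.append({
                "ln1": (np.ones(D), np.zeros(D)),
                "qkv": rng.normal(0, s, (D, 3 * D)),
                "proj": rng.normal(0, s, (D, D)) + np.eye(D) * 0.5,
                "ln2": (np.ones(D), np.zeros(D)),
                "fc1": rng.normal(0, np.sqrt(2.0 / D), (D, 4 * D)),
                "fc1_b": np.zeros(4 * D),
                "fc2": rng.normal(0, np.sqrt(1.0 / (4 * D)), (4 * D, D)),
                "fc2_b": np.zeros(D),
            })
        self.encoder = w
        self.blocks = blocks
        self.head = MLP(rng, D, cfg.vit_head, 1, activation="relu", init="he",
                        dropout=0.0)
        self._cls_cache: dict[int, np.ndarray] = {}

    # -- parameters ---------------------------------------------------------
    def encoder_state(self):
        flat = [self.encoder["patch"], self.encoder["patch_b"],
                self.encoder["cls"], self.encoder["pos"], *self.encoder["ln_f"]]
        for blk in self.blocks:
            flat += [*blk["ln1"], blk["qkv"], blk["proj"], *blk["ln2"],
                     blk["fc1"], blk["fc1_b"], blk["fc2"], blk["fc2_b"]]
        return [a.copy() for a in flat]

    def trainable_params(self):
        return self.head.params()

    def params(self):
        return self.head.params()

    def state(self):
        return [p.value.copy() for p in self.head.params()]

    def load_state(self, state):
        for p, v in zip(self.head.params(), state):
            p.value[...] = v

    # -- frozen encoder forward --------------------------------------------
    def _patchify(self, x):
        n, c, h, w = x.shape
        p = self.cfg.vit_patch
        x = x.reshape(n, c, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(n, (h // p) * (w // p), c * p * p)
        return x

    def _attention(self, h, blk):
        n, t, D = h.shape
        nh = self.cfg.vit_heads
        dh = D // nh
        qkv = h @ blk["qkv"]
        q, k, v = np.split(qkv, 3, axis=-1)

        def heads(a):
            return a.reshape(n, t, nh, dh).transpose(0, 2, 1, 3)
        q, k, v = heads(q), heads(k), heads(v)
        att = _softmax(q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh))
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, t, D)
        return out @ blk["proj"]

    def encode(self, x):
        """Forward the frozen encoder; return per-stage pooled vectors."""
        n = x.shape[0]
        tok = self._patchify(x) @ self.encoder["patch"] + self.encoder["patch_b"]
        cls = np.broadcast_to(self.encoder["cls"], (n, 1, tok.shape[2]))
        h = np.concatenate([cls, tok], axis=1) + self.encoder["pos"]
        L = len(self.blocks)
        stage_at = {max(1, int(np.ceil(L / 6))) - 1: "early",
                    max(1, int(np.ceil(L / 2))) - 1: "mid",
                    L - 1: "final"}
        got = {}
        for i, blk in enumerate(self.blocks):
            h = h + self._attention(_layernorm(h, *blk["ln1"]), blk)
            m = _gelu(_layernorm(h, *blk["ln2"]) @ blk["fc1"] + blk["fc1_b"])
            h = h + m @ blk["fc2"] + blk["fc2_b"]
            if i in stage_at:
                hn = _layernorm(h, *self.encoder["ln_f"])
                got[stage_at[i]] = {"cls": hn[:, 0, :],
                                    "tokens_mean": hn[:, 1:, :].mean(axis=1)}
        return got

    def _cls_final(self, x, batch=256):
        key = (id(x), x.shape[0])
        if key not in self._cls_cache:
            parts = [self.encode(x[s:s + batch])["final"]["cls"]
                     for s in range(0, x.shape[0], batch)]
            self._cls_cache = {key: np.vstack(parts)}  # keep one stack only
        return self._cls_cache[key]

    # -- training-facing API ------------------------------------------------
    def forward_train(self, x, rng):
        return self.head.forward(self._cls_final(x), train=True, rng=rng)

    def backward(self, gl):
        return self.head.backward(gl)

    def predict_logits(self, x, batch=256):
        return self.head.forward(self._cls_final(x, batch), train=False,
                                 cache=False).ravel()

    def available_tags(self):
        return ["early", "mid", "final"]

    def features(self, x, tag: LayerTag, batch=256):
        pooling = "cls" if tag.pooling == "auto" else tag.pooling
        if pooling not in ("cls", "tokens_mean"):
            raise ValueError(f"transformer taps support 'cls' or 'tokens_mean', "
                             f"not {tag.pooling!r}")
        parts = []
        for s in range(0, x.shape[0], batch):
            parts.append(self.encode(x[s:s + batch])[tag.stage][pooling])
        return np.vstack(parts)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_backbone(cfg: BackboneConfig, seed: int = 0):
    """Construct a backbone with deterministic seeded initialization.

    ``cfg.weights_path`` optionally points to an ``.npz`` of parameters
    saved by ``save_weights`` (externally pretrained encoders enter here).
    """
    if cfg.family == "conv":
        model = ConvBackbone(cfg, seed)
    else:
        model = ViTBackbone(cfg, seed)
    if cfg.weights_path:
        load_weights(model, cfg.weights_path)
    return model


def save_weights(model, path):
    np.savez(path, **{f"p{i}": p.value for i, p in enumerate(model.params())})


def load_weights(model, path):
    data = np.load(path)
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]


def _lr_at(cfg: TrainRunConfig, step: int, total: int) -> float:
    if cfg.schedule == "constant":
        return cfg.learning_rate
    warm = max(1, int(cfg.warmup_frac * total))
    if step < warm:
        return cfg.learning_rate * (step + 1) / warm
    t = (step - warm) / max(1, total - warm)
    return cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * t))


def train_classifier(model, train_set, val_set, run_cfg: TrainRunConfig | None = None):
    """Fit with BCE; return (model restored to best-val-AUROC epoch, history).

    ``train_set``/``val_set`` are (images, labels) with grayscale image
    stacks; labels must contain both classes. History records per-epoch
    mean training loss and validation AUROC.
    """
    cfg = run_cfg or TrainRunConfig()
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    y_tr = np.asarray(y_tr, dtype=np.float64).ravel()
    y_va = np.asarray(y_va, dtype=np.float64).ravel()
    if y_va.size == 0:
        raise ValueError("validation set must be non-empty")
    for name, y in (("training", y_tr), ("validation", y_va)):
        if np.unique(y).size < 2:
            raise ValueError(f"{name} labels contain a single class; "
                             "BCE evaluation is degenerate")
    xt = preprocess_images(x_tr)
    xv = preprocess_images(x_va)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7e]))
    opt = Adam(model.trainable_params(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    n = xt.shape[0]
    steps_per_epoch = max(1, n // cfg.batch_size)
    total_steps = steps_per_epoch * cfg.epochs
    history = []
    best_auroc, best_state, stale = -np.inf, model.state(), 0
    step = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = perm[s:s + cfg.batch_size]
            if idx.size < 2:
                continue
            logits = model.forward_train(xt[idx], rng)
            loss, gz = _bce_with_logits(logits, y_tr[idx])
            opt.zero_grad()
            model.backward(gz[:, None])
            opt.step(lr=_lr_at(cfg, step, total_steps))
            losses.append(loss)
            step += 1
        val_auroc = float(roc_auc_score(y_va, model.predict_logits(xv)))
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_auroc": val_auroc})
        if val_auroc > best_auroc:
            best_auroc, best_state, stale = val_auroc, model.state(), 0
        else:
            stale += 1
            if cfg.early_stop_patience and stale >= cfg.early_stop_patience:
                break
    model.load_state(best_state)
    return model, history


def extract_features(model, images: np.ndarray, tag: LayerTag | str) -> FeatureMatrix:
    """Layer-tap features, one row per image, in input order.

    Runs in evaluation mode (no dropout), so repeated calls on the same
    inputs are bit-identical. Zero-variance columns (e.g. from constant
    inputs) are detectable via ``FeatureMatrix.zero_variance_columns``.
    """
    if isinstance(tag, str):
        tag = LayerTag(stage=tag)
    if tag.stage not in model.available_tags():
        raise ValueError(f"unresolvable tag {tag.stage!r}; "
                         f"available: {model.available_tags()}")
    x = preprocess_images(images)
    values = model.features(x, tag)
    return FeatureMatrix(values, layer_tag=f"{model.family}/{tag.stage}")


def predict_proba(model, images: np.ndarray) -> np.ndarray:
    """Sigmoid class-1 probabilities, strictly inside (0, 1)."""
    logits = model.predict_logits(preprocess_images(images))
    return 1.0 / (1.0 + np.exp(-logits))
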