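"""Two-branch pathology-aware multi-label fundus classifier.

The network carries a *pathology branch* and a *disease branch*, each a
convolutional encoder producing a feature volume (C, H, W). The pathology
features F_p gate themselves through a channel-attention map

    w = sigmoid(relu(W @ gap(F_p) + b)),           w in [0.5, 1)

are selected channel-wise (Hadamard product), and are fused into the
disease features by element-wise addition:

    F_e = (F_p o w) + F_d.

A pathology head classifies fundus features from F_p; the disease head
classifies diseases from F_e. Routing the disease decision through
pathological evidence -- which is largely independent of patient sex and
age -- is what mitigates group disparities ("implicit fairness
learning"), without any explicit fairness regulariser.

The attention range [0.5, 1) is a direct consequence of composing ReLU
(non-negative output) with the sigmoid; it is asserted in the tests.

The reference recipe in the literature uses two ImageNet-pretrained
ResNet-101 encoders; this package ships a compact, width-configurable
convolutional encoder family suited to desk-scale experiments and exact
numerical testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Linear,
    Param,
    ReLU,
    global_avg_pool,
    sigmoid,
)

__all__ = [
    "FeatureVolume",
    "AttentionParams",
    "ModelConfig",
    "channel_attention",
    "select_pathology",
    "fuse",
    "TinyEncoder",
    "PathologyAwareNet",
    "BaselineNet",
]

# A feature volume is a (C, H, W) or batched (N, C, H, W) float array.
FeatureVolume = np.ndarray


@dataclass
class AttentionParams:
    """Affine parameters of the channel-attention map."""

    weight: np.ndarray  # (C, C)
    bias: np.ndarray  # (C,)

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        c = self.bias.shape[0]
        if self.weight.shape != (c, c):
            raise ValueError(
                f"attention weight must be square ({c}x{c}), got {self.weight.shape}"
            )


@dataclass
class ModelConfig:
    """Architecture configuration shared by both branches."""

    n_diseases: int
    n_features: int
    image_size: tuple[int, int] = (64, 80)
    in_channels: int = 3
    backbone: str = "tiny"
    channels: tuple[int, ...] = (8, 16, 16)
    kernels: tuple[int, ...] = (3, 3, 3)
    strides: tuple[int, ...] = (2, 2, 2)
    spatial_attention: bool = False
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_features < 1:
            raise ValueError("class counts must be >= 1")
        if self.backbone != "tiny":
            raise ValueError(
                f"unsupported backbone {self.backbone!r}; this build provides "
                "the compact convolutional encoder family ('tiny')"
            )
        if not (len(self.channels) == len(self.kernels) == len(self.strides)):
            raise ValueError("channels/kernels/strides must have equal length")

    @property
    def feature_channels(self) -> int:
        return self.channels[-1]

    def to_dict(self) -> dict:
        return {
            "n_diseases": self.n_diseases,
            "n_features": self.n_features,
            "image_size": list(self.image_size),
            "in_channels": self.in_channels,
            "backbone": self.backbone,
            "channels": list(self.channels),
            "kernels": list(self.kernels),
            "strides": list(self.strides),
            "spatial_attention": self.spatial_attention,
            "batch_norm": self.batch_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("image_size", "channels", "kernels", "strides"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# functional attention/fusion ops (single volume or batched)


def _as_batched(vol: FeatureVolume) -> tuple[np.ndarray, bool]:
    vol = np.asarray(vol, dtype=float)
    if vol.ndim == 3:
        return vol[None], True
    if vol.ndim == 4:
        return vol, False
    raise ValueError(f"feature volume must be (C,H,W) or (N,C,H,W), got {vol.shape}")


def channel_attention(f_p: FeatureVolume, params: AttentionParams) -> np.ndarray:
    """Channel-attention weights sigmoid(relu(W . gap(F_p) + b)).

    Returns a length-C vector (or (N, C) for a batched volume); every
    component lies in [0.5, 1) because the ReLU output is non-negative.
    """
    vol, squeeze = _as_batched(f_p)
    c = vol.shape[1]
    if params.bias.shape[0] != c:
        raise ValueError(
            f"attention params for C={params.bias.shape[0]} applied to a "
            f"volume with C={c} (shape {np.asarray(f_p).shape})"
        )
    f_avg = global_avg_pool(vol)  # (N, C)
    z = f_avg @ params.weight.T + params.bias
    w = sigmoid(np.maximum(z, 0.0))
    return w[0] if squeeze else w


def select_pathology(f_p: FeatureVolume, w: np.ndarray) -> FeatureVolume:
    """Channel-wise Hadamard selection F_p o w, broadcast over H x W."""
    vol, squeeze = _as_batched(f_p)
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        w = w[None]
    if w.shape[1] != vol.shape[1]:
        raise ValueError(
            f"attention vector length {w.shape[1]} != channel count {vol.shape[1]}"
        )
    out = vol * w[:, :, None, None]
    return out[0] if squeeze else out


def fuse(f_sel: FeatureVolume, f_d: FeatureVolume) -> FeatureVolume:
    """Element-wise sum of the selected pathology and disease volumes."""
    a = np.asarray(f_sel, dtype=float)
    b = np.asarray(f_d, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"cannot fuse volumes with shapes {a.shape} and {b.shape}")
    return a + b


# ---------------------------------------------------------------------------
# encoders and networks


class TinyEncoder:
    """Compact strided conv stack: (N, 3, H, W) -> (N, C, H', W')."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator, name: str):
        self.layers: list = []
        self._bns: list[BatchNorm2d] = []
        c_prev = config.in_channels
        for i, (c, k, s) in enumerate(zip(config.channels, config.kernels, config.strides)):
            self.layers.append(
                Conv2d(c_prev, c, kernel=k, stride=s, padding=k // 2, rng=rng, name=f"{name}.conv{i}")
            )
            if config.batch_norm:
                bn = BatchNorm2d(c, name=f"{name}.bn{i}")
                self.layers.append(bn)
                self._bns.append(bn)
            self.layers.append(ReLU())
            c_prev = c

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def set_mode(self, training: bool) -> None:
        for bn in self._bns:
            bn.training = training

    def extra_state(self) -> dict[str, np.ndarray]:
        out = {}
        for bn in self._bns:
            out[f"{bn.gamma.name[:-6]}.running_mean"] = bn.running_mean
            out[f"{bn.gamma.name[:-6]}.running_var"] = bn.running_var
        return out

    def load_extra_state(self, arrays: dict[str, np.ndarray]) -> None:
        for bn in self._bns:
            base = bn.gamma.name[:-6]
            bn.running_mean = np.array(arrays[f"{base}.running_mean"])
            bn.running_var = np.array(arrays[f"{base}.running_var"])

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class _SpatialGate:
    """CBAM-style spatial gate: sigmoid(conv([mean_C; max_C])) o F."""

    def __init__(self, rng: np.random.Generator, kernel: int = 5, name: str = "spatial"):
        self.conv = Conv2d(2, 1, kernel=kernel, stride=1, padding=kernel // 2, rng=rng, name=name)
        self._cache: tuple | None = None

    def forward(self, f: np.ndarray) -> np.ndarray:
        mean_c = f.mean(axis=1, keepdims=True)
        argmax = f.argmax(axis=1)
        max_c = f.max(axis=1, keepdims=True)
        pooled = np.concatenate([mean_c, max_c], axis=1)
        s = sigmoid(self.conv.forward(pooled))  # (N, 1, H, W)
        self._cache = (f, s, argmax)
        return f * s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f, s, argmax = self._cache
        n, c, h, w = f.shape
        df = grad * s
        ds = (grad * f).sum(axis=1, keepdims=True)
        dz = ds * s * (1 - s)
        dpooled = self.conv.backward(dz)
        df += dpooled[:, :1] / c  # mean path
        dmax = dpooled[:, 1]  # (N, H, W) -> scatter to argmax channel
        ni, hi, wi = np.meshgrid(
            np.arange(n), np.arange(h), np.arange(w), indexing="ij"
        )
        np.add.at(df, (ni, argmax, hi, wi), dmax)
        return df

    def params(self) -> list[Param]:
        return self.conv.params()


class PathologyAwareNet:
    """Two-branch network with pathology-aware channel attention."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        c = config.feature_channels
        self.encoder_p = TinyEncoder(config, rng, "encoder_p")
        self.encoder_d = TinyEncoder(config, rng, "encoder_d")
        self.attention = Linear(c, c, rng, "attention")
        self.spatial = _SpatialGate(rng) if config.spatial_attention else None
        self.head_p = Linear(c, config.n_features, rng, "head_p")
        self.head_d = Linear(c, config.n_diseases, rng, "head_d")
        self._cache: dict | None = None

    # -- forward -----------------------------------------------------------

    def attention_params(self) -> AttentionParams:
        return AttentionParams(weight=self.attention.W.value, bias=self.attention.b.value)

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Run both branches; returns logits and feature volumes.

        Keys: ``patho_logits`` (N, n_features), ``disease_logits``
        (N, n_diseases), ``F_p``, ``F_d``, ``F_e`` feature volumes and the
        channel-attention weights ``w``.
        """
        x = np.asarray(x, dtype=np.float64)
        f_p = self.encoder_p.forward(x)
        f_d = self.encoder_d.forward(x)
        n, c, h, w_ = f_p.shape
        a = global_avg_pool(f_p)
        z = self.attention.forward(a)
        r = np.maximum(z, 0.0)
        w = sigmoid(r)
        f_sel = f_p * w[:, :, None, None]
        if self.spatial is not None:
            f_sel = self.spatial.forward(f_sel)
        f_e = f_sel + f_d
        e = global_avg_pool(f_e)
        patho_logits = self.head_p.forward(a)
        disease_logits = self.head_d.forward(e)
        self._cache = {"f_p": f_p, "f_d": f_d, "a": a, "z": z, "w": w, "hw": (h, w_)}
        return {
            "patho_logits": patho_logits,
            "disease_logits": disease_logits,
            "F_p": f_p,
            "F_d": f_d,
            "F_e": f_e,
            "w": w,
        }

    # -- backward ----------------------------------------------------------

    def backward(
        self,
        d_patho_logits: np.ndarray,
        d_disease_logits: np.ndarray,
        d_f_p: np.ndarray | None = None,
        d_f_d: np.ndarray | None = None,
    ) -> None:
        """Accumulate parameter gradients for the cached forward pass.

        ``d_f_p`` / ``d_f_d`` carry extra gradient flowing directly into
        the feature volumes (the feature-consistency loss).
        """
        cache = self._cache
        f_p, w, a, z = cache["f_p"], cache["w"], cache["a"], cache["z"]
        h, w_sp = cache["hw"]
        hw = h * w_sp

        de = self.head_d.backward(d_disease_logits)  # (N, C)
        d_f_e = np.broadcast_to(de[:, :, None, None] / hw, f_p.shape).copy()
        d_f_sel = d_f_e.copy()
        d_fd_total = d_f_e.copy()
        if d_f_d is not None:
            d_fd_total += d_f_d
        if self.spatial is not None:
            d_f_sel = self.spatial.backward(d_f_sel)
        d_fp_total = d_f_sel * w[:, :, None, None]
        if d_f_p is not None:
            d_fp_total = d_fp_total + d_f_p
        dw = (d_f_sel * f_p).sum(axis=(2, 3))
        dr = dw * w * (1 - w)
        dz = np.where(z > 0, dr, 0.0)
        da = self.attention.backward(dz)
        da = da + self.head_p.backward(d_patho_logits)
        d_fp_total = d_fp_total + da[:, :, None, None] / hw
        self.encoder_p.backward(d_fp_total)
        self.encoder_d.backward(d_fd_total)

    def params(self) -> list[Param]:
        out = (
            self.encoder_p.params()
            + self.encoder_d.params()
            + self.attention.params()
            + self.head_p.params()
            + self.head_d.params()
        )
        if self.spatial is not None:
            out += self.spatial.params()
        return out

    def set_mode(self, training: bool) -> None:
        self.encoder_p.set_mode(training)
        self.encoder_d.set_mode(training)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {p.name: p.value for p in self.params()}
        out.update(self.encoder_p.extra_state())
        out.update(self.encoder_d.extra_state())
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = arrays[p.name]
        self.encoder_p.load_extra_state(arrays)
        self.encoder_d.load_extra_state(arrays)


class BaselineNet:
    """Single-branch disease classifier: encoder + affine head.

    The fairness comparator: no pathology branch, no attention, trained
    on disease labels alone.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = TinyEncoder(config, rng, "encoder")
        self.head = Linear(config.feature_channels, config.n_diseases, rng, "head")
        self._hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(x, dtype=np.float64)
        f = self.encoder.forward(x)
        self._hw = f.shape[2:]
        return {"disease_logits": self.head.forward(global_avg_pool(f)), "F_d": f}

    def backward(self, d_disease_logits: np.ndarray) -> None:
        de = self.head.backward(d_disease_logits)
        h, w = self._hw
        grad = np.broadcast_to(
            de[:, :, None, None] / (h * w), de.shape + (h, w)
        ).copy()
        self.encoder.backward(grad)

    def params(self) -> list[Param]:
        return self.encoder.params() + self.head.params()

    def set_mode(self, training: bool) -> None:
        self.encoder.set_mode(training)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {p.name: p.value for p in self.params()}
        out.update(self.encoder.extra_state())
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = arrays[p.name]
        self.encoder.load_extra_state(arrays)
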