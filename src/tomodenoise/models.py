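"""Small 3D denoiser backbones in pure numpy: U-Net and mixed-scale dense net.

Both models map a single-channel ``(d, h, w)`` volume to a same-shape output
and carry hand-written forward/backward passes over batched
``(batch, channels, d, h, w)`` arrays, so the training loop needs no
autodiff framework. The mixed-scale dense network (MS-D) replaces the
U-Net's down/up-sampling with dilated 3×3×3 convolutions whose dilation
cycles through a fixed list, and densely connects every layer to all later
layers — which is why it reaches comparable receptive fields with orders of
magnitude fewer trainable parameters than a U-Net.

Weight initialization is He-style and fully determined by ``config.seed``;
evaluation is deterministic (no dropout or noise at inference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Volume3D

__all__ = [
    "ModelConfig",
    "MSDNet3D",
    "UNet3D",
    "build_model",
    "apply_model",
    "count_parameters",
    "save_model",
    "load_model",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture selection and hyperparameters.

    U-Net: ``depth`` down-sampling steps (resolution scales = depth + 1),
    ``base_channels`` at full resolution doubling per scale, two 3³ convs
    per scale, max-pool down / transposed-conv up, ReLU, no normalization.
    Input sides must be divisible by ``2**depth``.

    MS-D: ``depth`` dilated 3³ conv layers of ``width`` channels each, dense
    connections, dilations cycling through ``dilations`` (default 1…10), and
    a final 1³ linear projection. Any input side ≥ 1 works.
    """

    arch: str = "msdnet3d"
    unet: dict = field(default_factory=lambda: {"depth": 3, "base_channels": 64})
    msd: dict = field(default_factory=lambda: {"depth": 10, "width": 1,
                                               "dilations": list(range(1, 11))})
    seed: int = 0
    dtype: str = "float32"

    def to_dict(self) -> dict:
        return {"arch": self.arch, "unet": dict(self.unet), "msd": dict(self.msd),
                "seed": self.seed, "dtype": self.dtype}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(arch=d.get("arch", "msdnet3d"), unet=dict(d.get("unet", {})),
                   msd=dict(d.get("msd", {})), seed=int(d.get("seed", 0)),
                   dtype=d.get("dtype", "float32"))


# --------------------------------------------------------------------------
# primitive layers (batched channel-first arrays: (B, C, D, H, W))
# --------------------------------------------------------------------------

_SPATIAL_PAD = ((0, 0), (0, 0))


def _tap_matmul(w_tap: np.ndarray, view: np.ndarray) -> np.ndarray:
    """(O, C) x (B, C, D, H, W) -> (B, O, D, H, W), batched matmul."""
    b, c = view.shape[:2]
    out = np.matmul(w_tap, view.reshape(b, c, -1))
    return out.reshape(b, w_tap.shape[0], *view.shape[2:])


def _tap_outer(gout: np.ndarray, view: np.ndarray) -> np.ndarray:
    """Σ_batch gout_b @ view_b^T : (B,O,...) x (B,C,...) -> (O, C)."""
    b, o = gout.shape[:2]
    c = view.shape[1]
    return np.matmul(gout.reshape(b, o, -1),
                     view.reshape(b, c, -1).transpose(0, 2, 1)).sum(axis=0)


def _conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
            dilation: int) -> np.ndarray:
    """Same-padded 3×3×3 convolution; x (B,C,D,H,W), w (O,C,3,3,3)."""
    _, _, d_, h_, w_ = x.shape
    p = dilation
    xp = np.pad(x, _SPATIAL_PAD + ((p, p), (p, p), (p, p)))
    out = None
    for i in range(3):
        for j in range(3):
            for k in range(3):
                view = xp[:, :, i * p:i * p + d_, j * p:j * p + h_, k * p:k * p + w_]
                piece = _tap_matmul(w[:, :, i, j, k], view)
                out = piece if out is None else out + piece
    if b is not None:
        out += b[None, :, None, None, None]
    return out


def _conv3d_grad(x: np.ndarray, w: np.ndarray, gout: np.ndarray, dilation: int):
    """Gradients of :func:`_conv3d` w.r.t. input, weight and bias."""
    _, _, d_, h_, w_ = x.shape
    p = dilation
    xp = np.pad(x, _SPATIAL_PAD + ((p, p), (p, p), (p, p)))
    gp = np.pad(gout, _SPATIAL_PAD + ((p, p), (p, p), (p, p)))
    gw = np.empty_like(w)
    gx = None
    for i in range(3):
        for j in range(3):
            for k in range(3):
                view = xp[:, :, i * p:i * p + d_, j * p:j * p + h_, k * p:k * p + w_]
                gw[:, :, i, j, k] = _tap_outer(gout, view)
                gview = gp[:, :, (2 - i) * p:(2 - i) * p + d_,
                           (2 - j) * p:(2 - j) * p + h_,
                           (2 - k) * p:(2 - k) * p + w_]
                piece = _tap_matmul(w[:, :, i, j, k].T, gview)
                gx = piece if gx is None else gx + piece
    gb = gout.sum(axis=(0, 2, 3, 4))
    return gx, gw, gb


class _Layer:
    """Parameterized layer: ``params``/``grads`` are dicts of arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv3x3(_Layer):
    def __init__(self, c_in: int, c_out: int, dilation: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / (27 * c_in))
        self.params = {
            "weight": rng.normal(0.0, scale, size=(c_out, c_in, 3, 3, 3)).astype(dtype),
            "bias": np.zeros(c_out, dtype=dtype),
        }
        self.dilation = dilation
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _conv3d(x, self.params["weight"], self.params["bias"], self.dilation)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx, gw, gb = _conv3d_grad(self._x, self.params["weight"], gout, self.dilation)
        self.grads["weight"] += gw
        self.grads["bias"] += gb
        return gx


class Conv1x1(_Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / c_in)
        self.params = {"weight": rng.normal(0.0, scale, size=(c_out, c_in)).astype(dtype),
                       "bias": np.zeros(c_out, dtype=dtype)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = _tap_matmul(self.params["weight"], x)
        return out + self.params["bias"][None, :, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["weight"] += _tap_outer(gout, self._x)
        self.grads["bias"] += gout.sum(axis=(0, 2, 3, 4))
        return _tap_matmul(self.params["weight"].T, gout)


class TConv2x2(_Layer):
    """Transposed conv, kernel 2, stride 2 (learned 2× upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / (8 * c_in))
        self.params = {"weight": rng.normal(0.0, scale,
                                            size=(c_in, c_out, 2, 2, 2)).astype(dtype),
                       "bias": np.zeros(c_out, dtype=dtype)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        b, c, d_, h_, w_ = x.shape
        o = self.params["weight"].shape[1]
        out = np.empty((b, o, 2 * d_, 2 * h_, 2 * w_))
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    out[:, :, i::2, j::2, k::2] = _tap_matmul(
                        self.params["weight"][:, :, i, j, k].T, x)
        return out + self.params["bias"][None, :, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx = None
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    gpiece = np.ascontiguousarray(gout[:, :, i::2, j::2, k::2])
                    self.grads["weight"][:, :, i, j, k] += _tap_outer(self._x, gpiece)
                    piece = _tap_matmul(self.params["weight"][:, :, i, j, k], gpiece)
                    gx = piece if gx is None else gx + piece
        self.grads["bias"] += gout.sum(axis=(0, 2, 3, 4))
        return gx


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _maxpool2(x: np.ndarray):
    b, c, d_, h_, w_ = x.shape
    r = x.reshape(b, c, d_ // 2, 2, h_ // 2, 2, w_ // 2, 2)
    r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d_ // 2, h_ // 2, w_ // 2, 8)
    arg = r.argmax(axis=-1)
    out = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _maxpool2_backward(gout: np.ndarray, arg: np.ndarray, in_shape) -> np.ndarray:
    b, c, d_, h_, w_ = in_shape
    r = np.zeros((b, c, d_ // 2, h_ // 2, w_ // 2, 8))
    np.put_along_axis(r, arg[..., None], gout[..., None], axis=-1)
    r = r.reshape(b, c, d_ // 2, h_ // 2, w_ // 2, 2, 2, 2)
    r = r.transpose(0, 1, 2, 5, 3, 6, 4, 7)
    return r.reshape(in_shape)


# --------------------------------------------------------------------------
# architectures
# --------------------------------------------------------------------------


class _Model:
    """Common surface: forward/backward over (B, C, d, h, w) arrays."""

    arch: str
    config: ModelConfig
    layers: dict[str, _Layer]

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": v for name, layer in self.layers.items()
                for k, v in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": v for name, layer in self.layers.items()
                for k, v in layer.grads.items()}

    def zero_grad(self) -> None:
        for layer in self.layers.values():
            layer.zero_grad()

    def set_parameters(self, flat: dict[str, np.ndarray]) -> None:
        for key, value in flat.items():
            name, pname = key.rsplit(".", 1)
            self.layers[name].params[pname][...] = value

    def validate_shape(self, shape) -> None:
        if any(s < 1 for s in shape):
            raise ValueError(f"invalid input shape {tuple(shape)}")

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, vol: np.ndarray) -> np.ndarray:
        """Single volume in, volume out (adds/strips batch+channel axes)."""
        self.validate_shape(vol.shape)
        return self.forward(vol[None, None])[0, 0].astype(np.float64)


class MSDNet3D(_Model):
    arch = "msdnet3d"

    def __init__(self, config: ModelConfig):
        self.config = config
        msd = config.msd
        depth = int(msd.get("depth", 10))
        width = int(msd.get("width", 1))
        dilations = list(msd.get("dilations", range(1, 11)))
        if depth < 1 or width < 1 or not dilations or min(dilations) < 1:
            raise ValueError("msd needs depth >= 1, width >= 1, positive dilations")
        self.depth, self.width, self.dilations = depth, width, dilations
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        self.layers = {}
        c_acc = 1
        for i in range(depth):
            dil = dilations[i % len(dilations)]
            self.layers[f"conv{i}"] = Conv3x3(c_acc, width, dil, rng, self.dtype)
            c_acc += width
        self.layers["final"] = Conv1x1(c_acc, 1, rng, self.dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        feats = [x]
        self._masks = []
        for i in range(self.depth):
            z = self.layers[f"conv{i}"].forward(np.concatenate(feats, axis=1))
            self._masks.append(z > 0)
            feats.append(_relu(z))
        self._n_feats = [f.shape[1] for f in feats]
        return self.layers["final"].forward(np.concatenate(feats, axis=1))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gout = np.asarray(gout, dtype=self.dtype)
        gcat = self.layers["final"].backward(gout)
        splits = np.cumsum(self._n_feats)[:-1]
        gfeats = list(np.split(gcat, splits, axis=1))
        for i in range(self.depth - 1, -1, -1):
            gz = gfeats.pop() * self._masks[i]
            gx = self.layers[f"conv{i}"].backward(gz)
            pieces = np.split(gx, np.cumsum(self._n_feats[:i + 1])[:-1], axis=1)
            for j, piece in enumerate(pieces):
                gfeats[j] = gfeats[j] + piece
        return gfeats[0]


class UNet3D(_Model):
    arch = "unet3d"

    def __init__(self, config: ModelConfig):
        self.config = config
        u = config.unet
        depth = int(u.get("depth", 3))
        base = int(u.get("base_channels", 64))
        if depth < 1 or base < 1:
            raise ValueError("unet needs depth >= 1 and base_channels >= 1")
        self.depth, self.base = depth, base
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        self.layers = {}
        chans = [base * 2 ** i for i in range(depth + 1)]
        c_in = 1
        for i, c in enumerate(chans[:-1]):  # encoder scales 0..depth-1
            self.layers[f"enc{i}a"] = Conv3x3(c_in, c, 1, rng, self.dtype)
            self.layers[f"enc{i}b"] = Conv3x3(c, c, 1, rng, self.dtype)
            c_in = c
        self.layers["bota"] = Conv3x3(chans[-2], chans[-1], 1, rng, self.dtype)
        self.layers["botb"] = Conv3x3(chans[-1], chans[-1], 1, rng, self.dtype)
        for i in range(depth - 1, -1, -1):
            self.layers[f"up{i}"] = TConv2x2(chans[i + 1], chans[i], rng, self.dtype)
            self.layers[f"dec{i}a"] = Conv3x3(2 * chans[i], chans[i], 1, rng, self.dtype)
            self.layers[f"dec{i}b"] = Conv3x3(chans[i], chans[i], 1, rng, self.dtype)
        self.layers["final"] = Conv1x1(base, 1, rng, self.dtype)

    def validate_shape(self, shape) -> None:
        div = 2 ** self.depth
        if any(s % div != 0 or s < div for s in shape):
            raise ValueError(
                f"unet3d with depth {self.depth} needs every side divisible by "
                f"{div}; got {tuple(shape)}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        self._cache = {}
        skips = []
        h = x
        for i in range(self.depth):
            h = _relu_cache(self, f"enc{i}a", self.layers[f"enc{i}a"].forward(h))
            h = _relu_cache(self, f"enc{i}b", self.layers[f"enc{i}b"].forward(h))
            skips.append(h)
            h, arg = _maxpool2(h)
            self._cache[f"pool{i}"] = (arg, skips[-1].shape)
        h = _relu_cache(self, "bota", self.layers["bota"].forward(h))
        h = _relu_cache(self, "botb", self.layers["botb"].forward(h))
        for i in range(self.depth - 1, -1, -1):
            h = self.layers[f"up{i}"].forward(h)
            h = np.concatenate([skips[i], h], axis=1)
            h = _relu_cache(self, f"dec{i}a", self.layers[f"dec{i}a"].forward(h))
            h = _relu_cache(self, f"dec{i}b", self.layers[f"dec{i}b"].forward(h))
        return self.layers["final"].forward(h)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gout = np.asarray(gout, dtype=self.dtype)
        g = self.layers["final"].backward(gout)
        gskips: dict[int, np.ndarray] = {}
        for i in range(self.depth):
            g = self.layers[f"dec{i}b"].backward(g * self._cache[f"dec{i}b"])
            g = self.layers[f"dec{i}a"].backward(g * self._cache[f"dec{i}a"])
            c_skip = g.shape[1] // 2
            gskips[i] = g[:, :c_skip]
            g = self.layers[f"up{i}"].backward(g[:, c_skip:])
        g = self.layers["botb"].backward(g * self._cache["botb"])
        g = self.layers["bota"].backward(g * self._cache["bota"])
        for i in range(self.depth - 1, -1, -1):
            arg, shape = self._cache[f"pool{i}"]
            g = _maxpool2_backward(g, arg, shape) + gskips[i]
            g = self.layers[f"enc{i}b"].backward(g * self._cache[f"enc{i}b"])
            g = self.layers[f"enc{i}a"].backward(g * self._cache[f"enc{i}a"])
        return g


def _relu_cache(model: _Model, name: str, z: np.ndarray) -> np.ndarray:
    model._cache[name] = z > 0
    return _relu(z)


# --------------------------------------------------------------------------
# public surface
# --------------------------------------------------------------------------

_ARCHS = {"msdnet3d": MSDNet3D, "unet3d": UNet3D}


def build_model(config: ModelConfig) -> _Model:
    """Instantiate a backbone; weights are a deterministic function of the seed."""
    if config.arch not in _ARCHS:
        raise ValueError(f"unknown architecture {config.arch!r}; "
                         f"choose from {sorted(_ARCHS)}")
    return _ARCHS[config.arch](config)


def apply_model(model: _Model, vol: Volume3D) -> Volume3D:
    """Run the denoiser on a whole volume (shape must satisfy the arch rule)."""
    out = model(vol.data.astype(np.float64))
    if not np.all(np.isfinite(out)):
        raise RuntimeError("model produced non-finite output")
    return vol.with_data(out)


def count_parameters(model: _Model) -> int:
    """Exact count of trainable scalars."""
    return int(sum(v.size for v in model.parameters().values()))


def save_model(model: _Model, path: str | Path) -> None:
    """Checkpoint = config JSON + all weight arrays in one .npz archive."""
    arrays = {f"param:{k}": v for k, v in model.parameters().items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> _Model:
    with np.load(path) as archive:
        cfg = ModelConfig.from_dict(json.loads(bytes(archive["config_json"].tobytes())))
        model = build_model(cfg)
        model.set_parameters({k[len("param:"):]: archive[k]
                              for k in archive.files if k.startswith("param:")})
    return model
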