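"""Self-supervised training: pair extraction, optimization, tiled inference.

Noise2Noise pairs come from two half-reconstructions (even/odd tilts or
even/odd movie-frame halves): random subvolume corners, both mapping
directions (a→b and b→a) so the learned mapping is symmetric, and optional
four-fold rotation augmentation about the tilt axis. The wedge-corruption
scheme ("ddw") additionally rotates each pair by a random 3D rotation and
corrupts the input with an artificial missing wedge in canonical
orientation; the loss is then restricted to the rotated acquisition wedge —
the Fourier region where the target actually carries measured information.
This scheme is a deliberately compact rendition of the published
wedge-corruption idea, not a reimplementation of any specific tool.

Optimization is Adam over the hand-written backward passes of
:mod:`tomodenoise.models`; everything is reproducible given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .fourier import WedgeMask, fsc, make_wedge_mask, rotation_about_axis
from .io import Volume3D
from .losses import LossSpec, get_loss
from .models import ModelConfig, _Model, build_model

__all__ = [
    "TrainingPair",
    "TrainConfig",
    "TrainingHistory",
    "extract_n2n_pairs",
    "extract_ddw_pairs",
    "train",
    "denoise_volume",
    "loss_comparison_report",
    "n2n_self_consistency_report",
]


@dataclass
class TrainingPair:
    """One (input, target) subvolume pair with optional Fourier loss mask."""

    input: np.ndarray
    target: np.ndarray
    loss_mask: WedgeMask | None = None
    provenance: tuple = ()

    def __post_init__(self) -> None:
        if self.input.shape != self.target.shape:
            raise ValueError("input/target shapes differ")

    def swapped(self) -> "TrainingPair":
        return TrainingPair(self.target, self.input, self.loss_mask,
                            self.provenance + ("swapped",))


@dataclass
class TrainConfig:
    """Training hyperparameters; every random choice derives from ``seed``."""

    pairs: int = 200
    subvolume_size: int = 32
    epochs: int = 10
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss: LossSpec = field(default_factory=LossSpec)
    augment: Literal["none", "tilt_axis_rot4"] = "tilt_axis_rot4"
    scheme: Literal["n2n", "ddw"] = "n2n"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pairs < 0 or self.subvolume_size < 1 or self.epochs < 0:
            raise ValueError("counts must be non-negative, subvolume_size >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    epoch_losses: list[float] = field(default_factory=list)
    state: dict | None = None  # resume checkpoint: optimizer moments + epoch

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tmean_loss\n")
            for i, v in enumerate(self.epoch_losses):
                fh.write(f"{i}\t{v:.8g}\n")


# --------------------------------------------------------------------------
# pair extraction
# --------------------------------------------------------------------------


def _random_corners(shape, size: int, n: int, rng: np.random.Generator) -> np.ndarray:
    maxc = np.asarray(shape) - size
    if np.any(maxc < 0):
        raise ValueError(f"subvolume size {size} larger than volume {tuple(shape)}")
    return np.stack([rng.integers(0, m + 1, size=n) for m in maxc], axis=1)


_ROT4 = [rotation_about_axis("y", a) for a in (0.0, 90.0, 180.0, 270.0)]


def _rot4_apply(sub: np.ndarray, k: int) -> np.ndarray:
    # rotation about Y = rot90 in the (z, x) plane; exact permutation path
    return np.rot90(sub, k=k, axes=(0, 2)).copy()


def extract_n2n_pairs(vol_a: Volume3D, vol_b: Volume3D,
                      cfg: TrainConfig) -> list[TrainingPair]:
    """Noise2Noise pairs from two half-volumes.

    Corners are sampled uniformly (seeded); each sampled corner emits the
    pair in both directions (a→b then b→a) until ``cfg.pairs`` is reached
    exactly. With ``augment="tilt_axis_rot4"`` each pair is rotated by one
    of {0°, 90°, 180°, 270°} about Y, the same rotation for input and target.
    """
    if tuple(vol_a.shape) != tuple(vol_b.shape):
        raise ValueError("half-volumes must have the same shape")
    rng = np.random.default_rng(cfg.seed)
    size = cfg.subvolume_size
    n_corners = (cfg.pairs + 1) // 2
    corners = _random_corners(vol_a.shape, size, max(n_corners, 1), rng)
    pairs: list[TrainingPair] = []
    for corner in corners:
        if len(pairs) >= cfg.pairs:
            break
        z, y, x = (int(c) for c in corner)
        sub_a = vol_a.data[z:z + size, y:y + size, x:x + size].astype(np.float64)
        sub_b = vol_b.data[z:z + size, y:y + size, x:x + size].astype(np.float64)
        k = int(rng.integers(0, 4)) if cfg.augment == "tilt_axis_rot4" else 0
        sub_a, sub_b = _rot4_apply(sub_a, k), _rot4_apply(sub_b, k)
        prov = ("a", (z, y, x), 90 * k)
        pairs.append(TrainingPair(sub_a, sub_b, None, prov))
        if len(pairs) < cfg.pairs:
            pairs.append(TrainingPair(sub_b, sub_a, None, ("b", (z, y, x), 90 * k)))
    return pairs


def extract_ddw_pairs(vol_a: Volume3D, vol_b: Volume3D,
                      acquisition_wedge: WedgeMask,
                      cfg: TrainConfig,
                      artificial_wedge: WedgeMask | None = None,
                      ) -> list[TrainingPair]:
    """Wedge-corrupted pairs for joint denoising / missing-wedge learning.

    Per pair: draw a random 3D rotation R, rotate both subvolumes by R,
    corrupt the input with the artificial wedge (canonical orientation,
    defaults to the acquisition wedge geometry), and attach the acquisition
    wedge rotated by R as the loss mask.
    """
    if tuple(vol_a.shape) != tuple(vol_b.shape):
        raise ValueError("half-volumes must have the same shape")
    size = cfg.subvolume_size
    if tuple(acquisition_wedge.shape) != (size, size, size):
        raise ValueError(
            f"acquisition wedge shape {acquisition_wedge.shape} must match "
            f"subvolume size {size}")
    if artificial_wedge is None:
        artificial_wedge = acquisition_wedge
    if tuple(artificial_wedge.shape) != (size, size, size):
        raise ValueError("artificial wedge shape must match subvolume size")
    rng = np.random.default_rng(cfg.seed)
    n_corners = (cfg.pairs + 1) // 2
    corners = _random_corners(vol_a.shape, size, max(n_corners, 1), rng)
    art_unshifted = artificial_wedge.unshifted()
    pairs: list[TrainingPair] = []
    for corner in corners:
        if len(pairs) >= cfg.pairs:
            break
        z, y, x = (int(c) for c in corner)
        rot = Rotation.random(random_state=int(rng.integers(0, 2 ** 31))).as_matrix()
        sub_a = Volume3D(vol_a.data[z:z + size, y:y + size, x:x + size])
        sub_b = Volume3D(vol_b.data[z:z + size, y:y + size, x:x + size])
        from .fourier import rotate_volume
        rot_a = rotate_volume(sub_a, rot).data.astype(np.float64)
        rot_b = rotate_volume(sub_b, rot).data.astype(np.float64)
        mask = acquisition_wedge.rotated(rot)
        corrupted_a = np.fft.ifftn(np.fft.fftn(rot_a) * art_unshifted).real
        corrupted_b = np.fft.ifftn(np.fft.fftn(rot_b) * art_unshifted).real
        prov = ((z, y, x), rot)
        pairs.append(TrainingPair(corrupted_a, rot_b, mask, ("a",) + prov))
        if len(pairs) < cfg.pairs:
            pairs.append(TrainingPair(corrupted_b, rot_a, mask, ("b",) + prov))
    return pairs


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _pair_loss_spec(base: LossSpec, pair: TrainingPair) -> LossSpec:
    if pair.loss_mask is None:
        return base
    if base.kind == "fsc":
        return replace(base, fourier_mask=pair.loss_mask)
    return base


def _masked_real_loss(pred, target, mask: WedgeMask, kind: str):
    """L2/L1 evaluated on wedge-filtered residuals (loss support restriction)."""
    m = mask.unshifted()
    diff_f = np.fft.fftn(pred - target) * m
    diff = np.fft.ifftn(diff_f).real
    n = pred.size
    if kind == "l2":
        loss = float(np.mean(diff ** 2))
        grad = 2.0 * np.fft.ifftn(np.fft.fftn(diff) * m).real / n
    else:
        loss = float(np.mean(np.abs(diff)))
        grad = np.fft.ifftn(np.fft.fftn(np.sign(diff) / n) * m).real
    return loss, grad


def train(model: _Model, pairs: Sequence[TrainingPair], cfg: TrainConfig,
          state: dict | None = None) -> tuple[_Model, TrainingHistory]:
    """Gradient-based training with seeded shuffling.

    Gradients are averaged over mini-batches; the history records the mean
    per-pair loss of each epoch. A NaN loss aborts with a diagnostic naming
    the offending batch. Each epoch's shuffle is derived from
    ``(cfg.seed, epoch)``, and ``history.state`` carries the optimizer
    moments, so resuming from a returned state continues bit-for-bit as if
    training had never stopped.
    """
    if len(pairs) == 0:
        raise ValueError("no training pairs")
    loss_fn, grad_fn = get_loss(cfg.loss)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    start_epoch = 0
    if state is not None:
        opt.t = state["t"]
        opt.m = {k: v.copy() for k, v in state["m"].items()}
        opt.v = {k: v.copy() for k, v in state["v"].items()}
        start_epoch = state["epoch"]
    history = TrainingHistory()
    for epoch in range(start_epoch, cfg.epochs):
        order = np.random.default_rng([cfg.seed, epoch]).permutation(len(pairs))
        epoch_loss = 0.0
        for b0 in range(0, len(order), cfg.batch_size):
            batch = [pairs[i] for i in order[b0:b0 + cfg.batch_size]]
            model.zero_grad()
            x = np.stack([p.input for p in batch])[:, None]
            pred = model.forward(x)
            batch_loss = 0.0
            grads = np.empty_like(pred)
            for s, pair in enumerate(batch):
                if pair.loss_mask is not None and cfg.loss.kind in ("l2", "l1"):
                    loss, grad = _masked_real_loss(pred[s, 0], pair.target,
                                                   pair.loss_mask, cfg.loss.kind)
                else:
                    spec_loss = _pair_loss_spec(cfg.loss, pair)
                    lf, gf = (get_loss(spec_loss) if spec_loss is not cfg.loss
                              else (loss_fn, grad_fn))
                    loss = lf(pred[s, 0], pair.target)
                    grad = gf(pred[s, 0], pair.target)
                batch_loss += loss
                grads[s, 0] = grad
            model.backward(grads / len(batch))
            batch_loss /= len(batch)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss in epoch {epoch}, batch starting at "
                    f"pair index {b0}: training aborted")
            if cfg.learning_rate > 0:
                opt.step(model.parameters(), model.gradients())
            epoch_loss += batch_loss * len(batch)
        history.epoch_losses.append(epoch_loss / len(order))
    history.state = {"t": opt.t, "m": {k: v.copy() for k, v in opt.m.items()},
                     "v": {k: v.copy() for k, v in opt.v.items()},
                     "epoch": cfg.epochs}
    return model, history


# --------------------------------------------------------------------------
# tiled inference
# --------------------------------------------------------------------------


def _cosine_window(tile: int, overlap: int) -> np.ndarray:
    """1D blend profile: raised-cosine ramps over the overlap margins."""
    w = np.ones(tile)
    if overlap > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(overlap) + 0.5) / overlap))
        w[:overlap] = ramp
        w[-overlap:] = ramp[::-1]
    return np.maximum(w, 1e-6)


def _tile_starts(extent: int, tile: int, stride: int) -> list[int]:
    starts = list(range(0, max(extent - tile, 0) + 1, stride))
    if starts[-1] != extent - tile:
        starts.append(extent - tile)
    return starts


def denoise_volume(model, vol: Volume3D, tile: int = 64,
                   overlap: int = 16) -> Volume3D:
    """Apply a model over a volume in overlapping tiles with cosine blending.

    The per-voxel blend weights are normalized to unity, so an identity
    model reproduces the input regardless of the tiling. If the tile is
    larger than the volume, the volume is processed as a single
    symmetrically padded tile.
    """
    if not 0 <= overlap < tile:
        raise ValueError("need 0 <= overlap < tile")
    runner: Callable[[np.ndarray], np.ndarray]
    runner = model if callable(model) and not isinstance(model, _Model) else model.__call__
    shape = vol.shape
    if any(s < tile for s in shape):
        pad = [(0, max(tile - s, 0)) for s in shape]
        padded = np.pad(vol.data.astype(np.float64), pad, mode="symmetric")
        out = denoise_volume(model, Volume3D(padded, vol.voxel_size), tile, overlap)
        return vol.with_data(out.data[:shape[0], :shape[1], :shape[2]])
    stride = tile - overlap
    win1 = _cosine_window(tile, overlap)
    win = win1[:, None, None] * win1[None, :, None] * win1[None, None, :]
    acc = np.zeros(shape)
    wacc = np.zeros(shape)
    data = vol.data.astype(np.float64)
    for z0 in _tile_starts(shape[0], tile, stride):
        for y0 in _tile_starts(shape[1], tile, stride):
            for x0 in _tile_starts(shape[2], tile, stride):
                sub = data[z0:z0 + tile, y0:y0 + tile, x0:x0 + tile]
                pred = np.asarray(runner(sub))
                acc[z0:z0 + tile, y0:y0 + tile, x0:x0 + tile] += pred * win
                wacc[z0:z0 + tile, y0:y0 + tile, x0:x0 + tile] += win
    return vol.with_data(acc / wacc)


# --------------------------------------------------------------------------
# loss-comparison harness
# --------------------------------------------------------------------------


def loss_comparison_report(vol_a: Volume3D, vol_b: Volume3D,
                           ground_truth: Volume3D,
                           model_config: ModelConfig,
                           cfg: TrainConfig,
                           tile: int | None = None,
                           ) -> dict:
    """Train the same backbone with L2 and with FSC loss; report FSC-to-truth.

    Returns a dict with per-shell FSC-to-ground-truth curves for the raw
    noisy volume and both trained models, plus the training histories. The
    comparison is reported, not judged: which loss retains more
    mid-frequency signal is a data-dependent outcome.
    """
    tile = tile or cfg.subvolume_size
    report: dict = {"shell_centers": None, "curves": {}, "histories": {}}
    noisy = vol_a
    curve = fsc(noisy, ground_truth)
    report["shell_centers"] = curve.shell_centers
    report["curves"]["noisy"] = curve.values
    for kind in ("l2", "fsc"):
        run_cfg = replace(cfg, loss=LossSpec(kind=kind))
        pairs = extract_n2n_pairs(vol_a, vol_b, run_cfg)
        model = build_model(model_config)
        model, history = train(model, pairs, run_cfg)
        denoised = denoise_volume(model, vol_a, tile=tile,
                                  overlap=min(tile // 4, tile - 1))
        report["curves"][kind] = fsc(denoised, ground_truth).values
        report["histories"][kind] = history.epoch_losses
    return report


def n2n_self_consistency_report(vol_a: Volume3D, vol_b: Volume3D,
                                raw_full: Volume3D,
                                model_config: ModelConfig,
                                cfg: TrainConfig,
                                tile: int | None = None) -> dict:
    """Train single-direction models a→b and b→a; report half-map FSC curves.

    Denoises each half with the model trained *from* it and returns the
    mutual FSC between the two denoised halves (independent residual noise,
    so it reflects shared signal) alongside each half's FSC to the raw
    full-dose reconstruction. The comparison is reported, not judged: the
    raw volume shares noise with each half, so its FSC to a partially
    denoised half is inflated by retained-noise correlation — only a
    near-complete denoiser makes the mutual curve dominate.
    """
    tile = tile or cfg.subvolume_size
    halves = {}
    for key, (src, dst) in {"ab": (vol_a, vol_b), "ba": (vol_b, vol_a)}.items():
        both = extract_n2n_pairs(src, dst, replace(cfg, pairs=2 * cfg.pairs))
        one_way = both[0::2]  # keep only the src->dst direction
        model = build_model(replace(model_config,
                                    seed=model_config.seed + (key == "ba")))
        model, _ = train(model, one_way, cfg)
        halves[key] = denoise_volume(model, src, tile=tile,
                                     overlap=min(tile // 4, tile - 1))
    mutual = fsc(halves["ab"], halves["ba"])
    return {
        "shell_centers": mutual.shell_centers,
        "mutual": mutual.values,
        "a_to_raw": fsc(halves["ab"], raw_full).values,
        "b_to_raw": fsc(halves["ba"], raw_full).values,
    }


def write_loss_comparison_tsv(report: dict, path: str | Path) -> None:
    keys = [k for k in ("noisy", "l2", "fsc") if k in report["curves"]]
    with open(path, "w") as fh:
        fh.write("shell_center\t" + "\t".join(f"fsc_{k}" for k in keys) + "\n")
        for i, c in enumerate(report["shell_centers"]):
            row = "\t".join(f"{report['curves'][k][i]:.6f}" for k in keys)
            fh.write(f"{c:.6f}\t{row}\n")
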