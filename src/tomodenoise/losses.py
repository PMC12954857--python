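"""Training objectives: L2, L1 and the Fourier-shell-correlation loss.

Each loss returns a scalar; the ``*_grad`` companions return the analytic
gradient with respect to the prediction, which the numpy training loop uses
in place of autodiff. The FSC loss is

    L = 1 - [ Σ_q w_q FSC(q) ] / [ Σ_q w_q ],

a trapezoid quadrature of the per-shell correlation over an inclusive shell
range (DC excluded by default), so L ∈ [0, 2], L(x, x) = 0 and lower is
better. Shells whose correlation denominator vanishes (e.g. everything
masked away inside a hard wedge) get zero quadrature weight rather than a
defined-zero correlation, so dead shells contribute no spurious gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .fourier import WedgeMask, shell_index_grid
from .io import Volume3D

__all__ = [
    "LossSpec",
    "l2_loss",
    "l1_loss",
    "fsc_loss",
    "l2_loss_grad",
    "l1_loss_grad",
    "fsc_loss_grad",
    "get_loss",
]


@dataclass
class LossSpec:
    """Configuration of a training loss.

    ``shell_width`` (cycles/voxel) and the inclusive shell index range
    ``shell_range`` apply to the FSC loss only; ``shell_range=None`` means
    shells 1..last (DC excluded). ``fourier_mask`` restricts which Fourier
    voxels contribute to the shell sums (wedge-aware training).
    """

    kind: Literal["l2", "l1", "fsc"] = "l2"
    shell_width: float | None = None
    shell_range: tuple[int, int] | None = None
    fourier_mask: WedgeMask | None = None


def _as_array(x) -> np.ndarray:
    if isinstance(x, Volume3D):
        return x.data.astype(np.float64)
    return np.asarray(x, dtype=np.float64)


def _check_shapes(pred, target) -> tuple[np.ndarray, np.ndarray]:
    p, t = _as_array(pred), _as_array(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    return p, t


def l2_loss(pred, target) -> float:
    """Mean squared voxel difference."""
    p, t = _check_shapes(pred, target)
    return float(np.mean((p - t) ** 2))


def l2_loss_grad(pred, target) -> np.ndarray:
    p, t = _check_shapes(pred, target)
    return 2.0 * (p - t) / p.size


def l1_loss(pred, target) -> float:
    """Mean absolute voxel difference."""
    p, t = _check_shapes(pred, target)
    return float(np.mean(np.abs(p - t)))


def l1_loss_grad(pred, target) -> np.ndarray:
    p, t = _check_shapes(pred, target)
    return np.sign(p - t) / p.size


def _fsc_shell_machinery(shape, spec: LossSpec):
    shell_width = spec.shell_width or 1.0 / max(shape)
    q, n_shells = shell_index_grid(shape, shell_width)
    if spec.fourier_mask is not None:
        if tuple(spec.fourier_mask.shape) != tuple(shape):
            raise ValueError("fourier_mask shape does not match the volumes")
        q = np.where(spec.fourier_mask.unshifted() >= 0.5, q, -1)
    q_lo, q_hi = spec.shell_range if spec.shell_range is not None else (1, n_shells - 1)
    if not (0 <= q_lo <= q_hi <= n_shells - 1):
        raise ValueError(
            f"shell_range {spec.shell_range} out of bounds for {n_shells} shells")
    return q, n_shells, q_lo, q_hi


def _trapezoid_weights(q_lo: int, q_hi: int, alive: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights on [q_lo, q_hi]; dead shells get 0."""
    w = np.zeros(len(alive))
    w[q_lo:q_hi + 1] = 1.0
    if q_hi > q_lo:
        w[q_lo] = 0.5
        w[q_hi] = 0.5
    return w * alive


def fsc_loss(pred, target, spec: LossSpec | None = None) -> float:
    """FSC loss ``1 − normalized trapezoid quadrature of per-shell FSC``."""
    return _fsc_loss_impl(pred, target, spec, want_grad=False)[0]


def fsc_loss_grad(pred, target, spec: LossSpec | None = None) -> np.ndarray:
    """Analytic gradient of :func:`fsc_loss` with respect to ``pred``."""
    return _fsc_loss_impl(pred, target, spec, want_grad=True)[1]


def _fsc_loss_impl(pred, target, spec, want_grad: bool):
    p, t = _check_shapes(pred, target)
    if not t.any():
        raise ValueError("all-zero target: FSC loss normalization undefined")
    if not p.any():
        raise ValueError("all-zero prediction: FSC loss normalization undefined")
    spec = spec or LossSpec(kind="fsc")
    q, n_shells, q_lo, q_hi = _fsc_shell_machinery(p.shape, spec)
    fp = np.fft.fftn(p)
    ft = np.fft.fftn(t)
    valid = q >= 0
    qv = q[valid]
    num = np.bincount(qv, weights=(fp * np.conj(ft)).real[valid], minlength=n_shells)
    a = np.bincount(qv, weights=(np.abs(fp) ** 2)[valid], minlength=n_shells)
    b = np.bincount(qv, weights=(np.abs(ft) ** 2)[valid], minlength=n_shells)
    denom = np.sqrt(a * b)
    alive = denom > 0
    corr = np.zeros(n_shells)
    np.divide(num, denom, out=corr, where=alive)
    w = _trapezoid_weights(q_lo, q_hi, alive)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("no live shells in the requested range; loss undefined")
    loss = 1.0 - float((w * corr).sum() / wsum)
    if not want_grad:
        return loss, None
    # Wirtinger gradient: dFSC_q/dF_p(k) = (conj(F_t)/denom - FSC_q conj(F_p)/a) / 2
    # for k in shell q; dL/dx = 2 Re FFT(g) with g the per-voxel coefficient.
    coef = np.zeros(n_shells)
    np.divide(w / wsum, denom, out=coef, where=alive)  # w_q / (W denom_q)
    corr_over_a = np.zeros(n_shells)
    np.divide(w / wsum * corr, a, out=corr_over_a, where=alive & (a > 0))
    g = np.zeros(p.shape, dtype=complex)
    qc = np.where(valid, q, 0)
    g = -(0.5) * (coef[qc] * np.conj(ft) - corr_over_a[qc] * np.conj(fp))
    g[~valid] = 0.0
    grad = 2.0 * np.fft.fftn(g).real / 1.0
    # FFT(g)[j] = Σ_k g_k e^{-2πi k·j}; factor 2 folds in the conjugate term
    return loss, grad


_LOSSES = {
    "l2": (l2_loss, l2_loss_grad),
    "l1": (l1_loss, l1_loss_grad),
    "fsc": (fsc_loss, fsc_loss_grad),
}


def get_loss(spec: LossSpec):
    """Return ``(loss_fn, grad_fn)`` closures for a :class:`LossSpec`."""
    if spec.kind not in _LOSSES:
        raise ValueError(f"unknown loss kind {spec.kind!r}")
    if spec.kind == "fsc":
        return (lambda p, t: fsc_loss(p, t, spec),
                lambda p, t: fsc_loss_grad(p, t, spec))
    return _LOSSES[spec.kind]
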