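"""Fourier-domain machinery: wedge masks, filtering, rotations and FSC.

The missing wedge of a single-axis tilt series (tilt axis Y, beam along Z)
is the set of Fourier-plane normals never measured. A projection at tilt
angle θ contributes the central section whose in-plane direction in the
(k_x, k_z) plane makes angle θ with the k_x axis, so the measured region of
a ``[tilt_min, tilt_max]`` acquisition is the set of directions whose folded
line angle lies inside that interval; the mask is constant along k_y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Volume3D

__all__ = [
    "WedgeMask",
    "FSCCurve",
    "make_wedge_mask",
    "apply_wedge",
    "lowpass",
    "rotate_volume",
    "rotation_about_axis",
    "fsc",
    "resolution_at_threshold",
    "shell_index_grid",
]


# --------------------------------------------------------------------------
# wedge masks
# --------------------------------------------------------------------------


@dataclass
class WedgeMask:
    """Hermitian-symmetric Fourier pass mask for an angular wedge.

    ``values`` are per-voxel pass weights in [0, 1] on the full fftshifted
    grid (DC at ``shape // 2``). ``soft_edge`` is the width, in degrees, of a
    raised-cosine taper outside the measured angular range; 0 gives a binary
    mask.
    """

    shape: tuple[int, int, int]
    tilt_min: float
    tilt_max: float
    soft_edge: float
    values: np.ndarray

    def rotated(self, rotation: np.ndarray) -> "WedgeMask":
        """Mask resampled under a rotation of Fourier space about DC.

        The rotation matrix acts on ``(z, y, x)`` frequency coordinates. Uses
        linear interpolation with nearest-edge fill; weights stay in [0, 1].
        """
        rotation = _check_rotation(rotation)
        center = (np.asarray(self.shape) // 2).astype(float)
        # output voxel o samples input at R^T (o - c) + c
        vals = ndimage.affine_transform(
            self.values, rotation.T, offset=center - rotation.T @ center,
            order=1, mode="nearest", output=np.float64,
        )
        return WedgeMask(self.shape, self.tilt_min, self.tilt_max,
                         self.soft_edge, np.clip(vals, 0.0, 1.0))

    def unshifted(self) -> np.ndarray:
        """Values reordered to match an unshifted ``np.fft.fftn`` grid."""
        return np.fft.ifftshift(self.values)


def _shifted_freq_grids(shape: tuple[int, int, int]):
    """fftshifted frequency coordinates (cycles/voxel) along z, y, x."""
    fz = np.fft.fftshift(np.fft.fftfreq(shape[0]))
    fy = np.fft.fftshift(np.fft.fftfreq(shape[1]))
    fx = np.fft.fftshift(np.fft.fftfreq(shape[2]))
    return np.meshgrid(fz, fy, fx, indexing="ij", sparse=True)


def make_wedge_mask(shape, tilt_min: float, tilt_max: float,
                    soft_edge: float = 0.0) -> WedgeMask:
    """Build the pass mask for a ``[tilt_min, tilt_max]`` degree tilt range.

    A full ±90° range yields an all-ones mask. The DC voxel always passes.
    """
    if not (-90 <= tilt_min < tilt_max <= 90):
        raise ValueError(
            f"need -90 <= tilt_min < tilt_max <= 90, got [{tilt_min}, {tilt_max}]")
    if soft_edge < 0:
        raise ValueError("soft_edge must be >= 0 degrees")
    shape = tuple(int(s) for s in shape)
    kz, _, kx = _shifted_freq_grids(shape)
    # folded line angle in (-90, 90]: the direction of the (k_x, k_z) line
    phi = np.degrees(np.arctan2(kz, kx))
    phi = np.where(phi > 90, phi - 180, phi)
    phi = np.where(phi <= -90, phi + 180, phi)
    # distance (degrees) outside the measured interval
    dist = np.maximum(tilt_min - phi, phi - tilt_max)
    dist = np.maximum(dist, 0.0)
    if soft_edge > 0:
        vals = np.where(dist >= soft_edge, 0.0,
                        0.5 * (1.0 + np.cos(np.pi * dist / soft_edge)))
    else:
        vals = (dist == 0.0).astype(np.float64)
    vals = np.broadcast_to(vals, shape).copy()
    # enforce Hermitian symmetry under *modular* negation: on even grids the
    # Nyquist plane is its own conjugate partner with the folded line angle
    # sign-flipped, so asymmetric ranges would otherwise break symmetry there
    reflected = np.roll(vals[::-1, ::-1, ::-1], (1, 1, 1), axis=(0, 1, 2))
    vals = np.maximum(vals, reflected)
    center = tuple(s // 2 for s in shape)
    vals[center] = 1.0  # DC always passes
    return WedgeMask(shape, float(tilt_min), float(tilt_max), float(soft_edge), vals)


def apply_wedge(vol: Volume3D, mask: WedgeMask,
                rotation: np.ndarray | None = None) -> Volume3D:
    """Multiply the volume's Fourier transform by the (optionally rotated) mask."""
    if tuple(vol.shape) != tuple(mask.shape):
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    m = mask.rotated(rotation) if rotation is not None else mask
    spectrum = np.fft.fftn(vol.data.astype(np.float64)) * m.unshifted()
    out = np.fft.ifftn(spectrum)
    scale = max(float(np.abs(vol.data).max()), 1e-30)
    imag_residue = float(np.abs(out.imag).max()) / scale
    if imag_residue > 1e-5:
        raise RuntimeError(
            f"imaginary residue {imag_residue:.2e} after wedge filtering; "
            "mask is not Hermitian-symmetric")
    return vol.with_data(out.real)


# --------------------------------------------------------------------------
# low-pass filter
# --------------------------------------------------------------------------


def lowpass(vol: Volume3D, cutoff: float, rolloff: float) -> Volume3D:
    """Radial low-pass: unity below ``cutoff``, Gaussian decay above.

    ``cutoff`` and ``rolloff`` are in cycles/pixel; the filter is
    ``exp(-(r - cutoff)^2 / (2 rolloff^2))`` for r > cutoff (a hard cut when
    ``rolloff`` is 0). The defaults used for band-limiting reconstructions
    downstream are cutoff 0.42 and roll-off 0.03 cycles/pixel.
    """
    corner = 0.5 * np.sqrt(3.0)
    if not 0 < cutoff <= corner + 1e-12:
        raise ValueError(f"cutoff must be in (0, {corner:.4f}], got {cutoff}")
    if rolloff < 0:
        raise ValueError("rolloff must be >= 0")
    kz, ky, kx = _shifted_freq_grids(vol.shape)
    r = np.fft.ifftshift(np.sqrt(kz * kz + ky * ky + kx * kx))
    excess = np.maximum(r - cutoff, 0.0)
    if rolloff > 0:
        filt = np.exp(-0.5 * (excess / rolloff) ** 2)
    else:
        filt = (excess == 0.0).astype(np.float64)
    out = np.fft.ifftn(np.fft.fftn(vol.data.astype(np.float64)) * filt).real
    return vol.with_data(out)


# --------------------------------------------------------------------------
# rotations
# --------------------------------------------------------------------------


def rotation_about_axis(axis: str, degrees: float) -> np.ndarray:
    """Proper rotation matrix acting on (z, y, x) coordinates, about a grid axis."""
    c, s = np.cos(np.radians(degrees)), np.sin(np.radians(degrees))
    if axis == "z":
        r = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    elif axis == "y":
        r = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    elif axis == "x":
        r = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    else:
        raise ValueError(f"axis must be one of z/y/x, got {axis!r}")
    return r


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-6):
        raise ValueError("rotation matrix must be proper (det = +1)")
    return rotation


def _as_signed_permutation(rotation: np.ndarray) -> np.ndarray | None:
    rounded = np.round(rotation)
    if not np.allclose(rotation, rounded, atol=1e-10):
        return None
    if not np.array_equal(np.abs(rounded).sum(axis=0), [1, 1, 1]):
        return None
    return rounded.astype(int)


def rotate_volume(vol: Volume3D, rotation: np.ndarray, order: int = 1) -> Volume3D:
    """Rotate a volume about its grid center.

    Voxels mapped from outside the source grid are filled with the volume
    mean (not zero) to avoid dark-corner bias in training losses. Rotations
    that are exact signed permutations of the axes (multiples of 90° about a
    grid axis) take an exact, interpolation-free path.
    """
    rotation = _check_rotation(rotation)
    perm = _as_signed_permutation(rotation)
    data = vol.data.astype(np.float64)
    center = (np.asarray(vol.shape, dtype=float) - 1.0) / 2.0
    if perm is not None:
        idx = np.indices(vol.shape).reshape(3, -1)
        src = perm.T @ (idx - center[:, None]) + center[:, None]
        src = np.round(src).astype(int)
        if np.all((src >= 0) & (src < np.asarray(vol.shape)[:, None])):
            out = data[src[0], src[1], src[2]].reshape(vol.shape)
            return vol.with_data(out)
        # non-cubic grids can map outside; fall through to interpolation
    out = ndimage.affine_transform(
        data, rotation.T, offset=center - rotation.T @ center,
        order=order, mode="constant", cval=float(data.mean()),
    )
    return vol.with_data(out)


# --------------------------------------------------------------------------
# Fourier shell correlation
# --------------------------------------------------------------------------


@dataclass
class FSCCurve:
    """Per-shell correlation values over spatial-frequency shells.

    ``shell_centers`` are the lower edges of shells of width ``shell_width``
    in cycles/voxel, starting at DC; values lie in [−1, 1]. ``empty_shells``
    flags shells whose correlation was reported as 0 because a denominator
    vanished (e.g. all voxels masked out).
    """

    shell_centers: np.ndarray
    values: np.ndarray
    shell_counts: np.ndarray
    empty_shells: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def shell_index_grid(shape, shell_width: float) -> tuple[np.ndarray, int]:
    """Shell index per unshifted-FFT voxel, and the number of shells to Nyquist.

    A voxel at radius r (cycles/voxel) belongs to shell ``floor(r / width)``;
    exact boundary radii go to the lower shell. Voxels beyond 0.5 cycles/voxel
    (grid corners) get index −1 and are excluded.
    """
    fz = np.fft.fftfreq(shape[0])
    fy = np.fft.fftfreq(shape[1])
    fx = np.fft.fftfreq(shape[2])
    kz, ky, kx = np.meshgrid(fz, fy, fx, indexing="ij", sparse=True)
    r = np.sqrt(kz * kz + ky * ky + kx * kx)
    q = np.floor(r / shell_width).astype(int)
    on_boundary = np.isclose(r / shell_width, q, atol=1e-9) & (q > 0)
    q = np.where(on_boundary, q - 1, q)
    n_shells = int(np.floor(0.5 / shell_width + 1e-9)) + 1
    q = np.where(r <= 0.5 + 1e-9, q, -1)
    q = np.where(q >= n_shells, n_shells - 1, q)
    return q, n_shells


def fsc(vol_a: Volume3D, vol_b: Volume3D, shell_width: float | None = None) -> FSCCurve:
    """Fourier shell correlation between two equally shaped volumes.

    Per shell q the value is ``Re Σ F_a conj(F_b) / sqrt(Σ|F_a|² Σ|F_b|²)``
    over the Fourier voxels in the shell. Default shell width is one Fourier
    voxel (1/n cycles/voxel for the largest grid side n).
    """
    if tuple(vol_a.shape) != tuple(vol_b.shape):
        raise ValueError(f"shape mismatch: {vol_a.shape} vs {vol_b.shape}")
    a = vol_a.data.astype(np.float64)
    b = vol_b.data.astype(np.float64)
    if not a.any():
        raise ValueError("first volume is all-zero; FSC undefined")
    if not b.any():
        raise ValueError("second volume is all-zero; FSC undefined")
    if shell_width is None:
        shell_width = 1.0 / max(a.shape)
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    q, n_shells = shell_index_grid(a.shape, shell_width)
    valid = q >= 0
    qv = q[valid]
    num = np.bincount(qv, weights=(fa * np.conj(fb)).real[valid], minlength=n_shells)
    pa = np.bincount(qv, weights=(np.abs(fa) ** 2)[valid], minlength=n_shells)
    pb = np.bincount(qv, weights=(np.abs(fb) ** 2)[valid], minlength=n_shells)
    counts = np.bincount(qv, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    empty = denom <= 0
    values = np.zeros(n_shells)
    np.divide(num, denom, out=values, where=~empty)
    values = np.clip(values, -1.0, 1.0)
    centers = np.arange(n_shells) * shell_width
    keep = counts > 0
    return FSCCurve(centers[keep], values[keep], counts[keep], empty[keep])


def resolution_at_threshold(curve: FSCCurve, threshold: float,
                            voxel_size: float) -> tuple[float, bool]:
    """Resolution (Å) where the FSC first drops below ``threshold``.

    The crossing frequency is located by linear interpolation between
    adjacent shells; the resolution is ``voxel_size / frequency``. If the
    curve never drops below the threshold, the Nyquist resolution
    ``2 * voxel_size`` is returned with the no-crossing flag set.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if len(curve) < 2:
        raise ValueError("FSC curve must have at least 2 shells")
    vals = curve.values
    freqs = curve.shell_centers
    below = np.nonzero(vals < threshold)[0]
    below = below[below > 0]  # DC shell of a sane pair is ~1; skip index 0
    if len(below) == 0:
        return 2.0 * voxel_size, True
    i = below[0]
    f0, f1 = freqs[i - 1], freqs[i]
    v0, v1 = vals[i - 1], vals[i]
    if v0 == v1:
        f_cross = f1
    else:
        f_cross = f0 + (f1 - f0) * (v0 - threshold) / (v0 - v1)
    if f_cross <= 0:
        return 2.0 * voxel_size, True
    return float(voxel_size / f_cross), False
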