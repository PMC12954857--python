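"""Core spatial data types and file I/O.

Volumes and tilt stacks are stored as MRC2014 files (mode 2, 32-bit float);
particle tables as tab-separated text with a ``z\\ty\\tx\\tscore`` header.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``; Z is the beam direction at 0° tilt and
  the tilt rotation is about Y,
* coordinates are 0-based voxel indices; any conversion to 1-based external
  conventions happens at file boundaries only,
* MRC files store X fastest / Z slowest, which maps directly onto a C-ordered
  ``(nz, ny, nx)`` numpy array.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Volume3D",
    "TiltSeries",
    "ParticleList",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_tilt_series",
    "write_tilt_series",
    "read_particles",
    "write_particles",
    "read_config",
    "write_config",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3D scalar density grid with isotropic voxel size in Ångström.

    Parameters
    ----------
    data
        Real scalar grid of shape ``(nz, ny, nx)``.
    voxel_size
        Edge length of a voxel in Å (> 0).
    origin
        Voxel offset of the grid corner, ``(z, y, x)``.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values (NaN/Inf)")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size, self.origin)

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same metadata, new grid."""
        return Volume3D(np.asarray(data, dtype=np.float32), self.voxel_size, self.origin)


@dataclass
class TiltSeries:
    """An ordered stack of 2D projections with their tilt angles.

    ``images`` has shape ``(n_tilts, ny, nx)``; ``tilt_angles`` are degrees,
    strictly increasing, all in (−90, 90). ``frames_per_tilt`` marks how many
    movie-frame sub-exposures each tilt notionally consists of (used by the
    frame-split training-pair scheme).
    """

    images: np.ndarray
    tilt_angles: np.ndarray
    pixel_size: float = 1.0
    frames_per_tilt: int | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError(f"tilt stack must be 3D, got shape {self.images.shape}")
        if self.tilt_angles.ndim != 1 or len(self.tilt_angles) != self.images.shape[0]:
            raise ValueError(
                f"need one tilt angle per image: {len(self.tilt_angles)} angles, "
                f"{self.images.shape[0]} images"
            )
        if np.any(np.diff(self.tilt_angles) <= 0):
            raise ValueError("tilt angles must be strictly increasing")
        if np.any(np.abs(self.tilt_angles) >= 90):
            raise ValueError("tilt angles must lie in (-90, 90) degrees")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("tilt images contain non-finite values")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frames_per_tilt is not None and self.frames_per_tilt < 1:
            raise ValueError("frames_per_tilt must be >= 1")

    @property
    def n_tilts(self) -> int:
        return self.images.shape[0]


@dataclass
class ParticleList:
    """Particle centers in 0-based ``(z, y, x)`` voxel coordinates with scores."""

    positions: np.ndarray  # (n, 3) float
    scores: np.ndarray  # (n,) float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.scores = np.atleast_1d(np.asarray(self.scores, dtype=np.float64))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3) in (z, y, x) order")
        if len(self.scores) != len(self.positions):
            raise ValueError("need one score per particle")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.labels is not None and len(self.labels) != len(self.positions):
            raise ValueError("need one label per particle")

    def __len__(self) -> int:
        return len(self.positions)

    def sorted_by_score(self, descending: bool = True) -> "ParticleList":
        """Stable sort by score; ties broken by (z, y, x) lexicographic order."""
        keys = np.lexsort(
            (self.positions[:, 2], self.positions[:, 1], self.positions[:, 0],
             -self.scores if descending else self.scores)
        )
        labels = [self.labels[i] for i in keys] if self.labels is not None else None
        return ParticleList(self.positions[keys], self.scores[keys], labels)

    def out_of_bounds(self, shape: Sequence[int]) -> np.ndarray:
        """Boolean flags for particles outside a ``(nz, ny, nx)`` volume."""
        shape = np.asarray(shape, dtype=float)
        return np.any((self.positions < 0) | (self.positions > shape - 1), axis=1)


# --------------------------------------------------------------------------
# MRC2014
# --------------------------------------------------------------------------

_HEADER_DTYPE = np.dtype(
    [
        ("nx", "<i4"), ("ny", "<i4"), ("nz", "<i4"),
        ("mode", "<i4"),
        ("nxstart", "<i4"), ("nystart", "<i4"), ("nzstart", "<i4"),
        ("mx", "<i4"), ("my", "<i4"), ("mz", "<i4"),
        ("cella", "<f4", 3), ("cellb", "<f4", 3),
        ("mapc", "<i4"), ("mapr", "<i4"), ("maps", "<i4"),
        ("dmin", "<f4"), ("dmax", "<f4"), ("dmean", "<f4"),
        ("ispg", "<i4"), ("nsymbt", "<i4"),
        ("extra", "V100"),
        ("origin", "<f4", 3),
        ("map", "S4"), ("machst", "u1", 4),
        ("rms", "<f4"),
        ("nlabl", "<i4"), ("label", "S80", 10),
    ]
)
assert _HEADER_DTYPE.itemsize == 1024

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _read_mrc(path: str | Path) -> tuple[np.ndarray, float, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        raw = fh.read(1024)
        if len(raw) < 1024:
            raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
        hdr = np.frombuffer(raw, dtype=_HEADER_DTYPE, count=1)[0]
        if hdr["map"] not in (b"MAP ", b"MAP\x00"):
            raise FormatError(f"{path}: bad MAP magic {hdr['map']!r} (not MRC2014)")
        mode = int(hdr["mode"])
        if mode not in _MODE_DTYPES:
            raise FormatError(f"{path}: unsupported MRC mode {mode}")
        nx, ny, nz = int(hdr["nx"]), int(hdr["ny"]), int(hdr["nz"])
        if min(nx, ny, nz) <= 0:
            raise FormatError(f"{path}: non-positive dimensions nx,ny,nz = {nx},{ny},{nz}")
        if not (hdr["mapc"], hdr["mapr"], hdr["maps"]) == (1, 2, 3):
            raise FormatError(
                f"{path}: unsupported axis mapping mapc,mapr,maps = "
                f"{int(hdr['mapc'])},{int(hdr['mapr'])},{int(hdr['maps'])} (expected 1,2,3)"
            )
        fh.seek(1024 + int(hdr["nsymbt"]))
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=np.dtype(_MODE_DTYPES[mode]).newbyteorder("<"), count=count)
        if data.size != count:
            raise FormatError(f"{path}: truncated data block ({data.size}/{count} values)")
    data = data.reshape(nz, ny, nx).astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: data block contains NaN/Inf values")
    mx = int(hdr["mx"]) or nx
    voxel = float(hdr["cella"][0]) / mx if hdr["cella"][0] > 0 else 1.0
    return data, voxel, np.asarray(hdr["origin"], dtype=float)


def _write_mrc(data: np.ndarray, voxel_size: float, path: str | Path,
               origin: Sequence[float] = (0.0, 0.0, 0.0), ispg: int = 1) -> None:
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    hdr = np.zeros((), dtype=_HEADER_DTYPE)
    hdr["nx"], hdr["ny"], hdr["nz"] = nx, ny, nz
    hdr["mode"] = 2
    hdr["mx"], hdr["my"], hdr["mz"] = nx, ny, nz
    hdr["cella"] = (nx * voxel_size, ny * voxel_size, nz * voxel_size)
    hdr["cellb"] = (90.0, 90.0, 90.0)
    hdr["mapc"], hdr["mapr"], hdr["maps"] = 1, 2, 3
    hdr["dmin"], hdr["dmax"], hdr["dmean"] = float(data.min()), float(data.max()), float(data.mean())
    hdr["ispg"] = ispg
    hdr["origin"] = tuple(origin)
    hdr["map"] = b"MAP "
    hdr["machst"] = (0x44, 0x44, 0x00, 0x00)  # little-endian IEEE
    hdr["rms"] = float(data.std())
    hdr["nlabl"] = 0
    with open(path, "wb") as fh:
        fh.write(hdr.tobytes())
        fh.write(data.tobytes())


def read_volume(path: str | Path) -> Volume3D:
    """Read an MRC2014 volume; voxel size is taken from the cell header."""
    data, voxel, origin = _read_mrc(path)
    return Volume3D(data, voxel, tuple(origin[::-1]))


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as MRC2014 mode 2 with header statistics set."""
    parent = Path(path).parent
    if not parent.is_dir():
        raise IOError(f"parent directory does not exist: {parent}")
    _write_mrc(vol.data, vol.voxel_size, path, origin=vol.origin[::-1], ispg=1)


def write_tilt_series(ts: TiltSeries, path: str | Path,
                      angles_path: str | Path | None = None) -> None:
    """Write a tilt stack as a 3D MRC (one section per tilt) plus an angle file.

    The sidecar text file (default ``<stem>.tlt``) holds one tilt angle in
    degrees per line.
    """
    _write_mrc(ts.images, ts.pixel_size, path, ispg=0)
    if angles_path is None:
        angles_path = Path(path).with_suffix(".tlt")
    np.savetxt(angles_path, ts.tilt_angles, fmt="%.4f")


def read_tilt_series(path: str | Path, angles_path: str | Path | None = None,
                     frames_per_tilt: int | None = None) -> TiltSeries:
    """Read a tilt stack written by :func:`write_tilt_series`."""
    data, pixel, _ = _read_mrc(path)
    if angles_path is None:
        angles_path = Path(path).with_suffix(".tlt")
    if not Path(angles_path).exists():
        raise FileNotFoundError(f"tilt-angle sidecar not found: {angles_path}")
    angles = np.atleast_1d(np.loadtxt(angles_path, dtype=float))
    return TiltSeries(data, angles, pixel, frames_per_tilt)


# --------------------------------------------------------------------------
# particle tables
# --------------------------------------------------------------------------

_PARTICLE_COLUMNS = ["z", "y", "x", "score"]


def read_particles(path: str | Path) -> ParticleList:
    """Read a TSV particle table with header columns z, y, x, score.

    An optional ``label`` column is preserved.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; expected header "
            + "\\t".join(_PARTICLE_COLUMNS)
        )
    if df[_PARTICLE_COLUMNS].isna().any().any():
        raise FormatError(f"{path}: table contains missing/NaN entries")
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    return ParticleList(df[["z", "y", "x"]].to_numpy(float), df["score"].to_numpy(float), labels)


def write_particles(particles: ParticleList, path: str | Path) -> None:
    """Write a particle table as TSV, row order preserved."""
    df = pd.DataFrame(particles.positions, columns=["z", "y", "x"])
    df["score"] = particles.scores
    if particles.labels is not None:
        df["label"] = particles.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


def read_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top level of config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
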