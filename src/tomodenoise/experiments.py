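"""Canned desk-scale experiments tying the simulator to training/evaluation.

These helpers define the package's standard synthetic study conditions: a
64³ phantom of non-overlapping spheres, a ±60° / 3°-step tilt series,
Gaussian per-tilt noise at 30% of the clean projection spread, T2T
splitting, and FBP half-reconstructions. Tests, the command-line interface
and the loss-comparison harness all draw from here so that "the synthetic
benchmark" means one thing across the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simulator as sim
from .io import ParticleList, TiltSeries, Volume3D

__all__ = ["SyntheticStudy", "simulate_split_study"]


@dataclass
class SyntheticStudy:
    """All artifacts of one synthetic acquisition + reconstruction run."""

    phantom: Volume3D
    truth: ParticleList
    clean_series: TiltSeries
    noisy_series: TiltSeries
    rec_full: Volume3D
    rec_a: Volume3D
    rec_b: Volume3D


def simulate_split_study(seed: int = 0, shape=(64, 64, 64), n_spheres: int = 12,
                         radius: float = 5.0, noise_fraction: float = 0.3,
                         scheme: str = "T2T", frames_per_tilt: int = 8,
                         tilt_min: float = sim.DEFAULT_TILT_MIN,
                         tilt_max: float = sim.DEFAULT_TILT_MAX,
                         tilt_step: float = sim.DEFAULT_TILT_STEP,
                         ) -> SyntheticStudy:
    """Simulate phantom → tilt series → noise → split → FBP reconstructions.

    ``noise_fraction`` sets the Gaussian sigma as a fraction of the clean
    projection standard deviation. For the T2T scheme the noisy full series
    is split by tilt parity; for F2F the clean series is split into averaged
    even/odd sub-exposure frame halves and the full series is their mean.
    """
    phantom, truth = sim.random_sphere_phantom(
        shape=shape, n_spheres=n_spheres, radius=radius, seed=seed)
    angles = sim.default_tilt_angles(tilt_min, tilt_max, tilt_step)
    clean = sim.project(phantom, angles)
    sigma = noise_fraction * float(clean.images.std())
    model = sim.NoiseModel("gaussian", sigma, seed=seed + 1)
    if scheme == "T2T":
        noisy = sim.add_noise(clean, model)
        half_a, half_b = sim.split_series(noisy, "T2T")
    elif scheme == "F2F":
        tagged = TiltSeries(clean.images, clean.tilt_angles, clean.pixel_size,
                            frames_per_tilt=frames_per_tilt)
        half_a, half_b = sim.split_series(tagged, "F2F", model)
        noisy = TiltSeries((half_a.images + half_b.images) / 2.0,
                           clean.tilt_angles, clean.pixel_size)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out_shape = phantom.shape
    return SyntheticStudy(
        phantom=phantom,
        truth=truth,
        clean_series=clean,
        noisy_series=noisy,
        rec_full=sim.reconstruct_fbp(noisy, out_shape),
        rec_a=sim.reconstruct_fbp(half_a, out_shape),
        rec_b=sim.reconstruct_fbp(half_b, out_shape),
    )
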