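"""Quantitative evaluation: paired-region SNR, particle matching, PR analysis.

SNR follows the paired signal/background protocol: for N region pairs the
signal amplitude of pair i is the mean difference s_i = mean(signal_i) −
mean(background_i) and the noise power is the background variance σ²_i; the
estimate is ``10 log10[(Σ s_i²/N) / (Σ σ²_i/N)]`` in dB (ratio of means, not
mean of ratios).

Particle matching is greedy and one-to-one: found particles are processed
in descending score (ties broken lexicographically by (z, y, x)) and each
takes its nearest unmatched ground-truth position within the tolerance
radius. Precision/recall/F1, PR curves swept over score thresholds, PR-AUC
by trapezoid over recall, F1-versus-Z-score profiles and mean match
distance all build on that matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import ParticleList, Volume3D

__all__ = [
    "RegionSet",
    "MatchResult",
    "estimate_snr",
    "match_particles",
    "precision_recall_f1",
    "pr_curve",
    "f1_vs_zscore",
    "mean_match_distance",
]


@dataclass
class RegionSet:
    """Cubic regions given as ``(corner, size)`` with corner = (z, y, x)."""

    boxes: list[tuple[tuple[int, int, int], int]]
    role: Literal["signal", "background"] = "signal"

    def validate(self, shape) -> None:
        for corner, size in self.boxes:
            if size < 2:
                raise ValueError(f"region size must be >= 2 voxels, got {size}")
            c = np.asarray(corner)
            if np.any(c < 0) or np.any(c + size > np.asarray(shape)):
                raise ValueError(f"region {corner} size {size} outside volume {shape}")

    def extract(self, vol: Volume3D) -> list[np.ndarray]:
        self.validate(vol.shape)
        out = []
        for (z, y, x), s in self.boxes:
            out.append(vol.data[z:z + s, y:y + s, x:x + s].astype(np.float64))
        return out


def estimate_snr(vol: Volume3D, signal: RegionSet, background: RegionSet) -> float:
    """Paired-region SNR estimate in dB (see module docstring)."""
    sig = signal.extract(vol)
    bg = background.extract(vol)
    if len(sig) != len(bg) or len(sig) == 0:
        raise ValueError(
            f"need equal, nonzero numbers of signal/background regions "
            f"(got {len(sig)}/{len(bg)})")
    amps = np.array([s.mean() - b.mean() for s, b in zip(sig, bg)])
    variances = np.array([b.var() for b in bg])
    mean_var = variances.mean()
    if mean_var <= 0:
        raise ValueError("all background regions have zero variance; SNR undefined")
    return float(10.0 * np.log10(np.mean(amps ** 2) / mean_var))


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------


@dataclass
class MatchResult:
    """One-to-one matches between found and ground-truth particles."""

    true_positives: list[tuple[int, int, float]]  # (found idx, truth idx, distance)
    false_positive_indices: list[int]
    false_negative_truth_indices: list[int]

    @property
    def n_tp(self) -> int:
        return len(self.true_positives)

    @property
    def n_fp(self) -> int:
        return len(self.false_positive_indices)

    @property
    def n_fn(self) -> int:
        return len(self.false_negative_truth_indices)


def match_particles(found: ParticleList, truth: ParticleList,
                    tolerance: float) -> MatchResult:
    """Greedy score-ordered one-to-one matching within a Euclidean tolerance."""
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    n_found, n_truth = len(found), len(truth)
    if n_found == 0 or n_truth == 0:
        return MatchResult([], list(range(n_found)), list(range(n_truth)))
    order = np.lexsort((found.positions[:, 2], found.positions[:, 1],
                        found.positions[:, 0], -found.scores))
    dists = cdist(found.positions, truth.positions)
    taken = np.zeros(n_truth, dtype=bool)
    tps: list[tuple[int, int, float]] = []
    fps: list[int] = []
    for fi in order:
        row = np.where(taken, np.inf, dists[fi])
        ti = int(np.argmin(row))  # ties -> lowest truth index
        if row[ti] <= tolerance:
            taken[ti] = True
            tps.append((int(fi), ti, float(row[ti])))
        else:
            fps.append(int(fi))
    fns = [int(t) for t in range(n_truth) if not taken[t]]
    return MatchResult(tps, sorted(fps), fns)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """precision = tp/(tp+fp) (1 with no found), recall = tp/(tp+fn), F1 harmonic."""
    n_truth = m.n_tp + m.n_fn
    if n_truth == 0:
        raise ValueError("no ground-truth particles: recall undefined")
    precision = 1.0 if (m.n_tp + m.n_fp) == 0 else m.n_tp / (m.n_tp + m.n_fp)
    recall = m.n_tp / n_truth
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _subset(found: ParticleList, keep: np.ndarray) -> ParticleList:
    labels = ([found.labels[i] for i in np.nonzero(keep)[0]]
              if found.labels is not None else None)
    return ParticleList(found.positions[keep], found.scores[keep], labels)


def pr_curve(found: ParticleList, truth: ParticleList, tolerance: float,
             ) -> tuple[np.ndarray, float]:
    """Precision–recall curve over descending score thresholds, plus PR-AUC.

    Returns ``(curve, auc)`` where curve rows are (recall, precision) and the
    area is a trapezoid over recall after prepending the (0, precision of the
    top-scored point) boundary.
    """
    if len(truth) == 0:
        raise ValueError("empty ground truth: PR curve undefined")
    if len(found) == 0:
        return np.array([(0.0, 1.0)]), 0.0
    thresholds = np.unique(found.scores)[::-1]
    points = []
    for thr in thresholds:
        m = match_particles(_subset(found, found.scores >= thr), truth, tolerance)
        p, r, _ = precision_recall_f1(m)
        points.append((r, p))
    points = [(0.0, points[0][1])] + points
    # at equal recall keep the best precision, so extra low-score false
    # positives that add no recall cannot erode the area
    best: dict[float, float] = {}
    for r, p in points:
        best[r] = max(best.get(r, 0.0), p)
    curve = np.asarray(sorted(best.items()))
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, float(np.clip(auc, 0.0, 1.0))


def f1_vs_zscore(found: ParticleList, truth: ParticleList, tolerance: float,
                 score_population: Sequence[float],
                 n_points: int = 25) -> np.ndarray:
    """F1 at thresholds on a uniform Z-score grid spanning the found scores.

    Z-scores are standardized against ``score_population`` (typically all
    voxel scores of the map the particles were extracted from). Rows of the
    returned array are (z, f1).
    """
    pop = np.asarray(score_population, dtype=float)
    mu, sd = pop.mean(), pop.std()
    if not sd > 0:
        raise ValueError("score population has zero standard deviation")
    if len(found) == 0:
        raise ValueError("no found particles")
    z = (found.scores - mu) / sd
    grid = (np.linspace(z.min(), z.max(), n_points) if n_points > 1
            else np.array([z.min()]))
    rows = []
    for z0 in grid:
        m = match_particles(_subset(found, z >= z0 - 1e-12), truth, tolerance)
        _, _, f1 = precision_recall_f1(m)
        rows.append((z0, f1))
    return np.asarray(rows)


def mean_match_distance(m: MatchResult) -> tuple[float, float]:
    """Mean and population std (divide by n) of true-positive match distances."""
    if m.n_tp == 0:
        raise ValueError("no true positives: mean distance undefined")
    d = np.array([t[2] for t in m.true_positives])
    return float(d.mean()), float(d.std())
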