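"""Outcome measures for neurite trajectories and their statistical tests.

Tortuosity is the ratio of the traversed path length to the straight
(chord) length between the first and last points; alignment is the unsigned
angle, folded to [0, 90] degrees, between the start-to-end chord and the
grating axis.  Group comparisons mirror the standard workflow for such
data: Shapiro-Wilk normality screening, Welch's two-sided t test for
normal-looking samples, Wilcoxon rank-sum (Mann-Whitney) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TrajectoryStats",
    "tortuosity",
    "alignment_angle",
    "angular_histogram",
    "compare_groups",
    "GroupComparison",
]


@dataclass(frozen=True)
class TrajectoryStats:
    """Summary of one trajectory."""

    path_length: float
    straight_length: float
    tortuosity: float
    alignment_deg: float

    @classmethod
    def from_trajectory(cls, points, axis_direction) -> "TrajectoryStats":
        p = np.asarray(points, dtype=float)
        seg = np.diff(p, axis=0)
        path = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        chord = float(np.hypot(*(p[-1] - p[0])))
        return cls(path, chord, tortuosity(p),
                   alignment_angle(p, axis_direction))


def tortuosity(points) -> float:
    """Path length over chord length; exactly 1 for straight paths.

    Raises
    ------
    ValueError
        For fewer than two distinct points, or coincident endpoints
        (the ratio is undefined).
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("a trajectory needs at least two points")
    seg = np.diff(p, axis=0)
    path = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if path == 0.0:
        raise ValueError("degenerate trajectory: all points coincide")
    chord = float(np.hypot(*(p[-1] - p[0])))
    if chord == 0.0:
        raise ValueError("coincident endpoints: tortuosity undefined")
    return path / chord


def alignment_angle(points, axis_direction) -> float:
    """Unsigned angle (deg, in [0, 90]) between the chord and the axis.

    The axis is a direction, not a vector: a chord at 170 deg to the axis
    scores 10 deg.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("a trajectory needs at least two points")
    chord = p[-1] - p[0]
    norm = float(np.hypot(*chord))
    if norm == 0.0:
        raise ValueError("zero-length chord: alignment undefined")
    d = np.asarray(axis_direction, dtype=float)
    d = d / float(np.hypot(*d))
    cosang = abs(float(chord @ d)) / norm
    return math.degrees(math.acos(min(cosang, 1.0)))


def angular_histogram(angles_deg: Sequence[float],
                      bin_width: float = 10.0) -> np.ndarray:
    """Percentages of angles per bin over [0, 90] degrees.

    Half-open bins [lo, hi), with the final bin closed at 90; the bin width
    must divide 90.  The percentages sum to 100.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle list")
    if np.any((a < 0) | (a > 90)):
        raise ValueError("angles must lie in [0, 90] degrees")
    n_bins = 90.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide 90")
    n_bins = round(n_bins)
    idx = np.minimum((a / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return 100.0 * counts / a.size


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    shapiro_a: tuple[float, float] | None
    shapiro_b: tuple[float, float] | None


def compare_groups(sample_a, sample_b,
                   test: Literal["welch_t", "wilcoxon_rank_sum"] = "welch_t",
                   ) -> GroupComparison:
    """Two-sided comparison of two independent samples.

    ``welch_t`` is preceded by a Shapiro-Wilk normality report per sample
    (the check is reported, not enforced); ``wilcoxon_rank_sum`` is the
    two-sided Mann-Whitney U test (exact for small untied samples).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    if test == "welch_t":
        if np.std(a) == 0.0 and np.std(b) == 0.0:
            if np.mean(a) == np.mean(b):
                # identical constant samples: no evidence of a difference
                sw = (float("nan"), float("nan"))
                return GroupComparison("welch_t", 0.0, 1.0, sw, sw)
            raise ValueError("zero-variance samples: Welch t undefined")
        sa = stats.shapiro(a)
        sb = stats.shapiro(b)
        t = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison("welch_t", float(t.statistic),
                               float(t.pvalue),
                               (float(sa.statistic), float(sa.pvalue)),
                               (float(sb.statistic), float(sb.pvalue)))
    if test == "wilcoxon_rank_sum":
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("wilcoxon_rank_sum", float(r.statistic),
                               float(r.pvalue), None, None)
    raise ValueError(f"unknown test {test!r}")
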