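"""Parametric nanograting substrates and growth-cone/ridge contact geometry.

A nanograting is an anisotropic substrate of alternating parallel ridges and
grooves.  All geometry lives in the 2-D substrate plane: the grating's main
direction is the along-ridge axis, the across-grating coordinate is the
signed distance perpendicular to it.  Ridge depth ``r_d`` does not generate
out-of-plane motion; it only modulates the strength of topographic guidance
(see :mod:`filoguide.guidance`).

The growth cone is represented by a disk of radius ``r_bar`` (default
1.14 um, the mean equivalent radius of non-spread PC12 growth cones) centred
on the neurite tip.  Contact between the disk and the ridge pattern is
classified into the two canonical cases used by the outgrowth simulator:

* ``case1`` -- the centre lies in a groove and the disk overlaps ridges on
  one or both sides; two candidate limit angles are produced.
* ``case2`` -- the centre lies within a ridge (or exactly on a border); the
  limit angle is unambiguous.
* ``no_contact`` -- the disk touches no ridge (only possible for grooves
  wider than the disk diameter); there is then no topographic bias.

Candidate angles are the *limit angles* of filopodia through the K1/K2
points, the intersections of the disk boundary with a ridge edge: a ridge
edge at lateral offset ``d`` meets the disk at along-axis height
``h = sqrt(r_bar**2 - d**2)`` and subtends ``beta = arcsin(d / r_bar)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
import pandas as pd

__all__ = [
    "Grating",
    "SwallowtailGrating",
    "GrowthConeDisk",
    "ContactInfo",
    "lateral_coordinate",
    "classify_contact",
    "ridge_intersection_height",
    "local_direction",
    "band_table",
]

DEFAULT_CONE_RADIUS_UM = 1.14


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    # snap the right-angle cases so axis-aligned gratings are exact
    if abs(c) < 1e-15:
        c = 0.0
    if abs(s) < 1e-15:
        s = 0.0
    return np.array([c, s])


@dataclass(frozen=True)
class Grating:
    """Straight nanograting.

    Parameters
    ----------
    ridge_width, groove_width, ridge_depth
        Band geometry in micrometres.  ``ridge_depth = 0`` encodes a flat
        substrate.
    angle_deg
        Orientation of the main (along-ridge) direction in the substrate
        plane; 0 is the +x axis.
    phase_offset
        Lateral shift (um) of the first ridge's lower edge from the origin.
    """

    ridge_width: float
    groove_width: float
    ridge_depth: float = 0.0
    angle_deg: float = 0.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.ridge_width <= 0 or self.groove_width <= 0:
            raise ValueError("ridge_width and groove_width must be positive")
        if self.ridge_depth < 0:
            raise ValueError("ridge_depth must be non-negative")

    @property
    def period(self) -> float:
        return self.ridge_width + self.groove_width

    @property
    def main_direction(self) -> np.ndarray:
        return _unit(self.angle_deg)

    @property
    def across_direction(self) -> np.ndarray:
        """Unit normal to the ridges (main direction rotated by +90 deg)."""
        return _unit(self.angle_deg + 90.0)

    @property
    def is_flat(self) -> bool:
        return self.ridge_depth == 0.0

    @classmethod
    def from_config(cls, cfg: dict) -> "Grating":
        """Build from a config mapping with ``*_nm`` keys (nm -> um)."""
        return cls(
            ridge_width=cfg["ridge_width_nm"] / 1000.0,
            groove_width=cfg["groove_width_nm"] / 1000.0,
            ridge_depth=cfg.get("ridge_depth_nm", 0.0) / 1000.0,
            angle_deg=cfg.get("angle_deg", 0.0),
            phase_offset=cfg.get("phase_offset_nm", 0.0) / 1000.0,
        )


@dataclass(frozen=True)
class SwallowtailGrating:
    """Grating whose trunk bifurcates into two branches deviating by +-phi.

    The trunk occupies the half-plane behind ``branch_point`` (along the
    trunk direction); past the branch point the local pattern is the trunk
    grating rotated by ``+phi_deg`` (upper branch, positive across side) or
    ``-phi_deg`` (lower branch).  Points exactly on the dividing line belong
    to the positive-rotation branch (deterministic tie-break).
    """

    trunk: Grating
    phi_deg: float
    branch_point: tuple[float, float] = (0.0, 0.0)
    upper: Grating = field(init=False)
    lower: Grating = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_deg < 90.0:
            raise ValueError("tail angle phi must lie in (0, 90) degrees")
        for sign, name in ((+1.0, "upper"), (-1.0, "lower")):
            g = Grating(
                ridge_width=self.trunk.ridge_width,
                groove_width=self.trunk.groove_width,
                ridge_depth=self.trunk.ridge_depth,
                angle_deg=self.trunk.angle_deg + sign * self.phi_deg,
                phase_offset=0.0,
            )
            # register the branch pattern so the branch point keeps its
            # lateral coordinate across the trunk/branch boundary
            shift = lateral_coordinate(np.asarray(self.branch_point), self.trunk)[0] - \
                lateral_coordinate(np.asarray(self.branch_point), g)[0]
            object.__setattr__(
                self, name,
                Grating(g.ridge_width, g.groove_width, g.ridge_depth,
                        g.angle_deg, g.phase_offset - shift),
            )

    def region(self, point) -> Literal["trunk", "upper", "lower"]:
        p = np.asarray(point, dtype=float) - np.asarray(self.branch_point)
        along = float(p @ self.trunk.main_direction)
        if along < 0.0:
            return "trunk"
        across = float(p @ self.trunk.across_direction)
        return "upper" if across >= 0.0 else "lower"

    def local_grating(self, point) -> Grating:
        return {"trunk": self.trunk, "upper": self.upper,
                "lower": self.lower}[self.region(point)]


Surface = Union[Grating, SwallowtailGrating]


@dataclass(frozen=True)
class GrowthConeDisk:
    """Virtual growth cone: a disk at the distal neurite point mass."""

    center: tuple[float, float]
    radius: float = DEFAULT_CONE_RADIUS_UM

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("growth-cone radius must be positive")


@dataclass(frozen=True)
class ContactInfo:
    """Result of classifying the growth-cone disk against the ridges.

    ``candidates`` holds the signed limit angles (degrees; positive turns
    toward the +across direction).  ``case1`` always carries two entries
    (equal when only one ridge is overlapped from a groove), ``case2`` one,
    ``no_contact`` none.  ``edge_offsets`` are the corresponding lateral
    distances of the K1/K2-type ridge-edge points from the disk centre.
    """

    case: Literal["case1", "case2", "no_contact"]
    ridge_indices: tuple[int, ...]
    candidates: tuple[float, ...]
    edge_offsets: tuple[float, ...]

    def __post_init__(self) -> None:
        n = {"case1": 2, "case2": 1, "no_contact": 0}[self.case]
        if len(self.candidates) != n:
            raise ValueError(f"{self.case} requires {n} candidate angle(s)")
        if any(abs(b) > 90.0 + 1e-12 for b in self.candidates):
            raise ValueError("limit angles must satisfy |beta| <= 90 deg")


def lateral_coordinate(point, grating: Grating) -> tuple[float, str]:
    """Signed across-grating coordinate of ``point`` and its band label.

    The label is ``"ridge"`` iff the across coordinate (mod period, relative
    to ``phase_offset``) falls inside a ridge band; band borders count as
    ridge, matching the contact classification where a centre on a border is
    handled as case 2.  Independent of the along-grating coordinate.
    """
    p = np.asarray(point, dtype=float)
    y = float(p @ grating.across_direction)
    c = (y - grating.phase_offset) % grating.period
    label = "ridge" if c <= grating.ridge_width else "groove"
    return y, label


def ridge_intersection_height(edge_offset: float, radius: float) -> float:
    """Along-grating height of the K point for an edge at lateral offset d.

    Intersection of the disk boundary with the planar projection of a ridge
    edge: ``h = sqrt(radius**2 - d**2)``.

    Raises
    ------
    ValueError
        If ``edge_offset`` is negative or exceeds the radius (no
        intersection).
    """
    if edge_offset < 0:
        raise ValueError("edge offset must be non-negative")
    if edge_offset > radius:
        raise ValueError(
            f"no intersection: edge offset {edge_offset} exceeds radius {radius}"
        )
    return math.sqrt(radius * radius - edge_offset * edge_offset)


def _limit_angle_deg(d: float, radius: float) -> float:
    return math.degrees(math.asin(min(d / radius, 1.0)))


def classify_contact(disk: GrowthConeDisk, grating: Grating) -> ContactInfo:
    """Classify the virtual growth-cone disk against the ridge pattern.

    Disks overlapping more than two ridges are reduced to the nearest
    ridge(s): the main ridge acts as a filter for the global orientation.
    For a centre deep inside a very wide ridge (no edge within one radius)
    the limit angle degenerates to 0: the substrate is locally unpatterned
    and no deviation from the grating axis is preferred.
    """
    y, label = lateral_coordinate(disk.center, grating)
    P = grating.period
    r = disk.radius
    c = (y - grating.phase_offset) % P
    band = math.floor((y - grating.phase_offset) / P)

    if label == "ridge":
        d_low, d_high = c, grating.ridge_width - c
        if min(d_low, d_high) > r:
            return ContactInfo("case2", (band,), (0.0,), (0.0,))
        # limit angle toward the nearer border; exact midpoint ties to +
        if d_low < d_high:
            s, d = -1.0, d_low
        else:
            s, d = +1.0, d_high
        return ContactInfo("case2", (band,), (s * _limit_angle_deg(d, r),), (d,))

    off = c - grating.ridge_width          # position inside the groove
    d_down = off                           # to the upper edge of ridge below
    d_up = grating.groove_width - off      # to the lower edge of ridge above
    down_hit, up_hit = d_down <= r, d_up <= r
    if down_hit and up_hit:
        return ContactInfo(
            "case1", (band, band + 1),
            (-_limit_angle_deg(d_down, r), +_limit_angle_deg(d_up, r)),
            (d_down, d_up),
        )
    if down_hit or up_hit:
        s, d, idx = (-1.0, d_down, band) if down_hit else (+1.0, d_up, band + 1)
        b = s * _limit_angle_deg(d, r)
        return ContactInfo("case1", (idx, idx), (b, b), (d, d))
    return ContactInfo("no_contact", (), (), ())


def local_direction(point, surface: Surface) -> np.ndarray:
    """Unit vector of the local principal (along-ridge) direction."""
    if isinstance(surface, Grating):
        return surface.main_direction
    return surface.local_grating(point).main_direction


def band_table(grating: Grating, n_periods: int = 5) -> pd.DataFrame:
    """Debug export: band index, type and across-extent for a few periods."""
    rows = []
    for k in range(n_periods):
        lo = grating.phase_offset + k * grating.period
        rows.append({"band": k, "type": "ridge", "y_min": lo,
                     "y_max": lo + grating.ridge_width})
        rows.append({"band": k, "type": "groove",
                     "y_min": lo + grating.ridge_width,
                     "y_max": lo + grating.period})
    return pd.DataFrame(rows)
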