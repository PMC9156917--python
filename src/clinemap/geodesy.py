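"""Great-circle geometry on a spherical Earth.

Distances, initial bearings, and signed cross-track / along-track distances
used to project grid cells onto a multi-segment transect path. Points are
(lat, lon) in degrees; distances are kilometres on a sphere of mean radius
R = 6371.0088 km. ``gc_distance`` broadcasts over arrays; the track functions
take single points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def _to_rad(lat, lon):
    return np.radians(np.asarray(lat, dtype=float)), np.radians(np.asarray(lon, dtype=float))


def gc_distance(p1, p2):
    """Haversine great-circle distance in km between (lat, lon) points."""
    lat1, lon1 = _to_rad(*p1)
    lat2, lon2 = _to_rad(*p2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing(p1, p2):
    """Initial bearing in radians, in (-pi, pi], of the great circle p1 -> p2.

    Zero is due north, pi/2 due east. Identical points have no bearing.
    """
    lat1, lon1 = _to_rad(*p1)
    lat2, lon2 = _to_rad(*p2)
    if np.all(lat1 == lat2) and np.all(lon1 == lon2):
        raise ValueError("bearing undefined for identical points")
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    theta = np.arctan2(y, x)
    # arctan2 returns [-pi, pi]; map -pi (due south approached from the west) to pi
    return np.where(theta == -np.pi, np.pi, theta) if np.ndim(theta) else (
        np.pi if theta == -np.pi else float(theta)
    )


def cross_track(p, seg_start, seg_end):
    """Signed perpendicular great-circle distance (km) from p to the great
    circle through seg_start -> seg_end; the sign gives the side of the path."""
    d13 = gc_distance(seg_start, p) / EARTH_RADIUS_KM
    if np.any(np.isclose(d13, np.pi)):
        raise ValueError("point antipodal to segment start: cross-track undefined")
    if np.all(d13 == 0.0):
        return 0.0 if np.ndim(d13) == 0 else np.zeros_like(d13)
    theta13 = initial_bearing(seg_start, p)
    theta12 = initial_bearing(seg_start, seg_end)
    return float(EARTH_RADIUS_KM * np.arcsin(np.sin(d13) * np.sin(theta13 - theta12)))


def along_track(p, seg_start, seg_end):
    """Distance (km) from seg_start to the nearest point to p on the great
    circle, negative when the projection falls behind seg_start."""
    d13 = gc_distance(seg_start, p) / EARTH_RADIUS_KM
    if np.all(d13 == 0.0):
        return 0.0
    dxt = cross_track(p, seg_start, seg_end) / EARTH_RADIUS_KM
    ratio = np.clip(np.cos(d13) / np.cos(dxt), -1.0, 1.0)
    dat = np.arccos(ratio)
    # the projection is behind seg_start when p lies more than 90 degrees of
    # bearing away from the segment direction
    theta13 = initial_bearing(seg_start, p)
    theta12 = initial_bearing(seg_start, seg_end)
    behind = np.cos(theta13 - theta12) < 0.0
    return float(EARTH_RADIUS_KM * np.where(behind, -dat, dat))


@dataclass
class Transect:
    """A named great-circle path: >= 2 waypoints and a corridor half-width."""

    name: str
    waypoints: list  # [(lat, lon), ...]
    corridor_halfwidth: float = 450.0

    def __post_init__(self) -> None:
        if len(self.waypoints) < 2:
            raise ValueError("a transect needs at least two waypoints")
        self.waypoints = [(float(a), float(b)) for a, b in self.waypoints]
        for a, b in zip(self.waypoints, self.waypoints[1:]):
            if a == b:
                raise ValueError("consecutive waypoints must be distinct")

    @property
    def segment_lengths(self) -> list:
        return [
            float(gc_distance(a, b))
            for a, b in zip(self.waypoints, self.waypoints[1:])
        ]

    @property
    def length(self) -> float:
        return sum(self.segment_lengths)

    @property
    def cumulative(self) -> list:
        """Cumulative along-path distance to the start of each segment."""
        out, acc = [], 0.0
        for L in self.segment_lengths:
            out.append(acc)
            acc += L
        return out

    def reversed(self) -> "Transect":
        return Transect(
            name=f"{self.name} (reversed)",
            waypoints=list(reversed(self.waypoints)),
            corridor_halfwidth=self.corridor_halfwidth,
        )

    @classmethod
    def from_json(cls, path) -> "Transect":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            name=d["name"],
            waypoints=[tuple(w) for w in d["waypoints"]],
            corridor_halfwidth=d.get("corridor_km", 450.0),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "name": self.name,
                    "waypoints": [list(w) for w in self.waypoints],
                    "corridor_km": self.corridor_halfwidth,
                },
                fh,
                indent=2,
            )


def project_point(p, transect: Transect):
    """Project one point onto a transect.

    Returns (along_km, cross_km) for the minimising segment, or None when the
    point's perpendicular projection falls outside every segment's span.
    along_km is cumulative along the whole path.
    """
    best = None
    cum = transect.cumulative
    lengths = transect.segment_lengths
    for i, (a, b) in enumerate(zip(transect.waypoints, transect.waypoints[1:])):
        xt = cross_track(p, a, b)
        at = along_track(p, a, b)
        if at < 0.0 or at > lengths[i]:
            continue
        if best is None or abs(xt) < abs(best[1]):
            best = (cum[i] + at, xt)
    return best


@dataclass(frozen=True)
class ProjectedCell:
    cell_index: tuple
    along_km: float
    cross_km: float
    q_hat: float
    n_scored: int


def project_cells(grid, transect: Transect, locus: str) -> list:
    """Project grid cells with a defined frequency at ``locus`` onto a transect.

    A cell is kept when its centre projects perpendicularly onto some segment
    and the minimal |cross-track| distance is within the corridor half-width.
    """
    out = []
    for idx, cell in grid.cells.items():
        if cell.n_scored.get(locus, 0) == 0:
            continue
        proj = project_point(cell.centre, transect)
        if proj is None:
            continue
        along, cross = proj
        if abs(cross) > transect.corridor_halfwidth:
            continue
        out.append(
            ProjectedCell(
                cell_index=idx,
                along_km=along,
                cross_km=cross,
                q_hat=cell.q_hat(locus),
                n_scored=cell.n_scored[locus],
            )
        )
    if not out:
        raise ValueError(
            f"no cell within {transect.corridor_halfwidth} km of transect "
            f"{transect.name!r} with data at locus {locus}"
        )
    out.sort(key=lambda c: c.along_km)
    return out
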