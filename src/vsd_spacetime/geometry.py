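"""Hexagonal photodiode-array geometry and zone partitions.

The recordings this package analyses come from a 464-channel hexagonal
photodiode array imaging a ~12 mm^2 patch of visual cortex covering areas
17, 18, 19 and 21.  The exact diode layout of the physical camera is not
public; all downstream computations only consume channel positions, so the
geometry here is a centered hexagonal lattice truncated to the requested
number of sites, with a pitch whose default reproduces the 12 mm^2 aperture
for 464 channels.

Conventions: channel ids are dense 0-based integers; positions are (x, y)
in mm on the cortical sheet; area labels are the integers {17, 18, 19, 21}
assigned in horizontal bands from the top (area 17) to the bottom (area 21)
of the aperture, mimicking the anterior-posterior arrangement of the ferret
visual areas.  A channel exactly on a band border belongs to the upper
(area-17) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexGeometry",
    "ZoneMap",
    "build_hex_geometry",
    "assign_zones",
    "cfov_centers",
]

#: Default inter-diode pitch (mm).  464 sites of a hexagonal lattice at this
#: pitch tile ~13 mm^2 (one lattice cell is sqrt(3)/2 * pitch^2), matching the
#: stated 12 mm^2 cortical aperture to within 15%.
DEFAULT_PITCH_MM = 0.18

AREA_LABELS = (17, 18, 19, 21)


@dataclass(frozen=True)
class HexGeometry:
    """Channel positions and cortical-area labels of the imaging array.

    Attributes
    ----------
    pos : (C, 2) float array of channel positions in mm.
    area : (C,) int array with values in {17, 18, 19, 21}.
    pitch_mm : nearest-neighbour spacing of the lattice.
    """

    pos: np.ndarray
    area: np.ndarray
    pitch_mm: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos, dtype=float)
        area = np.asarray(self.area, dtype=int)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("pos must be a (C, 2) array")
        if area.shape != (pos.shape[0],):
            raise ValueError("area must have one label per channel")
        bad = set(np.unique(area)) - set(AREA_LABELS)
        if bad:
            raise ValueError(f"unknown area labels: {sorted(bad)}")
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "area", area)

    @property
    def n_channels(self) -> int:
        return self.pos.shape[0]

    def distances_from(self, origin) -> np.ndarray:
        """Euclidean distance (mm) of every channel from ``origin``.

        ``origin`` may be an (x, y) pair or a channel id.
        """
        origin = np.asarray(self._resolve_point(origin), dtype=float)
        return np.hypot(*(self.pos - origin).T)

    def _resolve_point(self, point):
        if np.isscalar(point) or (isinstance(point, np.ndarray) and point.ndim == 0):
            return self.pos[int(point)]
        return np.asarray(point, dtype=float)

    def nearest_channels(self, center, k: int) -> np.ndarray:
        """Ids of the ``k`` channels nearest ``center`` (ties by channel id)."""
        d = self.distances_from(center)
        order = np.lexsort((np.arange(self.n_channels), np.round(d, 12)))
        return np.sort(order[:k])

    def area_channels(self, areas) -> np.ndarray:
        """Channel ids whose area label is in ``areas`` (int or iterable)."""
        if np.isscalar(areas):
            areas = (areas,)
        return np.flatnonzero(np.isin(self.area, list(areas)))

    def hull_area_mm2(self) -> float:
        """Area of the convex hull of the channel positions (mm^2)."""
        from scipy.spatial import ConvexHull

        return float(ConvexHull(self.pos).volume)


@dataclass(frozen=True)
class ZoneMap:
    """A partition of the channels into named zones."""

    zone: np.ndarray  # (C,) array of zone-name strings
    names: tuple = field(default=())

    def __post_init__(self) -> None:
        zone = np.asarray(self.zone, dtype=object)
        names = tuple(self.names) if self.names else tuple(dict.fromkeys(zone))
        missing = set(zone) - set(names)
        if missing:
            raise ValueError(f"zones not declared in names: {sorted(missing)}")
        object.__setattr__(self, "zone", zone)
        object.__setattr__(self, "names", names)

    def channels(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.zone == name)

    def counts(self) -> dict:
        return {n: int(np.sum(self.zone == n)) for n in self.names}

    def to_tsv(self, path) -> None:
        """Write the per-channel zone assignment as tab-separated text."""
        import pandas as pd

        frame = pd.DataFrame({"zone": self.zone})
        frame.to_csv(path, sep="\t", index_label="channel")


def _hex_lattice(n_rings: int, pitch_mm: float) -> np.ndarray:
    """All sites of a centered hexagonal lattice with ``n_rings`` rings."""
    a = np.array([1.0, 0.0])
    b = np.array([0.5, np.sqrt(3.0) / 2.0])
    pts = []
    for i in range(-n_rings, n_rings + 1):
        for j in range(-n_rings, n_rings + 1):
            if abs(i + j) <= n_rings:
                pts.append(i * a + j * b)
    return pitch_mm * np.asarray(pts)


def build_hex_geometry(
    n_channels: int,
    pitch_mm: float = DEFAULT_PITCH_MM,
    area_fractions=(0.25, 0.5, 0.75),
) -> HexGeometry:
    """Build a centered hexagonal array of ``n_channels`` diodes.

    Sites of a hexagonal lattice are ranked by distance from the center
    (ties broken by polar angle) and the nearest ``n_channels`` kept, giving
    a roughly circular aperture.  Deterministic: identical inputs produce
    bit-identical coordinates.

    Parameters
    ----------
    n_channels : number of diodes (>= 7, i.e. at least center + first ring).
    pitch_mm : nearest-neighbour spacing in mm (> 0).
    area_fractions : increasing y-quantile cut points splitting the aperture
        into the 4 area bands 21 | 19 | 18 | 17 from bottom to top.
    """
    if n_channels < 7:
        raise ValueError("n_channels must be >= 7 (center plus one ring)")
    if pitch_mm <= 0:
        raise ValueError("pitch_mm must be positive")
    # enough rings that the truncated disc surely fits
    n_rings = int(np.ceil(np.sqrt(n_channels / 3.0))) + 2
    pts = _hex_lattice(n_rings, pitch_mm)
    if len(pts) < n_channels:  # pragma: no cover - generous ring margin
        raise ValueError(
            f"lattice with {n_rings} rings has only {len(pts)} sites; "
            "increase the ring count"
        )
    r = np.hypot(pts[:, 0], pts[:, 1])
    theta = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
    order = np.lexsort((theta, np.round(r / pitch_mm, 9)))
    pos = pts[order[:n_channels]]

    qs = np.quantile(pos[:, 1], area_fractions)
    area = np.empty(n_channels, dtype=int)
    y = pos[:, 1]
    area[y < qs[0]] = 21
    area[(y >= qs[0]) & (y < qs[1])] = 19
    area[(y >= qs[1]) & (y < qs[2])] = 18
    area[y >= qs[2]] = 17
    return HexGeometry(pos=pos, area=area, pitch_mm=float(pitch_mm))


def cfov_centers(geometry: HexGeometry) -> dict:
    """Retinotopic centers of the CFOV representations.

    The center of field of view is mapped twice, at the area 17/18 border and
    at the area 19/21 border.  Returns ``{"cfov_1718": (x, y),
    "cfov_1921": (x, y)}`` at the mid-x of the respective border.
    """
    x0 = float(np.mean(geometry.pos[:, 0]))
    y = geometry.pos[:, 1]
    # the 17/18 and 19/21 borders sit at the upper and lower area-band cuts
    return {"cfov_1718": (x0, float(np.quantile(y, 0.75))),
            "cfov_1921": (x0, float(np.quantile(y, 0.25)))}


def _border_y_at(polyline: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Piecewise-linear border height y(x), constant beyond the endpoints."""
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
        raise ValueError("each border polyline needs >= 2 (x, y) points")
    order = np.argsort(poly[:, 0], kind="stable")
    px, py = poly[order, 0], poly[order, 1]
    return np.interp(x, px, py)


def assign_zones(
    geometry: HexGeometry,
    borders=(),
    zone_names=None,
    cfov=None,
    k: int = 4,
) -> ZoneMap:
    """Partition the channels into zones by border polylines and CFOV centers.

    ``borders`` is a sequence of polylines ((P, 2) point arrays) ordered from
    the area-17 (top) side downward; a channel below ``m`` borders gets zone
    ``zone_names[m]``.  A channel exactly on a border is assigned to the zone
    above it (the area-17 side).  A border lying entirely outside the aperture
    leaves every channel on one side, collapsing the partition.

    ``cfov`` maps zone names to (x, y) centers; each claims the ``k`` channels
    nearest its center (default 4, the number of diodes sampling the CFOV
    representation).  CFOV zones override the border zones; if two CFOV zones
    contest a channel the earlier-declared zone keeps it.
    """
    borders = list(borders)
    if zone_names is None:
        zone_names = [f"zone_{i}" for i in range(len(borders) + 1)]
    if len(zone_names) != len(borders) + 1:
        raise ValueError("need exactly one more zone name than borders")

    x, y = geometry.pos[:, 0], geometry.pos[:, 1]
    below = np.zeros(geometry.n_channels, dtype=int)
    for poly in borders:
        below += (y < _border_y_at(poly, x)).astype(int)
    zone = np.asarray([zone_names[m] for m in below], dtype=object)

    names = list(zone_names)
    if cfov:
        claimed = np.zeros(geometry.n_channels, dtype=bool)
        for name, center in cfov.items():
            idx = geometry.nearest_channels(center, k)
            idx = idx[~claimed[idx]]
            zone[idx] = name
            claimed[idx] = True
            names.append(name)
    # drop names that ended up empty (e.g. degenerate borders)
    names = [n for n in names if np.any(zone == n)]
    return ZoneMap(zone=zone, names=tuple(names))
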