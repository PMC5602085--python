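"""Spatial objects and cross-modality correspondence.

The three instruments probe overlapping patches of the central retina in
different native units: the multifocal ERG stimulates scaled hexagons in
visual-field degrees, perimetry tests discrete point locations in degrees,
and the OCT reports thicknesses over millimetre grids on the retina.  This
module holds the hexagon layout, named regional masks (central 7 / central
19 hexagons, SAP point sets), the mm <-> degree conversion, and the
centrifugal ganglion-cell displacement used when matching perimetry points
to ganglion-cell locations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, RangeError

#: Default retina-to-visual-field conversion.  With 3.3 deg/mm the 4.0 mm
#: vertical and 4.8 mm horizontal diameters of the ganglion-cell annulus map
#: to 13.2 deg and 15.8 deg of visual field.
DEG_PER_MM = 3.3

#: Ganglion-cell displacement anchors (eccentricity mm -> displacement mm).
#: Displacement is maximal near 1 mm and negligible by 4 mm.
_DISPLACEMENT_ANCHORS = ((1.0, 0.62), (4.0, 0.12))


# ---------------------------------------------------------------------------
# Hexagon layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HexLayout:
    """A multifocal stimulus layout of scaled hexagons.

    Attributes
    ----------
    centers : (n, 2) array
        Hexagon centres in visual-field degrees, fovea at the origin,
        right-eye orientation.
    areas : (n,) array
        Relative solid-angle scale factor per hexagon (ring 0 == 1).
    ring_index : (n,) int array
        Hexagonal ring of each element (0 = central hexagon).
    """

    centers: np.ndarray
    areas: np.ndarray
    ring_index: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        r = np.asarray(self.ring_index, dtype=int)
        if c.ndim != 2 or c.shape[1] != 2 or len(a) != len(c) or len(r) != len(c):
            raise DataError("inconsistent layout arrays")
        if np.any(a <= 0):
            raise DataError("hexagon areas must be positive")
        if np.any(r < 0):
            raise DataError("ring indices must be non-negative")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "ring_index", r)

    @property
    def n_hexagons(self) -> int:
        return len(self.ring_index)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_hexagons)

    @property
    def max_ring(self) -> int:
        return int(self.ring_index.max())

    def to_frame(self) -> pd.DataFrame:
        """Serializable table (id, x_deg, y_deg, ring, area_scale)."""
        return pd.DataFrame({
            "id": self.ids,
            "x_deg": self.centers[:, 0],
            "y_deg": self.centers[:, 1],
            "ring": self.ring_index,
            "area_scale": self.areas,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HexLayout":
        df = df.sort_values("id")
        return cls(
            centers=df[["x_deg", "y_deg"]].to_numpy(float),
            areas=df["area_scale"].to_numpy(float),
            ring_index=df["ring"].to_numpy(int),
        )


@dataclass(frozen=True)
class RegionMask:
    """A named spatial subset of one modality's elements.

    ``member_ids`` must be unique; they index into the referenced layout or
    point table.  An empty mask is permitted (a selection can legitimately
    come up empty) but is flagged with a warning at construction.
    """

    modality: str
    member_ids: tuple
    label: str

    def __post_init__(self):
        ids = tuple(sorted(self.member_ids))
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate ids in mask {self.label!r}")
        if not ids:
            warnings.warn(f"region mask {self.label!r} is empty", stacklevel=3)
        object.__setattr__(self, "member_ids", ids)

    def __len__(self) -> int:
        return len(self.member_ids)

    def to_dict(self) -> dict:
        return {"modality": self.modality, "label": self.label,
                "member_ids": list(self.member_ids)}


@dataclass(frozen=True)
class AnnulusSpec:
    """Elliptical annulus over which ganglion-cell layer thickness is averaged.

    Diameters are on the retina in mm.  The inner exclusion removes the
    foveola, where ganglion cells are displaced away from their receptive
    fields and the layer is anatomically absent.
    """

    vertical_diameter: float = 4.0
    horizontal_diameter: float = 4.8
    inner_exclusion_diameter: float = 1.0

    def __post_init__(self):
        if min(self.vertical_diameter, self.horizontal_diameter,
               self.inner_exclusion_diameter) <= 0:
            raise ConfigurationError("annulus diameters must be positive")
        if self.inner_exclusion_diameter >= min(self.vertical_diameter,
                                                self.horizontal_diameter):
            raise ConfigurationError("inner exclusion must be smaller than the annulus")


def _axial_patch(max_ring: int) -> list[tuple[int, int, int]]:
    """All axial hex coordinates (q, r) with hex-ring distance <= max_ring."""
    cells = []
    for q in range(-max_ring, max_ring + 1):
        for r in range(-max_ring, max_ring + 1):
            ring = max(abs(q), abs(r), abs(q + r))
            if ring <= max_ring:
                cells.append((q, r, ring))
    return cells


def _axial_to_xy(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    x = q + 0.5 * r
    y = (math.sqrt(3) / 2.0) * r
    return np.column_stack([x, y])


def build_hex_layout(preset: str | pd.DataFrame = "veris103",
                     eccentricity_scaling: float = 1.3,
                     extent_radius_deg: float = 23.0) -> HexLayout:
    """Build a multifocal hexagon layout.

    The shipped ``"veris103"`` preset is a 103-element quasi-circular patch
    covering the central 50 degrees: full hexagonal rings 0-5 (91 elements)
    plus the 12 nearest elements of ring 6.  Hexagon area grows with ring
    index by ``eccentricity_scaling`` per ring, emulating the eccentricity
    scaling that approximately equalizes per-element response amplitude.

    A :class:`pandas.DataFrame` with columns (id, x_deg, y_deg, ring,
    area_scale) may be passed instead for a user-defined grid.
    """
    if isinstance(preset, pd.DataFrame):
        return HexLayout.from_frame(preset)
    if preset == "veris103":
        cells = _axial_patch(6)
    else:
        raise ConfigurationError(f"unknown layout preset {preset!r}")
    if eccentricity_scaling <= 0:
        raise ConfigurationError("eccentricity_scaling must be positive")

    q = np.array([c[0] for c in cells])
    r = np.array([c[1] for c in cells])
    ring = np.array([c[2] for c in cells])
    xy = _axial_to_xy(q, r)
    if preset == "veris103":
        # keep rings 0-5 complete, then the 12 ring-6 cells closest to centre
        # (drops the 6 corner cells), giving 103 elements.
        radius = np.hypot(xy[:, 0], xy[:, 1])
        keep = ring <= 5
        ring6 = np.flatnonzero(ring == 6)
        keep[ring6[np.argsort(radius[ring6])[:12]]] = True
        xy, ring = xy[keep], ring[keep]

    # radial stretch: ring-k centres pushed out by scaling^(k/2) so larger
    # peripheral hexagons do not overlap; then normalize the extent.
    stretch = eccentricity_scaling ** (ring / 2.0)
    xy = xy * stretch[:, None]
    rmax = np.hypot(xy[:, 0], xy[:, 1]).max()
    if rmax > 0:
        xy = xy * (extent_radius_deg / rmax)
    areas = eccentricity_scaling ** ring.astype(float)

    order = np.lexsort((np.arctan2(xy[:, 1], xy[:, 0]), ring))
    return HexLayout(centers=xy[order], areas=areas[order], ring_index=ring[order])


def central_hexagons(layout: HexLayout, n_rings: int) -> RegionMask:
    """Mask of all hexagons with ring index <= ``n_rings``.

    ``n_rings=1`` gives the central 7 hexagons (about 10 degrees for the
    default layout); ``n_rings=2`` the central 19 (about 15 degrees).
    """
    if n_rings < 0 or n_rings > layout.max_ring:
        raise RangeError(f"n_rings={n_rings} outside 0..{layout.max_ring}")
    ids = tuple(np.flatnonzero(layout.ring_index <= n_rings))
    label = {1: "central10", 2: "central15"}.get(n_rings, f"central_rings{n_rings}")
    return RegionMask(modality="mfERG", member_ids=ids, label=label)


def mm_to_degrees(length_mm, factor: float = DEG_PER_MM):
    """Convert a retinal length in mm to visual-field degrees (linear map)."""
    if factor <= 0:
        raise ConfigurationError("degrees-per-mm factor must be positive")
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(length_mm < 0):
        raise RangeError("length must be non-negative")
    out = length_mm * factor
    return float(out) if out.ndim == 0 else out


def drasdo_displacement(eccentricity_mm):
    """Centrifugal ganglion-cell displacement (mm) at a retinal eccentricity.

    Piecewise-linear through the anchors (1 mm, 0.62 mm) and (4 mm, 0.12 mm),
    held constant outside [1, 4] mm.  Ganglion cell bodies near the fovea sit
    peripheral to their receptive fields by this amount.
    """
    ecc = np.asarray(eccentricity_mm, dtype=float)
    if np.any(ecc < 0):
        raise RangeError("eccentricity must be non-negative")
    (x0, y0), (x1, y1) = _DISPLACEMENT_ANCHORS
    out = np.interp(ecc, [x0, x1], [y0, y1])
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Perimetry point geometry
# ---------------------------------------------------------------------------

def g2_point_table() -> pd.DataFrame:
    """A G2-style perimetry point grid (synthetic stand-in).

    56 locations on concentric rings out to 26 degrees, denser centrally,
    mimicking the central emphasis of the G2 test pattern.  Columns:
    point_id, x_deg, y_deg.
    """
    rings = [  # (eccentricity deg, n points, angular offset deg)
        (2.8, 4, 45.0),
        (5.0, 8, 22.5),
        (8.0, 12, 15.0),
        (12.0, 8, 0.0),
        (15.0, 8, 22.5),
        (21.0, 8, 0.0),
        (26.0, 8, 22.5),
    ]
    rows = []
    pid = 0
    for ecc, n, off in rings:
        for k in range(n):
            ang = math.radians(off + 360.0 * k / n)
            rows.append((pid, ecc * math.cos(ang), ecc * math.sin(ang)))
            pid += 1
    return pd.DataFrame(rows, columns=["point_id", "x_deg", "y_deg"])


def default_additional_15deg_points(point_table: pd.DataFrame) -> tuple:
    """Default 4 extra points completing the 15-degree perimetry set.

    One per quadrant, chosen from the ~12-degree ring at the diagonals
    (their displaced ganglion-cell eccentricity falls inside the annulus
    extent).  User-overridable in :func:`select_sap_points`.
    """
    ecc = np.hypot(point_table["x_deg"], point_table["y_deg"])
    ring12 = point_table[np.isclose(ecc, 12.0, atol=0.5)]
    chosen = []
    for qx, qy in ((1, 1), (-1, 1), (-1, -1), (1, -1)):
        quad = ring12[(np.sign(ring12["x_deg"]) == qx)
                      & (np.sign(ring12["y_deg"]) == qy)]
        if len(quad):
            d = np.abs(np.arctan2(quad["y_deg"], quad["x_deg"])
                       - math.atan2(qy, qx))
            chosen.append(int(quad.iloc[int(np.argmin(d))]["point_id"]))
    return tuple(sorted(chosen))


def displaced_eccentricity_deg(x_deg, y_deg, deg_per_mm: float = DEG_PER_MM):
    """Eccentricity of the ganglion cells serving a visual-field point.

    The point's nominal eccentricity plus the centrifugal displacement,
    expressed back in degrees.
    """
    ecc_deg = np.hypot(np.asarray(x_deg, float), np.asarray(y_deg, float))
    ecc_mm = ecc_deg / deg_per_mm
    return ecc_deg + mm_to_degrees(drasdo_displacement(ecc_mm), deg_per_mm)


def select_sap_points(point_table: pd.DataFrame, region: str,
                      extra_point_ids: tuple | None = None,
                      displacement: bool = True,
                      deg_per_mm: float = DEG_PER_MM) -> RegionMask:
    """Select the perimetry points for the central 10 or 15 degree analysis.

    ``central10``: every point whose (displacement-corrected) eccentricity is
    within 10 degrees.  ``central15``: the central-10 set plus exactly four
    configured additional points, so the two masks are nested by
    construction.
    """
    if region not in ("central10", "central15"):
        raise ConfigurationError(f"unknown SAP region {region!r}")
    if displacement:
        ecc_eff = displaced_eccentricity_deg(point_table["x_deg"],
                                             point_table["y_deg"], deg_per_mm)
    else:
        ecc_eff = np.hypot(point_table["x_deg"], point_table["y_deg"])
    central10 = set(point_table.loc[np.asarray(ecc_eff) <= 10.0,
                                    "point_id"].astype(int))
    if region == "central10":
        return RegionMask("SAP", tuple(central10), "central10")

    if extra_point_ids is None:
        extra_point_ids = default_additional_15deg_points(point_table)
    extra = set(int(i) for i in extra_point_ids)
    known = set(point_table["point_id"].astype(int))
    if not extra <= known:
        raise ConfigurationError("additional 15-degree points missing from table")
    if extra & central10:
        raise ConfigurationError(
            "central15 additional points overlap the central10 set; "
            "the 15-degree set must extend the 10-degree set by 4 points")
    if len(extra) != 4:
        raise ConfigurationError("exactly 4 additional points required for central15")
    return RegionMask("SAP", tuple(central10 | extra), "central15")
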