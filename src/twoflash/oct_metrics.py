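"""Macular OCT summaries and normative-percentile flags.

Two structural measures are used: full macular thickness (mT) averaged over
the central 1 mm disc plus the 1-3 mm inner ring of the ETDRS grid
(area-weighted), and the ganglion cell + inner plexiform layer (GCIPL)
thickness averaged over an elliptical annulus (4.8 mm horizontal x 4.0 mm
vertical, 1 mm foveolar exclusion).  Sector values are flagged yellow/red
against the 5th/1st percentile of a control-derived normative sample, the
convention of clinical device printouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .geometry import AnnulusSpec

#: ETDRS sector names: centre disc, inner-ring and outer-ring quadrants.
ETDRS_SECTORS = ("center",
                 "inner_superior", "inner_nasal", "inner_inferior", "inner_temporal",
                 "outer_superior", "outer_nasal", "outer_inferior", "outer_temporal")

#: Six GCIPL wedge sectors of the elliptical annulus.
GCIPL_SECTORS = ("superior", "superonasal", "inferonasal",
                 "inferior", "inferotemporal", "superotemporal")

# disk/ring radii of the ETDRS grid in mm
_R_CENTER, _R_INNER = 0.5, 1.5


@dataclass(frozen=True)
class OctSummary:
    """Per-eye OCT feature set: central mT, GCIPL annulus mean, sector flags."""

    eye_id: str
    mT_central: float
    gcipl_mean: float
    mt_sectors: dict
    gcipl_sectors: dict
    mt_flags: dict = field(default_factory=dict)
    gcipl_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mT_central <= 0 or self.gcipl_mean <= 0:
            raise DataError("thicknesses must be positive")


@dataclass
class NormativeDB:
    """Control-derived quantiles used by every abnormality criterion.

    Built exclusively from control-group records.  Tables:

    mferg
        index dc10..ic2_15, columns q01/q025/q05/q50/q95/q975/q99 (µV).
    sap_points
        index point_id, columns mean_db plus the point-wise probability-class
        quantiles q05/q02/q01/q005 of measured sensitivity (dB).
    mt_sectors / gcipl_sectors
        index sector name, columns q01/q05 (µm).
    """

    n_controls: int
    seed: int | None
    mferg: pd.DataFrame
    sap_points: pd.DataFrame
    mt_sectors: pd.DataFrame
    gcipl_sectors: pd.DataFrame
    control_mean_age: float = 50.0
    age_correction_db_per_decade: float = -0.1

    def __post_init__(self):
        for tbl in (self.mferg, self.sap_points, self.mt_sectors,
                    self.gcipl_sectors):
            qcols = sorted([c for c in tbl.columns if c.startswith("q")],
                           key=_qlevel)
            arr = tbl[qcols].to_numpy(float)
            if np.any(np.diff(arr, axis=1) < -1e-9):
                raise DataError("normative quantiles are not ordered")

    def sap_normal_db(self, point_id: int, age: float) -> float:
        """Age-corrected normal sensitivity for a point (dB)."""
        base = float(self.sap_points.loc[point_id, "mean_db"])
        return base + self.age_correction_db_per_decade * (age - self.control_mean_age) / 10.0


def _qlevel(col: str) -> float:
    # 'q005' -> 0.5, 'q01' -> 1, 'q025' -> 2.5, 'q05' -> 5, 'q50' -> 50 ...
    return {"q005": 0.5, "q01": 1.0, "q02": 2.0, "q025": 2.5, "q05": 5.0,
            "q50": 50.0, "q95": 95.0, "q975": 97.5, "q99": 99.0}[col]


def empirical_quantiles(values: np.ndarray, levels: dict[str, float]) -> dict:
    """Empirical quantiles (linear interpolation) at the named levels (%)."""
    values = np.asarray(values, dtype=float)
    return {name: float(np.quantile(values, lvl / 100.0))
            for name, lvl in levels.items()}


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def etdrs_central_mT(sector_values: dict) -> float:
    """Central macular thickness: area-weighted mean of the ETDRS centre disc
    and the four inner-ring quadrants (1 + 3 mm circles); the outer ring is
    ignored.

    Weights are the geometric sector areas: pi*0.5^2 for the centre and
    pi*(1.5^2 - 0.5^2)/4 per inner quadrant.
    """
    missing = [s for s in ETDRS_SECTORS if s not in sector_values]
    if missing:
        raise DataError(f"missing ETDRS sectors: {missing}")
    a_center = np.pi * _R_CENTER ** 2
    a_inner_quadrant = np.pi * (_R_INNER ** 2 - _R_CENTER ** 2) / 4.0
    num = sector_values["center"] * a_center
    den = a_center
    for s in ETDRS_SECTORS[1:5]:
        num += sector_values[s] * a_inner_quadrant
        den += a_inner_quadrant
    return float(num / den)


def gcipl_annulus_mean(values, spec: AnnulusSpec = AnnulusSpec(),
                       grid_n: int = 481) -> float:
    """Mean GCIPL thickness over the elliptical annulus.

    ``values`` is either a dict of the 6 wedge sectors (unweighted mean; the
    device sectors are near-equal-area by construction) or a callable
    ``f(x_mm, y_mm)`` thickness map, integrated numerically over the annulus
    (outer ellipse minus the scaled inner foveolar exclusion).  The central
    exclusion never contributes.
    """
    if isinstance(values, dict):
        missing = [s for s in GCIPL_SECTORS if s not in values]
        if missing:
            raise DataError(f"missing GCIPL sectors: {missing}")
        return float(np.mean([values[s] for s in GCIPL_SECTORS]))

    ax, ay = spec.horizontal_diameter / 2.0, spec.vertical_diameter / 2.0
    # inner exclusion: ellipse of the same aspect ratio, vertical diameter =
    # inner_exclusion_diameter
    scale = spec.inner_exclusion_diameter / spec.vertical_diameter
    bx, by = ax * scale, ay * scale
    x = np.linspace(-ax, ax, grid_n)
    y = np.linspace(-ay, ay, grid_n)
    X, Y = np.meshgrid(x, y)
    inside = ((X / ax) ** 2 + (Y / ay) ** 2 <= 1.0) \
        & ((X / bx) ** 2 + (Y / by) ** 2 > 1.0)
    thick = np.asarray(values(X, Y), dtype=float)
    return float(thick[inside].mean())


def flag_sectors(sector_values: dict, normative_sectors: pd.DataFrame) -> dict:
    """Yellow/red flags per sector against normative percentiles.

    red if value <= 1st percentile; yellow if <= 5th percentile (and above
    the 1st); otherwise normal.  Boundaries are inclusive, matching the
    '<=5% / <=1% of normal population' device convention.
    """
    flags = {}
    for sector, value in sector_values.items():
        if sector not in normative_sectors.index:
            raise DataError(f"sector {sector!r} absent from normative table")
        q01 = normative_sectors.loc[sector, "q01"]
        q05 = normative_sectors.loc[sector, "q05"]
        if value <= q01:
            flags[sector] = "red"
        elif value <= q05:
            flags[sector] = "yellow"
        else:
            flags[sector] = "normal"
    return flags


def summarize_oct(eye_id: str, mt_sectors: dict, gcipl_sectors: dict,
                  normative: NormativeDB | None = None) -> OctSummary:
    """Bundle the per-eye OCT features, with sector flags when a normative
    database is supplied."""
    mt_flags = flag_sectors(mt_sectors, normative.mt_sectors) if normative else {}
    gc_flags = flag_sectors(gcipl_sectors, normative.gcipl_sectors) if normative else {}
    return OctSummary(
        eye_id=eye_id,
        mT_central=etdrs_central_mT(mt_sectors),
        gcipl_mean=gcipl_annulus_mean(gcipl_sectors),
        mt_sectors=dict(mt_sectors), gcipl_sectors=dict(gcipl_sectors),
        mt_flags=mt_flags, gcipl_flags=gc_flags,
    )
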