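"""Perimetry summaries: linear mean sensitivity and mean defect.

Point sensitivities arrive in dB.  Because the dB scale is logarithmic,
sensitivities are converted point-wise to linear units (10^(dB/10)) *before*
averaging — the mean of 20 and 30 dB in linear units is 550, not 10^2.5 —
giving the regional linear mean sensitivities MS10 and MS15.  The mean
defect (MD) stays in dB: the mean of (age-corrected normal minus measured)
over the region, positive = loss (Octopus convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .geometry import RegionMask
from .oct_metrics import NormativeDB

#: Probability classes of the point-wise deviation plot, from the normative
#: point distributions.  Ordered from least to most abnormal.
PROBABILITY_CLASSES = (">=5%", "<5%", "<2%", "<1%", "<0.5%")


@dataclass(frozen=True)
class FieldSummary:
    """Per-eye perimetry features for the central 10/15 degree analysis."""

    eye_id: str
    ms10_linear: float
    ms15_linear: float
    md10_db: float
    md15_db: float
    global_md_db: float
    per_point_probability: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)  # label -> tuple of point ids

    def __post_init__(self):
        if self.ms10_linear <= 0 or self.ms15_linear <= 0:
            raise DataError("linear mean sensitivities must be positive")
        bad = set(self.per_point_probability.values()) - set(PROBABILITY_CLASSES)
        if bad:
            raise DataError(f"unknown probability classes {bad}")


def db_to_linear(sensitivity_db):
    """Decibel sensitivity to linear (relative 1/Lambert) units: 10^(dB/10)."""
    arr = np.asarray(sensitivity_db, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("sensitivities must be finite")
    out = np.power(10.0, arr / 10.0)
    return float(out) if out.ndim == 0 else out


def _probability_class(measured_db: float, point_row: pd.Series) -> str:
    if measured_db < point_row["q005"]:
        return "<0.5%"
    if measured_db < point_row["q01"]:
        return "<1%"
    if measured_db < point_row["q02"]:
        return "<2%"
    if measured_db < point_row["q05"]:
        return "<5%"
    return ">=5%"


def regional_field_summary(field: pd.DataFrame, normative: NormativeDB,
                           masks: dict[str, RegionMask], age: float,
                           eye_id: str = "") -> FieldSummary:
    """Regional summaries of one eye's field.

    Parameters
    ----------
    field : DataFrame with columns (point_id, sensitivity_db).
    normative : control-derived point means and quantiles.
    masks : {"central10": ..., "central15": ...} from
        :func:`twoflash.geometry.select_sap_points`.
    age : subject age in years, for the age-corrected normal values.
    """
    field = field.set_index("point_id") if "point_id" in field.columns else field
    missing = [p for p in field.index if p not in normative.sap_points.index]
    if missing:
        raise DataError(f"points missing from normative table: {missing}")

    normal_db = np.array([normative.sap_normal_db(p, age) for p in field.index])
    measured = field["sensitivity_db"].to_numpy(float)
    defect = normal_db - measured

    def _regional(ids):
        sel = field.index.isin(ids)
        if not sel.any():
            raise DataError("empty regional mask")
        return (float(np.mean(db_to_linear(measured[sel]))),
                float(np.mean(defect[sel])))

    ms10, md10 = _regional(masks["central10"].member_ids)
    ms15, md15 = _regional(masks["central15"].member_ids)

    probs = {int(p): _probability_class(m, normative.sap_points.loc[p])
             for p, m in zip(field.index, measured)}
    return FieldSummary(
        eye_id=eye_id, ms10_linear=ms10, ms15_linear=ms15,
        md10_db=md10, md15_db=md15, global_md_db=float(np.mean(defect)),
        per_point_probability=probs,
        masks={label: tuple(m.member_ids) for label, m in masks.items()},
    )
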