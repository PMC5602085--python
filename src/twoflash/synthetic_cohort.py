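"""Synthetic three-group cohort generator (controls / PPG / POAG).

A latent per-eye disease severity, anchored to the eye's ganglion-cell layer
thickness, jointly drives every modality the analysis consumes:

* a spatially smooth ganglion-integrity field g(x, y) in [0, 1] scales the
  inner-retinal terms of the per-hexagon mfERG response (the direct-component
  adaptation and both induced components), while the outer-retinal term is
  spared;
* GCIPL and total macular thickness are drawn from the per-group normal
  distributions with a shared latent factor (structural coupling);
* perimetric sensitivity follows the integrity field through a
  functional-reserve ceiling (loss is invisible until integrity drops below
  1 - reserve), plus a group-level focal scotoma for perimetric glaucoma —
  this is what lets preperimetric eyes combine structural loss with normal
  fields.

Raw traces are synthesized as superposed per-hexagon responses on the
m-sequence schedule plus 1/f-and-white noise, so the full signal chain
(artifact rejection, filtering, kernel extraction) can be exercised.  A
feature-level fast mode generates the kernels directly with matched noise
scale, for large Monte-Carlo calibration runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .geometry import HexLayout, g2_point_table
from .stimulus import FrameSchedule

GROUPS = ("control", "PPG", "POAG")


@dataclass(frozen=True)
class GroupParams:
    """Per-group cohort parameters (demographics + structural targets)."""

    n: int
    age_mean: float
    age_sd: float
    male_prop: float
    gcipl_mean: float  # µm
    gcipl_sd: float
    mt_mean: float     # µm
    mt_sd: float
    md_mean: float     # dB, documentation target of the group's field loss
    focal_defect_db: float = 0.0
    severity_shift: float = 0.0  # additive severity offset (loss knob)

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("group size must be >= 0")
        if min(self.age_sd, self.gcipl_sd, self.mt_sd) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if not 0 <= self.male_prop <= 1:
            raise ConfigurationError("male_prop must be in [0, 1]")


def default_groups() -> dict[str, GroupParams]:
    """The reference three-group design: 16 control, 6 preperimetric (PPG),
    20 perimetric (POAG) eyes with the corresponding demographic and
    thickness distributions."""
    return {
        "control": GroupParams(n=16, age_mean=49.2, age_sd=7.02, male_prop=2 / 16,
                               gcipl_mean=80.7, gcipl_sd=4.7,
                               mt_mean=308.4, mt_sd=12.7, md_mean=0.12),
        "PPG": GroupParams(n=6, age_mean=63.0, age_sd=15.9, male_prop=5 / 6,
                           gcipl_mean=68.2, gcipl_sd=10.2,
                           mt_mean=302.6, mt_sd=15.8, md_mean=-0.08),
        "POAG": GroupParams(n=20, age_mean=60.6, age_sd=12.4, male_prop=0.80,
                            gcipl_mean=65.4, gcipl_sd=9.3,
                            mt_mean=296.5, mt_sd=18.7, md_mean=4.7,
                            focal_defect_db=10.0),
    }


@dataclass(frozen=True)
class CohortDesign:
    """All tunable parameters of the synthetic cohort.

    A fixed ``seed`` makes :func:`simulate_cohort` bit-identical.
    """

    groups: dict = field(default_factory=default_groups)
    seed: int = 0
    # --- structure-function coupling -------------------------------------
    severity_scale_um: float = 40.0        # GCIPL µm lost at full severity
    structure_function_rho: float = 0.5    # GCIPL-mT latent correlation
    spatial_variation: float = 0.3         # spatial unevenness of the loss
    # --- mfERG -----------------------------------------------------------
    trace_sample_rate: float = 1200.0      # Hz
    trace_noise_sd_uv: float = 8.0
    pink_fraction: float = 0.5             # share of 1/f noise power
    noise_band_factor: float = 0.6         # post-filter noise retention
    amplitude_gain_sd: float = 0.12        # lognormal inter-eye gain
    age_amp_slope_per_year: float = -0.004
    # --- SAP -------------------------------------------------------------
    hill_center_db: float = 30.0
    hill_slope_db_per_deg: float = 0.25
    sap_age_slope_db_per_decade: float = -0.1
    sap_age_ref: float = 50.0
    sap_reserve: float = 0.5               # functional reserve fraction
    sap_gamma: float = 2.5                 # sensitivity-loss exponent
    sap_point_noise_db: float = 0.6        # independent per-point noise
    sap_common_noise_db: float = 0.8       # shared per-eye sensitivity offset
    focal_defect_radius_deg: float = 3.0
    focal_center_ecc_range: tuple = (6.0, 20.0)
    # --- OCT -------------------------------------------------------------
    age_gcipl_slope_um_per_year: float = -0.1
    mt_sector_noise_um: float = 3.0
    gcipl_sector_noise_um: float = 2.0
    outer_ring_offset_um: float = -25.0
    # --- cohort structure -------------------------------------------------
    two_eyes_prob: float = 0.0

    def zero_noise(self) -> "CohortDesign":
        """Copy with every stochastic term silenced (identity-case testing)."""
        groups = {k: replace(g, age_sd=0.0, gcipl_sd=0.0, mt_sd=0.0)
                  for k, g in self.groups.items()}
        return replace(self, groups=groups, trace_noise_sd_uv=0.0,
                       amplitude_gain_sd=0.0, sap_point_noise_db=0.0,
                       sap_common_noise_db=0.0, mt_sector_noise_um=0.0,
                       gcipl_sector_noise_um=0.0, spatial_variation=0.0)


@dataclass
class EyeRecord:
    """One synthetic eye's complete multimodal raw data."""

    eye_id: str
    subject_id: str
    group: str
    age: float
    gender: str
    laterality: str
    sap_field: pd.DataFrame          # point_id, x_deg, y_deg, sensitivity_db
    mt_sectors: dict
    gcipl_sectors: dict
    trace_segments: list | None = None
    kernels: np.ndarray | None = None  # (n_hex, epoch_n), fast mode
    severity: float = 0.0

    def __post_init__(self):
        db = self.sap_field["sensitivity_db"].to_numpy(float)
        if np.any(db < 0) or np.any(db > 40):
            raise DataError("SAP sensitivities must lie in [0, 40] dB")
        if any(v <= 0 for v in self.mt_sectors.values()) \
                or any(v <= 0 for v in self.gcipl_sectors.values()):
            raise DataError("thicknesses must be positive")


# ---------------------------------------------------------------------------
# Response templates
# ---------------------------------------------------------------------------

def _gauss(t, mu, sig):
    return np.exp(-0.5 * ((t - mu) / sig) ** 2)


def response_templates(sample_rate: float, epoch_ms: float = 105.0):
    """Outer- and inner-retinal per-hexagon response templates (µV).

    ``outer``: biphasic outer-retinal wave of the direct component (negative
    lobe 15-25 ms, positive 25-45 ms), unaffected by ganglion integrity.
    ``inner``: the adaptive direct-component term plus both induced
    components (45-75, 75-105 ms); scaled by the integrity field.
    ``gf``: full-field global-flash response added at every step regardless
    of the focal bit (cancelled by first-order extraction).
    """
    n = int(round(epoch_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate * 1000.0  # ms
    outer = -0.20 * _gauss(t, 20, 4) + 0.35 * _gauss(t, 32, 6)
    inner = (0.65 * _gauss(t, 35, 5)                       # DC adaptation
             - 0.18 * _gauss(t, 50, 4) + 0.60 * _gauss(t, 58, 5)   # IC1
             - 0.15 * _gauss(t, 80, 5) + 0.50 * _gauss(t, 88, 6))  # IC2
    gf = 1.2 * _gauss(t, 55, 6) + 1.0 * _gauss(t, 85, 6)
    return outer, inner, gf


def _smooth_field(rng: np.random.Generator, extent_deg: float = 25.0):
    """A random smooth zero-mean spatial modulation pattern on the field."""
    n_waves = 3
    amp = rng.normal(0.0, 1.0, n_waves) / np.sqrt(n_waves)
    theta = rng.uniform(0, 2 * np.pi, n_waves)
    freq = rng.uniform(0.5, 1.5, n_waves) * np.pi / extent_deg
    phase = rng.uniform(0, 2 * np.pi, n_waves)

    def phi(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.zeros(np.broadcast(x, y).shape)
        for a, th, f, ph in zip(amp, theta, freq, phase):
            out = out + a * np.cos(f * (x * np.cos(th) + y * np.sin(th)) + ph)
        return out

    return phi


def _pink_white_noise(rng, n, sd, pink_fraction):
    if sd <= 0 or n == 0:
        return np.zeros(n)
    from scipy.fft import irfft, next_fast_len, rfft
    white = rng.standard_normal(n)
    m = next_fast_len(n)  # pad: n may contain a large prime factor
    spec = rfft(rng.standard_normal(m))
    f = np.fft.rfftfreq(m)
    f[0] = f[1] if m > 1 else 1.0
    pink = irfft(spec / np.sqrt(f), m)[:n]
    pink = pink - pink.mean()
    pink /= max(pink.std(), 1e-12)
    mix = (np.sqrt(1 - pink_fraction) * white + np.sqrt(pink_fraction) * pink)
    return sd * mix


# GCIPL wedge-sector centre angles (deg, right-eye field convention)
_GCIPL_SECTOR_ANGLES = {
    "superior": 90.0, "superonasal": 150.0, "inferonasal": 210.0,
    "inferior": 270.0, "inferotemporal": 330.0, "superotemporal": 30.0,
}
_GCIPL_SECTOR_ECC_DEG = 5.3

_ETDRS_INNER_ANGLES = {"inner_superior": 90.0, "inner_nasal": 180.0,
                       "inner_inferior": 270.0, "inner_temporal": 0.0}


# ---------------------------------------------------------------------------
# Eye simulation
# ---------------------------------------------------------------------------

def simulate_eye(design: CohortDesign, group: str, schedule: FrameSchedule,
                 layout: HexLayout, rng: np.random.Generator,
                 eye_id: str = "eye0", subject_id: str = "subj0",
                 laterality: str = "OD", include_trace: bool = True,
                 point_table: pd.DataFrame | None = None,
                 _shared: dict | None = None) -> EyeRecord:
    """Simulate one eye of the given group.

    ``_shared`` optionally carries subject-level draws (age, gender, latent
    structural factor) so a second eye of the same subject is correlated.
    """
    if group not in design.groups:
        raise ConfigurationError(f"unknown group label {group!r}")
    gp: GroupParams = design.groups[group]
    if point_table is None:
        point_table = g2_point_table()

    shared = _shared or {}
    age = shared.get("age")
    if age is None:
        age = float(np.clip(rng.normal(gp.age_mean, gp.age_sd), 18.0, 95.0))
    gender = shared.get("gender") or ("M" if rng.random() < gp.male_prop else "F")
    z0 = shared.get("z0")
    if z0 is None:
        z0 = float(rng.standard_normal())

    # --- structural draws -------------------------------------------------
    rho = design.structure_function_rho
    z1, z2 = rng.standard_normal(2)
    age_term = design.age_gcipl_slope_um_per_year * (age - gp.age_mean)
    gcipl_draw = gp.gcipl_mean + gp.gcipl_sd * (np.sqrt(rho) * z0
                                                + np.sqrt(1 - rho) * z1) + age_term
    mt_draw = gp.mt_mean + gp.mt_sd * (np.sqrt(rho) * z0 + np.sqrt(1 - rho) * z2)

    ref_gcipl = design.groups["control"].gcipl_mean
    severity = float(np.clip((ref_gcipl - gcipl_draw) / design.severity_scale_um
                             + gp.severity_shift, 0.0, 1.0))
    # the severity_shift loss knob lowers the structural output coherently
    gcipl_base = gcipl_draw - gp.severity_shift * design.severity_scale_um

    phi = _smooth_field(rng)

    def integrity(x, y):
        return np.clip(1.0 - severity * (1.0 + design.spatial_variation
                                         * phi(x, y)), 0.0, 1.0)

    # --- mfERG ------------------------------------------------------------
    rate = design.trace_sample_rate
    outer, inner, gf = response_templates(rate)
    gain = float(np.exp(rng.normal(0.0, design.amplitude_gain_sd))
                 * (1.0 + design.age_amp_slope_per_year * (age - gp.age_mean)))
    g_hex = integrity(layout.centers[:, 0], layout.centers[:, 1])
    responses = gain * (outer[None, :] + g_hex[:, None] * inner[None, :])

    trace_segments = None
    kernels = None
    if include_trace:
        trace_segments = _synthesize_trace(design, schedule, responses,
                                           gain * gf, rng)
    else:
        L = schedule.n_steps
        k_sd = (2.0 * design.trace_noise_sd_uv * design.noise_band_factor
                / np.sqrt(L))
        kernels = responses + rng.normal(0.0, k_sd, responses.shape) \
            if k_sd > 0 else responses.copy()

    # --- SAP --------------------------------------------------------------
    x = point_table["x_deg"].to_numpy(float)
    y = point_table["y_deg"].to_numpy(float)
    ecc = np.hypot(x, y)
    normal_db = (design.hill_center_db - design.hill_slope_db_per_deg * ecc
                 + design.sap_age_slope_db_per_decade
                 * (age - design.sap_age_ref) / 10.0)
    g_pts = integrity(x, y)
    f_eff = np.minimum(1.0, g_pts / max(1.0 - design.sap_reserve, 1e-6))
    diffuse = -10.0 * design.sap_gamma * np.log10(np.maximum(f_eff, 1e-4))
    focal = np.zeros_like(ecc)
    if gp.focal_defect_db > 0:
        ang = rng.uniform(0, 2 * np.pi)
        c_ecc = rng.uniform(*design.focal_center_ecc_range)
        cx, cy = c_ecc * np.cos(ang), c_ecc * np.sin(ang)
        depth = gp.focal_defect_db * min(severity / 0.38, 1.8)
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        focal = depth * np.exp(-d2 / (2 * design.focal_defect_radius_deg ** 2))
    noise = rng.normal(0.0, design.sap_point_noise_db, len(ecc)) \
        if design.sap_point_noise_db > 0 else 0.0
    common = rng.normal(0.0, design.sap_common_noise_db) \
        if design.sap_common_noise_db > 0 else 0.0
    measured = np.clip(normal_db - diffuse - focal + noise + common, 0.0, 40.0)
    sap_field = point_table.assign(sensitivity_db=measured)

    # --- OCT sectors --------------------------------------------------------
    mt_noise = design.mt_sector_noise_um
    mt_sectors = {"center": mt_draw + (rng.normal(0, mt_noise) if mt_noise else 0.0)}
    for name in _ETDRS_INNER_ANGLES:
        mt_sectors[name] = mt_draw + (rng.normal(0, mt_noise) if mt_noise else 0.0)
    for quad in ("superior", "nasal", "inferior", "temporal"):
        mt_sectors[f"outer_{quad}"] = (mt_draw + design.outer_ring_offset_um
                                       + (rng.normal(0, mt_noise) if mt_noise else 0.0))

    phi_sect = {s: float(phi(_GCIPL_SECTOR_ECC_DEG * np.cos(np.radians(a)),
                             _GCIPL_SECTOR_ECC_DEG * np.sin(np.radians(a))))
                for s, a in _GCIPL_SECTOR_ANGLES.items()}
    phi_mean = np.mean(list(phi_sect.values()))
    gc_noise = design.gcipl_sector_noise_um
    gcipl_sectors = {}
    for s in _GCIPL_SECTOR_ANGLES:
        mod = -design.severity_scale_um * severity * design.spatial_variation \
            * (phi_sect[s] - phi_mean)
        gcipl_sectors[s] = max(float(gcipl_base + mod
                                     + (rng.normal(0, gc_noise) if gc_noise else 0.0)),
                               5.0)
    for k in mt_sectors:
        mt_sectors[k] = max(float(mt_sectors[k]), 5.0)

    return EyeRecord(
        eye_id=eye_id, subject_id=subject_id, group=group, age=age,
        gender=gender, laterality=laterality, sap_field=sap_field,
        mt_sectors=mt_sectors, gcipl_sectors=gcipl_sectors,
        trace_segments=trace_segments, kernels=kernels, severity=severity,
    )


def _synthesize_trace(design: CohortDesign, schedule: FrameSchedule,
                      responses: np.ndarray, gf_wave: np.ndarray,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Overlap-add per-hexagon responses on the m-sequence schedule."""
    mseq = schedule.mseq
    L = schedule.n_steps
    rate = design.trace_sample_rate
    sps_step = schedule.samples_per_step(rate)
    n_hex, epoch_n = responses.shape

    shifts = np.array([mseq.per_hexagon_shift[h] for h in range(n_hex)])
    bits_mat = mseq.bits[(np.arange(L)[None, :] - shifts[:, None]) % L]
    step_contrib = bits_mat.T.astype(float) @ responses  # (L, epoch_n)
    step_contrib += gf_wave[None, :]

    trace = np.zeros(L * sps_step)
    view = trace.reshape(L, sps_step)
    for k0 in range(0, epoch_n, sps_step):
        chunk = step_contrib[:, k0:k0 + sps_step]
        rows = (np.arange(L) + k0 // sps_step) % L
        view[rows, :chunk.shape[1]] += chunk

    trace = trace + _pink_white_noise(rng, len(trace),
                                      design.trace_noise_sd_uv,
                                      design.pink_fraction)
    return [trace[a * sps_step:b * sps_step]
            for a, b in schedule.segment_step_slices]


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(design: CohortDesign, schedule: FrameSchedule,
                    layout: HexLayout, include_trace: bool = True,
                    point_table: pd.DataFrame | None = None,
                    rng: np.random.Generator | None = None,
                    groups: tuple | None = None) -> list[EyeRecord]:
    """Simulate the full cohort (default 16 control + 6 PPG + 20 POAG eyes).

    With ``two_eyes_prob > 0`` consecutive eyes within a group may share a
    subject (correlated structural factor, same age/gender); group sizes
    always count eyes.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if point_table is None:
        point_table = g2_point_table()
    eyes: list[EyeRecord] = []
    subj_counter = 0
    for group in (groups or GROUPS):
        if group not in design.groups:
            raise ConfigurationError(f"unknown group label {group!r}")
        n = design.groups[group].n
        i = 0
        while i < n:
            subj_counter += 1
            subject_id = f"S{subj_counter:03d}"
            pair = (design.two_eyes_prob > 0 and i + 1 < n
                    and rng.random() < design.two_eyes_prob)
            shared = {
                "age": float(np.clip(rng.normal(design.groups[group].age_mean,
                                                design.groups[group].age_sd),
                                     18.0, 95.0)),
                "gender": "M" if rng.random() < design.groups[group].male_prop else "F",
                "z0": float(rng.standard_normal()),
            }
            for lat in (("OD", "OS") if pair else ("OD",)):
                eyes.append(simulate_eye(
                    design, group, schedule, layout, rng,
                    eye_id=f"E{len(eyes) + 1:03d}", subject_id=subject_id,
                    laterality=lat, include_trace=include_trace,
                    point_table=point_table, _shared=shared))
                i += 1
    return eyes


def cohort_manifest(eyes: list[EyeRecord]) -> pd.DataFrame:
    """Tidy per-eye manifest (eye_id, subject_id, group, age, gender, ...)."""
    return pd.DataFrame([{
        "eye_id": e.eye_id, "subject_id": e.subject_id, "group": e.group,
        "age": e.age, "gender": e.gender, "laterality": e.laterality,
        "severity": e.severity,
    } for e in eyes])
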