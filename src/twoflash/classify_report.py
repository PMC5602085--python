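"""Per-eye abnormality classification, modality cross-tabulation, and the
end-to-end pipeline.

Abnormality in the central 15 degrees is defined per modality:

* SAP — at least one point with probability < 0.5% on the deviation plot;
* 2F-mfERG — the DC, IC1 and/or IC2 regional RMS average outside the 95%
  quantile of controls (read one-sided, i.e. below the control 5th
  percentile, since glaucomatous damage reduces amplitude; a two-sided
  option exists);
* OCT — at least one yellow or red sector (below the 5th / 1st normative
  percentile) on the mT or GCIPL map.

The cross-tabulation reports how often the modalities agree, in particular
the share of eyes with mfERG and ganglion-cell-layer alterations but an
intact central field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, mferg_signal, oct_metrics, perimetry, stats, stimulus
from .errors import ConfigurationError, DataError, TwoflashError
from .mferg_signal import EpochRMS
from .oct_metrics import NormativeDB, OctSummary, empirical_quantiles
from .perimetry import FieldSummary
from .synthetic_cohort import (CohortDesign, EyeRecord, simulate_cohort,
                               cohort_manifest)

log = logging.getLogger(__name__)

MFERG_FEATURES = ("dc10", "ic1_10", "ic2_10", "dc15", "ic1_15", "ic2_15")


@dataclass(frozen=True)
class AbnormalityFlags:
    """Per-eye abnormality calls for the central 15-degree analysis."""

    eye_id: str
    sap_abnormal: bool
    mferg_abnormal: bool
    mt_abnormal: bool
    gcipl_abnormal: bool
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CrossTab:
    """Counts and percentages of every modality-agreement category."""

    n_eyes: int
    counts: dict
    percentages: dict  # name -> {"pct", "num", "den", "denominator"}

    def __post_init__(self):
        primary = ("no_alterations", "mferg_only", "mt_and_gcipl",
                   "gcipl_only", "mt_only", "other")
        if sum(self.counts[k] for k in primary) != self.n_eyes:
            raise DataError("cross-tab counts do not sum to the number of eyes")


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def eye_epoch_rms(eye: EyeRecord, schedule: stimulus.FrameSchedule,
                  layout: geometry.HexLayout, hex_masks: dict,
                  sample_rate: float, windows=None) -> EpochRMS:
    """Run one eye through the signal chain to its regional epoch RMS.

    Trace mode: artifact rejection (two passes), per-segment 1-200 Hz
    zero-phase band-pass, kernel extraction, epoch RMS.  Fast mode (the eye
    carries pre-generated kernels): epoch RMS directly.
    """
    if eye.kernels is not None:
        kernels = [mferg_signal.KernelWaveform(h, eye.kernels[h], sample_rate)
                   for h in range(eye.kernels.shape[0])]
    else:
        cleaned, _ = mferg_signal.reject_artifacts(eye.trace_segments)
        filtered = [mferg_signal.bandpass(seg, sample_rate) for seg in cleaned]
        kernels = mferg_signal.extract_first_order_kernels(
            filtered, schedule.mseq, schedule, layout, sample_rate)
    return mferg_signal.regional_rms(kernels, hex_masks, windows,
                                     eye_id=eye.eye_id)


def build_normative_db(control_eyes: list[EyeRecord],
                       epoch_rms_list: list[EpochRMS],
                       seed: int | None = None,
                       age_correction_db_per_decade: float = -0.1
                       ) -> NormativeDB:
    """Empirical normative quantiles from control-group records only.

    Quantiles use linear interpolation; the sample size and seed provenance
    are recorded for reproducibility.
    """
    if any(e.group != "control" for e in control_eyes):
        raise DataError("normative database must be built from controls only")
    if len(control_eyes) != len(epoch_rms_list):
        raise DataError("need one EpochRMS per control eye")

    mferg_rows = {}
    for featname in MFERG_FEATURES:
        vals = np.array([getattr(r, featname) for r in epoch_rms_list])
        mferg_rows[featname] = empirical_quantiles(
            vals, {"q01": 1, "q025": 2.5, "q05": 5, "q50": 50,
                   "q95": 95, "q975": 97.5, "q99": 99})
    mferg = pd.DataFrame(mferg_rows).T

    fields = pd.concat([e.sap_field.assign(_eye=e.eye_id)
                        for e in control_eyes])
    sap_rows = {}
    for pid, sub in fields.groupby("point_id"):
        v = sub["sensitivity_db"].to_numpy(float)
        row = {"mean_db": float(np.mean(v))}
        row.update(empirical_quantiles(v, {"q005": 0.5, "q01": 1,
                                           "q02": 2, "q05": 5}))
        sap_rows[int(pid)] = row
    sap_points = pd.DataFrame(sap_rows).T

    def _sector_quantiles(getter, names):
        rows = {}
        for s in names:
            v = np.array([getter(e)[s] for e in control_eyes])
            rows[s] = empirical_quantiles(v, {"q01": 1, "q05": 5})
        return pd.DataFrame(rows).T

    return NormativeDB(
        n_controls=len(control_eyes), seed=seed, mferg=mferg,
        sap_points=sap_points,
        mt_sectors=_sector_quantiles(lambda e: e.mt_sectors,
                                     oct_metrics.ETDRS_SECTORS),
        gcipl_sectors=_sector_quantiles(lambda e: e.gcipl_sectors,
                                        oct_metrics.GCIPL_SECTORS),
        control_mean_age=float(np.mean([e.age for e in control_eyes])),
        age_correction_db_per_decade=age_correction_db_per_decade,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_eye(field_summary: FieldSummary | None,
                 epoch_rms: EpochRMS | None,
                 oct_summary: OctSummary | None,
                 normative: NormativeDB,
                 mferg_region: str = "15",
                 two_sided: bool = False) -> AbnormalityFlags:
    """Apply the central-15-degree abnormality criteria to one eye."""
    missing = [name for name, obj in (("SAP", field_summary),
                                      ("mfERG", epoch_rms),
                                      ("OCT", oct_summary)) if obj is None]
    if missing:
        raise DataError(f"partial record: missing modalities {missing}; "
                        "no flags assigned")

    central15 = set(field_summary.masks.get("central15", ()))
    sap_hits = [p for p, cls in field_summary.per_point_probability.items()
                if p in central15 and cls == "<0.5%"]

    mferg_hits = {}
    for epoch in ("dc", "ic1", "ic2"):
        feat = f"dc{mferg_region}" if epoch == "dc" else f"{epoch}_{mferg_region}"
        value = getattr(epoch_rms, feat)
        row = normative.mferg.loc[feat]
        low = value < row["q05"] if not two_sided else value < row["q025"]
        high = two_sided and value > row["q975"]
        if low or high:
            mferg_hits[feat] = value

    mt_hits = {s: f for s, f in oct_summary.mt_flags.items() if f != "normal"}
    gc_hits = {s: f for s, f in oct_summary.gcipl_flags.items() if f != "normal"}

    return AbnormalityFlags(
        eye_id=epoch_rms.eye_id or field_summary.eye_id,
        sap_abnormal=bool(sap_hits), mferg_abnormal=bool(mferg_hits),
        mt_abnormal=bool(mt_hits), gcipl_abnormal=bool(gc_hits),
        details={"sap_points": sap_hits, "mferg": mferg_hits,
                 "mt_sectors": mt_hits, "gcipl_sectors": gc_hits},
    )


def crosstab_report(flags: list[AbnormalityFlags],
                    groups: dict[str, str] | None = None) -> CrossTab:
    """Cross-tabulate modality agreement across eyes.

    Percentages state their denominator explicitly: categories over all eyes
    use ``n_eyes``; the within-GCIPL-thinning categories use the number of
    eyes with a GCIPL alteration.
    """
    if not flags:
        raise DataError("need at least one eye")
    n = len(flags)
    c = {
        "no_alterations": 0, "mferg_only": 0, "mt_and_gcipl": 0,
        "gcipl_only": 0, "mt_only": 0, "other": 0, "gcipl_thin": 0,
        "thin_mferg_not_sap": 0, "thin_sap_not_mferg": 0,
        "thin_both_sap_mferg": 0, "thin_neither": 0,
        "mferg_gcipl_no_sap": 0,
    }
    by_group: dict[str, int] = {}
    for f in flags:
        any_flag = f.sap_abnormal or f.mferg_abnormal or f.mt_abnormal \
            or f.gcipl_abnormal
        if not any_flag:
            c["no_alterations"] += 1
        elif f.mferg_abnormal and not (f.sap_abnormal or f.mt_abnormal
                                       or f.gcipl_abnormal):
            c["mferg_only"] += 1
        elif f.mt_abnormal and f.gcipl_abnormal:
            c["mt_and_gcipl"] += 1
        elif f.gcipl_abnormal:
            c["gcipl_only"] += 1
        elif f.mt_abnormal:
            c["mt_only"] += 1
        else:
            c["other"] += 1
        if f.gcipl_abnormal:
            c["gcipl_thin"] += 1
            if f.mferg_abnormal and not f.sap_abnormal:
                c["thin_mferg_not_sap"] += 1
            elif f.sap_abnormal and not f.mferg_abnormal:
                c["thin_sap_not_mferg"] += 1
            elif f.sap_abnormal and f.mferg_abnormal:
                c["thin_both_sap_mferg"] += 1
            else:
                c["thin_neither"] += 1
        if f.mferg_abnormal and f.gcipl_abnormal and not f.sap_abnormal:
            c["mferg_gcipl_no_sap"] += 1
            if groups:
                g = groups.get(f.eye_id, "?")
                by_group[g] = by_group.get(g, 0) + 1

    thin = c["gcipl_thin"]

    def pct(num, den, denominator):
        return {"pct": 100.0 * num / den if den else 0.0,
                "num": num, "den": den, "denominator": denominator}

    percentages = {
        "mferg_gcipl_no_sap": pct(c["mferg_gcipl_no_sap"], n, "all eyes"),
        "thin_mferg_not_sap": pct(c["thin_mferg_not_sap"], thin,
                                  "eyes with GCIPL thinning"),
        "thin_sap_not_mferg": pct(c["thin_sap_not_mferg"], thin,
                                  "eyes with GCIPL thinning"),
        "thin_both_sap_mferg": pct(c["thin_both_sap_mferg"], thin,
                                   "eyes with GCIPL thinning"),
    }
    if groups:
        c["mferg_gcipl_no_sap_by_group"] = by_group
    return CrossTab(n_eyes=n, counts=c, percentages=percentages)


def example_crosstab_flags() -> tuple[list[AbnormalityFlags], dict[str, str]]:
    """A worked 26-eye early-glaucoma agreement table.

    Six preperimetric and twenty perimetric glaucoma eyes with known flag
    combinations: one fully normal eye, one mfERG-only, seventeen with both
    mT and GCIPL alterations, six with GCIPL thinning but normal mT, one
    with abnormal mT only; among the 23 GCIPL-thin eyes, eight have an
    abnormal mfERG with intact field, four the reverse, three both.
    Returns (flags, eye_id -> group).
    """
    rows = []  # (group, sap, mferg, mt, gcipl)
    rows.append(("PPG", False, False, False, False))   # fully normal
    rows.append(("PPG", False, True, False, False))    # mfERG only
    rows += [("PPG", False, True, True, True)] * 3     # thin, mfERG+ SAP-
    rows += [("POAG", False, True, True, True)] * 5
    rows += [("POAG", True, False, True, True)] * 4    # thin, SAP+ mfERG-
    rows += [("POAG", True, True, True, True)] * 3     # thin, both
    rows += [("POAG", False, False, True, True)] * 2   # thin, neither
    rows += [("PPG", False, False, False, True)]       # GCIPL only, neither
    rows += [("POAG", False, False, False, True)] * 5
    rows += [("POAG", False, False, True, False)]      # mT only
    flags, groups = [], {}
    for i, (g, sap, mf, mt, gc) in enumerate(rows, start=1):
        eid = f"X{i:02d}"
        flags.append(AbnormalityFlags(eye_id=eid, sap_abnormal=sap,
                                      mferg_abnormal=mf, mt_abnormal=mt,
                                      gcipl_abnormal=gc))
        groups[eid] = g
    return flags, groups


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 1,
    "mode": "fast",            # "trace" runs the full signal chain
    "mseq_order": 13,
    "frame_rate": 75.0,
    "frames_per_step": 6,
    "n_segments": 16,
    "sample_rate": 1200.0,
    "n_normative_controls": 120,
    "group_sizes": None,        # e.g. {"control": 16, "PPG": 6, "POAG": 20}
    "two_eyes_prob": 0.0,
    "format": "csv",
}

#: structure-function model pairs mirroring the headline regression table:
#: function features (10 deg) against central macular thickness, function
#: features (15 deg) against GCIPL.
SF_PAIRS = [
    ("dc10", "mT"), ("ic1_10", "mT"), ("ic2_10", "mT"), ("ms10_linear", "mT"),
    ("dc15", "gcipl"), ("ic1_15", "gcipl"), ("ic2_15", "gcipl"),
    ("ms15_linear", "gcipl"),
]

ROC_MARKERS = ["dc10", "ic1_10", "ic2_10", "ms10_linear", "md10_db", "mT",
               "dc15", "ic1_15", "ic2_15", "ms15_linear", "md15_db", "gcipl"]


def _build_world(cfg):
    layout = geometry.build_hex_layout("veris103")
    mseq = stimulus.generate_msequence(cfg["mseq_order"],
                                       n_channels=layout.n_hexagons)
    schedule = stimulus.build_frame_schedule(
        mseq, frame_rate=cfg["frame_rate"],
        frames_per_step=cfg["frames_per_step"], n_segments=cfg["n_segments"])
    hex_masks = {"central10": geometry.central_hexagons(layout, 1),
                 "central15": geometry.central_hexagons(layout, 2)}
    point_table = geometry.g2_point_table()
    sap_masks = {
        "central10": geometry.select_sap_points(point_table, "central10"),
        "central15": geometry.select_sap_points(point_table, "central15"),
    }
    return layout, schedule, hex_masks, point_table, sap_masks


def _design_from_config(cfg) -> CohortDesign:
    design = CohortDesign(seed=cfg["seed"], two_eyes_prob=cfg["two_eyes_prob"])
    if cfg.get("group_sizes"):
        groups = {}
        for name, gp in design.groups.items():
            groups[name] = replace(gp, n=int(cfg["group_sizes"].get(name, 0)))
        design = replace(design, groups=groups)
    return design


def feature_table(eyes, epoch_rms_list, field_summaries, oct_summaries
                  ) -> pd.DataFrame:
    """Tidy per-eye feature table joining all three modalities."""
    rows = []
    for e, rms, fs, oc in zip(eyes, epoch_rms_list, field_summaries,
                              oct_summaries):
        row = {"eye_id": e.eye_id, "subject_id": e.subject_id,
               "group": e.group, "age": e.age, "gender": e.gender}
        row.update(rms.as_dict())
        row.update({"ms10_linear": fs.ms10_linear, "ms15_linear": fs.ms15_linear,
                    "md10_db": fs.md10_db, "md15_db": fs.md15_db,
                    "mT": oc.mT_central, "gcipl": oc.gcipl_mean})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None
                 ) -> dict:
    """Execute simulate -> signal -> perimetry -> oct -> stats -> classify.

    Returns the report bundle as a dict of DataFrames/objects; when
    ``out_dir`` is given, also writes the manifest, feature table,
    regression and ROC tables, per-eye flags, cross-tab and a run log.
    Re-running with the same config is bit-identical.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    include_trace = cfg["mode"] == "trace"
    if cfg["mode"] not in ("trace", "fast"):
        raise ConfigurationError(f"unknown mode {cfg['mode']!r}")

    layout, schedule, hex_masks, point_table, sap_masks = _build_world(cfg)
    design = _design_from_config(cfg)
    rate = float(cfg["sample_rate"])

    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_norm = [np.random.default_rng(s) for s in ss.spawn(2)]

    eyes = simulate_cohort(design, schedule, layout,
                           include_trace=include_trace,
                           point_table=point_table, rng=rng_cohort)

    # normative sample: an independent set of control eyes
    n_norm = int(cfg["n_normative_controls"])
    norm_groups = {"control": replace(design.groups["control"], n=n_norm)}
    norm_design = replace(design, groups={**design.groups, **norm_groups})
    norm_eyes = simulate_cohort(norm_design, schedule, layout,
                                include_trace=include_trace,
                                point_table=point_table, rng=rng_norm,
                                groups=("control",))

    def _rms(eye_list):
        return [eye_epoch_rms(e, schedule, layout, hex_masks, rate)
                for e in eye_list]

    rms_all, rms_norm = _rms(eyes), _rms(norm_eyes)
    normative = build_normative_db(norm_eyes, rms_norm, seed=seed)

    def _summaries(eye_list, rms_list):
        fss, ocs = [], []
        for e, r in zip(eye_list, rms_list):
            fss.append(perimetry.regional_field_summary(
                e.sap_field[["point_id", "sensitivity_db"]], normative,
                sap_masks, age=e.age, eye_id=e.eye_id))
            ocs.append(oct_metrics.summarize_oct(e.eye_id, e.mt_sectors,
                                                 e.gcipl_sectors, normative))
        return fss, ocs

    fs_all, oct_all = _summaries(eyes, rms_all)
    features = feature_table(eyes, rms_all, fs_all, oct_all)

    bundle: dict = {"config": cfg, "manifest": cohort_manifest(eyes),
                    "features": features, "normative": normative}
    notices: list[str] = []

    labels = (features["group"] != "control").astype(int).to_numpy()
    if labels.sum() == 0 or labels.sum() == len(labels):
        notices.append("stats stage skipped: need both glaucoma and control "
                       "eyes for regressions and ROC")
        bundle["structure_function"] = None
        bundle["roc"] = None
    else:
        sf_rows = []
        for response, predictor in SF_PAIRS:
            try:
                fit = stats.fit_structure_function(features, response, predictor)
            except TwoflashError as exc:  # degenerate on tiny cohorts
                notices.append(f"regression {response}~{predictor} skipped: {exc}")
                continue
            sf_rows.append({"response": response, "predictor": predictor,
                            "slope": fit.slope, "ci_low": fit.ci95[0],
                            "ci_high": fit.ci95[1], "p": fit.p_value,
                            "mixed_model": fit.mixed, "n": fit.n})
        sf = pd.DataFrame(sf_rows)
        if len(sf):
            sf["p_fdr"] = stats.fdr_adjust(sf["p"].to_numpy())
        bundle["structure_function"] = sf

        roc_rows, rocs = [], {}
        for marker in ROC_MARKERS:
            res = stats.adjusted_roc(features[marker], labels,
                                     age=features["age"],
                                     gender=features["gender"],
                                     marker_name=marker)
            rocs[marker] = res
            roc_rows.append({"marker": marker, "auc": res.auc,
                             "se_auc": res.se_auc, "n_cases": res.n_cases,
                             "n_controls": res.n_controls})
        bundle["roc"] = pd.DataFrame(roc_rows)
        bundle["roc_results"] = rocs
        headline = ["dc10", "ic2_10", "gcipl", "mT"]
        delong_rows = []
        for i, a in enumerate(headline):
            for b in headline[i + 1:]:
                cmp = stats.delong_compare(rocs[a], rocs[b])
                delong_rows.append({"marker_a": a, "marker_b": b,
                                    "z": cmp["z"], "p": cmp["p"]})
        bundle["delong"] = pd.DataFrame(delong_rows)

    flags = [classify_eye(fs, r, oc, normative)
             for fs, r, oc in zip(fs_all, rms_all, oct_all)]
    bundle["flags"] = flags
    patient_flags = [f for f, e in zip(flags, eyes) if e.group != "control"]
    if patient_flags:
        groups_map = {e.eye_id: e.group for e in eyes}
        bundle["crosstab"] = crosstab_report(patient_flags, groups_map)
    else:
        bundle["crosstab"] = None
        notices.append("cross-tab skipped: no glaucoma eyes")
    bundle["notices"] = notices

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), cfg)
    return bundle


def _write_bundle(bundle, out_dir: Path, cfg):
    import twoflash
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = cfg.get("format", "csv")

    def _write(df, name):
        if df is None or not len(df):
            return
        if fmt == "json":
            df.to_json(out_dir / f"{name}.json", orient="records", indent=2)
        else:
            df.to_csv(out_dir / f"{name}.csv", index=False)

    _write(bundle["manifest"], "manifest")
    _write(bundle["features"], "features")
    _write(bundle.get("structure_function"), "structure_function")
    _write(bundle.get("roc"), "roc")
    _write(bundle.get("delong"), "delong")
    flags_df = pd.DataFrame([{
        "eye_id": f.eye_id, "sap_abnormal": f.sap_abnormal,
        "mferg_abnormal": f.mferg_abnormal, "mt_abnormal": f.mt_abnormal,
        "gcipl_abnormal": f.gcipl_abnormal} for f in bundle["flags"]])
    _write(flags_df, "flags")
    if bundle.get("crosstab") is not None:
        ct = bundle["crosstab"]
        (out_dir / "crosstab.json").write_text(json.dumps(
            {"n_eyes": ct.n_eyes, "counts": ct.counts,
             "percentages": ct.percentages}, indent=2, sort_keys=True))
    runlog = {
        "package_version": twoflash.__version__,
        "numpy_version": np.__version__,
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "n_eyes": int(len(bundle["manifest"])),
        "notices": bundle["notices"],
    }
    (out_dir / "runlog.json").write_text(json.dumps(runlog, indent=2,
                                                    sort_keys=True))
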