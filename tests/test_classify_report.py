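import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import twoflash as tf
from twoflash import classify_report as cr
from twoflash import mferg_signal as ms
from twoflash import oct_metrics as om
from twoflash import synthetic_cohort as sc
from twoflash.cli import main as cli_main
from twoflash.errors import DataError


@pytest.fixture(scope="module")
def normative_world(schedule13, layout103, hex_masks, sap_masks):
    """Normative DB from 300 fast-mode control eyes, plus the helpers to
    summarize further eyes against it."""
    design = sc.CohortDesign()
    design = replace(design, groups={
        "control": replace(design.groups["control"], n=300)})
    eyes = sc.simulate_cohort(design, schedule13, layout103,
                              include_trace=False,
                              rng=np.random.default_rng(99),
                              groups=("control",))
    rms = [cr.eye_epoch_rms(e, schedule13, layout103, hex_masks, 1200.0)
           for e in eyes]
    normative = cr.build_normative_db(eyes, rms, seed=99)
    return normative, eyes, rms


def summarize(eye, rms, normative, sap_masks):
    from twoflash import perimetry
    fs = perimetry.regional_field_summary(
        eye.sap_field[["point_id", "sensitivity_db"]], normative, sap_masks,
        age=eye.age, eye_id=eye.eye_id)
    oc = om.summarize_oct(eye.eye_id, eye.mt_sectors, eye.gcipl_sectors,
                          normative)
    return fs, oc


class TestClassifyEye:
    def test_median_control_eye_all_normal(self, normative_world, sap_masks,
                                           schedule13, layout103, hex_masks):
        normative, eyes, rms_list = normative_world
        # an eye sitting at the normative medians triggers nothing
        design = sc.CohortDesign().zero_noise()
        eye = sc.simulate_eye(design, "control", schedule13, layout103,
                              np.random.default_rng(0), include_trace=False)
        rms = cr.eye_epoch_rms(eye, schedule13, layout103, hex_masks, 1200.0)
        fs, oc = summarize(eye, rms, normative, sap_masks)
        flags = cr.classify_eye(fs, rms, oc, normative)
        assert not any([flags.sap_abnormal, flags.mferg_abnormal,
                        flags.mt_abnormal, flags.gcipl_abnormal])

    def test_low_dc15_triggers_mferg_only(self, normative_world, sap_masks,
                                          schedule13, layout103, hex_masks):
        normative, _, _ = normative_world
        design = sc.CohortDesign().zero_noise()
        eye = sc.simulate_eye(design, "control", schedule13, layout103,
                              np.random.default_rng(0), include_trace=False)
        rms = cr.eye_epoch_rms(eye, schedule13, layout103, hex_masks, 1200.0)
        fs, oc = summarize(eye, rms, normative, sap_masks)
        depressed = replace(rms, dc15=float(normative.mferg.loc["dc15", "q01"]))
        flags = cr.classify_eye(fs, depressed, oc, normative)
        assert flags.mferg_abnormal and "dc15" in flags.details["mferg"]
        assert not (flags.sap_abnormal or flags.mt_abnormal
                    or flags.gcipl_abnormal)

    def test_missing_modality_is_partial_record_error(self, normative_world):
        normative, _, _ = normative_world
        with pytest.raises(DataError, match="missing modalities.*SAP"):
            cr.classify_eye(None, None, None, normative)

    def test_classification_monotone_under_thinning(self, normative_world,
                                                    sap_masks, schedule13,
                                                    layout103, hex_masks):
        """Decreasing a thickness or RMS value never clears a flag."""
        normative, eyes, rms_list = normative_world
        eye, rms = eyes[0], rms_list[0]
        fs, oc = summarize(eye, rms, normative, sap_masks)
        base = cr.classify_eye(fs, rms, oc, normative)
        thin = {s: v - 20.0 for s, v in eye.gcipl_sectors.items()}
        oc_thin = om.summarize_oct(eye.eye_id, eye.mt_sectors, thin, normative)
        worse = cr.classify_eye(fs, replace(rms, dc15=rms.dc15 * 0.2),
                                oc_thin, normative)
        assert worse.gcipl_abnormal >= base.gcipl_abnormal
        assert worse.mferg_abnormal >= base.mferg_abnormal
        assert worse.gcipl_abnormal and worse.mferg_abnormal

    def test_specificity_calibration_per_epoch(self, normative_world,
                                               schedule13, layout103,
                                               hex_masks):
        """Fresh control eyes fall below the control 5th percentile about 5%
        of the time, per epoch (one-sided 95%-quantile criterion)."""
        normative, _, _ = normative_world
        design = sc.CohortDesign()
        design = replace(design, groups={
            "control": replace(design.groups["control"], n=400)})
        fresh = sc.simulate_cohort(design, schedule13, layout103,
                                   include_trace=False,
                                   rng=np.random.default_rng(123),
                                   groups=("control",))
        rates = {}
        for feat in ("dc15", "ic1_15", "ic2_15"):
            q05 = normative.mferg.loc[feat, "q05"]
            vals = [getattr(cr.eye_epoch_rms(e, schedule13, layout103,
                                             hex_masks, 1200.0), feat)
                    for e in fresh]
            rates[feat] = np.mean([v < q05 for v in vals])
        for feat, rate in rates.items():
            assert 0.01 < rate < 0.10, (feat, rate)


class TestCrosstab:
    def test_reference_26_eye_table(self):
        flags, groups = cr.example_crosstab_flags()
        assert len(flags) == 26
        ct = cr.crosstab_report(flags, groups)
        assert ct.counts["gcipl_thin"] == 23
        assert ct.counts["mt_and_gcipl"] == 17
        assert ct.counts["gcipl_only"] == 6
        assert ct.counts["mt_only"] == 1
        assert ct.counts["mferg_only"] == 1
        assert ct.counts["no_alterations"] == 1
        p = ct.percentages
        assert p["mferg_gcipl_no_sap"]["pct"] == pytest.approx(100 * 8 / 26)
        assert p["thin_mferg_not_sap"]["pct"] == pytest.approx(100 * 8 / 23)
        assert p["thin_sap_not_mferg"]["pct"] == pytest.approx(100 * 4 / 23)
        assert ct.counts["mferg_gcipl_no_sap_by_group"] == {"PPG": 3,
                                                            "POAG": 5}

    def test_all_normal_eyes(self):
        flags = [cr.AbnormalityFlags(f"e{i}", False, False, False, False)
                 for i in range(5)]
        ct = cr.crosstab_report(flags)
        assert ct.counts["no_alterations"] == 5
        assert all(v["pct"] == 0.0 for v in ct.percentages.values())

    def test_counts_partition_eyes(self):
        rng = np.random.default_rng(0)
        flags = [cr.AbnormalityFlags(f"e{i}", *rng.integers(0, 2, 4).astype(bool))
                 for i in range(40)]
        ct = cr.crosstab_report(flags)  # __post_init__ asserts the partition
        assert ct.n_eyes == 40

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            cr.crosstab_report([])


def _hash_dir(path):
    digest = hashlib.sha256()
    for p in sorted(Path(path).rglob("*")):
        if p.is_file():
            digest.update(p.name.encode())
            digest.update(p.read_bytes())
    return digest.hexdigest()


class TestRunPipeline:
    CFG = {"seed": 11, "mode": "fast", "n_normative_controls": 60}

    def test_deterministic_output_digests(self, tmp_path):
        cr.run_pipeline(self.CFG, out_dir=tmp_path / "a")
        cr.run_pipeline(self.CFG, out_dir=tmp_path / "b")
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_default_cohort_covers_42_eyes(self, tmp_path):
        bundle = cr.run_pipeline(
            {**self.CFG, "group_sizes": {"control": 16, "PPG": 6, "POAG": 20}},
            out_dir=tmp_path)
        assert len(bundle["manifest"]) == 42
        runlog = json.loads((tmp_path / "runlog.json").read_text())
        assert runlog["n_eyes"] == 42
        assert (tmp_path / "features.csv").exists()
        assert (tmp_path / "roc.csv").exists()
        roc = pd.read_csv(tmp_path / "roc.csv")
        assert set(cr.ROC_MARKERS) == set(roc["marker"])
        sf = pd.read_csv(tmp_path / "structure_function.csv")
        assert {"slope", "p", "p_fdr"} <= set(sf.columns)

    def test_control_only_skips_stats_with_notice(self):
        bundle = cr.run_pipeline(
            {**self.CFG, "group_sizes": {"control": 12, "PPG": 0, "POAG": 0}})
        assert bundle["roc"] is None
        assert any("skipped" in n for n in bundle["notices"])
        assert bundle["crosstab"] is None


class TestCli:
    def test_all_subcommand_writes_bundle(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("mode: fast\nn_normative_controls: 40\n"
                       "group_sizes: {control: 8, PPG: 3, POAG: 8}\n")
        res = runner.invoke(cli_main, ["all", "--config", str(cfg),
                                       "--seed", "3", "--out",
                                       str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "crosstab.json").exists()
        assert (tmp_path / "out" / "features.csv").exists()

    def test_simulate_keeps_only_manifest(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("mode: fast\nn_normative_controls: 40\n"
                       "group_sizes: {control: 6, PPG: 2, POAG: 4}\n")
        res = runner.invoke(cli_main, ["simulate", "--config", str(cfg),
                                       "--seed", "3", "--out",
                                       str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "manifest.csv").exists()
        assert not (tmp_path / "out" / "roc.csv").exists()

    def test_validation_error_exit_code(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("mode: warp\n")
        res = runner.invoke(cli_main, ["all", "--config", str(cfg)])
        assert res.exit_code == 1
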