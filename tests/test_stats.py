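import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from twoflash import stats as st
from twoflash.errors import (DataError, DegenerateInputError, PairingError,
                             RangeError)


def brute_force_F(groups):
    """Between/within mean-square ratio by direct summation."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def brute_force_auc(scores, labels):
    """Concordant-pair count with half weight for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAnova:
    def test_identical_groups_give_null_result(self):
        out = st.anova_oneway({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1]})
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        jit = lambda v: v + rng.normal(0, 1e-6, 3)
        out = st.anova_oneway({"a": jit(np.zeros(3)), "b": jit(np.ones(3)),
                               "c": jit(np.full(3, 2.0))})
        assert out["p"] < 1e-6
        for p in out["pairwise"].values():
            assert p < 1e-6

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_f_statistic_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = {k: rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(4, 9))
                  for k in "abc"}
        out = st.anova_oneway(groups)
        assert out["F"] == pytest.approx(
            brute_force_F(list(groups.values())), rel=1e-9)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(0, 1, 6) for k in "abcd"}
        out = st.anova_oneway(groups)
        assert all(p <= 1.0 for p in out["pairwise"].values())
        assert len(out["pairwise"]) == 6

    def test_tiny_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            st.anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert st.fdr_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_hand_example(self):
        adj = st.fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 25)
        adj = st.fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        # order preserving
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            st.fdr_adjust([0.5, 1.2])


def _cohort_frame(rng, n, slope=0.05, subjects=None):
    mT = rng.normal(300, 15, n)
    age = rng.uniform(40, 75, n)
    gender = rng.choice(["M", "F"], n)
    y = slope * mT + 0.02 * age + 0.3 * (gender == "M") + rng.normal(0, 0.8, n)
    return pd.DataFrame({
        "y": y, "mT": mT, "age": age, "gender": gender,
        "subject_id": subjects if subjects is not None
        else [f"s{i}" for i in range(n)]})


class TestStructureFunction:
    def test_slope_recovery_coverage(self):
        """95% CI covers the generating slope in >= 90% of 100 seeds."""
        hits = 0
        for seed in range(100):
            df = _cohort_frame(np.random.default_rng(seed), 200, slope=0.05)
            fit = st.fit_structure_function(df, "y", "mT")
            hits += fit.ci95[0] <= 0.05 <= fit.ci95[1]
        assert hits >= 90

    def test_null_predictor_calibration(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            df = _cohort_frame(rng, 120, slope=0.0)
            fit = st.fit_structure_function(df, "y", "mT")
            hits += fit.ci95[0] <= 0.0 <= fit.ci95[1]
        assert 85 <= hits <= 100

    def test_mixed_model_widens_ci_for_clustered_eyes(self):
        rng = np.random.default_rng(3)
        n_subj = 60
        subj_eff = rng.normal(0, 3.0, n_subj)
        rows = []
        for i in range(n_subj):
            # thickness is a subject-level (between-subject) predictor: both
            # eyes share it, so treating eyes as independent understates the
            # slope uncertainty
            mT = rng.normal(300, 15)
            age = rng.uniform(40, 75)
            for _ in range(2):
                rows.append({"subject_id": f"s{i}", "mT": mT, "age": age,
                             "gender": "F",
                             "y": 0.05 * mT + subj_eff[i] + rng.normal(0, .5)})
        df = pd.DataFrame(rows)
        mixed = st.fit_structure_function(df, "y", "mT", covariates=("age",))
        naive = st.fit_structure_function(
            df.assign(subject_id=[f"u{i}" for i in range(len(df))]),
            "y", "mT", covariates=("age",))
        assert mixed.mixed and not naive.mixed
        assert (mixed.ci95[1] - mixed.ci95[0]) > (naive.ci95[1] - naive.ci95[0])

    def test_constant_predictor_rejected(self):
        df = _cohort_frame(np.random.default_rng(0), 50)
        with pytest.raises(DegenerateInputError):
            st.fit_structure_function(df.assign(mT=300.0), "y", "mT")

    def test_too_few_cases_rejected(self):
        df = _cohort_frame(np.random.default_rng(0), 8)
        with pytest.raises(DataError):
            st.fit_structure_function(df, "y", "mT")

    def test_per_group_slopes(self):
        rng = np.random.default_rng(9)
        a = _cohort_frame(rng, 60, slope=0.05).assign(group="g1")
        b = _cohort_frame(rng, 60, slope=-0.05).assign(group="g2")
        fits = st.fit_structure_function_by_group(pd.concat([a, b]), "y", "mT")
        assert fits["g1"].slope > 0 > fits["g2"].slope


class TestAdjustedRoc:
    def test_matches_bruteforce_on_small_fixtures(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 21))
            labels = np.zeros(n, dtype=int)
            labels[: n // 2] = 1
            marker = rng.normal(labels, 1.0)
            res = st.adjusted_roc(marker, labels)
            assert res.auc == pytest.approx(
                brute_force_auc(res.scores, labels), abs=1e-12)
            # with no covariates the score is monotone in the marker
            assert res.auc == pytest.approx(
                brute_force_auc(marker, labels), abs=1e-12)

    def test_perfect_separation_gives_unit_auc(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.4, 0.3, 0.2, 0.1]
        labels = [1] * 5 + [0] * 5
        assert st.mann_whitney_auc(scores, labels) == 1.0
        res = st.adjusted_roc(np.array(scores), np.array(labels))
        assert res.auc == 1.0

    def test_one_discordant_pair(self):
        # swap the closest case/control pair: 24 of 25 pairs concordant
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.55, 0.4, 0.3, 0.2, 0.1]
        labels = [1] * 5 + [0] * 5
        assert st.mann_whitney_auc(scores, labels) == pytest.approx(0.96)

    def test_noise_marker_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        labels = rng.integers(0, 2, n)
        res = st.adjusted_roc(rng.normal(0, 1, n), labels)
        assert res.auc == pytest.approx(0.5, abs=0.03)

    def test_constant_covariates_equal_unadjusted(self):
        rng = np.random.default_rng(1)
        labels = np.array([0, 1] * 10)
        marker = rng.normal(labels, 0.8)
        plain = st.adjusted_roc(marker, labels)
        adj = st.adjusted_roc(marker, labels,
                              age=np.full(20, 60.0), gender=["F"] * 20)
        assert adj.auc == pytest.approx(plain.auc, abs=1e-12)

    def test_adjustment_uses_informative_covariates(self):
        rng = np.random.default_rng(2)
        n = 300
        labels = rng.integers(0, 2, n)
        age = 50 + 10 * labels + rng.normal(0, 3, n)
        res = st.adjusted_roc(rng.normal(0, 1, n), labels, age=age)
        assert res.auc > 0.8  # age separates even though the marker is noise

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            st.adjusted_roc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(0)
        labels = np.array([0, 1] * 15)
        marker = rng.normal(labels, 1.0)
        a = st.adjusted_roc(marker, labels)
        b = st.adjusted_roc(marker.copy(), labels)
        out = st.delong_compare(a, b)
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        labels = np.array([0, 1] * 20)
        a = st.adjusted_roc(rng.normal(labels, 0.7), labels)
        b = st.adjusted_roc(rng.normal(labels, 2.0), labels)
        ab = st.delong_compare(a, b)
        ba = st.delong_compare(b, a)
        assert ab["z"] == pytest.approx(-ba["z"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_power_to_separate_strong_from_null_marker(self):
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 100)
            strong = st.adjusted_roc(rng.normal(1.8 * labels, 1.0), labels)
            null = st.adjusted_roc(rng.normal(0, 1, 200), labels)
            wins += st.delong_compare(strong, null)["p"] < 0.01
        assert wins >= 38

    def test_unpaired_inputs_rejected(self):
        rng = np.random.default_rng(2)
        la = np.array([0, 1] * 10)
        lb = np.array([1, 0] * 10)
        a = st.adjusted_roc(rng.normal(la, 1), la)
        b = st.adjusted_roc(rng.normal(lb, 1), lb)
        with pytest.raises(PairingError):
            st.delong_compare(a, b)

    def test_variance_against_proc_reference(self, tmp_path):
        """Cross-check AUC, DeLong SE and the paired test against R pROC."""
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1], 15)
        m1 = rng.normal(1.2 * labels, 1.0)
        m2 = rng.normal(0.6 * labels, 1.0)
        df = pd.DataFrame({"label": labels, "m1": m1, "m2": m2})
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(pROC))
            d <- read.csv("{csv}")
            r1 <- roc(d$label, d$m1, quiet=TRUE, direction="<")
            r2 <- roc(d$label, d$m2, quiet=TRUE, direction="<")
            t <- roc.test(r1, r2, method="delong", paired=TRUE)
            cat(sprintf("%.15g", c(auc(r1), sqrt(var(r1)), auc(r2),
                                   t$p.value)), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        auc1_r, se1_r, auc2_r, p_r = map(float, out.stdout.split())

        a = st.adjusted_roc(m1, labels)
        b = st.adjusted_roc(m2, labels)
        assert a.auc == pytest.approx(auc1_r, abs=1e-9)
        assert b.auc == pytest.approx(auc2_r, abs=1e-9)
        assert a.se_auc == pytest.approx(se1_r, abs=1e-9)
        assert st.delong_compare(a, b)["p"] == pytest.approx(p_r, abs=1e-9)
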