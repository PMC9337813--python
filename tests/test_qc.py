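"""Drift correction, feature filtering and transform behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabosvd import (
    IntensityMatrix,
    QCParams,
    SimulationConfig,
    autoscale,
    compute_feature_qc,
    compute_rsd,
    dilution_response,
    filter_features,
    glog,
    glog_transform,
    loess_drift_correct,
    qc_pipeline,
    simulate_study,
)


def toy_manifest(n_study=10, n_qc=4, batch=1, start_order=1):
    rows = []
    order = start_order
    for i in range(n_qc):
        rows.append(("qc%d_%d" % (batch, i), "", "pooled_qc", batch, np.nan))
    for i in range(n_study):
        rows.append(("s%d_%d" % (batch, i), "subj%d_%d" % (batch, i),
                     "study", batch, np.nan))
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "sample_type",
                                     "batch", "dilution_fraction"])
    # interleave QC among study samples
    df = df.sample(frac=1, random_state=batch).reset_index(drop=True)
    df["run_order"] = np.arange(start_order, start_order + len(df))
    df["platform"] = "lipid RPC+"
    return df


class TestRSD:
    @pytest.mark.parametrize(
        "values,expected",
        [([5, 5, 5], 0.0), ([1, 2, 3], 50.0), ([10, 10, 10, 10], 0.0)],
    )
    def test_worked_examples(self, values, expected):
        assert compute_rsd(values) == pytest.approx(expected)

    @pytest.mark.parametrize("values", [[5], [], [1, -3], [0, 0, 0]])
    def test_undefined_cases_flagged_nan(self, values):
        assert math.isnan(compute_rsd(values))

    def test_threshold_is_strict(self):
        """RSD 29.9% passes, exactly 30.0% fails."""
        qc = pd.DataFrame({
            "rsd_qc": [29.9, 30.0], "rsd_study": [100.0, 100.0],
            "dilution_r": [0.9, 0.9], "n_qc_used": [5, 5],
            "n_study_used": [50, 50], "n_dilution_used": [6, 6],
            "missing_fraction": [0.0, 0.0]},
            index=["a", "b"])
        flags, _ = filter_features(qc, QCParams())
        assert bool(flags.loc["a", "pass_rsd_qc"])
        assert not bool(flags.loc["b", "pass_rsd_qc"])


class TestDriftCorrection:
    def test_identity_without_drift(self):
        man = toy_manifest(n_study=20, n_qc=6)
        rng = np.random.default_rng(0)
        base = rng.uniform(1e4, 1e5, 5)
        vals = pd.DataFrame(np.tile(base[:, None], (1, len(man))),
                            index=[f"f{i}" for i in range(5)],
                            columns=man["sample_id"])
        # study samples vary biologically; QC stays at the pooled level
        corrected, diag = loess_drift_correct(
            IntensityMatrix(vals), man, QCParams())
        np.testing.assert_allclose(corrected.values.to_numpy(),
                                   vals.to_numpy(), rtol=1e-6)
        assert diag["corrected"].all()
        assert corrected.state == "corrected"

    def test_linear_drift_removed_and_truth_recovered(self):
        """Multiplicative 1+0.002*run_order drift: QC RSD falls, truth r>=0.99."""
        cfg = SimulationConfig(
            n_subjects_per_cohort=(80, 120), n_features=40, n_batches=1,
            qc_interval=8, drift_amplitude=0.0, batch_offset_sd=0.0,
            tech_cv=0.05, bio_cv=1.0, seed=14)
        study = simulate_study(cfg)
        man = study["manifest"]
        drift = 1 + 0.002 * man.set_index("sample_id")["run_order"]
        raw = study["truth"].clean * study["truth"].tech_noise
        raw = raw * drift.loc[raw.columns]
        corrected, _ = loess_drift_correct(IntensityMatrix(raw), man, QCParams())
        qc_cols = man.loc[man["sample_type"] == "pooled_qc", "sample_id"]
        pre = 100 * raw[qc_cols].std(axis=1, ddof=1) / raw[qc_cols].mean(axis=1)
        post_vals = corrected.values[qc_cols]
        post = 100 * post_vals.std(axis=1, ddof=1) / post_vals.mean(axis=1)
        assert (post < pre).mean() > 0.95
        st_cols = man.loc[man["sample_type"] == "study", "sample_id"]
        cv = corrected.values[st_cols].to_numpy()
        cl = study["truth"].clean[st_cols].to_numpy()
        for i in range(len(cv)):
            assert np.corrcoef(cv[i], cl[i])[0, 1] >= 0.99

    def test_between_batch_offsets_equalized(self):
        """Batches at x1.0 and x1.5 response end up with equal means (<2%)."""
        man = pd.concat([toy_manifest(16, 4, batch=1),
                         toy_manifest(16, 4, batch=2, start_order=100)],
                        ignore_index=True)
        offset = np.where(man["batch"] == 1, 1.0, 1.5)
        vals = pd.DataFrame([1000.0 * offset, 5e4 * offset],
                            index=["f0", "f1"], columns=man["sample_id"])
        corrected, _ = loess_drift_correct(IntensityMatrix(vals), man, QCParams())
        for b_means in corrected.values.T.groupby(man.set_index("sample_id")["batch"]):
            pass
        by_batch = corrected.values.T.groupby(
            man.set_index("sample_id")["batch"]).mean()
        rel = (by_batch.loc[1] - by_batch.loc[2]).abs() / by_batch.loc[1]
        assert (rel < 0.02).all()

    def test_reference_level_preserved(self):
        """Per feature, the median pooled-QC intensity is unchanged (1e-3 rel)."""
        cfg = SimulationConfig(n_subjects_per_cohort=(40, 60), n_features=25,
                               n_batches=2, qc_interval=8, drift_amplitude=0.15,
                               tech_cv=0.08, seed=15)
        study = simulate_study(cfg)
        man = study["manifest"]
        corrected, _ = loess_drift_correct(
            IntensityMatrix(study["intensities"]), man, QCParams())
        qc_cols = man.loc[man["sample_type"] == "pooled_qc", "sample_id"]
        before = study["intensities"][qc_cols].median(axis=1)
        after = corrected.values[qc_cols].median(axis=1)
        np.testing.assert_allclose(after, before, rtol=1e-3)

    def test_too_few_qc_in_batch_raises(self):
        man = toy_manifest(n_study=10, n_qc=2)
        vals = pd.DataFrame(np.ones((3, len(man))), columns=man["sample_id"],
                            index=list("abc"))
        with pytest.raises(ValueError, match="batch 1"):
            loess_drift_correct(IntensityMatrix(vals), man, QCParams())

    def test_disabled_platform_passes_through(self):
        man = toy_manifest(n_study=6, n_qc=1)  # would fail the QC-count check
        vals = pd.DataFrame(np.ones((2, len(man))), columns=man["sample_id"],
                            index=["a", "b"])
        params = QCParams(loess_enabled={"lipid RPC+": False})
        corrected, diag = loess_drift_correct(IntensityMatrix(vals), man, params)
        assert corrected.state == "corrected"
        pd.testing.assert_frame_equal(corrected.values, vals)
        assert not diag["corrected"].any()


class TestDilutionResponse:
    FRACS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.01)

    def make(self, intensities):
        man = pd.DataFrame({
            "sample_id": [f"d{i}" for i in range(6)],
            "subject_id": "", "sample_type": "dilution_qc",
            "run_order": range(1, 7), "batch": 1,
            "dilution_fraction": self.FRACS, "platform": "lipid RPC+"})
        vals = pd.DataFrame([intensities], index=["f0"],
                            columns=man["sample_id"])
        return IntensityMatrix(vals), man

    def test_proportional_gives_r_one(self):
        mat, man = self.make([10, 8, 6, 4, 2, 0.1])
        assert dilution_response(mat, man)["f0"] == pytest.approx(1.0)

    def test_constant_response_undefined(self):
        mat, man = self.make([7, 7, 7, 7, 7, 7])
        assert math.isnan(dilution_response(mat, man)["f0"])

    def test_matches_closed_form_pearson(self):
        y = [10, 8, 6, 4, 2, 9]
        mat, man = self.make(y)
        x = np.array(self.FRACS)
        yv = np.array(y, float)
        expected = ((x - x.mean()) @ (yv - yv.mean())) / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((yv - yv.mean()) ** 2).sum()))
        assert dilution_response(mat, man)["f0"] == pytest.approx(expected)


class TestFilterFeatures:
    def frame(self, rsd_qc, dilution_r, rsd_study):
        return pd.DataFrame({
            "rsd_qc": [rsd_qc], "rsd_study": [rsd_study],
            "dilution_r": [dilution_r], "n_qc_used": [10],
            "n_study_used": [100], "n_dilution_used": [36],
            "missing_fraction": [0.0]}, index=["f"])

    @pytest.mark.parametrize(
        "rsd_qc,dil_r,rsd_study,expected",
        [
            (25.0, 0.9, 30.0, True),   # 30 > 1.1*25 = 27.5
            (25.0, 0.9, 27.0, False),  # 27 < 27.5: variance-ratio failure
            (0.0, 1.0, 5.0, True),     # constant QC: any study variance passes
            (35.0, 0.9, 100.0, False),
            (25.0, 0.6, 100.0, False),
        ],
    )
    def test_three_criteria_arithmetic(self, rsd_qc, dil_r, rsd_study, expected):
        flags, _ = filter_features(self.frame(rsd_qc, dil_r, rsd_study),
                                   QCParams())
        assert bool(flags["pass_overall"].iloc[0]) is expected

    def test_dilution_criterion_vacuous_without_series(self):
        """NMR-style datasets with no dilution series skip the linearity rule."""
        qc = self.frame(10.0, np.nan, 50.0)
        qc["n_dilution_used"] = 0
        flags, report = filter_features(qc, QCParams())
        assert bool(flags["pass_dilution"].iloc[0])
        assert bool(flags["pass_overall"].iloc[0])
        assert not report["dilution_criterion_applied"]

    def test_undefined_metrics_fail_their_criterion(self):
        flags, _ = filter_features(self.frame(np.nan, 0.9, 50.0), QCParams())
        assert not bool(flags["pass_rsd_qc"].iloc[0])
        assert not bool(flags["pass_overall"].iloc[0])


class TestGlog:
    def test_reduces_to_natural_log_at_lambda_zero(self):
        assert glog(np.e, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_defined_at_zero(self):
        assert glog(0.0, 1.0) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_large_x_asymptote(self):
        assert abs(glog(1e6, 1.0) - math.log(1e6)) < 1e-9

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            glog(1.0, -0.5)

    @settings(max_examples=200, deadline=None)
    @given(
        x1=st.floats(0, 1e8, allow_nan=False),
        dx=st.floats(1e-6, 1e8, allow_nan=False),
        lam=st.floats(1e-12, 1e12, allow_nan=False),
    )
    def test_strictly_monotone(self, x1, dx, lam):
        assert glog(x1, lam) < glog(x1 + dx, lam)


class TestAutoscale:
    def make(self, rows):
        n = len(rows[0])
        man = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "subject_id": [f"p{i}" for i in range(n)],
            "sample_type": "study", "run_order": range(1, n + 1),
            "batch": 1, "dilution_fraction": np.nan, "platform": "x"})
        vals = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                            columns=man["sample_id"], dtype=float)
        return IntensityMatrix(vals, state="transformed"), man

    def test_hand_computed_example(self):
        mat, man = self.make([[1, 2, 3]])
        scaled, _ = autoscale(mat, man)
        np.testing.assert_allclose(scaled.values.to_numpy(),
                                   [[-1.0, 0.0, 1.0]])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        mat, man = self.make(rng.lognormal(10, 1, (8, 40)).tolist())
        scaled, stats = autoscale(mat, man)
        assert (scaled.values.mean(axis=1).abs() < 1e-10).all()
        assert ((scaled.values.std(axis=1, ddof=1) - 1).abs() < 1e-10).all()

    def test_constant_feature_dropped(self):
        mat, man = self.make([[1, 2, 3], [5, 5, 5]])
        scaled, stats = autoscale(mat, man)
        assert list(scaled.values.index) == ["f0"]
        assert stats.loc["f1", "dropped_reason"] == "zero variance"

    def test_state_machine_enforced(self):
        mat, man = self.make([[1, 2, 3]])
        raw = IntensityMatrix(mat.values, state="raw")
        with pytest.raises(ValueError, match="transformed"):
            autoscale(raw, man)
        with pytest.raises(ValueError, match="state transition"):
            raw.advance(raw.values, "scaled")


class TestPipeline:
    def test_pass_fail_matches_scalar_recomputation(self, demo_study, demo_qc):
        """Pipeline QC decisions equal a per-feature scalar recomputation."""
        params = QCParams()
        corrected = demo_qc["corrected"].values
        man = demo_study["manifest"].set_index("sample_id")
        qc_cols = man.index[man["sample_type"] == "pooled_qc"]
        st_cols = man.index[man["sample_type"] == "study"]
        dil = man[man["sample_type"] == "dilution_qc"]
        for feat in corrected.index:
            rsd_qc = compute_rsd(corrected.loc[feat, qc_cols])
            rsd_study = compute_rsd(corrected.loc[feat, st_cols])
            r = np.corrcoef(dil["dilution_fraction"],
                            corrected.loc[feat, dil.index])[0, 1]
            expect = (
                (rsd_qc < params.rsd_qc_max)
                and (r > params.dilution_r_min)
                and (rsd_study > params.study_to_qc_rsd_ratio_min * rsd_qc)
            )
            assert bool(demo_qc["feature_qc"].loc[feat, "pass_overall"]) == expect

    def test_report_counts_consistent(self, demo_qc):
        fq = demo_qc["feature_qc"]
        rep = demo_qc["report"]
        assert rep["n_pass"] == int(fq["pass_overall"].sum())
        assert rep["n_fail_rsd_qc"] == int((~fq["pass_rsd_qc"]).sum())
        assert demo_qc["scaled"].values.shape[0] <= rep["n_pass"]
        assert demo_qc["scaled"].state == "scaled"

    def test_pipeline_deterministic(self, demo_study):
        a = qc_pipeline(demo_study["intensities"], demo_study["manifest"])
        b = qc_pipeline(demo_study["intensities"], demo_study["manifest"])
        pd.testing.assert_frame_equal(a["feature_qc"], b["feature_qc"])
        pd.testing.assert_frame_equal(a["scaled"].values, b["scaled"].values)
        assert a["report"] == b["report"]

    def test_missing_values_tolerated(self, demo_study):
        raw = demo_study["intensities"].copy()
        rng = np.random.default_rng(0)
        mask = rng.random(raw.shape) < 0.05
        raw = raw.mask(mask)
        result = qc_pipeline(raw, demo_study["manifest"])
        assert result["report"]["n_pass"] > 0
        assert np.isfinite(result["glog_lambda"])
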