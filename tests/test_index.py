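"""Reweighting, resistance-index scoring, stratification and evaluation."""

import numpy as np
import pandas as pd
import pytest

from melres import (
    DegenerateStratificationError,
    GeneSignature,
    MissingProbeError,
    ResistanceIndexModel,
    UnweightedSignatureError,
    compute_ri,
    evaluate_cohort,
    load_melphalan_signature,
    reweight_signature,
    stratify,
    hazard_ratio_report,
)
from melres.survival import CoxPH, SurvivalData

from _oracles import grid_cox_mle


class TestReweighting:
    def test_single_probe_matches_grid_oracle(self, planted_cohort):
        """A one-probe reweighting on a tiny cohort with binary expression
        is a univariate Cox fit; its new weight matches brute-force
        partial-likelihood grid maximisation."""
        cohort, _ = planted_cohort
        probe = cohort.expression.index[0]
        sig = GeneSignature(pd.DataFrame({"probe_id": [probe], "weight": [0.0]}))
        expr = cohort.expression.iloc[:, :8].copy()
        expr.loc[probe] = [1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        clin = cohort.clinical.iloc[:8]
        from melres.simulate import PatientCohort
        tiny = PatientCohort(expression=expr, clinical=clin)
        rw = reweight_signature(sig, tiny)
        t, e = tiny.pfs
        oracle = grid_cox_mle(t, e, expr.loc[probe].to_numpy())
        assert abs(rw.new_weights.iloc[0] - oracle) < 1e-3

    def test_missing_probe_error_lists_ids(self, planted_cohort):
        cohort, _ = planted_cohort
        sig = GeneSignature(pd.DataFrame(
            {"probe_id": ["nope_at", cohort.expression.index[0]],
             "weight": [0.0, 0.0]}))
        with pytest.raises(MissingProbeError, match="nope_at"):
            reweight_signature(sig, cohort)

    def test_constant_probe_dropped_with_warning(self, planted_cohort):
        cohort, _ = planted_cohort
        probes = list(cohort.expression.index[:3])
        expr = cohort.expression.copy()
        expr.loc[probes[0]] = 1.0  # constant across patients
        from melres.simulate import PatientCohort
        cohort2 = PatientCohort(expression=expr, clinical=cohort.clinical)
        sig = GeneSignature(pd.DataFrame({"probe_id": probes, "weight": 0.0}))
        with pytest.warns(UserWarning, match="zero-variance"):
            rw = reweight_signature(sig, cohort2)
        assert rw.dropped_probes == (probes[0],)
        # identical to fitting without the degenerate probe
        sig_manual = GeneSignature(pd.DataFrame({"probe_id": probes[1:],
                                                 "weight": 0.0}))
        rw_manual = reweight_signature(sig_manual, cohort2)
        np.testing.assert_allclose(rw.new_weights.to_numpy(),
                                   rw_manual.new_weights.to_numpy())

    def test_training_ri_equals_cox_linear_predictor(self, planted_cohort,
                                                     planted_signature):
        cohort, w = planted_cohort
        rw = reweight_signature(planted_signature, cohort)
        ri = compute_ri(rw, cohort.expression)
        X = cohort.expression.loc[rw.probe_ids].T
        fit = CoxPH().fit(X, SurvivalData(*cohort.pfs))
        np.testing.assert_allclose(ri.to_numpy(), fit.linear_predictor_,
                                   atol=1e-10)


class TestComputeRI:
    def test_zero_expression_gives_zero(self):
        sig = load_melphalan_signature()
        expr = pd.DataFrame(0.0, index=sig.probe_ids, columns=["s1", "s2"])
        ri = compute_ri(sig, expr)
        np.testing.assert_allclose(ri.to_numpy(), 0.0)

    def test_published_single_probe_weight(self):
        """Unit expression on SLC31A2's probe alone scores its new weight."""
        sig = load_melphalan_signature()
        expr = pd.DataFrame(0.0, index=sig.probe_ids, columns=["s1"])
        expr.loc["204204_at", "s1"] = 1.0
        assert compute_ri(sig, expr).iloc[0] == pytest.approx(-0.507)

    def test_published_two_probe_additivity(self):
        sig = load_melphalan_signature()
        expr = pd.DataFrame(0.0, index=sig.probe_ids, columns=["s1"])
        expr.loc["204204_at", "s1"] = 1.0
        expr.loc["202043_s_at", "s1"] = 1.0
        assert compute_ri(sig, expr).iloc[0] == pytest.approx(-0.021)

    def test_unweighted_signature_rejected(self):
        sig = GeneSignature(pd.DataFrame({"probe_id": ["a"], "weight": [1.0]}))
        expr = pd.DataFrame([[0.5]], index=["a"], columns=["s1"])
        with pytest.raises(UnweightedSignatureError):
            compute_ri(sig, expr)


class TestStratify:
    def test_quartile_arithmetic_400_distinct(self, rng):
        ri = pd.Series(rng.permutation(400).astype(float))
        a = stratify(ri)
        counts = a.counts()
        assert counts["sensitive"] == 100
        assert counts["intermediate"] == 200
        assert counts["resistant"] == 100
        merged = a.merged_stratum.value_counts()
        assert merged["non_resistant"] == 300

    def test_rank_invariance_under_monotone_transform(self, rng):
        ri = pd.Series(rng.standard_normal(97))
        a = stratify(ri)
        b = stratify(np.exp(ri) * 3.0 + 5.0)
        pd.testing.assert_series_equal(a.stratum, b.stratum)

    def test_all_equal_rejected(self):
        with pytest.raises(DegenerateStratificationError):
            stratify(pd.Series(np.ones(10)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            stratify(pd.Series([1.0, 2.0, 3.0]))

    def test_boundary_assigned_downward(self):
        ri = pd.Series(np.arange(4, dtype=float))
        a = stratify(ri)
        assert list(a.stratum) == ["sensitive", "intermediate", "intermediate",
                                   "resistant"]


class TestEstimatorShape:
    def test_fit_predict_roundtrip(self, planted_cohort, planted_signature):
        cohort, _ = planted_cohort
        model = ResistanceIndexModel(planted_signature).fit(cohort)
        ri = model.predict(cohort.expression)
        assert len(ri) == cohort.n_patients
        params = model.get_params()
        assert params["endpoint"] == "pfs"

    def test_predict_before_fit_rejected(self, planted_signature):
        model = ResistanceIndexModel(planted_signature)
        with pytest.raises(UnweightedSignatureError):
            model.predict(pd.DataFrame())


class TestEvaluation:
    def test_end_to_end_rank_invariance(self, planted_cohort, planted_signature):
        """Adding a constant to one probe's expression shifts every RI by a
        constant and leaves strata, log-rank and stratum HRs unchanged."""
        cohort, _ = planted_cohort
        rw = reweight_signature(planted_signature, cohort)
        ri1 = compute_ri(rw, cohort.expression)
        shifted = cohort.expression.copy()
        shifted.loc[rw.probe_ids[0]] += 10.0
        ri2 = compute_ri(rw, shifted)
        diff = ri2 - ri1
        np.testing.assert_allclose(diff, diff.iloc[0], atol=1e-10)
        a1, a2 = stratify(ri1), stratify(ri2)
        pd.testing.assert_series_equal(a1.stratum, a2.stratum)
        e1 = evaluate_cohort(cohort, a1, with_rcs=False, horizons=())
        e2 = evaluate_cohort(cohort, a2, with_rcs=False, horizons=())
        assert e1.pfs.logrank.chi_square == pytest.approx(
            e2.pfs.logrank.chi_square, abs=1e-9)
        assert e1.pfs.univariate_hr == pytest.approx(e2.pfs.univariate_hr,
                                                     abs=1e-9)

    def test_planted_signal_detected(self, planted_cohort, planted_signature):
        cohort, _ = planted_cohort
        rw = reweight_signature(planted_signature, cohort)
        assignment = stratify(compute_ri(rw, cohort.expression))
        ev = evaluate_cohort(cohort, assignment, horizons=(24.0,))
        assert ev.pfs.univariate_hr > 1.0
        assert ev.pfs.logrank.p_value < 0.05
        assert ev.pfs.rcs is not None
        assert 24.0 in ev.pfs.roc

    def test_hazard_ratio_report_layout(self, planted_cohort, planted_signature):
        cohort, _ = planted_cohort
        rw = reweight_signature(planted_signature, cohort)
        assignment = stratify(compute_ri(rw, cohort.expression))
        rep = hazard_ratio_report(cohort, assignment, endpoint="pfs")
        assert list(rep.index) == ["RI(75,100]", "Age", "SexMale", "ISS2", "ISS3"]
        assert {"uni_hazard_ratio", "uni_p_value", "multi_hazard_ratio",
                "multi_p_value"} <= set(rep.columns)
        assert (rep["uni_hazard_ratio"] > 0).all()
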