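"""Calibration fitting, reference standardization, response factors, and
the batchwise method cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcexpose import (
    CertifiedReference,
    NoiseModel,
    ValidationError,
    compare_methods,
    compute_rf,
    external_quant,
    fit_calibration,
    make_universe,
    match_all,
    quantify_study,
    rf_quant,
    rs_single,
    rs_two_point,
    simulate_study,
)
from gcexpose.quantify import results_frame
from gcexpose.simulate import DEFAULT_DILUTION_LEVELS


class TestFitCalibration:
    def test_noiseless_exact_line(self):
        levels = list(DEFAULT_DILUTION_LEVELS)
        responses = [100 * l for l in levels]
        model = fit_calibration(levels, responses, "X")
        assert model.slope == pytest.approx(100.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.linearity_rho == 1.0
        assert model.passes_linearity

    def test_idl_arithmetic(self):
        # replicates at the lowest nonzero level with SD 1.5, slope 100
        levels = [0, 0, 0.05, 0.05, 0.05, 2, 2, 2]
        low = [5.0 - 1.5, 5.0, 5.0 + 1.5]  # SD exactly 1.5
        responses = [0, 0] + low + [200, 200, 200]
        model = fit_calibration(levels, responses, "X")
        sd = np.std(low, ddof=1)
        assert model.idl == pytest.approx(3 * sd / model.slope)

    def test_strictly_monotone_response_has_rho_one(self):
        levels = [0, 0.05, 0.1, 0.25, 0.5, 1, 2]
        responses = [1, 2, 4, 9, 30, 31, 200]  # monotone but not linear
        assert fit_calibration(levels, responses, "X").linearity_rho == 1.0

    def test_degenerate_levels_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration([1, 1, 1], [1, 2, 3], "X")

    def test_negative_slope_flagged_non_quantifiable(self):
        model = fit_calibration([0, 1, 2], [10, 5, 0], "X")
        assert not model.quantifiable
        res = external_quant(3.0, model)
        assert res.concentration is None and "non_quantifiable" in res.flags


class TestRsSingle:
    def test_ratio_formula(self):
        res = rs_single(2.0, 1.0, 0.1)
        assert res.concentration == pytest.approx(0.2)
        assert res.method == "rs_single"

    def test_zero_sample_intensity_gives_zero(self):
        assert rs_single(0.0, 10.0, 0.5).concentration == 0.0

    def test_missing_reference_flagged(self):
        res = rs_single(2.0, float("nan"), 0.1)
        assert res.concentration is None
        assert "reference_missing" in res.flags

    @settings(deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        i_sample=st.floats(0.0, 1e6),
        i_ref=st.floats(1e-3, 1e6),
        c_ref=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, scale, i_sample, i_ref, c_ref):
        """Multiplying all intensities of a batch by a constant leaves
        concentrations unchanged: the mechanism by which concurrent
        reference materials absorb batch effects."""
        a = rs_single(i_sample, i_ref, c_ref).concentration
        b = rs_single(i_sample * scale, i_ref * scale, c_ref).concentration
        assert b == pytest.approx(a, rel=1e-9)

    def test_noiseless_study_recovered_to_machine_precision(self, noiseless_study):
        chems, library, refs, table, truth = noiseless_study
        refs_58 = [r for r in refs if r.srm_id == "srm_1958"]
        matches, _ = match_all(table, library)
        results = quantify_study(table, matches, refs_58)
        df = results_frame(results)
        assert (df["method"] == "rs_single").all()
        merged = df.merge(
            truth.concentrations.rename(
                columns={"sample_id": "sample", "concentration": "true"}
            ),
            on=["chemical", "sample"],
        )
        assert len(merged) == 17 * 20
        rel = ((merged["concentration"] - merged["true"]) / merged["true"]).abs()
        assert rel.max() < 1e-9


class TestRsTwoPoint:
    REFS = {
        "srm_1957": CertifiedReference("X", "srm_1957", 1.0),
        "srm_1958": CertifiedReference("X", "srm_1958", 3.0),
    }

    def test_line_through_origin(self):
        res = rs_two_point({"srm_1957": 100.0, "srm_1958": 300.0}, self.REFS, 200.0)
        assert res.concentration == pytest.approx(2.0)
        assert res.method == "rs_two_point"
        assert res.flags == []

    def test_negative_x_intercept_uses_the_line(self):
        # slope 100, intercept 50, x-intercept -0.5 <= 0: keep the line
        res = rs_two_point({"srm_1957": 150.0, "srm_1958": 350.0}, self.REFS, 250.0)
        assert res.concentration == pytest.approx(2.0)
        assert "x_intercept_fallback" not in res.flags

    def test_positive_x_intercept_falls_back_to_single_point(self):
        # slope 100, intercept -50, x-intercept +0.5 > 0: fall back
        res = rs_two_point({"srm_1957": 50.0, "srm_1958": 250.0}, self.REFS, 100.0)
        assert "x_intercept_fallback" in res.flags
        assert res.method == "rs_single"
        assert res.concentration == pytest.approx(3.0 * 100.0 / 250.0)

    def test_zero_intercept_equals_rs_single(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            slope = rng.uniform(10, 1000)
            c57, c58 = sorted(rng.uniform(0.1, 5.0, size=2))
            refs = {
                "srm_1957": CertifiedReference("X", "srm_1957", c57),
                "srm_1958": CertifiedReference("X", "srm_1958", c58),
            }
            i_s = rng.uniform(0, 1000)
            two = rs_two_point(
                {"srm_1957": slope * c57, "srm_1958": slope * c58}, refs, i_s
            )
            one = rs_single(i_s, slope * c58, c58)
            assert two.concentration == pytest.approx(one.concentration, rel=1e-9)

    def test_mixed_units_rejected(self):
        refs = {
            "srm_1957": CertifiedReference("X", "srm_1957", 1.0, unit="ng/mL"),
            "srm_1958": CertifiedReference("X", "srm_1958", 3.0, unit="ng/kg"),
        }
        with pytest.raises(ValidationError, match="unit"):
            rs_two_point({"srm_1957": 1.0, "srm_1958": 3.0}, refs, 1.0)


class TestResponseFactor:
    def test_rf_and_quantification(self):
        rf = compute_rf(500.0, 5.0, chemical_name="X")
        assert rf.rf == pytest.approx(100.0)
        assert rf_quant(250.0, rf).concentration == pytest.approx(2.5)

    def test_rf_from_two_srm_injections_is_mean(self):
        rf = compute_rf([480.0, 520.0], 5.0, chemical_name="X")
        assert rf.rf == pytest.approx(100.0)

    def test_rf_quant_equals_rs_single_under_proportional_response(self):
        """With response I = k*c, RF (from the SRM) and single-point RS
        reduce to the same ratio."""
        k, c_ref = 37.5, 1.6
        i_ref = k * c_ref
        rf = compute_rf(i_ref, c_ref, chemical_name="X")
        for i_sample in (0.0, 12.3, 250.0):
            assert rf_quant(i_sample, rf).concentration == pytest.approx(
                rs_single(i_sample, i_ref, c_ref).concentration
            )

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValidationError):
            compute_rf(0.0, 5.0)


class TestCompareMethods:
    def _results(self, frame, method):
        from gcexpose.quantify import QuantResult

        return [
            QuantResult(c, s, float(v), "ng/mL", method)
            for (c, s), v in frame.stack().items()
        ]

    def test_scaled_results_have_rho_one(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            rng.lognormal(0, 1, size=(3, 10)),
            index=["A", "B", "C"],
            columns=[f"S{i}" for i in range(10)],
        )
        a = self._results(frame, "rs_single")
        b = self._results(2.0 * frame, "external_curve")
        cmp = compare_methods(a, b)
        assert (cmp["rho_abs"] == 1.0).all()

    def test_reversed_ranking_has_abs_rho_one(self):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["A"], columns=list("wxyz")
        )
        cmp = compare_methods(
            self._results(frame, "a"), self._results(5.0 - frame, "b")
        )
        assert cmp["rho_abs"].iloc[0] == 1.0

    def test_insufficient_overlap_noted(self):
        frame = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s1", "s2"])
        cmp = compare_methods(self._results(frame, "a"), self._results(frame, "b"))
        assert cmp["note"].iloc[0] == "insufficient overlap"


class TestQuantifyStudy:
    def test_cascade_two_point_when_both_srms_available(self, noiseless_study):
        chems, library, refs, table, truth = noiseless_study
        matches, _ = match_all(table, library)
        results = quantify_study(table, matches, refs)
        df = results_frame(results)
        # noiseless proportional response: the two-point line passes through
        # the origin, so no fallback fires and every result is two-point
        assert (df["method"] == "rs_two_point").all()
        merged = df.merge(
            truth.concentrations.rename(
                columns={"sample_id": "sample", "concentration": "true"}
            ),
            on=["chemical", "sample"],
        )
        rel = ((merged["concentration"] - merged["true"]) / merged["true"]).abs()
        assert rel.max() < 1e-9

    def test_cascade_single_point_when_only_srm_1958_certified(self, noiseless_study):
        chems, library, refs, table, _ = noiseless_study
        matches, _ = match_all(table, library)
        refs_58 = [r for r in refs if r.srm_id == "srm_1958"]
        df = results_frame(quantify_study(table, matches, refs_58))
        assert (df["method"] == "rs_single").all()

    def test_no_applicable_method_reported(self, noiseless_study):
        chems, library, refs, table, _ = noiseless_study
        matches, _ = match_all(table, library)
        df = results_frame(quantify_study(table, matches, []))
        assert (df["method"] == "none").all()
        assert df["flags"].str.contains("no_applicable_method").all()

    def test_batchwise_rs_absorbs_batch_drift(self):
        """With a +/-20%-scale response drift between batches, batchwise RS
        recovers planted concentrations exactly (noiseless), while pooling
        SRM intensities across batches would not."""
        noise = NoiseModel.noiseless(seed=21)
        chems, library, refs = make_universe(8, (4, 5), noise)
        table, truth = simulate_study(
            chems, 10, n_batches=4, noise=noise,
            batch_scale=[0.8, 1.0, 1.1, 1.2],
        )
        matches, _ = match_all(table, library)
        results = quantify_study(table, matches, refs)
        df = results_frame(results).dropna(subset=["concentration"])
        merged = df.merge(
            truth.concentrations.rename(
                columns={"sample_id": "sample", "concentration": "true"}
            ),
            on=["chemical", "sample"],
        )
        rel = ((merged["concentration"] - merged["true"]) / merged["true"]).abs()
        assert rel.max() < 1e-9

        # a pooled-SRM variant shows the drift
        intens = matches[0].quantifier_intensity
        srm_cols = table.samples_with_role("srm_1958")
        pooled_ref = float(intens[srm_cols].mean())
        chem = matches[0].chemical_name
        c_ref = next(
            r.mass_fraction for r in refs
            if r.chemical_name == chem and r.srm_id == "srm_1958"
        )
        sample_b1 = [s for s in table.samples_with_role("study")
                     if table.manifest.loc[s, "batch_id"] == 1][0]
        pooled = rs_single(float(intens[sample_b1]), pooled_ref, c_ref).concentration
        true = truth.concentration(chem, sample_b1)
        assert abs(pooled - true) / true > 0.01

    def test_batch_scale_invariance_of_concentrations(self):
        noise = NoiseModel.noiseless(seed=31)
        chems, library, refs = make_universe(5, (4, 4), noise)
        table, _ = simulate_study(chems, 6, n_batches=2, noise=noise)
        matches, _ = match_all(table, library)
        base = results_frame(quantify_study(table, matches, refs))

        scaled = table.intensities.copy()
        b2 = table.manifest.index[table.manifest["batch_id"] == 2]
        scaled[b2] = scaled[b2] * 3.7
        from gcexpose import FeatureTable

        table2 = FeatureTable(table.meta.copy(), scaled, table.manifest.copy())
        matches2, _ = match_all(table2, library)
        again = results_frame(quantify_study(table2, matches2, refs))
        merged = base.merge(again, on=["chemical", "sample"], suffixes=("_a", "_b"))
        assert np.allclose(
            merged["concentration_a"], merged["concentration_b"], rtol=1e-9
        )

    def test_parameter_recovery_at_ten_percent_cv(self):
        """Median absolute relative error of single-point RS <= 10% at
        per-injection CV 0.1 over >= 1000 chemical-sample events."""
        noise = NoiseModel(seed=41, ppm_sigma=1.0, rt_sigma=2.0 / 60.0,
                           intensity_cv=0.1, blank_background_features=0)
        chems, library, refs = make_universe(50, (3, 4), noise)
        table, truth = simulate_study(chems, 20, noise=noise)
        refs_58 = [r for r in refs if r.srm_id == "srm_1958"]
        matches, _ = match_all(table, library)
        df = results_frame(quantify_study(table, matches, refs_58)).dropna(
            subset=["concentration"]
        )
        merged = df.merge(
            truth.concentrations.rename(
                columns={"sample_id": "sample", "concentration": "true"}
            ),
            on=["chemical", "sample"],
        )
        assert len(merged) >= 1000
        rel = ((merged["concentration"] - merged["true"]) / merged["true"]).abs()
        assert rel.median() <= 0.10
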