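"""Hill fitting, synergy reference models, combination ratio, DSS."""

import numpy as np
import pytest

from combnet.synergy import (
    DoseResponseSurface,
    HillParams,
    combination_ratio,
    dss,
    expected_response,
    fit_hill,
    synergy_score,
)
from combnet.synthetic import SurfaceSpec, simulate_surface

DOSES = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])


class TestHill:
    def test_parameter_recovery(self):
        truth = HillParams(e_min=0.0, e_max=1.0, ec50=100.0, slope=1.0)
        fit = fit_hill(DOSES, truth(DOSES))
        assert fit.e_min == pytest.approx(0.0, abs=0.01)
        assert fit.e_max == pytest.approx(1.0, abs=0.01)
        assert fit.ec50 == pytest.approx(100.0, rel=0.01)
        assert fit.slope == pytest.approx(1.0, rel=0.01)

    def test_midpoint_identity(self):
        h = HillParams(e_min=0.1, e_max=0.9, ec50=50.0, slope=1.7)
        assert h(50.0) == pytest.approx((0.1 + 0.9) / 2)

    def test_constant_responses_flagged(self):
        fit = fit_hill(DOSES, np.full(5, 0.5))
        assert fit.flagged
        assert fit.e_min == pytest.approx(0.5, abs=0.02)
        assert fit.e_max == pytest.approx(0.5, abs=0.02)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_hill([1.0, 10.0, 100.0], [0.1, 0.5, 0.9])

    def test_inverse_roundtrip(self):
        h = HillParams(e_min=0.0, e_max=0.8, ec50=30.0, slope=2.0)
        for y in (0.1, 0.4, 0.7):
            assert h(h.inverse(y)) == pytest.approx(y, abs=1e-9)


class TestExpectedResponse:
    def setup_method(self):
        self.ha = HillParams(e_min=0.0, e_max=1.0, ec50=100.0, slope=1.0)
        self.hb = HillParams(e_min=0.0, e_max=1.0, ec50=100.0, slope=1.0)

    def test_bliss_independence(self):
        # y_a = y_b = 0.5 at ec50 -> expected 0.75
        assert expected_response("bliss", 100.0, 100.0, self.ha, self.hb) == pytest.approx(0.75)

    def test_hsa_is_max(self):
        hb = HillParams(e_min=0.0, e_max=0.6, ec50=100.0, slope=1.0)
        # y_a(100)=0.5, y_b(100)=0.3 -> HSA expected 0.5
        assert expected_response("hsa", 100.0, 100.0, self.ha, hb) == pytest.approx(0.5)

    def test_loewe_sham_identity(self):
        # drug combined with itself: expected(x, x) = y(2x)
        for x in (10.0, 100.0, 1000.0):
            exp = expected_response("loewe", x, x, self.ha, self.ha)
            assert exp == pytest.approx(self.ha(2 * x), abs=1e-6)

    def test_loewe_single_agent_edges(self):
        assert expected_response("loewe", 0.0, 100.0, self.ha, self.hb) == pytest.approx(0.5)
        assert expected_response("loewe", 100.0, 0.0, self.ha, self.hb) == pytest.approx(0.5)


class TestSynergyScore:
    def test_bliss_null_is_zero(self):
        surf = simulate_surface(SurfaceSpec(interaction="bliss_independent"))
        assert synergy_score(surf, "bliss").score == pytest.approx(0.0, abs=1e-9)

    def test_bliss_shift_recovered(self):
        spec = SurfaceSpec(
            hill_a=HillParams(0.0, 0.6, 100.0, 1.0),
            hill_b=HillParams(0.0, 0.6, 300.0, 1.2),
            interaction="bliss_independent",
            shift_delta=0.10,
        )
        assert synergy_score(simulate_surface(spec), "bliss").score == pytest.approx(10.0, abs=1e-9)

    def test_hsa_null_is_zero_and_bliss_nonpositive(self):
        surf = simulate_surface(SurfaceSpec(interaction="hsa_max"))
        assert synergy_score(surf, "hsa").score == pytest.approx(0.0, abs=1e-9)
        # max(y_a, y_b) <= y_a + y_b - y_a*y_b, so the Bliss excess of an
        # HSA-null surface is <= 0 cell-wise
        assert synergy_score(surf, "bliss").score <= 0.0

    @pytest.mark.parametrize("slope", [0.5, 1.0, 2.0, 3.0])
    def test_loewe_sham_zero(self, slope):
        spec = SurfaceSpec(
            hill_a=HillParams(0.0, 1.0, 100.0, slope), interaction="sham_self"
        )
        res = synergy_score(simulate_surface(spec), "loewe")
        assert np.abs(res.excess).max() <= 1e-3

    def test_zip_null_is_zero(self):
        surf = simulate_surface(SurfaceSpec(interaction="bliss_independent"))
        assert abs(synergy_score(surf, "zip").score) <= 0.1

    def test_bliss_expected_dominates_hsa_cellwise(self):
        surf = simulate_surface(SurfaceSpec(interaction="bliss_independent"))
        hsa = synergy_score(surf, "hsa").expected
        bliss = synergy_score(surf, "bliss").expected
        assert np.all(bliss >= hsa - 1e-12)

    @pytest.mark.parametrize("model", ["hsa", "bliss", "loewe"])
    def test_swap_invariance(self, model):
        spec = SurfaceSpec(
            hill_a=HillParams(0.0, 0.9, 50.0, 1.3),
            hill_b=HillParams(0.0, 0.7, 400.0, 0.8),
            interaction="bliss_independent",
            shift_delta=0.05,
        )
        surf = simulate_surface(spec)
        swapped = DoseResponseSurface(
            drug_a=surf.drug_b,
            drug_b=surf.drug_a,
            doses_a=surf.doses_b,
            doses_b=surf.doses_a,
            mono_a=surf.mono_b,
            mono_b=surf.mono_a,
            combo=surf.combo.T,
        )
        s1 = synergy_score(surf, model)
        s2 = synergy_score(swapped, model)
        assert s1.score == pytest.approx(s2.score, abs=1e-6)
        assert np.allclose(s1.excess, s2.excess.T, atol=1e-6)


class TestCombinationRatio:
    def _surface(self, mono_a, mono_b, combo):
        return DoseResponseSurface(
            drug_a="a",
            drug_b="b",
            doses_a=DOSES,
            doses_b=DOSES,
            mono_a=np.asarray(mono_a),
            mono_b=np.asarray(mono_b),
            combo=np.asarray(combo),
        )

    def test_direct_ratio(self):
        surf = self._surface(
            np.full(5, 0.5), np.full(5, 0.4), np.full((5, 5), 0.8)
        )
        cr, mean, n_undef = combination_ratio(surf)
        assert np.allclose(cr, 1.6) and mean == pytest.approx(1.6) and n_undef == 0

    def test_combo_equals_best_single(self):
        surf = self._surface(np.full(5, 0.5), np.full(5, 0.3), np.full((5, 5), 0.5))
        _, mean, _ = combination_ratio(surf)
        assert mean == pytest.approx(1.0)

    def test_combo_below_both_singles(self):
        surf = self._surface(np.full(5, 0.5), np.full(5, 0.4), np.full((5, 5), 0.2))
        _, mean, _ = combination_ratio(surf)
        assert mean < 1.0

    def test_zero_singles_undefined(self):
        mono = np.zeros(5)
        surf = self._surface(mono, np.full(5, 0.4), np.full((5, 5), 0.4))
        cr, _, n_undef = combination_ratio(surf)
        assert n_undef == 0  # max single is 0.4 everywhere
        surf2 = self._surface(mono, mono, np.full((5, 5), 0.1))
        with pytest.raises(ValueError):
            combination_ratio(surf2)


class TestDSS:
    def test_inactive_drug_scores_zero(self):
        assert dss(DOSES, np.full(5, 0.05)) == 0.0

    def test_fully_active_scores_hundred(self):
        assert dss(DOSES, np.ones(5)) == pytest.approx(100.0)

    def test_step_response_matches_trapezoid_oracle(self):
        resp = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        ex = np.maximum(resp - 0.1, 0.0)
        lg = np.log10(DOSES)
        oracle = 100 * np.trapezoid(ex, lg) / (0.9 * (lg[-1] - lg[0]))
        assert dss(DOSES, resp) == pytest.approx(oracle)

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            dss([10.0], [0.5])


class TestRoundTrip:
    def test_combo_csv_roundtrip(self, tmp_path):
        from combnet.synergy import read_combo_csv, write_combo_csv

        surf = simulate_surface(SurfaceSpec(shift_delta=0.05, replicate_noise_sd=0.01))
        path = tmp_path / "combo.csv"
        write_combo_csv([surf], path)
        (back,) = read_combo_csv(path)
        assert np.allclose(back.combo, surf.combo)
        assert np.allclose(back.mono_a, surf.mono_a)
        assert np.allclose(back.doses_b, surf.doses_b)
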