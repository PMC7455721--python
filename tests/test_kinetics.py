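import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deadstab import kinetics, synthio
from deadstab.io import ConfigError, FormatError


def _ct(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "ct_target", "ct_ref"])


class TestDdct:
    def test_worked_two_cycle_example(self):
        # treated dCT 2 vs control dCT 4 -> ddCT -2 -> fold 4
        table = _ct(
            [
                ["c1", "control", 24.0, 20.0],
                ["c2", "control", 24.0, 20.0],
                ["t1", "treated", 22.0, 20.0],
            ]
        )
        out = kinetics.ddct(table, "control")
        assert out.loc[2, "rel_expr"] == pytest.approx(4.0)

    def test_calibrator_mean_expression_one(self):
        table = _ct(
            [
                ["c1", "control", 25.0, 20.0],
                ["c2", "control", 25.0, 20.0],
                ["t1", "treated", 23.5, 20.0],
            ]
        )
        out = kinetics.ddct(table, "control")
        assert out.loc[out.group == "control", "rel_expr"].mean() == pytest.approx(1.0)

    @given(st.floats(min_value=-5, max_value=5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_instrument_offset_invariance(self, shift):
        base = _ct(
            [
                ["c1", "control", 24.0, 20.0],
                ["t1", "treated", 22.0, 19.0],
            ]
        )
        shifted = base.copy()
        shifted[["ct_target", "ct_ref"]] += shift
        a = kinetics.ddct(base, "control")["rel_expr"]
        b = kinetics.ddct(shifted, "control")["rel_expr"]
        assert np.allclose(a, b)

    def test_missing_reference_rejected(self):
        table = _ct([["c1", "control", 24.0, np.nan]])
        with pytest.raises(FormatError):
            kinetics.ddct(table, "control")


class TestNormalizeDecay:
    def test_series_to_percent(self):
        raw = pd.DataFrame(
            {"replicate": ["r1"] * 3, "time_hr": [0.0, 4.0, 8.0], "value": [0.8, 0.4, 0.2]}
        )
        out = kinetics.normalize_decay(raw)
        assert list(out.relative_abundance) == [100.0, 50.0, 25.0]

    def test_constant_series_all_hundred(self):
        raw = pd.DataFrame(
            {"replicate": ["r1"] * 3, "time_hr": [0.0, 4.0, 8.0], "value": [0.3] * 3}
        )
        assert (kinetics.normalize_decay(raw).relative_abundance == 100.0).all()

    def test_gain_invariance_across_replicates(self):
        raw = pd.DataFrame(
            {
                "replicate": ["r1"] * 3 + ["r2"] * 3,
                "time_hr": [0.0, 4.0, 8.0] * 2,
                "value": [0.8, 0.4, 0.2, 8.0, 4.0, 2.0],
            }
        )
        out = kinetics.normalize_decay(raw)
        r1 = out[out.replicate == "r1"].relative_abundance.to_numpy()
        r2 = out[out.replicate == "r2"].relative_abundance.to_numpy()
        assert np.allclose(r1, r2)

    def test_nonpositive_t0_rejected(self):
        raw = pd.DataFrame(
            {"replicate": ["r1"] * 2, "time_hr": [0.0, 4.0], "value": [0.0, 0.1]}
        )
        with pytest.raises(FormatError):
            kinetics.normalize_decay(raw)


class TestHalfLife:
    def test_closed_form_exact(self):
        course = pd.DataFrame(
            {"replicate": ["r1"] * 3, "time_hr": [0.0, 4.0, 8.0],
             "relative_abundance": [100.0, 50.0, 25.0]}
        )
        fit = kinetics.fit_half_life(course)
        assert fit.t_half_hr == pytest.approx(4.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.k_per_hr * fit.t_half_hr == pytest.approx(np.log(2.0))

    @given(st.floats(min_value=0.5, max_value=50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_exact_on_noiseless_exponential(self, t_half):
        t = np.array([0.0, 4.0, 8.0])
        course = pd.DataFrame(
            {"replicate": ["r1"] * 3, "time_hr": t,
             "relative_abundance": 100.0 * 2.0 ** (-t / t_half)}
        )
        fit = kinetics.fit_half_life(course)
        assert fit.t_half_hr == pytest.approx(t_half, rel=1e-9)

    def test_flat_series_flagged_stable(self):
        course = pd.DataFrame(
            {"replicate": ["r1"] * 3, "time_hr": [0.0, 4.0, 8.0],
             "relative_abundance": [100.0, 100.0, 100.0]}
        )
        fit = kinetics.fit_half_life(course)
        assert fit.stable and np.isinf(fit.t_half_hr)

    def test_ci_coverage_nominal(self):
        cover = 0
        n_sim = 200
        for s in range(n_sim):
            c = synthio.simulate_decay(4.0, cv=0.05, n_reps=3, seed=s)
            fit = kinetics.fit_half_life(kinetics.normalize_decay(c))
            cover += fit.ci_lower_hr <= 4.0 <= fit.ci_upper_hr
        assert 0.90 <= cover / n_sim <= 0.99


class TestCompareDecay:
    @staticmethod
    def _arms(t_ctrl, t_ko, seed, cv=0.05):
        c = synthio.simulate_decay({"control": t_ctrl, "ko": t_ko}, cv=cv, n_reps=3, seed=seed)
        cn = kinetics.normalize_decay(c)
        return cn[cn.genotype == "control"], cn[cn.genotype == "ko"]

    def test_identical_courses_p_one(self):
        ctrl, _ = self._arms(4.0, 4.0, seed=40)
        res = kinetics.compare_decay(ctrl, ctrl)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["direction"] == "none"

    def test_power_on_fourfold_half_life_change(self):
        hits = 0
        for s in range(50):
            ctrl, ko = self._arms(2.0, 8.0, seed=1000 + s)
            res = kinetics.compare_decay(ctrl, ko)
            hits += res["p_value"] < 0.05 and res["direction"] == "stabilized"
        assert hits / 50 >= 0.9

    def test_label_swap_flips_direction_keeps_p(self):
        ctrl, ko = self._arms(2.0, 8.0, seed=41)
        a = kinetics.compare_decay(ctrl, ko)
        b = kinetics.compare_decay(ko, ctrl)
        assert a["p_value"] == pytest.approx(b["p_value"])
        assert {a["direction"], b["direction"]} == {"stabilized", "destabilized"}

    def test_type_one_error_near_alpha(self):
        fp = 0
        n_sim = 300
        for s in range(n_sim):
            ctrl, ko = self._arms(4.0, 4.0, seed=5000 + s)
            fp += kinetics.compare_decay(ctrl, ko)["p_value"] < 0.05
        assert 0.01 <= fp / n_sim <= 0.10

    def test_single_replicate_rejected(self):
        c = synthio.simulate_decay({"control": 4.0, "ko": 4.0}, n_reps=1, seed=0)
        cn = kinetics.normalize_decay(c)
        with pytest.raises(ConfigError):
            kinetics.compare_decay(cn[cn.genotype == "control"], cn[cn.genotype == "ko"])


class TestRip:
    def test_equality_gives_hundred_percent(self):
        res = kinetics.rip_enrichment(20.0, 25.0, 20.0 - np.log2(10), 0.1)
        assert res["percent_input_ab"] == pytest.approx(100.0)

    def test_one_cycle_earlier_doubles_fold(self):
        res = kinetics.rip_enrichment(20.0, 26.0, 25.0, 0.1)
        assert res["fold_over_igg"] == pytest.approx(2.0)

    def test_dilution_adjustment(self):
        res = kinetics.rip_enrichment(20.0, 26.0, 25.0, 0.1)
        assert res["input_ct_adjusted"] == pytest.approx(20.0 - np.log2(10.0))

    @given(st.floats(min_value=-4, max_value=4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_instrument_offset_invariance(self, shift):
        a = kinetics.rip_enrichment(20.0, 26.0, 24.0, 0.05)
        b = kinetics.rip_enrichment(20.0 + shift, 26.0 + shift, 24.0 + shift, 0.05)
        assert a["fold_over_igg"] == pytest.approx(b["fold_over_igg"])
        assert a["percent_input_ab"] == pytest.approx(b["percent_input_ab"])

    def test_bad_input_fraction(self):
        with pytest.raises(ConfigError):
            kinetics.rip_enrichment(20.0, 26.0, 24.0, 0.0)


class TestBetaCellMass:
    def test_formula(self):
        assert kinetics.beta_cell_mass(10.0, 100.0, 200.0) == pytest.approx(20.0)

    def test_edge_cases(self):
        assert kinetics.beta_cell_mass(0.0, 100.0, 200.0) == 0.0
        assert kinetics.beta_cell_mass(100.0, 100.0, 200.0) == 200.0

    def test_validation(self):
        with pytest.raises(ConfigError):
            kinetics.beta_cell_mass(10.0, 0.0, 200.0)
        with pytest.raises(ConfigError):
            kinetics.beta_cell_mass(110.0, 100.0, 200.0)
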