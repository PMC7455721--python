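import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from deadstab import de, synthio
from deadstab.de import EmptyResultError
from deadstab.io import ConfigError, CountMatrix


def _cm(counts, groups, feature="exon"):
    return CountMatrix(pd.DataFrame(counts), pd.Series(groups), feature)


class TestFilter:
    def test_cpm_rule_arithmetic(self, two_group_series):
        # libraries of 10,000 reads, so CPM = count x 100; gene 'a' reaches
        # CPM >= 1000 in exactly three samples, gene 'b' never does
        counts = pd.DataFrame(
            [[12, 1, 2, 15, 11, 3], [5, 5, 5, 5, 5, 5]],
            index=["a", "b"],
            columns=two_group_series.index,
        )
        filler = (10_000 - counts.sum(axis=0)).rename("filler")
        full = pd.concat([counts, filler.to_frame().T])
        cm = _cm(full, two_group_series)
        kept = de.filter_expressed(cm, cpm_min=1000.0, min_samples=3)
        assert "a" in kept.gene_ids and "b" not in kept.gene_ids

    def test_zero_threshold_is_identity(self, small_counts):
        kept = de.filter_expressed(small_counts, cpm_min=0.0, min_samples=1)
        assert list(kept.gene_ids) == list(small_counts.gene_ids)

    def test_all_removed_raises(self, small_counts):
        with pytest.raises(EmptyResultError):
            de.filter_expressed(small_counts, cpm_min=1e9)


class TestTmm:
    def test_identical_columns_give_unit_factors(self, two_group_series):
        col = np.random.default_rng(0).poisson(100, 50)
        counts = pd.DataFrame({s: col for s in two_group_series.index})
        fac = de.tmm_factors(_cm(counts, two_group_series))
        assert np.allclose(fac, 1.0)

    def test_pure_depth_difference_equalized(self, two_group_series):
        rng = np.random.default_rng(1)
        base = rng.poisson(500, 200)
        counts = pd.DataFrame({s: base for s in two_group_series.index})
        counts["ko_1"] = base * 2  # doubled depth, no composition change
        cm = _cm(counts, two_group_series)
        fac = de.tmm_factors(cm)
        # no composition change, so factors stay 1 and scaling by the
        # effective library size equalizes the normalized counts
        assert np.allclose(fac, 1.0, atol=1e-9)
        norm = counts / (cm.lib_sizes * fac)
        spread = norm.max(axis=1) - norm.min(axis=1)
        assert np.allclose(spread, 0.0, atol=1e-12)

    def test_brute_force_trimmed_mean_toy(self):
        # 20-gene toy, two samples: independent weighted-trim computation
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {"s1": rng.poisson(100, 20) + 1, "s2": rng.poisson(150, 20) + 1}
        )
        groups = pd.Series({"s1": "control", "s2": "knockout"})
        fac = de.tmm_factors(_cm(counts, groups), ref="s1")
        x1, x2 = counts["s1"].to_numpy(float), counts["s2"].to_numpy(float)
        n1, n2 = x1.sum(), x2.sum()
        m = np.log2((x2 / n2) / (x1 / n1))
        a = 0.5 * np.log2((x2 / n2) * (x1 / n1))
        w = (n2 - x2) / (n2 * x2) + (n1 - x1) / (n1 * x1)
        lo_m, hi_m = np.quantile(m, [0.3, 0.7])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        f2 = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        expected = pd.Series({"s1": 1.0, "s2": f2})
        expected /= np.exp(np.log(expected).mean())
        assert fac["s2"] / fac["s1"] == pytest.approx(
            expected["s2"] / expected["s1"], rel=1e-9
        )

    def test_factors_geometric_mean_one(self, small_counts):
        fac = de.tmm_factors(small_counts)
        assert np.exp(np.log(fac).mean()) == pytest.approx(1.0, rel=1e-12)

    def test_zero_total_sample_rejected(self, two_group_series):
        counts = pd.DataFrame(
            np.ones((5, 6), int), index=list("abcde"), columns=two_group_series.index
        )
        counts["ko_3"] = 0
        with pytest.raises(ConfigError):
            de.tmm_factors(_cm(counts, two_group_series))


class TestDispersion:
    def test_poisson_counts_give_near_zero(self):
        cfg = {"frac_stabilized": 0.0, "frac_transcription": 0.0, "phi": 0.0}
        exon, _, _ = synthio.simulate_exon_intron_counts(2000, 3, cfg, seed=10)
        phi = de.estimate_dispersion(exon)
        assert np.median(phi) < 0.01

    def test_recovers_known_dispersion(self):
        cfg = {"frac_stabilized": 0.0, "frac_transcription": 0.0, "phi": 0.1}
        exon, _, _ = synthio.simulate_exon_intron_counts(2000, 3, cfg, seed=11)
        phi = de.estimate_dispersion(exon)
        assert 0.05 <= np.median(phi) <= 0.2

    def test_constant_gene_floored_at_zero(self, two_group_series):
        counts = pd.DataFrame(
            {s: [100, 200] for s in two_group_series.index}, index=["a", "b"]
        )
        phi = de.estimate_dispersion(_cm(counts, two_group_series))
        assert (phi == 0).all()

    def test_requires_replication(self):
        groups = pd.Series({"s1": "control", "s2": "knockout"})
        counts = pd.DataFrame({"s1": [10], "s2": [20]}, index=["a"])
        with pytest.raises(ConfigError):
            de.estimate_dispersion(_cm(counts, groups))


class TestExactTest:
    def test_identical_groups_p_one(self, two_group_series):
        counts = pd.DataFrame(
            {s: [100, 200] for s in two_group_series.index}, index=["a", "b"]
        )
        res = de.nb_test(_cm(counts, two_group_series), 0.1)
        assert (res.PValue == 1.0).all()

    def test_poisson_limit_matches_enumeration_oracle(self):
        # 2v2 toy at phi=0 embedded in equal-depth libraries; the oracle sums
        # the conditional binomial pmf over every split of the total
        groups = pd.Series(
            {"c1": "control", "c2": "control", "k1": "knockout", "k2": "knockout"}
        )
        counts = pd.DataFrame(
            {"c1": [100, 900], "c2": [110, 890], "k1": [400, 600], "k2": [380, 620]},
            index=["g1", "filler"],
        )
        res = de.nb_test(_cm(counts, groups), 0.0)
        p_impl = float(res.loc[res.gene_id == "g1", "PValue"].iloc[0])
        S, obs = 990, 210
        pmf = binom.pmf(np.arange(S + 1), S, 0.5)
        p_oracle = min(1.0, 2.0 * min(pmf[: obs + 1].sum(), pmf[obs:].sum()))
        assert p_impl == pytest.approx(p_oracle, abs=1e-10, rel=1e-9)

    def test_null_type_one_error(self):
        cfg = {"frac_stabilized": 0.0, "frac_transcription": 0.0, "phi": 0.1}
        exon, _, _ = synthio.simulate_exon_intron_counts(4000, 3, cfg, seed=12)
        res = de.de_pipeline(exon)
        assert (res.PValue < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_scale_invariance_post_tmm(self, two_group_series):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(300, size=(100, 6)),
            index=[f"g{i}" for i in range(100)],
            columns=two_group_series.index,
        )
        cm1 = _cm(counts, two_group_series)
        scaled = counts.copy()
        scaled["ko_2"] = scaled["ko_2"] * 4
        cm2 = _cm(scaled, two_group_series)
        r1 = de.nb_test(cm1, 0.05, factors=de.tmm_factors(cm1))
        r2 = de.nb_test(cm2, 0.05, factors=de.tmm_factors(cm2))
        # equal up to integer rounding of the equalized pseudo-counts
        assert np.abs(r1.PValue - r2.PValue).max() < 0.02

    def test_dispersion_length_mismatch(self, small_counts):
        with pytest.raises(ConfigError):
            de.nb_test(small_counts, pd.Series([0.1] * 5))


class TestBhFdr:
    def test_hand_step_up(self):
        assert np.allclose(de.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert de.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (de.bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.1, np.nan])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw(self, ps):
        adj = de.bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
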