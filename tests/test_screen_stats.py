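"""Normalization, QC filtering, empirical-Bayes z-scores and calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bescan.screen_stats import (
    CountMatrix,
    QCRules,
    aggregate_elements,
    benchmark_thresholds,
    classify_variants,
    eb_zscore,
    normalize_and_l2fc,
    normalize_rpm,
    qc_filter,
)
from oracles import oracle_bh


def toy_matrix(counts_dict, assays):
    counts = pd.DataFrame(counts_dict)
    counts.index = [f"g{i}" for i in range(len(counts))]
    samples = pd.DataFrame(
        {"assay": [a for a, _ in assays], "replicate": [r for _, r in assays]},
        index=list(counts_dict),
    )
    return CountMatrix(counts, samples)


class TestQC:
    def test_zero_in_control_removed(self):
        m = toy_matrix(
            {"control_R1": [10, 0, 5, 8, 9, 7], "IFNg_R1": [5] * 6},
            [("control", "R1"), ("IFNg", "R1")],
        )
        filtered, log = qc_filter(m, QCRules(min_reads_any_sample=None))
        assert len(filtered.counts) == 5
        assert "g1" not in filtered.counts.index
        assert log.set_index("guide_id").loc["g1", "rule"] == "zero_reads_in_reference_sample"

    def test_plasmid_over_representation_removed(self):
        m = toy_matrix(
            {"plasmid_R1": [500, 50_001, 400], "control_R1": [500, 600, 700]},
            [("plasmid", "R1"), ("control", "R1")],
        )
        filtered, log = qc_filter(m, QCRules(min_reads_any_sample=None))
        assert list(filtered.counts.index) == ["g0", "g2"]
        assert "over_represented" in log.iloc[0]["rule"]

    def test_low_count_guide_removed(self):
        m = toy_matrix(
            {"control_R1": [500, 99, 400], "IFNg_R2": [500, 600, 700]},
            [("control", "R1"), ("IFNg", "R2")],
        )
        filtered, log = qc_filter(m, QCRules())
        assert "g1" not in filtered.counts.index
        assert "below_min_reads_100" in set(log["rule"])

    def test_control_fold_difference_rule_optional(self):
        m = toy_matrix(
            {"control_R1": [500, 1000, 400], "control_R2": [510, 240, 390]},
            [("control", "R1"), ("control", "R2")],
        )
        filtered, _ = qc_filter(
            m, QCRules(min_reads_any_sample=None, max_control_fold_diff=3.0)
        )
        assert "g1" not in filtered.counts.index
        kept, _ = qc_filter(m, QCRules(min_reads_any_sample=None))
        assert "g1" in kept.counts.index

    def test_all_removed_is_fatal(self):
        m = toy_matrix({"control_R1": [0, 0]}, [("control", "R1")])
        with pytest.raises(ValueError, match="every guide"):
            qc_filter(m, QCRules())


class TestNormalization:
    def test_printed_formula(self):
        counts = pd.DataFrame({"s": [500, 999_500]})
        norm = normalize_rpm(counts)
        assert norm.loc[0, "s"] == pytest.approx(501.0)

    def test_sum_identity_per_sample(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 5000, size=(300, 3)), columns=list("abc"))
        norm = normalize_rpm(counts)
        for c in "abc":
            assert (norm[c] - 1).sum() == pytest.approx(1e6, rel=1e-9)

    def test_identical_columns_give_zero_l2fc(self):
        m = toy_matrix(
            {"control_R1": [5, 50, 500], "IFNg_R1": [5, 50, 500]},
            [("control", "R1"), ("IFNg", "R1")],
        )
        res = normalize_and_l2fc(m, "IFNg_R1", "control_R1")
        assert np.allclose(res["l2fc"], 0.0)

    def test_doubling_norm_rpm_adds_one_l2fc(self):
        m = toy_matrix(
            {"control_R1": [1000, 1000], "IFNg_R1": [2001, 999]},
            [("control", "R1"), ("IFNg", "R1")],
        )
        res = normalize_and_l2fc(m, "IFNg_R1", "control_R1")
        # guide 0 treated norm_rpm is exactly twice its reference norm_rpm
        ratio = res.loc["g0", "norm_rpm_treated"] / res.loc["g0", "norm_rpm_reference"]
        assert res.loc["g0", "l2fc"] == pytest.approx(np.log2(ratio))

    def test_zero_total_is_fatal(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_rpm(pd.DataFrame({"s": [0, 0]}))


class TestEBZ:
    @staticmethod
    def homoscedastic(n=2000, sd=0.4, seed=4):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"g{i}" for i in range(n)])
        l2fc = pd.Series(rng.normal(0, sd, n), index=idx)
        abundance = pd.Series(rng.uniform(400, 600, n), index=idx)
        controls = list(idx[:100])
        return l2fc, abundance, controls

    def test_control_guides_center_to_zero(self):
        l2fc, ab, controls = self.homoscedastic()
        z = eb_zscore(l2fc, controls, ab)
        centered = l2fc - l2fc.loc[controls].mean()
        assert abs(centered.loc[controls].mean()) < 1e-12
        # z of a guide sitting exactly at the control mean is zero
        l2fc2 = l2fc.copy()
        l2fc2.iloc[500] = l2fc.loc[controls].mean()
        z2 = eb_zscore(l2fc2, controls, ab)
        assert z2.iloc[500] == pytest.approx(0.0, abs=1e-12)

    def test_homoscedastic_sd_recovery_within_5pct(self):
        l2fc, ab, controls = self.homoscedastic()
        z = eb_zscore(l2fc, controls, ab)
        centered = l2fc - l2fc.loc[controls].mean()
        implied_sd = (centered / z).dropna()
        pooled = centered.std(ddof=1)
        assert np.all(np.abs(implied_sd / pooled - 1) < 0.05)

    def test_shift_invariance(self):
        l2fc, ab, controls = self.homoscedastic()
        z1 = eb_zscore(l2fc, controls, ab)
        z2 = eb_zscore(l2fc + 3.7, controls, ab)
        assert np.allclose(z1, z2, atol=1e-9)

    def test_sd_monotone_in_abundance(self):
        rng = np.random.default_rng(8)
        n = 1000
        idx = pd.Index([f"g{i}" for i in range(n)])
        ab = pd.Series(np.linspace(2000, 50, n), index=idx)
        # noisier at low abundance
        l2fc = pd.Series(rng.normal(0, 0.2 + 0.4 * (ab.max() - ab) / ab.max()), index=idx)
        z = eb_zscore(l2fc, list(idx[::10]), ab, window=200)
        implied_sd = ((l2fc - l2fc.loc[idx[::10]].mean()) / z).loc[idx]
        diffs = np.diff(implied_sd.to_numpy())
        assert (diffs >= -1e-9).all()  # sd never shrinks as abundance falls

    def test_too_few_controls_is_fatal(self):
        l2fc, ab, _ = self.homoscedastic(n=100)
        with pytest.raises(ValueError, match="20"):
            eb_zscore(l2fc, ["g0", "g1"], ab)


class TestAggregate:
    def test_four_unit_z_guides_give_normz_two(self):
        z = pd.Series(1.0, index=[f"g{i}" for i in range(4)])
        el = pd.Series("E", index=z.index)
        res = aggregate_elements(z, el)
        assert res.loc["E", "normZ"] == pytest.approx(2.0)
        assert res.loc["E", "n_guides"] == 4

    def test_single_guide_element_keeps_z(self):
        z = pd.Series([1.7], index=["g0"])
        res = aggregate_elements(z, pd.Series("E", index=z.index))
        assert res.loc["E", "normZ"] == pytest.approx(1.7)

    def test_bh_matches_direct_computation(self):
        rng = np.random.default_rng(12)
        z = pd.Series(rng.normal(0, 2, 10), index=[f"g{i}" for i in range(10)])
        el = pd.Series([f"E{i}" for i in range(10)], index=z.index)
        res = aggregate_elements(z, el)
        expected = oracle_bh(list(res["p"]))
        assert np.allclose(res["fdr"], expected)

    def test_empty_mapping_gives_empty_result(self):
        res = aggregate_elements(pd.Series(dtype=float), pd.Series(dtype=object))
        assert len(res) == 0


class TestClassify:
    @staticmethod
    def frame(zs):
        elements = list(zs)
        normZ = pd.Series(zs)
        p = 2 * stats.norm.sf(np.abs(normZ))
        from statsmodels.stats.multitest import multipletests
        return pd.DataFrame(
            {"n_guides": 4, "normZ": normZ, "p": p,
             "fdr": multipletests(p, method="fdr_bh")[1]},
            index=elements,
        )

    def test_benchmarked_lof_sof_gof(self):
        prolif = self.frame({"A": 6.0, "B": 5.0, "C": -4.0, "D": 0.3,
                             "bmL": 5.5, "bmG": -3.5})
        facs = self.frame({"A": 5.0, "B": 0.0, "C": -0.2, "D": 0.1,
                           "bmL": 5.0, "bmG": 0.0})
        calls = classify_variants(
            prolif, facs, benchmark_lof=["bmL"], benchmark_gof=["bmG"]
        )["call"]
        assert calls["A"] == "LOF"      # enriched in both assays
        assert calls["B"] == "SOF"      # proliferation only
        assert calls["C"] == "GOF"      # depleted; FACS cannot support
        assert calls["D"] == "neutral"

    def test_thresholds_from_benchmark_quantiles(self):
        prolif = self.frame({"bm1": 4.0, "bm2": 6.0, "g1": -5.0, "x": 0.0})
        thr = benchmark_thresholds(prolif, None, ["bm1", "bm2"], ["g1"], quantile=0.05)
        assert thr.lof_z == pytest.approx(np.quantile([4.0, 6.0], 0.05))
        assert thr.gof_z == pytest.approx(5.0)

    def test_single_assay_degradation(self):
        prolif = self.frame({"A": 6.0, "C": -6.0, "D": 0.2})
        calls = classify_variants(prolif, facs=None)["call"]
        assert calls["A"] == "LOF" and calls["C"] == "GOF" and calls["D"] == "neutral"

    def test_non_significant_never_called(self):
        prolif = self.frame({"A": 1.0, "B": -1.0, "C": 0.0})
        assert set(classify_variants(prolif)["call"]) == {"neutral"}
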