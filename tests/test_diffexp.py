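"""Differential origin analysis: normalization, NB test, BH, classes."""

import numpy as np
import pandas as pd
import pytest

from g4ori import (
    CLASS_LABELS,
    ValidationError,
    bh_adjust,
    class_summary,
    class_summary_from_percentages,
    classify_origins,
    nb_differential,
    normalize_counts,
)

CONDITIONS = {
    "c1": "control", "c2": "control", "c3": "control",
    "t1": "treated", "t2": "treated",
}
SAMPLES = list(CONDITIONS)


def nb_counts(rng, n, mean, alpha, n_samples=5):
    r = 1 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=(n, n_samples))


def median_of_ratios_oracle(m):
    """Hand-rolled reference: per-sample median of count/geomean ratios."""
    keep = (m > 0).all(axis=1)
    geo = np.prod(m[keep].astype(float), axis=1) ** (1 / m.shape[1])
    return np.array(
        [np.median(m[keep, j] / geo) for j in range(m.shape[1])]
    )


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf, _ = normalize_counts(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_ratio_two(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf, norm = normalize_counts(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.allclose(norm["a"] * sf["a"], counts["a"])

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matrix_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = nb_counts(rng, 500, 100, 0.1)
        sf, _ = normalize_counts(pd.DataFrame(m, columns=SAMPLES))
        assert np.allclose(sf.to_numpy(), median_of_ratios_oracle(m))

    def test_no_all_positive_origin_falls_back_with_warning(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            sf, _ = normalize_counts(counts)
        assert np.allclose(sf, 1.0)  # equal totals

    def test_size_factors_match_pydeseq2(self):
        """Independent cross-check against the DESeq2 reimplementation."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(7)
        m = nb_counts(rng, 300, 150, 0.08)
        counts = pd.DataFrame(m, columns=SAMPLES,
                              index=[f"o{i}" for i in range(300)])
        sf, _ = normalize_counts(counts)
        meta = pd.DataFrame(
            {"condition": [CONDITIONS[s] for s in SAMPLES]}, index=SAMPLES
        )
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        ref = np.asarray(dds.obs["size_factors"], dtype=float)
        assert np.allclose(sf.to_numpy(), ref, rtol=1e-6)


class TestNBDifferential:
    def test_identical_conditions_null_result(self):
        counts = pd.DataFrame(
            {s: [100, 50, 200] for s in SAMPLES},
            index=["o1", "o2", "o3"],
        )
        res = nb_differential(counts, CONDITIONS)
        assert np.allclose(res["log2FC"], 0)
        assert np.allclose(res["pvalue"], 1)

    def test_all_zero_origin(self):
        counts = pd.DataFrame(
            {s: [0, 100] for s in SAMPLES}, index=["dead", "alive"]
        )
        res = nb_differential(counts, CONDITIONS)
        assert res.loc["dead", "pvalue"] == 1.0
        assert res.loc["dead", "log2FC"] == 0.0

    def test_sample_order_within_condition_irrelevant(self):
        rng = np.random.default_rng(3)
        m = nb_counts(rng, 200, 100, 0.05)
        counts = pd.DataFrame(m, columns=SAMPLES)
        swapped = counts[["c2", "c1", "c3", "t2", "t1"]]
        a = nb_differential(counts, CONDITIONS)
        b = nb_differential(swapped, CONDITIONS)
        assert np.allclose(a["pvalue"], b["pvalue"])

    def test_planted_fourfold_change_detected_with_high_power(self):
        """A 4-fold planted change at mean 100 (3 vs 2 replicates) is
        recovered for >90% of origins at FDR 0.01."""
        rng = np.random.default_rng(44)
        r = 1 / 0.05
        planted = np.hstack(
            [
                rng.negative_binomial(r, r / (r + 100), size=(2000, 3)),
                rng.negative_binomial(r, r / (r + 400), size=(2000, 2)),
            ]
        )
        nulls = rng.negative_binomial(r, r / (r + 100), size=(3000, 5))
        counts = pd.DataFrame(
            np.vstack([planted, nulls]),
            index=[f"o{i}" for i in range(5000)],
            columns=SAMPLES,
        )
        res = nb_differential(counts, CONDITIONS)
        power = float((res["FDR"].to_numpy()[:2000] <= 0.01).mean())
        assert power > 0.9

    def test_pure_null_yields_few_non_insensitive_calls(self):
        """Under a pure null at FDR <= 0.01 the non-insensitive fraction
        stays below 2%."""
        rng = np.random.default_rng(45)
        r = 1 / 0.05
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + 100), size=(5000, 5)),
            index=[f"o{i}" for i in range(5000)],
            columns=SAMPLES,
        )
        res = nb_differential(counts, CONDITIONS)
        pres = pd.DataFrame(
            {"present_ctrl": True, "present_trt": True}, index=counts.index
        )
        classes = classify_origins(res, pres)
        assert float((classes != "insensitive").mean()) <= 0.02

    def test_needs_two_samples_per_condition(self):
        counts = pd.DataFrame({"c1": [1], "c2": [2], "t1": [3]})
        with pytest.raises(ValidationError, match="per condition"):
            nb_differential(
                counts, {"c1": "control", "c2": "control", "t1": "treated"}
            )


class TestBH:
    def test_hand_computed_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_adjusted_dominates_raw_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClassify:
    def _diff(self, lfc, fdr):
        return pd.DataFrame(
            {"log2FC": lfc, "FDR": fdr},
            index=[f"o{i}" for i in range(len(lfc))],
        )

    def _presence(self, ctrl, trt, n):
        return pd.DataFrame(
            {"present_ctrl": ctrl, "present_trt": trt},
            index=[f"o{i}" for i in range(n)],
        )

    def test_five_class_rules(self):
        diff = self._diff([2.5, -2.5, 2.0, -2.0, 0.1], [0.001] * 4 + [0.5])
        pres = self._presence(
            [False, True, True, True, True],
            [True, False, True, True, True],
            5,
        )
        got = classify_origins(diff, pres).tolist()
        assert got == ["new", "suppressed", "reinforced", "reduced", "insensitive"]

    def test_high_fdr_insensitive_regardless_of_fc(self):
        diff = self._diff([8.0], [0.5])
        got = classify_origins(diff, self._presence([True], [True], 1))
        assert got.tolist() == ["insensitive"]

    def test_sub_threshold_fc_insensitive(self):
        diff = self._diff([0.5], [1e-10])
        got = classify_origins(diff, self._presence([True], [True], 1))
        assert got.tolist() == ["insensitive"]

    def test_inconsistent_flags_logged_as_insensitive(self, caplog):
        diff = self._diff([3.0], [0.001])  # significant up but absent in treated
        pres = self._presence([True], [False], 1)
        with caplog.at_level("WARNING"):
            got = classify_origins(diff, pres)
        assert got.tolist() == ["insensitive"]
        assert "contradicting" in caplog.text

    def test_labels_partition(self):
        rng = np.random.default_rng(1)
        n = 500
        diff = self._diff(rng.normal(0, 2, n), rng.random(n))
        pres = self._presence(rng.random(n) > 0.1, rng.random(n) > 0.1, n)
        got = classify_origins(diff, pres)
        assert set(got) <= set(CLASS_LABELS)
        assert len(got) == n


class TestClassSummary:
    def test_share_of_affected_from_study_percentages(self):
        summary = class_summary_from_percentages(
            {"insensitive": 77.9, "new": 15.7, "reinforced": 0.6, "reduced": 0.7}
        )
        assert summary.loc["suppressed", "pct_of_all"] == pytest.approx(5.1)
        assert summary.loc["new", "pct_of_affected"] == pytest.approx(
            100 * 15.7 / 22.1, abs=0.05
        )

    def test_counts_and_percentages(self):
        classes = pd.Series(
            ["insensitive"] * 8 + ["new"] * 2, index=[f"o{i}" for i in range(10)]
        )
        s = class_summary(classes)
        assert s["pct_of_all"].sum() == pytest.approx(100)
        assert s.loc["new", "pct_of_affected"] == pytest.approx(100)

    def test_all_insensitive_flagged(self):
        classes = pd.Series(["insensitive"] * 5)
        s = class_summary(classes)
        assert s.attrs["no_affected_flag"]
        assert (s["pct_of_affected"] == 0).all()

    def test_empty_classification_errors(self):
        with pytest.raises(ValidationError):
            class_summary(pd.Series([], dtype=object))
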