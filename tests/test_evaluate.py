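"""Splits, AUC estimators, trends, enrichment: hand oracles and properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from widlo import (
    annotation_enrichment,
    association_scan,
    auc_ci,
    linear_trend,
    preset_masks,
    roc_auc,
    stratified_split,
    subgroup_auc,
)


class TestRocAuc:
    def test_hand_enumerated_four_points(self):
        # pairs: (0.35>0.1)✓ (0.35>0.4)✗ (0.8>0.1)✓ (0.8>0.4)✓ → 3/4
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_string_labels_O_is_positive(self):
        assert roc_auc([0.1, 0.9], ["L", "O"]) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        base = roc_auc(s, y)
        assert roc_auc(np.exp(s), y) == pytest.approx(base, abs=1e-12)
        assert roc_auc(3 * s - 7, y) == pytest.approx(base, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAucCi:
    def _fixture(self, n=200, sep=1.0, seed=0):
        rng = np.random.default_rng(seed)
        s = np.r_[rng.normal(0, 1, n), rng.normal(sep, 1, n)]
        y = np.r_[np.zeros(n), np.ones(n)]
        return s, y

    def test_delong_and_bootstrap_agree(self):
        s, y = self._fixture()
        d = auc_ci(s, y, method="delong")
        b = auc_ci(s, y, method="stratified_bootstrap", seed=1)
        assert abs(d["ci_low"] - b["ci_low"]) < 0.03
        assert abs(d["ci_high"] - b["ci_high"]) < 0.03

    def test_separable_ci_truncates_at_one(self):
        s = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        d = auc_ci(s, y, method="delong")
        assert d["auc"] == 1.0 and d["ci_high"] == 1.0

    def test_bootstrap_deterministic_under_seed(self):
        s, y = self._fixture(n=30)
        a = auc_ci(s, y, method="stratified_bootstrap", seed=5)
        b = auc_ci(s, y, method="stratified_bootstrap", seed=5)
        assert a == b

    def test_delong_ci_shrinks_with_n(self):
        widths = []
        for n in (25, 100, 400):
            s, y = self._fixture(n=n, seed=2)
            d = auc_ci(s, y, method="delong")
            widths.append(d["ci_high"] - d["ci_low"])
        assert widths[0] > widths[1] > widths[2]

    def test_unknown_method(self):
        s, y = self._fixture(n=20)
        with pytest.raises(ValueError, match="unknown"):
            auc_ci(s, y, method="jackknife")


class TestStratifiedSplit:
    def _sheet(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "age": rng.uniform(20, 80, n),
                "IC": rng.uniform(0, 1, n),
                "label": np.where(rng.random(n) < 0.5, "L", "O"),
            },
            index=[f"s{i:04d}" for i in range(n)],
        )

    def test_single_stratum_counts(self):
        sheet = pd.DataFrame(
            {"age": 45.0, "IC": 0.2, "label": "L"},
            index=[f"s{i}" for i in range(300)],
        )
        out = stratified_split(sheet, age_bins=np.array([0, 100]),
                              ic_bins=np.array([0, 1]), seed=1)
        assert (out == "training").sum() == 200
        assert (out == "validation").sum() == 100

    def test_two_sample_stratum_splits_one_one(self):
        sheet = pd.DataFrame({"age": 45.0, "IC": 0.2, "label": "L"},
                             index=["a", "b"])
        out = stratified_split(sheet, age_bins=np.array([0, 100]),
                              ic_bins=np.array([0, 1]), seed=1)
        assert sorted(out) == ["training", "validation"]

    def test_deterministic(self):
        sheet = self._sheet(200)
        a = stratified_split(sheet, seed=3)
        b = stratified_split(sheet, seed=3)
        assert a.equals(b)

    def test_label_prevalence_preserved_per_stratum(self):
        sheet = self._sheet(600, seed=4)
        out = stratified_split(sheet, seed=5)
        # global prevalence in training vs validation within a few percent
        for part in ("training", "validation"):
            sub = sheet.loc[out == part]
            frac = (sub["label"] == "L").mean()
            full = (sheet["label"] == "L").mean()
            assert abs(frac - full) < 0.05

    def test_overall_training_share_near_two_thirds(self):
        sheet = self._sheet(600, seed=6)
        out = stratified_split(sheet, seed=7)
        share = (out == "training").mean()
        assert abs(share - 2 / 3) < 0.05


class TestLinearTrend:
    def test_exact_linear_relationship(self):
        age = pd.Series(np.arange(30, 60, 1.0), index=[f"s{i}" for i in range(30)])
        idx = 2.0 * age
        fit = linear_trend(idx, age, covariate_name="age")
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit["slope_p"] < 1e-30

    def test_duplicated_data_same_slope_smaller_p(self, rng):
        age = pd.Series(rng.uniform(20, 70, 30), index=[f"s{i}" for i in range(30)])
        idx = 0.1 * age + pd.Series(rng.normal(0, 1, 30), index=age.index)
        one = linear_trend(idx, age)
        both = linear_trend(
            pd.concat([idx, idx.set_axis([f"t{i}" for i in range(30)])]),
            pd.concat([age, age.set_axis([f"t{i}" for i in range(30)])]),
        )
        assert both["slope"] == pytest.approx(one["slope"], abs=1e-10)
        assert both["slope_p"] < one["slope_p"]

    def test_constant_covariate_rejected(self):
        idx = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        cov = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            linear_trend(idx, cov)


class TestEnrichment:
    def test_selected_equals_background_or_one(self):
        probes = [f"cg{j}" for j in range(50)]
        ann = pd.Series(["island"] * 25 + ["open_sea"] * 25, index=probes)
        out = annotation_enrichment(set(probes), set(probes), ann)
        # degenerate margins: Fisher returns OR of an empty-remainder table
        assert (out["rest_in"] == 0).all()

    def test_matches_hypergeometric_oracle(self):
        """Fisher p equals the exact two-sided hypergeometric computation."""
        selected = {f"s{j}" for j in range(20)}
        rest = {f"b{j}" for j in range(980)}
        background = selected | rest
        ann = {}
        for j, p in enumerate(sorted(selected)):
            ann[p] = "open_sea" if j < 10 else "island"
        for j, p in enumerate(sorted(rest)):
            ann[p] = "open_sea" if j < 90 else "island"
        out = annotation_enrichment(selected, background, pd.Series(ann))
        a, b, c, d = 10, 10, 90, 890
        oracle_or, oracle_p = stats.fisher_exact([[a, b], [c, d]])
        assert out.loc["open_sea", "p"] == pytest.approx(oracle_p, abs=1e-10)
        assert out.loc["open_sea", "odds_ratio"] == pytest.approx(oracle_or)
        assert oracle_or == pytest.approx((10 / 10) / (90 / 890))
        assert out.loc["open_sea", "p"] < 0.001

    def test_empty_category_reported_na(self):
        probes = [f"cg{j}" for j in range(10)]
        ann = pd.Series("island", index=probes)
        # category 'shore' exists only via an unannotated probe set: craft one
        out = annotation_enrichment(set(probes[:3]), set(probes), ann)
        assert set(out.index) == {"island"}

    def test_unannotated_become_unknown(self):
        probes = [f"cg{j}" for j in range(10)]
        ann = pd.Series("island", index=probes[:5])
        out = annotation_enrichment(set(probes[:3]), set(probes), ann)
        assert "unknown" in out.index

    def test_selected_not_subset_is_error(self):
        with pytest.raises(ValueError, match="subset"):
            annotation_enrichment({"a"}, {"b"}, pd.Series(dtype=object))


class TestSubgroups:
    def test_all_mask_equals_global(self, rng):
        n = 60
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        labels = pd.Series(np.where(rng.random(n) < 0.5, "L", "O"), index=scores.index)
        masks = {"all": pd.Series(True, index=scores.index)}
        table = subgroup_auc(scores, labels, masks)
        assert table.loc["all", "auc"] == pytest.approx(roc_auc(scores, labels))

    def test_single_class_subgroup_is_na_with_warning(self, rng):
        n = 40
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        labels = pd.Series(["L"] * 20 + ["O"] * 20, index=scores.index)
        masks = {"first_half": pd.Series([True] * 20 + [False] * 20, index=scores.index)}
        with pytest.warns(UserWarning, match="first_half"):
            table = subgroup_auc(scores, labels, masks)
        assert np.isnan(table.loc["first_half", "auc"])

    def test_preset_masks_cover_cohort(self, small_cohort, small_fractions):
        sheet = small_cohort.sample_sheet.join(small_fractions["IC"])
        masks = preset_masks(sheet)
        assert len(masks) == 4
        total = masks["age<50"] | masks["age>=50"]
        assert total.all()


class TestAssociationScan:
    def test_strong_index_is_significant_and_adjustment_robust(self, rng):
        n = 120
        labels = np.where(rng.random(n) < 0.5, "L", "O")
        idx = pd.Series(
            np.where(labels == "O", 1.5, -1.5) + rng.normal(0, 1, n),
            index=[f"s{i}" for i in range(n)],
        )
        sheet = pd.DataFrame(
            {"label": labels, "age": rng.uniform(20, 70, n),
             "IC": rng.uniform(0, 0.7, n)},
            index=idx.index,
        )
        out = association_scan(idx, sheet)
        idx_rows = out[out["term"] == "index"].set_index("model")
        assert (idx_rows["OR"] > 1).all()
        assert (idx_rows.loc["age+ic", "p"]) < 0.01

    def test_null_index_ci_covers_one(self, rng):
        n = 100
        labels = np.where(rng.random(n) < 0.5, "L", "O")
        idx = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        sheet = pd.DataFrame({"label": labels}, index=idx.index)
        out = association_scan(idx, sheet, adjustments={"unadjusted": []})
        row = out[out["term"] == "index"].iloc[0]
        assert row["ci_low"] < 1 < row["ci_high"]

    def test_missing_covariate_is_error(self, rng):
        idx = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        sheet = pd.DataFrame(
            {"label": ["L", "O"] * 15}, index=idx.index
        )
        with pytest.raises(ValueError, match="absent"):
            association_scan(idx, sheet, adjustments={"m": ["bmi"]})
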