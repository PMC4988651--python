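import numpy as np
import pandas as pd
import pytest

from ventriflow import phantom as ph
from ventriflow.cohort_stats import (
    CohortTable,
    bsa_mosteller,
    classify_remodeling,
    cohort_report,
    correlation_analysis,
    group_compare,
    load_cohort,
    paired_compare,
    save_cohort,
    subgroup_analysis,
)


class TestIndexing:
    def test_mosteller_reference_values(self):
        assert bsa_mosteller(170.0, 68.0) == pytest.approx(1.792, abs=1e-3)
        assert bsa_mosteller(60.0, 60.0) == pytest.approx(1.0)

    def test_indexing_consistency(self):
        # a 133 ml LVEDV at BSA 1.797 m^2 indexes to ~74 ml/m^2
        assert 133.0 / 1.797 == pytest.approx(74.0, abs=0.1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            bsa_mosteller(-170.0, 68.0)

    def test_derived_columns(self):
        df = pd.DataFrame(
            {"subject_id": ["a"], "group": ["control"], "height_cm": [170.0],
             "weight_kg": [68.0], "lvedv_ml": [133.0], "lvesv_ml": [48.0],
             "lvef_pct": [63.9]}
        )
        t = CohortTable(df)
        assert t.df["bsa_m2"].iloc[0] == pytest.approx(1.792, abs=1e-3)
        assert t.df["lvedvi_ml_m2"].iloc[0] == pytest.approx(74.2, abs=0.1)
        assert bool(t.df["lvef_consistent"].iloc[0])

    def test_inconsistent_lvef_flagged(self):
        df = pd.DataFrame(
            {"subject_id": ["a"], "group": ["patient"], "lvedv_ml": [100.0],
             "lvesv_ml": [40.0], "lvef_pct": [70.0]}  # implied 60 %
        )
        assert not bool(CohortTable(df).df["lvef_consistent"].iloc[0])


class TestRemodelingFlags:
    @pytest.mark.parametrize(
        "lvedvi, lvesvi, expected",
        [(95.0, 32.0, True), (95.0, 28.0, False), (88.0, 32.0, False), (90.0, 31.0, False)],
    )
    def test_mild_remodeling_conjunction(self, lvedvi, lvesvi, expected):
        flags = classify_remodeling(lvedvi=lvedvi, lvesvi=lvesvi, lvef=60.0)
        assert flags["mild_remodeling"] is expected

    def test_dysfunction_boundary_is_strict(self):
        assert classify_remodeling(lvef=59.0)["mild_systolic_dysfunction"] is False
        assert classify_remodeling(lvef=58.9)["mild_systolic_dysfunction"] is True

    def test_missing_inputs_give_missing_flags(self):
        flags = classify_remodeling(lvedvi=95.0)
        assert flags["mild_remodeling"] is None


class TestLoading:
    def test_csv_round_trip(self, tmp_path):
        cohort = ph.make_synthetic_cohort(seed=1)
        path = save_cohort(cohort, tmp_path / "cohort.csv")
        back = load_cohort(path)
        assert back.n == cohort.n
        pd.testing.assert_series_equal(back.df["df_volume_ratio"],
                                       cohort.df["df_volume_ratio"], atol=1e-9)

    def test_schema_map_renames(self, tmp_path):
        df = pd.DataFrame({"ID": ["a", "b", "c"], "arm": ["control"] * 3, "EDV": [1, 2, 3]})
        df.to_csv(tmp_path / "t.csv", index=False)
        t = load_cohort(tmp_path / "t.csv",
                        schema_map={"ID": "subject_id", "arm": "group", "EDV": "lvedv_ml"})
        assert list(t.df["lvedv_ml"]) == [1, 2, 3]

    def test_schema_map_missing_column_rejected(self, tmp_path):
        pd.DataFrame({"subject_id": ["a"], "group": ["control"]}).to_csv(
            tmp_path / "t.csv", index=False)
        with pytest.raises(ValueError, match="absent"):
            load_cohort(tmp_path / "t.csv", schema_map={"nope": "lvedv_ml"})

    def test_duplicate_ids_rejected(self, tmp_path):
        pd.DataFrame({"subject_id": ["a", "a"], "group": ["control"] * 2}).to_csv(
            tmp_path / "t.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_cohort(tmp_path / "t.csv")

    def test_missing_height_leaves_indices_missing(self, tmp_path):
        pd.DataFrame(
            {"subject_id": ["a"], "group": ["control"], "weight_kg": [70.0],
             "lvedv_ml": [120.0]}
        ).to_csv(tmp_path / "t.csv", index=False)
        t = load_cohort(tmp_path / "t.csv")
        assert np.isnan(t.df["bsa_m2"].iloc[0])
        assert np.isnan(t.df["lvedvi_ml_m2"].iloc[0])


class TestCorrelation:
    def test_exact_collinearity(self):
        df = pd.DataFrame(
            {"subject_id": list("abcdef"), "group": ["patient"] * 6,
             "x": [1.0, 2, 3, 4, 5, 6], "y": [2.0, 4, 6, 8, 10, 12]}
        )
        out = correlation_analysis(CohortTable(df), ["x"], ["y"])
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] < 1e-10

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame(
            {"subject_id": list("abcd"), "group": ["patient"] * 4,
             "x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]}
        )
        out = correlation_analysis(CohortTable(df), ["x"], ["y"])
        assert np.isnan(out.iloc[0]["r"])
        assert "variance" in out.iloc[0]["note"]

    def test_holm_adjustment_available(self):
        c = ph.make_synthetic_cohort(seed=2)
        out = correlation_analysis(c, ["df_volume_ratio", "ne_volume_ratio"],
                                   ["lvedvi_ml_m2", "lvesvi_ml_m2"], holm=True)
        assert "p_holm" in out.columns
        assert (out["p_holm"].dropna() >= out["p"].dropna() - 1e-15).all()


class TestGroupCompare:
    def _table(self, a, b):
        df = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(len(a) + len(b))],
             "group": ["control"] * len(a) + ["patient"] * len(b),
             "v": np.concatenate([a, b])}
        )
        return CohortTable(df)

    def test_identical_groups_p_one(self):
        x = np.arange(8.0)
        res = group_compare(self._table(x, x), "v")
        assert res["p"] == pytest.approx(1.0)

    def test_power_with_large_separation(self):
        rng = np.random.default_rng(0)
        res = group_compare(
            self._table(rng.normal(0, 1, 10000), rng.normal(1, 1, 10000)), "v")
        assert res["p"] < 1e-6

    def test_nonnormal_data_routes_to_mwu(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(0, 1.5, 200), rng.lognormal(0.1, 1.5, 200)
        res = group_compare(self._table(a, b), "v", method="auto")
        assert res["method"] == "mwu"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_compare(self._table(np.array([1.0]), np.array([1.0, 2.0])), "v")

    def test_paired_null_p_values_are_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            x = rng.normal(67.0, 12.0, 26)
            y = x + rng.normal(0.0, 4.0, 26)  # same mean: the null holds
            pvals.append(paired_compare(x, y)["p"])
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.005 <= frac <= 0.12


class TestSubgroups:
    def test_boundary_lvedvi_assigned_to_lower_group(self):
        df = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(7)],
             "group": ["control"] * 2 + ["patient"] * 5,
             # 60 cm / 60 kg gives BSA exactly 1 m^2, so LVEDVI == LVEDV
             "height_cm": [60.0] * 7, "weight_kg": [60.0] * 7,
             "lvedv_ml": [140.0, 138.0, 74.0, 74.0, 60.0, 90.0, 95.0],
             "v": [1.0, 2, 3, 4, 5, 6, 7]}
        )
        t = CohortTable(df)
        res = subgroup_analysis(t, stratifier="lvedvi", vars=["v"])
        groups = res["v"]["groups"]
        assert groups["lower_lvedvi"]["n"] == 3  # two at exactly 74 plus one below
        assert groups["higher_lvedvi"]["n"] == 2

    def test_stratification_is_a_partition(self):
        c = ph.make_synthetic_cohort(seed=3)
        from ventriflow.cohort_stats import _strata

        strata = _strata(c, "lvedvi", 74.0)
        patients = c.df["group"] == "patient"
        assert strata[patients].isin(["lower_lvedvi", "higher_lvedvi"]).all()
        assert (strata[~patients] == "control").all()

    def test_identical_groups_give_near_zero_f(self):
        base = np.array([1.0, 2.0, 3.0, 4.0] * 3)
        df = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(12)],
             "group": ["control"] * 4 + ["patient"] * 8,
             "lge": ["na"] * 4 + ["neg"] * 4 + ["pos"] * 4,
             "v": base}
        )
        res = subgroup_analysis(CohortTable(df), stratifier="lge", vars=["v"])
        assert res["v"]["anova_F"] == pytest.approx(0.0, abs=1e-12)
        assert res["v"]["anova_p"] == pytest.approx(1.0)

    def test_empty_stratum_rejected(self):
        df = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(6)],
             "group": ["control"] * 3 + ["patient"] * 3,
             "lge": ["na"] * 3 + ["neg"] * 3,
             "v": [1.0, 2, 3, 4, 5, 6]}
        )
        with pytest.raises(ValueError):
            subgroup_analysis(CohortTable(df), stratifier="lge", vars=["v"])

    def test_report_assembles_all_tables(self):
        rep = cohort_report(ph.make_synthetic_cohort(seed=4))
        assert {"correlations", "subgroups_lvedvi", "subgroups_lge",
                "inflow_vs_outflow"} <= set(rep)
        assert set(rep["correlations"]["population"]) == {"all", "patients"}
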