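"""Epistasis statistics: the multiplicative null and the s-eps trend."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fitscape as fs
from fitscape.epistasis import (EpistasisRecord, normalize_to_ancestor,
                                records_from_strain_table)

pos_fitness = st.floats(0.05, 5.0)


class TestEpsilon:
    def test_neutral_partner_returns_other(self):
        assert fs.multiplicative_expectation(1.0, 1.33) == pytest.approx(1.33)

    def test_product_of_printed_singles(self):
        assert fs.multiplicative_expectation(1.420, 1.457) == \
            pytest.approx(2.069, abs=1e-3)

    @given(pos_fitness, pos_fitness)
    @settings(max_examples=50, deadline=None)
    def test_expectation_commutes(self, a, b):
        assert fs.multiplicative_expectation(a, b) == \
            fs.multiplicative_expectation(b, a)

    @given(pos_fitness, pos_fitness)
    @settings(max_examples=50, deadline=None)
    def test_epsilon_zero_iff_multiplicative(self, w_i, w_g):
        assert fs.epistasis(w_i * w_g, w_i, w_g) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_antagonistic_example_with_sign_epistasis(self):
        eps = fs.epistasis(1.2, 1.3, 1.4)
        assert eps == pytest.approx(-0.62)
        assert fs.is_sign_epistatic(1.2, 1.3, 1.4)  # beneficial alone,
        # deleterious in the background (1.2 < 1.4)

    def test_constructed_multiplicative_case_from_printed_values(self):
        assert fs.epistasis(1.420 * 1.457, 1.420, 1.457) == pytest.approx(0.0)

    def test_focal_background_labeling_symmetry(self):
        # swapping which single is focal relabels but keeps epsilon
        assert fs.epistasis(1.9, 1.3, 1.4) == fs.epistasis(1.9, 1.4, 1.3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fs.epistasis(1.0, 0.0, 1.0)


def multiplicative_table():
    """Strain table whose combination fitness is exactly multiplicative."""
    singles = {"A1": 1.3, "A2": 1.1, "B2": 1.2}
    rows = [{"strain": "ancestor", "genotype": "", "category": "ancestor",
             "fitness_obs": 1.0}]
    for m, w in singles.items():
        rows.append({"strain": m, "genotype": m, "category": "single",
                     "fitness_obs": w})
    for a in ("A1", "A2"):
        rows.append({"strain": f"{a}+B2", "genotype": f"{a};B2",
                     "category": "combination",
                     "fitness_obs": singles[a] * singles["B2"]})
    return pd.DataFrame(rows)


class TestRecordsFromStrainTable:
    def test_multiplicative_table_gives_zero_epsilon(self):
        recs = records_from_strain_table(multiplicative_table())
        assert np.allclose(recs["epsilon"], 0.0)
        assert not recs["sign_epistasis"].any()

    def test_each_pair_yields_two_records(self, clean_study):
        recs = records_from_strain_table(clean_study)
        assert len(recs) == 2 * 12
        a3b5 = recs[(recs["mutation_id"] == "A3") &
                    (recs["background_id"] == "B5")]
        assert len(a3b5) == 1

    def test_epsilon_matches_direct_formula(self, clean_study):
        norm = normalize_to_ancestor(clean_study)
        w = {r["genotype"]: r["fitness_obs"] for _, r in norm.iterrows()
             if r["category"] != "inducible"}
        recs = records_from_strain_table(clean_study)
        for _, r in recs.iterrows():
            combo = ";".join(sorted(r["mutation_id"].split(";") +
                                    r["background_id"].split(";")))
            expect = w[combo] - w[r["mutation_id"]] * w[r["background_id"]]
            assert r["epsilon"] == pytest.approx(expect, abs=1e-12)

    def test_landscape_generated_data_is_antagonistic(self, clean_study):
        # curvature of the benefit-cost surface makes combinations fall
        # short of the multiplicative expectation
        recs = records_from_strain_table(clean_study)
        assert recs["epsilon"].mean() < -0.1
        assert recs["sign_epistasis"].any()

    def test_missing_single_raises(self):
        df = multiplicative_table()
        df = df[df["strain"] != "A2"]
        with pytest.raises(ValueError, match="A2"):
            records_from_strain_table(df)

    def test_missing_ancestor_raises(self):
        df = multiplicative_table()
        with pytest.raises(ValueError, match="ancestor"):
            records_from_strain_table(df[df["genotype"] != ""])


class TestMultiplicativeFitnessNull:
    def test_exact_multiplicative_table(self):
        r2, adj, resid = fs.fit_multiplicative_fitness_null(
            multiplicative_table())
        assert r2 == pytest.approx(1.0)
        assert np.allclose(resid["residual"], 0.0)

    def test_landscape_data_systematic_negative_residuals_at_high_expectation(
            self, clean_study):
        r2, adj, resid = fs.fit_multiplicative_fitness_null(clean_study)
        top = resid.nlargest(4, "expected")
        assert (top["residual"] < 0).all()
        assert resid["residual"].mean() < 0
        assert r2 < 1.0

    def test_single_row_table_rejected(self):
        df = pd.DataFrame([{"strain": "ancestor", "genotype": "",
                            "category": "ancestor", "fitness_obs": 1.0}])
        with pytest.raises(ValueError, match="combination|ancestor"):
            fs.fit_multiplicative_fitness_null(df)


class TestSEpsilonTrend:
    def test_all_multiplicative_gives_zero_slope_and_means(self):
        recs = records_from_strain_table(multiplicative_table())
        trend = fs.s_epsilon_trend(recs)
        assert trend.slope == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(trend.per_mutation["mean_epsilon"], 0.0)

    def test_landscape_data_slope_negative(self, clean_study):
        recs = records_from_strain_table(clean_study)
        trend = fs.s_epsilon_trend(recs)
        assert trend.slope < 0

    def test_identical_epsilon_sets_give_p_one(self):
        rows = []
        for m, s in (("X", 0.2), ("Y", 0.3)):
            for e in (-0.1, -0.2, -0.3):
                rows.append({"mutation_id": m, "background_id": "Z",
                             "w_i": 1 + s, "w_g": 1.0, "w_ig": 1.0,
                             "s_i": s, "epsilon": e,
                             "sign_epistasis": False})
        trend = fs.s_epsilon_trend(pd.DataFrame(rows), compare=("X", "Y"))
        assert trend.t_pvalue == pytest.approx(1.0)

    def test_welch_comparison_detects_difference(self, clean_study):
        recs = records_from_strain_table(clean_study)
        trend = fs.s_epsilon_trend(recs, compare=("A3", "B3"))
        assert trend.t_pvalue is not None and 0 <= trend.t_pvalue <= 1

    def test_fewer_than_two_mutations_rejected(self):
        one = pd.DataFrame([{"mutation_id": "X", "background_id": "Y",
                             "w_i": 1.1, "w_g": 1.0, "w_ig": 1.05,
                             "s_i": 0.1, "epsilon": -0.05,
                             "sign_epistasis": False}])
        with pytest.raises(ValueError):
            fs.s_epsilon_trend(one)


class TestNormalizeDataset:
    def test_ancestor_maps_to_one(self):
        df = pd.DataFrame({"genotype": ["", "m1"], "fitness": [2.0, 3.0]})
        out = fs.normalize_dataset(df)
        assert out.loc[out["genotype"] == "", "fitness"].iloc[0] == 1.0
        assert out.loc[out["genotype"] == "m1", "fitness"].iloc[0] == 1.5

    def test_exp2_transform_for_doublings_data(self):
        df = pd.DataFrame({"genotype": ["", "m1"], "fitness": [1.0, 2.0]})
        out = fs.normalize_dataset(df, transform="exp2")
        # 2^2 / 2^1 = 2
        assert out.loc[out["genotype"] == "m1", "fitness"].iloc[0] == \
            pytest.approx(2.0)

    def test_none_transform_is_identity_before_division(self):
        df = pd.DataFrame({"genotype": ["", "m1"], "fitness": [1.0, 1.7]})
        out = fs.normalize_dataset(df, transform="none")
        assert out.loc[out["genotype"] == "m1", "fitness"].iloc[0] == \
            pytest.approx(1.7)

    def test_missing_ancestor_raises(self):
        df = pd.DataFrame({"genotype": ["m1"], "fitness": [2.0]})
        with pytest.raises(ValueError, match="ancestor"):
            fs.normalize_dataset(df)


def test_load_genotype_fitness_csv_roundtrip(tmp_path):
    df = pd.DataFrame({"genotype": ["", "m1", "m2", "m1;m2"],
                       "fitness": [1.0, 1.2, 1.1, 1.3],
                       "dataset": ["d", "d", "d", "d"]})
    path = tmp_path / "gf.csv"
    df.to_csv(path, index=False)
    back = fs.load_genotype_fitness_csv(path)
    assert list(back["genotype"]) == ["", "m1", "m2", "m1;m2"]
    recs = records_from_strain_table(
        back.rename(columns={"fitness": "fitness_obs"}))
    assert len(recs) == 2


def test_loader_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"genotype": [""]}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="fitness"):
        fs.load_genotype_fitness_csv(path)
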