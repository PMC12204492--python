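"""Input-count connectivity statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avoidpop.connectivity import (
    connectivity_pca_similarity,
    proportions,
    region_anova,
    similarity_index,
    subtype_decoder,
)
from avoidpop.core import ValidationError
from avoidpop.synth import generate_input_counts


@pytest.fixture(scope="module")
def distinct_counts():
    profiles = {
        "Glp1r": np.r_[np.ones(13), 8.0],
        "Foxp2": np.r_[8.0, np.ones(13)],
        "Calcr": np.ones(14),
    }
    return generate_input_counts(5, profiles, concentration=200.0, seed=0)


class TestProportions:
    def test_rows_sum_to_one(self, distinct_counts):
        p = proportions(distinct_counts)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_simple_rows(self):
        df = pd.DataFrame([[2, 2], [5, 0]], columns=["A", "B"])
        p = proportions(df)
        assert p.iloc[0].tolist() == [0.5, 0.5]
        assert p.iloc[1].tolist() == [1.0, 0.0]

    def test_zero_total_excluded(self):
        df = pd.DataFrame([[1, 1], [0, 0]], columns=["A", "B"])
        assert len(proportions(df)) == 1


class TestRegionAnova:
    def test_planted_region_flagged(self, rng):
        # proportions are compositional: enriching SuM necessarily depletes
        # every other region a little, so with realistic subject noise only
        # the large SuM effect should survive FDR
        profiles = {
            "Glp1r": np.ones(14),
            "Foxp2": np.r_[np.ones(4), 6.0, np.ones(9)],  # SuM-enriched
        }
        icm = generate_input_counts(6, profiles, concentration=40.0, seed=2)
        p = proportions(icm)
        table = region_anova(p, icm.subtype)
        assert table.loc["SuM", "p_adj"] < 0.05
        others = table.drop(index="SuM")["p_adj"]
        assert (others < 0.05).sum() <= 2

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(0.5, 1.0, size=6)
        props = pd.DataFrame({"R": np.r_[a, b]})
        sub = pd.Series(["x"] * 6 + ["y"] * 6, index=props.index)
        table = region_anova(props, sub)
        t = stats.ttest_ind(a, b).statistic
        assert table.loc["R", "F"] == pytest.approx(t**2, rel=1e-10)

    def test_null_calibration_controlled(self, rng):
        rejections = 0
        total = 0
        for rep in range(25):
            icm = generate_input_counts(
                5, {"a": np.ones(10), "b": np.ones(10)},
                concentration=50.0, regions=tuple(f"R{i}" for i in range(10)),
                seed=rng,
            )
            table = region_anova(proportions(icm), icm.subtype)
            rejections += int((table["p_adj"] < 0.05).sum())
            total += len(table)
        assert rejections / total <= 0.06

    def test_bh_monotone_in_raw_p(self, distinct_counts):
        table = region_anova(proportions(distinct_counts),
                             distinct_counts.subtype)
        t = table.dropna().sort_values("p")
        assert (np.diff(t["p_adj"]) >= -1e-12).all()
        assert (t["p_adj"] >= t["p"] - 1e-12).all()


class TestPcaSimilarity:
    def test_similarity_formula(self):
        assert similarity_index(0.0) == 1.0
        assert similarity_index(1.0) == 0.5

    def test_distinct_groups_less_similar(self, distinct_counts):
        res = connectivity_pca_similarity(
            proportions(distinct_counts), distinct_counts.subtype,
            n_perm=200, seed=0,
        )
        assert res.similarity.loc["Glp1r", "Foxp2"] < 0.9
        assert res.permutation_p.loc["Glp1r", "Foxp2"] < 0.05
        assert res.fisher_p.loc["Glp1r", "Foxp2"] < 0.05

    def test_fisher_statistic_null_distribution(self, rng):
        # -2 sum(log p) over k independent uniform p-values is chi^2(2k)
        stats_ = []
        for _ in range(300):
            ps = rng.uniform(size=3)
            stats_.append(-2 * np.log(ps).sum())
        _, p = stats.kstest(stats_, stats.chi2(6).cdf)
        assert p > 0.01

    def test_identical_groups_uniform_permutation_p(self, rng):
        ps = []
        for rep in range(10):
            icm = generate_input_counts(
                6, {"a": np.ones(8), "b": np.ones(8)},
                concentration=30.0, regions=tuple(f"R{i}" for i in range(8)),
                seed=rng,
            )
            res = connectivity_pca_similarity(
                proportions(icm), icm.subtype, n_perm=99, seed=rng
            )
            ps.append(res.permutation_p.iloc[0, 1])
        assert np.mean(np.array(ps) < 0.2) <= 0.5


class TestSubtypeDecoder:
    def test_separable_profiles_perfect(self):
        # three classes: with only two, a label permutation occasionally
        # reproduces the exact partition and ties the null maximum
        profiles = {
            "Glp1r": np.r_[np.ones(13), 9.0],
            "Foxp2": np.r_[9.0, np.ones(13)],
            "Calcr": np.r_[np.ones(6), 9.0, np.ones(7)],
        }
        icm = generate_input_counts(5, profiles, concentration=np.inf,
                                    total_cells=4000, seed=0)
        res = subtype_decoder(proportions(icm), icm.subtype,
                              n_boot=50, n_perm=99, seed=0)
        assert res.loocv_accuracy == 1.0
        assert res.permutation_p == pytest.approx(1 / 100)
        assert res.significant

    def test_identical_profiles_not_significant(self, rng):
        icm = generate_input_counts(
            5, {"a": np.ones(8), "b": np.ones(8)},
            concentration=30.0, regions=tuple(f"R{i}" for i in range(8)),
            seed=3,
        )
        res = subtype_decoder(proportions(icm), icm.subtype,
                              n_boot=30, n_perm=99, seed=1)
        assert not res.significant

    def test_confusion_rows_are_class_counts(self, distinct_counts):
        res = subtype_decoder(proportions(distinct_counts),
                              distinct_counts.subtype,
                              n_boot=10, n_perm=19, seed=0)
        counts = distinct_counts.subtype.value_counts()
        for cls in res.confusion.index:
            assert res.confusion.loc[cls].sum() == counts[cls]

    def test_single_subtype_errors(self, rng):
        props = pd.DataFrame(rng.random((4, 3)))
        with pytest.raises(ValidationError):
            subtype_decoder(props, pd.Series(["a"] * 4, index=props.index))
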