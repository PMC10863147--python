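import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from drivergene import (
    ExpressionMatrix,
    bh_adjust,
    nb_wald_test,
    pearson_correlate,
    size_factors,
    spearman_by_stratum,
    wilcoxon_markers,
)
from drivergene.diffexp import _exact_ranksum_p
from drivergene.stratify import BinaryGroups, StratifiedGroups
from drivergene.synthdata import simulate_bulk


class TestBhAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal_inputs(self):
        assert bh_adjust([1.0])[0] == 1.0
        np.testing.assert_allclose(bh_adjust([0.05] * 10), 0.05)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    def test_dominates_raw_and_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]}, index=["A", "B", "C"])
        np.testing.assert_allclose(size_factors(ExpressionMatrix(df)), [1.0, 1.0])

    def test_doubled_library_median_of_ratios(self):
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=["A", "B", "C"])
        np.testing.assert_allclose(
            size_factors(ExpressionMatrix(df)), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_no_common_gene_needs_pseudo_reference(self):
        df = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]}, index=["A", "B"])
        m = ExpressionMatrix(df)
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(m)
        f = size_factors(m, pseudo_reference=True)
        assert (f > 0).all()


def _two_group(counts_low, counts_high, prefix="s"):
    n1, n2 = counts_low.shape[1], counts_high.shape[1]
    cols = [f"{prefix}{i}" for i in range(n1 + n2)]
    df = pd.DataFrame(
        np.concatenate([counts_low, counts_high], axis=1),
        index=[f"G{i}" for i in range(counts_low.shape[0])],
        columns=cols,
    )
    groups = StratifiedGroups(
        low_ids=cols[:n1], high_ids=cols[n1:], middle_ids=[], driver_gene="G0", thresholds=(0, 0)
    )
    return ExpressionMatrix(df, layer="counts"), groups


class TestNbWald:
    def test_scaled_libraries_cancel_to_zero_lfc(self):
        base = np.array([[100, 110, 90, 105], [50, 55, 45, 52], [10, 12, 9, 11]])
        m, groups = _two_group(base, base * 3)
        res = nb_wald_test(m, groups, shrink_lfc=False).df
        np.testing.assert_allclose(res["lfc"], 0.0, atol=0.05)

    def test_planted_fold_change_detected(self, rng):
        n = 15
        low = rng.negative_binomial(10, 10 / (10 + 50), size=(200, n))
        high = rng.negative_binomial(10, 10 / (10 + 50), size=(200, n))
        high[0] = rng.negative_binomial(10, 10 / (10 + 200), size=n)  # 4-fold up
        m, groups = _two_group(low, high)
        res = nb_wald_test(m, groups).df.set_index("gene")
        assert res.loc["G0", "lfc"] > 0
        assert res.loc["G0", "lfc_shrunk"] > 0
        assert res.loc["G0", "padj"] <= 0.05

    def test_all_zero_gene_reported_na_excluded_from_bh(self, rng):
        low = rng.poisson(50, size=(20, 5))
        high = rng.poisson(50, size=(20, 5))
        low[3] = 0
        high[3] = 0
        m, groups = _two_group(low, high)
        res = nb_wald_test(m, groups).df
        assert np.isnan(res.loc[3, "p"])
        assert np.isnan(res.loc[3, "padj"])
        assert res["p"].drop(3).notna().all()

    def test_shrunk_lfc_never_flips_sign(self, rng):
        low = rng.poisson(30, size=(100, 8))
        high = rng.poisson(40, size=(100, 8))
        m, groups = _two_group(low, high)
        res = nb_wald_test(m, groups).df.dropna(subset=["lfc"])
        same = np.sign(res["lfc_shrunk"]) == np.sign(res["lfc"])
        assert (same | (res["lfc_shrunk"] == 0)).all()

    def test_requires_counts_layer(self, small_counts):
        from drivergene import normalize_cpm

        cpm = normalize_cpm(small_counts)
        groups = StratifiedGroups(
            low_ids=["s1", "s2"], high_ids=["s3", "s4"], middle_ids=[], driver_gene="X", thresholds=(0, 0)
        )
        with pytest.raises(ValueError, match="counts"):
            nb_wald_test(cpm, groups)


def _brute_force_ranksum_p(pos, neg):
    """Independent oracle: enumerate every group assignment."""
    combined = np.concatenate([pos, neg])
    ranks = scipy.stats.rankdata(combined)
    n1 = len(pos)
    w_obs = ranks[:n1].sum()
    mean = n1 * (len(combined) + 1) / 2
    dev = abs(w_obs - mean)
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        w = ranks[list(idx)].sum()
        count += abs(w - mean) >= dev - 1e-9
        total += 1
    return count / total


class TestWilcoxonMarkers:
    def test_fully_separated_exact_p(self):
        df = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["G1"], columns=list("abcdef"))
        m = ExpressionMatrix(df, layer="counts")
        g = BinaryGroups(positive_ids=list("abc"), negative_ids=list("def"), driver_gene="X")
        res = wilcoxon_markers(m, g).df
        assert res.loc[0, "p"] == pytest.approx(0.1)
        assert res.loc[0, "direction"] == "down"

    def test_identical_multisets_give_p_one(self):
        df = pd.DataFrame([[1, 2, 3, 1, 2, 3]], index=["G1"], columns=list("abcdef"))
        m = ExpressionMatrix(df, layer="counts")
        g = BinaryGroups(positive_ids=list("abc"), negative_ids=list("def"), driver_gene="X")
        assert wilcoxon_markers(m, g).df.loc[0, "p"] == 1.0

    def test_constant_gene_has_undefined_direction(self):
        df = pd.DataFrame([[7, 7, 7, 7], [1, 2, 3, 4]], index=["G1", "G2"], columns=list("abcd"))
        m = ExpressionMatrix(df, layer="counts")
        g = BinaryGroups(positive_ids=["a", "b"], negative_ids=["c", "d"], driver_gene="X")
        res = wilcoxon_markers(m, g).df
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "direction"] == "NA"

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 8, size=2)
            pos = rng.integers(0, 6, size=n1).astype(float)  # heavy ties on purpose
            neg = rng.integers(0, 6, size=n2).astype(float)
            if np.all(np.concatenate([pos, neg]) == pos[0]):
                continue
            assert _exact_ranksum_p(pos, neg) == pytest.approx(
                _brute_force_ranksum_p(pos, neg), abs=1e-12
            )


class TestPearsonCorrelate:
    def _matrix(self, driver, genes):
        data = {"DRIVER": driver}
        data.update(genes)
        df = pd.DataFrame(data).T
        df.columns = [f"s{i}" for i in range(len(driver))]
        return ExpressionMatrix(df - df.min().min(), layer="normalized")

    def test_affine_and_reversed_genes(self):
        m = self._matrix([1, 2, 3, 4], {"UP": [3, 5, 7, 9], "DOWN": [9, 7, 5, 3]})
        res = pearson_correlate(m, "DRIVER").df.set_index("gene")
        assert res.loc["UP", "coefficient"] == pytest.approx(1.0)
        assert res.loc["DOWN", "coefficient"] == pytest.approx(-1.0)

    def test_hand_computed_half_correlation(self):
        m = self._matrix([1, 2, 3], {"G": [1, 3, 2]})
        res = pearson_correlate(m, "DRIVER").df.set_index("gene")
        assert res.loc["G", "coefficient"] == pytest.approx(0.5)

    def test_zero_variance_driver_rejected(self):
        m = self._matrix([2, 2, 2], {"G": [1, 3, 2]})
        with pytest.raises(ValueError, match="variance"):
            pearson_correlate(m, "DRIVER")

    def test_driver_correlates_with_itself_perfectly(self, rng):
        vals = rng.normal(size=10)
        m = self._matrix(vals, {"OTHER": rng.normal(size=10)})
        res = pearson_correlate(m, "DRIVER").df.set_index("gene")
        assert res.loc["DRIVER", "coefficient"] == pytest.approx(1.0)


class TestSpearmanByStratum:
    def test_monotone_and_reversed(self):
        driver = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=[f"s{i}" for i in range(8)])
        scores = pd.DataFrame(
            {f"s{i}": [np.exp(i), -i] for i in range(8)}, index=["SIG_UP", "SIG_DOWN"]
        )
        strata = pd.Series(["t1"] * 8, index=driver.index)
        res = spearman_by_stratum(driver, scores, strata).df.set_index("signature")
        assert res.loc["SIG_UP", "coefficient"] == pytest.approx(1.0)
        assert res.loc["SIG_DOWN", "coefficient"] == pytest.approx(-1.0)

    def test_small_stratum_skipped_with_warning(self):
        driver = pd.Series([1, 2, 3, 4, 5, 6, 7], index=[f"s{i}" for i in range(7)])
        scores = pd.DataFrame({f"s{i}": [i] for i in range(7)}, index=["SIG"])
        strata = pd.Series(["big"] * 4 + ["small"] * 3, index=driver.index)
        with pytest.warns(UserWarning, match="small"):
            res = spearman_by_stratum(driver, scores, strata).df
        assert set(res["stratum"]) == {"big"}


class TestNullCalibrationSmoke:
    def test_null_type_one_error_near_nominal(self):
        m, _, _ = simulate_bulk(n_samples=20, n_genes=400, program_size=1, rho=0.5, lfc=0.0, seed=77)
        ids = m.sample_ids
        groups = StratifiedGroups(
            low_ids=ids[:10], high_ids=ids[10:], middle_ids=[], driver_gene="DRIVER", thresholds=(0, 0)
        )
        p = nb_wald_test(m, groups).df["p"].dropna()
        assert 0.01 <= (p <= 0.05).mean() <= 0.10
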