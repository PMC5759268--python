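"""Twin concordance screen: MSE oracles, RZ pairing, ESS classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from supersim.io import MethylationMatrix, PairSet
from supersim.simulate import LocusClass, LocusSpec, simulate_twin_cohort
from supersim.twins import (
    classify_ess,
    locus_mse_fold,
    make_randomized_pairs,
    mse_distribution_stats,
    pair_mse,
    screen_twins,
    top_variance_filter,
)
from conftest import consecutive_pairs, random_matrix


def brute_force_mse(matrix, pairs):
    """Independent double-loop implementation of the pairwise MSE."""
    out = {}
    for probe in matrix.probe_ids:
        total, count = 0.0, 0
        for a, b in pairs.pairs:
            va = matrix.beta.loc[probe, a]
            vb = matrix.beta.loc[probe, b]
            if np.isfinite(va) and np.isfinite(vb):
                total += (va - vb) ** 2
                count += 1
        out[probe] = total / count if count else np.nan
    return pd.Series(out)


class TestPairMSE:
    def test_direct_evaluation(self):
        beta = pd.DataFrame({"a1": [0.2], "b1": [0.2], "a2": [0.4], "b2": [0.6]},
                            index=["p"])
        matrix = MethylationMatrix(beta)
        pairs = PairSet([("a1", "b1"), ("a2", "b2")], "MZ")
        assert pair_mse(matrix, pairs)["p"] == pytest.approx(0.02, abs=1e-15)

    def test_identical_cotwins_give_zero(self, rng):
        matrix = random_matrix(rng, 10, 6)
        matrix.beta["s1"] = matrix.beta["s0"]
        pairs = PairSet([("s0", "s1")], "MZ")
        assert pair_mse(matrix, pairs).max() == 0.0

    def test_matches_brute_force_with_missing_values(self, rng):
        matrix = random_matrix(rng, 50, 40, missing_rate=0.1)
        pairs = consecutive_pairs(matrix.sample_ids)
        fast = pair_mse(matrix, pairs)
        slow = brute_force_mse(matrix, pairs)
        pd.testing.assert_series_equal(fast, slow, atol=1e-12, check_names=False)

    def test_empty_pairset_raises(self, rng):
        with pytest.raises(ValueError):
            pair_mse(random_matrix(rng, 3, 4), PairSet([], "MZ"))


class TestRandomizedPairs:
    def test_four_samples_give_two_disjoint_pairs(self):
        rz = make_randomized_pairs(["a", "b", "c", "d"], seed=0)
        assert len(rz) == 2
        assert len({s for p in rz.pairs for s in p}) == 4

    def test_odd_sample_dropped(self):
        rz = make_randomized_pairs(list("abcde"), seed=0)
        assert len(rz) == 2

    def test_deterministic_per_seed(self):
        a = make_randomized_pairs(list("abcdef"), seed=42)
        b = make_randomized_pairs(list("abcdef"), seed=42)
        assert a.pairs == b.pairs

    def test_matchings_approximately_uniform(self):
        """For 4 samples there are 3 perfect matchings; each should appear
        with frequency about 1/3 over many seeds."""
        counts = {}
        for seed in range(1500):
            rz = make_randomized_pairs(["a", "b", "c", "d"], seed=seed)
            key = frozenset(frozenset(p) for p in rz.pairs)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        for count in counts.values():
            assert count / 1500 == pytest.approx(1 / 3, abs=0.05)

    def test_fewer_than_two_samples_raises(self):
        with pytest.raises(ValueError):
            make_randomized_pairs(["a"], seed=0)


class TestTopVarianceFilter:
    def test_single_highest_variance_probe(self, rng):
        matrix = random_matrix(rng, 10, 30)
        selected = top_variance_filter(matrix, 0.1)
        variances = matrix.beta.var(axis=1, ddof=0)
        assert list(selected) == [variances.idxmax()]

    def test_full_fraction_keeps_all(self, rng):
        matrix = random_matrix(rng, 7, 5)
        assert len(top_variance_filter(matrix, 1.0)) == 7

    def test_constant_probe_never_selected(self, rng):
        matrix = random_matrix(rng, 6, 8)
        matrix.beta.loc["p0"] = 0.5
        selected = top_variance_filter(matrix, 0.5)
        assert "p0" not in selected

    def test_invalid_fraction_raises(self, rng):
        with pytest.raises(ValueError):
            top_variance_filter(random_matrix(rng, 3, 3), 0.0)


class TestClassifyESS:
    @pytest.mark.parametrize(
        "norm_mz,norm_dz,beta_range,expected",
        [
            (0.2, 0.5, 0.5, True),    # ratio 2.5, all criteria pass
            (0.2, 0.4, 0.5, False),   # ratio exactly 2: strict inequality
            (0.6, 3.0, 0.5, False),   # MZ/RZ exclusion rule
            (0.2, 0.5, 0.4, False),   # range exactly at threshold: strict
            (0.0, 0.5, 0.5, True),    # zero MZ MSE: maximal supersimilarity
        ],
    )
    def test_threshold_arithmetic(self, norm_mz, norm_dz, beta_range, expected):
        assert classify_ess(norm_mz, norm_dz, beta_range) is expected

    def test_vectorized_agrees_with_scalar(self, rng):
        mz, dz, rg = rng.random(50), rng.random(50) * 3, rng.random(50)
        vec = classify_ess(mz, dz, rg)
        for i in range(50):
            assert vec[i] == classify_ess(mz[i], dz[i], rg[i])


class TestLocusMSEFold:
    def test_tenfold_construction(self):
        beta = pd.DataFrame(
            {"m1": [0.5, 0.5], "m2": [0.51, 0.51], "d1": [0.5, 0.5],
             "d2": [0.5316227766016838, 0.5316227766016838]},
            index=["pa", "pb"],
        )
        matrix = MethylationMatrix(beta)
        mz = PairSet([("m1", "m2")], "MZ")
        dz = PairSet([("d1", "d2")], "DZ")
        fold = locus_mse_fold(matrix, ["pa", "pb"], mz, dz)
        assert fold == pytest.approx(10.0, rel=1e-9)

    def test_zero_mz_mse_gives_infinity(self):
        beta = pd.DataFrame({"m1": [0.5], "m2": [0.5], "d1": [0.2], "d2": [0.6]},
                            index=["p"])
        matrix = MethylationMatrix(beta)
        fold = locus_mse_fold(matrix, ["p"], PairSet([("m1", "m2")], "MZ"),
                              PairSet([("d1", "d2")], "DZ"))
        assert np.isinf(fold)

    def test_early_established_locus_has_large_fold(self):
        loci = [LocusSpec(LocusClass.EARLY_STOCHASTIC)] * 6
        cohort = simulate_twin_cohort(50, 80, loci, seed=2)
        fold = locus_mse_fold(
            cohort.matrix, cohort.matrix.probe_ids,
            cohort.pairs["MZ"], cohort.pairs["DZ"],
        )
        assert fold > 2.0


class TestMSEDistributionStats:
    def test_symmetric_sample_not_skewed(self):
        values = np.concatenate([np.linspace(-1, 1, 50), np.linspace(-1, 1, 50)])
        stats_ = mse_distribution_stats(values + 5.0)
        assert abs(stats_["skew_statistic"]) < 1.0
        assert stats_["skew_p"] > 0.2

    def test_left_skewed_sample_detected(self, rng):
        values = 1.0 - rng.exponential(0.2, size=5000)
        assert mse_distribution_stats(values)["skew_p"] < 1e-10

    def test_extreme_value_z_score(self):
        values = np.concatenate([np.full(99, 0.5) + np.linspace(-0.01, 0.01, 99), [0.0]])
        z = mse_distribution_stats(values)["z"]
        assert z.min() < -5

    def test_degenerate_distribution_raises(self):
        with pytest.raises(ValueError):
            mse_distribution_stats(np.full(20, 0.3))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            mse_distribution_stats([0.1] * 7)


class TestScreenTwins:
    def test_monotonicity_noise_increases_mz_mse(self):
        """More measurement noise means more discordance in MZ co-twins at
        early-established loci, shrinking the DZ/MZ separation."""
        folds = []
        for noise in (0.01, 0.05, 0.10):
            loci = [LocusSpec(LocusClass.EARLY_STOCHASTIC, noise_sd=noise)] * 30
            cohort = simulate_twin_cohort(80, 80, loci, seed=13)
            mse_mz = pair_mse(cohort.matrix, cohort.pairs["MZ"]).mean()
            folds.append(mse_mz)
        assert folds[0] < folds[1] < folds[2]

    def test_screen_returns_all_probes_with_flags(self):
        loci = [LocusSpec(LocusClass.EARLY_STOCHASTIC)] * 5 + [
            LocusSpec(LocusClass.LATE_STOCHASTIC)
        ] * 15
        cohort = simulate_twin_cohort(30, 30, loci, seed=4)
        records = screen_twins(cohort.matrix, cohort.pairs["MZ"], cohort.pairs["DZ"],
                               rz_seed=1)
        assert len(records) == 20
        assert records["is_top_variance"].sum() == 2  # ceil(0.1 * 20)
        assert set(records.columns) >= {"mse_mz", "norm_dz", "is_ess"}
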