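"""Cluster construction, conditional logistic fits, permutation events."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from supersim.cancer import (
    ClusterDef,
    build_clusters,
    clr_fit,
    cluster_events,
    permutation_test,
    probe_associations,
    rank_normalize,
    recurrence,
    select_significant_clusters,
)
from supersim.io import PairSet
from supersim.simulate import simulate_matched_casecontrol


def numerical_clr_mle(diffs):
    """Independent one-parameter conditional-likelihood maximizer."""
    diffs = np.asarray(diffs, dtype=float)

    def negloglik(beta):
        return np.sum(np.log1p(np.exp(-diffs * beta)))

    return optimize.minimize_scalar(
        negloglik, bounds=(-20, 20), method="bounded", options={"xatol": 1e-10}
    ).x


def annotation(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "probe_id": [f"cg{p}" for p in positions],
        }
    )


class TestBuildClusters:
    def test_hand_enumerated_positions(self):
        clusters = build_clusters(annotation([100, 550, 900, 5000, 5200, 9000]))
        assert len(clusters) == 2
        assert clusters[0].probe_ids == ("cg100", "cg550", "cg900")
        assert clusters[1].probe_ids == ("cg5000", "cg5200")
        assert clusters[0].span == 800

    def test_gap_of_exactly_500_joins(self):
        clusters = build_clusters(annotation([0, 500]))
        assert len(clusters) == 1

    def test_all_isolated_probes_give_no_clusters(self):
        assert build_clusters(annotation([0, 600, 1300])) == []

    def test_chromosomes_never_merge(self):
        ann = pd.concat([annotation([0, 100], "chr1"), annotation([150, 250], "chr2")])
        clusters = build_clusters(ann)
        assert len(clusters) == 2
        assert {c.chrom for c in clusters} == {"chr1", "chr2"}


class TestRankNormalize:
    def test_ascending_ranks(self):
        np.testing.assert_array_equal(rank_normalize([0.5, 0.1, 0.9]), [2, 1, 3])

    def test_ties_get_average_rank(self):
        np.testing.assert_array_equal(rank_normalize([0.5, 0.5]), [1.5, 1.5])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.random(30)
        np.testing.assert_array_equal(
            rank_normalize(x), rank_normalize(np.log(x + 1.0))
        )


class TestCLRFit:
    def test_binary_discordant_pairs_closed_form(self):
        """6 case-exposed-only vs 3 control-exposed-only discordant pairs:
        the conditional MLE is ln(6/3) = ln 2."""
        diffs = np.array([1.0] * 6 + [-1.0] * 3 + [0.0] * 5)
        out = clr_fit(diffs)
        assert out["coefficient"] == pytest.approx(np.log(2), abs=1e-6)
        assert out["coefficient"] == pytest.approx(numerical_clr_mle(diffs), abs=1e-6)

    def test_uninformative_exposure(self):
        out = clr_fit(np.zeros(12))
        assert out["coefficient"] == 0.0 and out["p"] == 1.0

    def test_separation_is_flagged(self):
        out = clr_fit(np.ones(10))
        assert not out["converged"] and np.isnan(out["p"])

    def test_continuous_exposure_recovery(self, rng):
        """500 matched pairs with true log-odds 0.5 per unit exposure."""
        n = 500
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        p_first = 1.0 / (1.0 + np.exp(-0.5 * (x1 - x2)))
        first_is_case = rng.random(n) < p_first
        diffs = np.where(first_is_case, x1 - x2, x2 - x1)
        out = clr_fit(diffs)
        assert out["coefficient"] == pytest.approx(0.5, abs=0.15)
        assert out["coefficient"] == pytest.approx(numerical_clr_mle(diffs), abs=1e-6)

    def test_matches_numerical_mle_on_random_instances(self, rng):
        for _ in range(10):
            diffs = rng.normal(size=40)
            out = clr_fit(diffs)
            assert out["coefficient"] == pytest.approx(numerical_clr_mle(diffs), abs=1e-6)

    def test_pair_role_exchange_flips_coefficient_sign(self, rng):
        diffs = rng.normal(0.3, 1.0, size=60)
        a = clr_fit(diffs)
        b = clr_fit(-diffs)
        assert a["coefficient"] == pytest.approx(-b["coefficient"], abs=1e-8)
        assert a["p"] == pytest.approx(b["p"], abs=1e-10)


class TestClusterEvents:
    def test_majority_sign_count(self):
        out = cluster_events([0.01, 0.03, 0.2], [1.0, 0.5, -2.0])
        assert out["N"] == 2 and out["Pmin"] == pytest.approx(0.01)

    def test_sign_split(self):
        assert cluster_events([0.01, 0.02], [1.0, -1.0])["N"] == 1

    def test_no_significant_probes(self):
        out = cluster_events([0.3, 0.4], [1.0, 1.0])
        assert out["N"] == 0 and out["Pmin"] == pytest.approx(0.3)

    def test_all_missing(self):
        out = cluster_events([np.nan, np.nan], [1.0, 1.0])
        assert out["N"] == 0 and np.isnan(out["Pmin"])


class TestRecurrence:
    def test_counts_types_with_two_concordant_hits(self):
        assert recurrence([3, 2, 1, 0, 2, 0, 0]) == 3

    def test_all_zero(self):
        assert recurrence([0, 0, 0]) == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            recurrence([])


CLUSTERS3 = [
    ClusterDef(f"c{i}", tuple(f"c{i}p{j}" for j in range(3)), "chr1", 200)
    for i in range(3)
]


class TestPermutationTest:
    def test_reproducible_given_seed(self):
        cohort = simulate_matched_casecontrol(
            20, CLUSTERS3, {"c0"}, delta=0.06, noise_sd=0.05,
            covariates="none", seed=3,
        )
        study = cohort.extras["study"]
        a = permutation_test(cohort.matrix, [study], CLUSTERS3, n_perm=200, seed=9)
        b = permutation_test(cohort.matrix, [study], CLUSTERS3, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_requires_seed(self):
        cohort = simulate_matched_casecontrol(
            10, CLUSTERS3, set(), covariates="none", seed=3
        )
        with pytest.raises(ValueError, match="seed"):
            permutation_test(cohort.matrix, [cohort.extras["study"]], CLUSTERS3,
                             n_perm=100, seed=None)

    def test_observed_events_invariant_to_pair_ordering(self):
        cohort = simulate_matched_casecontrol(
            20, CLUSTERS3, {"c0"}, delta=0.06, noise_sd=0.05,
            covariates="none", seed=4,
        )
        study = cohort.extras["study"]
        probes = [p for c in CLUSTERS3 for p in c.probe_ids]
        obs = probe_associations(cohort.matrix, study, probes)
        shuffled = PairSet(list(reversed(study.pairs.pairs)), "CC")
        study_rev = type(study)(study.cancer_type, shuffled, study.covariates)
        obs_rev = probe_associations(cohort.matrix, study_rev, probes)
        np.testing.assert_allclose(obs["p"], obs_rev["p"], atol=1e-10)

    def test_monte_carlo_matches_small_exhaustive_enumeration(self):
        """6-pair study: the permutation p equals the exhaustive 64-assignment
        quadrant probability within binomial 99% error."""
        cluster = [ClusterDef("c0", ("c0p0", "c0p1", "c0p2"), "chr1", 100)]
        cohort = simulate_matched_casecontrol(
            6, cluster, {"c0"}, delta=0.07, noise_sd=0.06,
            covariates="none", seed=8,
        )
        study = cohort.extras["study"]
        matrix = cohort.matrix
        res = permutation_test(matrix, [study], cluster, n_perm=4000, seed=10)
        mc_p = res["p_event_i"].iloc[0]

        obs = probe_associations(matrix, study, list(cluster[0].probe_ids))
        obs_ev = cluster_events(obs["p"], obs["coefficient"])
        hits = 0
        for flips in itertools.product([False, True], repeat=6):
            pairs = [
                (b, a) if flip else (a, b)
                for (a, b), flip in zip(study.pairs.pairs, flips)
            ]
            flipped = type(study)(study.cancer_type, PairSet(pairs, "CC"), None)
            perm = probe_associations(matrix, flipped, list(cluster[0].probe_ids))
            ev = cluster_events(perm["p"], perm["coefficient"])
            if (
                ev["N"] >= obs_ev["N"]
                and np.isfinite(ev["Pmin"])
                and ev["Pmin"] <= obs_ev["Pmin"]
            ):
                hits += 1
        exact = hits / 64
        bound = 2.58 * np.sqrt(exact * (1 - exact) / 4000) + 1 / 4001
        assert abs(mc_p - exact) < bound + 1e-9

    def test_strong_effect_attains_permutation_floor(self):
        cohort = simulate_matched_casecontrol(
            40, CLUSTERS3, {"c0"}, delta=0.08, noise_sd=0.05,
            covariates="none", seed=21,
        )
        res = permutation_test(cohort.matrix, [cohort.extras["study"]], CLUSTERS3,
                               n_perm=499, seed=22)
        affected = res[res["cluster_id"] == "c0"]
        assert affected["p_event_i"].iloc[0] == pytest.approx(1 / 500)

    def test_recurrence_event_across_cancer_types(self):
        studies = []
        matrices = []
        for t in range(2):
            cohort = simulate_matched_casecontrol(
                30, CLUSTERS3, {"c0"}, delta=0.07, noise_sd=0.05,
                covariates="none", cancer_type=f"type{t}", seed=40 + t,
            )
            cohort.extras["study"].pairs = PairSet(
                [(f"t{t}_{a}", f"t{t}_{b}") for a, b in cohort.extras["study"].pairs.pairs],
                "CC",
            )
            cohort.matrix.beta.columns = [
                f"t{t}_{c}" for c in cohort.matrix.beta.columns
            ]
            studies.append(cohort.extras["study"])
            matrices.append(cohort.matrix.beta)
        from supersim.io import MethylationMatrix

        merged = MethylationMatrix(pd.concat(matrices, axis=1))
        res = permutation_test(merged, studies, CLUSTERS3, n_perm=300, seed=50)
        affected = res[res["cluster_id"] == "c0"]
        assert (affected["recurrence_obs"] == 2).all()
        assert (affected["p_event_ii"] < 0.05).all()


class TestSelectSignificantClusters:
    def make_results(self, pvals):
        return pd.DataFrame(
            {
                "cluster_id": [f"c{i}" for i in range(len(pvals))],
                "cancer_type": "x",
                "n_probes": np.arange(len(pvals))[::-1] + 2,
                "p_event_i": pvals,
            }
        )

    def test_single_small_p_flagged(self):
        results = self.make_results([0.001] + [0.9] * 9)
        out = select_significant_clusters(results, top_k=10)
        assert out.loc[out["cluster_id"] == "c0", "q"].iloc[0] == pytest.approx(0.01)
        assert out["is_significant"].sum() == 1

    def test_all_unit_p_none_flagged(self):
        out = select_significant_clusters(self.make_results([1.0] * 10), top_k=10)
        assert out["is_significant"].sum() == 0

    def test_restricts_to_most_cpg_rich(self):
        results = self.make_results([0.001] * 12)
        out = select_significant_clusters(results, top_k=5)
        assert out["cluster_id"].nunique() == 5
        assert set(out["cluster_id"]) == {"c0", "c1", "c2", "c3", "c4"}
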