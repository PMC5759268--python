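#!/usr/bin/env python
"""Twin-pair concordance screen on a simulated twin cohort.

Generates a cohort at the reference study scale (100 MZ + 160 DZ pairs;
1000 loci: 100 established before cleavage, 800 after, 100 genetically
determined; measurement noise SD 0.03), runs the MSE screen with RZ
normalization, and summarizes the epigenetic-supersimilarity calls against
ground truth together with the distributional statistics of the normalized
MSEs.  Writes results/ess_screen_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from supersim.simulate import default_twin_loci, simulate_twin_cohort
from supersim.twins import mse_distribution_stats, screen_twins

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    loci = default_twin_loci(100, 800, 100, noise_sd=0.03)
    cohort = simulate_twin_cohort(100, 160, loci, seed=SEED)
    records = screen_twins(
        cohort.matrix, cohort.pairs["MZ"], cohort.pairs["DZ"], rz_seed=SEED
    )
    records = records.join(cohort.truth["locus_class"])

    by_class = records.groupby("locus_class").agg(
        n=("is_ess", "size"),
        ess_called=("is_ess", "sum"),
        mean_norm_mz=("norm_mz", "mean"),
        mean_norm_dz=("norm_dz", "mean"),
        mean_range=("beta_range", "mean"),
    )
    stats_mz = mse_distribution_stats(records["norm_mz"])
    stats_dz = mse_distribution_stats(records["norm_dz"])

    OUT.mkdir(exist_ok=True)
    by_class.to_csv(OUT / "ess_screen_summary.tsv", sep="\t")

    print("ESS screen on simulated twin cohort (seed", SEED, ")")
    print(by_class.to_string(float_format="%.3f"))
    print(
        f"\nnormalized MZ MSE: {stats_mz['mean']:.2f} +/- {stats_mz['sd']:.2f} "
        f"(left-skew p = {stats_mz['skew_p']:.2e})"
    )
    print(
        f"normalized DZ MSE: {stats_dz['mean']:.2f} +/- {stats_dz['sd']:.2f} "
        f"(left-skew p = {stats_dz['skew_p']:.2e})"
    )
    early = by_class.loc["EARLY_STOCHASTIC"]
    print(
        f"\npre-cleavage loci recovered: {early['ess_called']}/{early['n']} "
        f"({100 * early['ess_called'] / early['n']:.1f}%)"
    )


if __name__ == "__main__":
    main()
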