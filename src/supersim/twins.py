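"""Twin-pair methylation concordance screen (epigenetic supersimilarity).

Concordance within a pair class is measured inversely by the probe-specific
mean squared error from the line of identity,

    MSE = (1/n) * sum_i (beta_iA - beta_iB)^2 ,

computed for monozygotic (MZ), dizygotic (DZ), and randomized (RZ) pairs.
MZ and DZ MSEs are normalized by the RZ MSE, which simulates pairwise MSE in
the general population.  Under purely genetic determination (DZ twins
identical by descent at half their haplotypes, MZ at all), normalized DZ MSE
should not exceed twice normalized MZ MSE; probes where it does — with
substantial interindividual variation — exhibit epigenetic supersimilarity
(ESS), the signature of methylation established before embryo cleavage.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import SCREEN_COLUMNS, MethylationMatrix, PairSet

logger = logging.getLogger("supersim.twins")

ESS_RATIO_MIN = 2.0
ESS_RANGE_MIN = 0.4
ESS_MZ_RZ_MAX = 0.5
LOW_SUPPORT_PAIRS = 10


def pair_mse(matrix: MethylationMatrix, pairs: PairSet) -> pd.Series:
    """Per-probe mean squared within-pair beta difference.

    A pair contributes to a probe only when both members are observed; a probe
    with no complete pair gets NaN.
    """
    if len(pairs) == 0:
        raise ValueError("PairSet is empty")
    a = matrix.values_for(pairs.left)
    b = matrix.values_for(pairs.right)
    sq = (a - b) ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mse = np.nanmean(sq, axis=1)
    return pd.Series(mse, index=matrix.beta.index, name=f"mse_{pairs.pair_class.lower()}")


def make_randomized_pairs(sample_ids, seed: int) -> PairSet:
    """Random perfect matching over the pooled samples (RZ normalization).

    Samples are permuted with a seeded generator and paired consecutively;
    with an odd count the last sample is dropped.
    """
    ids = list(sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two samples to randomize pairs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    pairs = [(ids[perm[i]], ids[perm[i + 1]]) for i in range(0, len(ids) - 1, 2)]
    return PairSet(pairs, pair_class="RZ")


def probe_variance(matrix: MethylationMatrix) -> pd.Series:
    """Population (ddof=0) variance per probe over non-missing samples."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(matrix.beta.to_numpy(dtype=float), axis=1, ddof=0)
    return pd.Series(var, index=matrix.beta.index, name="variance")


def probe_range(matrix: MethylationMatrix) -> pd.Series:
    """Interindividual beta range (max - min) per probe."""
    values = matrix.beta.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rng_ = np.nanmax(values, axis=1) - np.nanmin(values, axis=1)
    return pd.Series(rng_, index=matrix.beta.index, name="beta_range")


def top_variance_filter(matrix: MethylationMatrix, fraction: float) -> pd.Index:
    """Probes in the top ``fraction`` of interindividual variance.

    Keeps the ceil(fraction * P) highest-variance probes; ties broken by
    lexicographic probe ID.  All-missing probes are excluded with a warning.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    var = probe_variance(matrix)
    missing = var.index[var.isna()]
    if len(missing):
        warnings.warn(f"{len(missing)} all-missing probes excluded from variance ranking")
        var = var.dropna()
    k = int(np.ceil(fraction * len(var)))
    order = pd.DataFrame(
        {"variance": var.to_numpy(), "probe_id": var.index.to_numpy()}
    ).sort_values(["variance", "probe_id"], ascending=[False, True])
    return pd.Index(order["probe_id"].iloc[:k])


def classify_ess(
    norm_mz,
    norm_dz,
    beta_range,
    ratio_min: float = ESS_RATIO_MIN,
    range_min: float = ESS_RANGE_MIN,
    mz_rz_max: float = ESS_MZ_RZ_MAX,
):
    """Epigenetic-supersimilarity call from normalized MSEs and beta range.

    True iff DZ/MZ normalized MSE > ``ratio_min`` (strict) and interindividual
    range > ``range_min`` and normalized MZ MSE <= ``mz_rz_max`` (probes with
    MZ concordance no better than half the population level are excluded as
    unreliable).  A probe with normalized MZ MSE of exactly zero but nonzero
    DZ MSE is maximal ESS: the ratio is treated as +infinity.
    """
    norm_mz = np.asarray(norm_mz, dtype=float)
    norm_dz = np.asarray(norm_dz, dtype=float)
    beta_range = np.asarray(beta_range, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            norm_mz > 0,
            norm_dz / np.where(norm_mz > 0, norm_mz, 1.0),
            np.where(norm_dz > 0, np.inf, np.nan),
        )
    ok = (ratio > ratio_min) & (beta_range > range_min) & (norm_mz <= mz_rz_max)
    result = np.where(np.isnan(ratio) | np.isnan(beta_range) | np.isnan(norm_mz), False, ok)
    return bool(result) if result.ndim == 0 else result.astype(bool)


def locus_mse_fold(
    matrix: MethylationMatrix,
    probes_in_locus,
    mz_pairs: PairSet,
    dz_pairs: PairSet,
) -> float:
    """Locus-average DZ/MZ MSE fold (mean over probes of each class's MSE)."""
    probes = list(probes_in_locus)
    if not probes:
        raise ValueError("locus contains no probes")
    mse_mz = pair_mse(matrix, mz_pairs).loc[probes].mean()
    mse_dz = pair_mse(matrix, dz_pairs).loc[probes].mean()
    if mse_mz == 0:
        return float("inf")
    return float(mse_dz / mse_mz)


def mse_distribution_stats(norm_values) -> dict:
    """Distributional summary of normalized MSE values.

    Returns the sample mean and SD, a moment-based (D'Agostino) skewness
    statistic with a one-sided left-skew p-value, and a per-value z-score —
    the basis for the "> 5 SD below the expected normal mean" argument that
    supersimilar probes lie beyond sampling error.
    """
    values = np.asarray(norm_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 8:
        raise ValueError("need at least 8 values for the skewness test")
    sd = values.std(ddof=1)
    if sd == 0 or np.ptp(values) == 0:
        raise ValueError("degenerate distribution: zero standard deviation")
    mean = values.mean()
    stat, p_left = stats.skewtest(values, alternative="less")
    return {
        "mean": float(mean),
        "sd": float(sd),
        "skew_statistic": float(stat),
        "skew_p": float(p_left),
        "z": (values - mean) / sd,
    }


def screen_twins(
    matrix: MethylationMatrix,
    mz_pairs: PairSet,
    dz_pairs: PairSet,
    top_fraction: float = 0.1,
    rz_seed: int = 0,
    n_rz: int = 1,
    ratio_min: float = ESS_RATIO_MIN,
    range_min: float = ESS_RANGE_MIN,
    mz_rz_max: float = ESS_MZ_RZ_MAX,
) -> pd.DataFrame:
    """Full per-probe twin screen.

    Pools the MZ and DZ samples into one population for the variance ranking,
    the beta range, and the RZ pairing; computes MZ/DZ/RZ MSEs, RZ-normalized
    MSEs (optionally averaged over ``n_rz`` independent re-pairings) and the
    ESS call.  Probes with fewer than 10 complete pairs in any class are
    flagged ``low_support``.
    """
    pooled = sorted(set(mz_pairs.left + mz_pairs.right + dz_pairs.left + dz_pairs.right))
    pooled_matrix = MethylationMatrix(matrix.beta.loc[:, pooled])

    mse_mz = pair_mse(matrix, mz_pairs)
    mse_dz = pair_mse(matrix, dz_pairs)
    rz_mses = []
    for i in range(max(1, n_rz)):
        rz = make_randomized_pairs(pooled, seed=rz_seed + i)
        rz_mses.append(pair_mse(matrix, rz))
    mse_rz = pd.concat(rz_mses, axis=1).mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        norm_mz = mse_mz / mse_rz
        norm_dz = mse_dz / mse_rz

    variance = probe_variance(pooled_matrix)
    beta_range = probe_range(pooled_matrix)
    top = top_variance_filter(pooled_matrix, top_fraction)

    records = pd.DataFrame(
        {
            "probe_id": matrix.beta.index,
            "mse_mz": mse_mz,
            "mse_dz": mse_dz,
            "mse_rz": mse_rz,
            "norm_mz": norm_mz,
            "norm_dz": norm_dz,
            "variance": variance,
            "beta_range": beta_range,
        },
        index=matrix.beta.index,
    )
    records["is_top_variance"] = records.index.isin(top)
    records["is_ess"] = classify_ess(
        records["norm_mz"], records["norm_dz"], records["beta_range"],
        ratio_min=ratio_min, range_min=range_min, mz_rz_max=mz_rz_max,
    )
    records["is_negative_control"] = False  # filled by the SIV stage

    def complete_pairs(pairs: PairSet) -> np.ndarray:
        a = matrix.values_for(pairs.left)
        b = matrix.values_for(pairs.right)
        return np.sum(np.isfinite(a) & np.isfinite(b), axis=1)

    support = np.minimum.reduce(
        [complete_pairs(mz_pairs), complete_pairs(dz_pairs)]
    )
    records["low_support"] = support < LOW_SUPPORT_PAIRS
    logger.info(
        "twin screen: %d probes, %d top-variance, %d ESS",
        len(records), int(records["is_top_variance"].sum()), int(records["is_ess"].sum()),
    )
    return records[SCREEN_COLUMNS + ["low_support"]]
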