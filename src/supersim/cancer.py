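"""Cluster-level association between baseline blood methylation and later
cancer in matched case-control studies.

Probes are grouped into clusters (all CpGs within 500 bp of one another,
minimum two).  Per probe, M-values are rank-normalized across the study's
samples and associated with case status by conditional logistic regression
(CLR) on 1:1 matched pairs — equivalent to an intercept-free logistic model
of the within-pair (case - control) differences against a constant outcome.
Cluster evidence is summarized by two events:

* event i  — N, the count of significant (p < 0.05) probes with concordant
  coefficient sign, together with Pmin, the minimal probe p-value;
* event ii — Recurrence, the number of cancer types in which the cluster has
  at least two significant concordant probes.

Significance is calibrated by permutation: case/control status is reassigned
within each pair at random, probe-level CLRs are refit, and events are
recounted; p-values use the add-one (r + 1) / (n + 1) estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .io import MethylationMatrix, PairSet, beta_to_m

logger = logging.getLogger("supersim.cancer")

CLUSTER_MAX_GAP = 500
CLUSTER_MIN_SIZE = 2
EVENT_ALPHA = 0.05
DEFAULT_N_PERM = 20_000
CLUSTER_FDR = 0.25
TOP_K_CLUSTERS = 10

_NEWTON_TOL = 1e-10
_NEWTON_MAXITER = 60
_SEPARATION_BOUND = 30.0


@dataclass(frozen=True)
class ClusterDef:
    """A chromosomal run of probes, consecutive members <= 500 bp apart."""

    cluster_id: str
    probe_ids: tuple
    chrom: str
    span: int

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 2:
            raise ValueError("a cluster needs at least two probes")

    @property
    def size(self) -> int:
        return len(self.probe_ids)


@dataclass
class MatchedStudy:
    """One matched case-control study: ordered (case, control) pairs plus
    per-sample covariates that may differ within pairs (cell proportions,
    BMI, alcohol, smoking).  Matching covariates are absorbed by the
    pairing itself and must not be included."""

    cancer_type: str
    pairs: PairSet
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.pairs.pair_class != "CC":
            raise ValueError("MatchedStudy pairs must have pair_class 'CC'")
        if self.covariates is not None:
            samples = set(self.pairs.left) | set(self.pairs.right)
            missing = samples - set(self.covariates.index)
            if missing:
                raise ValueError(f"covariates missing for samples: {sorted(missing)[:5]}")


def build_clusters(
    annotation: pd.DataFrame,
    max_gap: int = CLUSTER_MAX_GAP,
    min_size: int = CLUSTER_MIN_SIZE,
) -> list[ClusterDef]:
    """Single-linkage chaining of probes along each chromosome.

    Consecutive probes at most ``max_gap`` bp apart join one cluster; runs
    shorter than ``min_size`` are dropped.
    """
    annotation = annotation.reset_index(drop=True)
    clusters: list[ClusterDef] = []
    for chrom, sub in annotation.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "probe_id"])
        pos = sub["pos"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or pos[i] - pos[i - 1] > max_gap:
                run = ids[start:i]
                if len(run) >= min_size:
                    clusters.append(
                        ClusterDef(
                            cluster_id=f"{chrom}:{pos[start]}",
                            probe_ids=tuple(run),
                            chrom=str(chrom),
                            span=int(pos[i - 1] - pos[start]),
                        )
                    )
                start = i
    return clusters


def rank_normalize(values) -> np.ndarray:
    """Ascending ranks 1..N with average ties.

    Applied per probe across all samples of a study; rank invariance under
    monotone transforms makes the downstream regression distribution-free in
    the exposure.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] < 2:
        raise ValueError("need at least 2 samples to rank")
    return stats.rankdata(arr, axis=-1, method="average")


def _clr_newton(Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Newton-Raphson for the 1:1 matched conditional likelihood.

    ``Xs`` has shape (P, n_pairs, k): per problem, within-pair (case minus
    control) differences.  The conditional log likelihood is
    sum_i log sigma(x_i' beta).  Returns (beta, se, ok) where ``ok`` is False
    on separation or singular curvature; the standard error reported is for
    the first (exposure) coefficient pattern-free via the inverse observed
    information.
    """
    P, n, k = Xs.shape
    beta = np.zeros((P, k))
    ok = np.ones(P, dtype=bool)
    eye = np.eye(k) * 1e-12
    for _ in range(_NEWTON_MAXITER):
        eta = np.einsum("pnk,pk->pn", Xs, beta)
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        grad = np.einsum("pnk,pn->pk", Xs, 1.0 - prob)
        w = prob * (1.0 - prob)
        info = np.einsum("pnk,pn,pnl->pkl", Xs, w, Xs) + eye
        try:
            step = np.linalg.solve(info, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            ok[:] = False
            break
        beta = beta + step
        if np.abs(step).max() < _NEWTON_TOL:
            break
    diverged = np.abs(beta).max(axis=1) > _SEPARATION_BOUND
    ok &= ~diverged
    eta = np.einsum("pnk,pk->pn", Xs, beta)
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = prob * (1.0 - prob)
    info = np.einsum("pnk,pn,pnl->pkl", Xs, w, Xs) + np.eye(k) * 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.einsum("pkk->pk", cov))
    return beta, se, ok


def clr_fit(exposure_diff, covariate_diffs=None) -> dict:
    """Conditional logistic regression on within-pair differences.

    ``exposure_diff`` is the per-pair case-minus-control difference of the
    exposure (e.g. methylation rank); ``covariate_diffs`` an optional
    (n_pairs, n_cov) array of covariate differences.  Returns the exposure
    coefficient, its standard error and a Wald p-value (normal reference).

    An exposure that never differs within a pair carries no information:
    coefficient 0, p = 1.  Separation (unbounded likelihood) is flagged with
    an NaN p-value.
    """
    d = np.asarray(exposure_diff, dtype=float).reshape(-1, 1)
    if covariate_diffs is not None:
        C = np.asarray(covariate_diffs, dtype=float)
        if C.ndim == 1:
            C = C.reshape(-1, 1)
        X = np.hstack([d, C])
    else:
        X = d
    if X.shape[0] == 0:
        raise ValueError("no informative pairs")
    if np.all(d == 0):
        return {"coefficient": 0.0, "se": np.nan, "p": 1.0, "converged": True}
    beta, se, ok = _clr_newton(X[None, :, :])
    if not ok[0]:
        return {"coefficient": np.nan, "se": np.nan, "p": np.nan, "converged": False}
    coef, s = float(beta[0, 0]), float(se[0, 0])
    z = coef / s if s > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return {"coefficient": coef, "se": s, "p": p, "converged": True}


def cluster_events(p_values, coefficients, alpha: float = EVENT_ALPHA) -> dict:
    """Cluster summary: N (significant probes of the majority coefficient
    sign) and Pmin (minimal probe p-value)."""
    p = np.asarray(p_values, dtype=float)
    coef = np.asarray(coefficients, dtype=float)
    valid = np.isfinite(p)
    if not valid.any():
        return {"N": 0, "Pmin": np.nan}
    sig = valid & (p < alpha)
    n_pos = int(np.sum(sig & (coef > 0)))
    n_neg = int(np.sum(sig & (coef < 0)))
    return {"N": max(n_pos, n_neg), "Pmin": float(np.nanmin(p[valid]))}


def recurrence(n_by_type) -> int:
    """Number of cancer types with at least two significant concordant probes."""
    arr = np.asarray(list(n_by_type))
    if arr.size == 0:
        raise ValueError("no cancer types evaluated")
    return int(np.sum(arr >= 2))


def _study_differences(
    matrix: MethylationMatrix, study: MatchedStudy, probe_ids
) -> tuple[np.ndarray, np.ndarray | None]:
    """Cached within-pair differences: rank-normalized M-value differences
    (probes, pairs) and covariate differences (pairs, n_cov)."""
    samples = study.pairs.left + study.pairs.right
    betas = matrix.beta.loc[list(probe_ids), samples].to_numpy(dtype=float)
    ranks = rank_normalize(beta_to_m(betas))
    n_pairs = len(study.pairs)
    expo_diff = ranks[:, :n_pairs] - ranks[:, n_pairs:]
    cov_diff = None
    if study.covariates is not None and study.covariates.shape[1] > 0:
        cases = study.covariates.loc[study.pairs.left].to_numpy(dtype=float)
        controls = study.covariates.loc[study.pairs.right].to_numpy(dtype=float)
        cov_diff = cases - controls
    return expo_diff, cov_diff


def _fit_probes(expo_diff: np.ndarray, cov_diff: np.ndarray | None):
    """Batched CLR over probes sharing one study's covariate differences."""
    P, n = expo_diff.shape
    if cov_diff is not None:
        k = 1 + cov_diff.shape[1]
        Xs = np.empty((P, n, k))
        Xs[:, :, 0] = expo_diff
        Xs[:, :, 1:] = cov_diff[None, :, :]
    else:
        Xs = expo_diff[:, :, None]
    beta, se, ok = _clr_newton(Xs)
    coef = beta[:, 0]
    s = se[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(s > 0, coef / s, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
    uninformative = np.all(expo_diff == 0, axis=1)
    coef = np.where(uninformative, 0.0, coef)
    p = np.where(uninformative, 1.0, p)
    p = np.where(ok, p, np.nan)
    coef = np.where(ok, coef, np.nan)
    return coef, p


def probe_associations(
    matrix: MethylationMatrix, study: MatchedStudy, probe_ids
) -> pd.DataFrame:
    """Observed per-probe CLR coefficients and p-values for one study."""
    expo_diff, cov_diff = _study_differences(matrix, study, probe_ids)
    coef, p = _fit_probes(expo_diff, cov_diff)
    return pd.DataFrame(
        {"probe_id": list(probe_ids), "coefficient": coef, "p": p}
    ).set_index("probe_id")


def permutation_test(
    matrix: MethylationMatrix,
    studies: list[MatchedStudy],
    clusters: list[ClusterDef],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = EVENT_ALPHA,
) -> pd.DataFrame:
    """Permutation calibration of cluster events across matched studies.

    For each permutation the case/control status is reassigned independently
    within every pair (probability 1/2), probe-level CLRs are refit from the
    cached within-pair differences (only the difference signs flip), and the
    cluster events are recounted.  Event i is counted per (cluster, cancer
    type) when N_rnd >= N_obs and Pmin_rnd <= Pmin_obs; event ii per cluster
    when Recurrence_rnd >= Recurrence_obs.  P-values use (r + 1) / (n + 1).
    """
    if not clusters:
        raise ValueError("no clusters supplied")
    if seed is None:
        raise ValueError("a seed is required for reproducible permutations")
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-value resolution is coarse", n_perm)
    rng = np.random.default_rng(seed)

    probe_order: list[str] = []
    cluster_slices: list[tuple[str, slice]] = []
    available = set(matrix.probe_ids)
    for cluster in clusters:
        present = [p for p in cluster.probe_ids if p in available]
        if len(present) < 1:
            continue
        start = len(probe_order)
        probe_order.extend(present)
        cluster_slices.append((cluster.cluster_id, slice(start, start + len(present))))
    if not cluster_slices:
        raise ValueError("no cluster probes present in the matrix")
    cluster_ids = [cid for cid, _ in cluster_slices]
    n_clusters = len(cluster_slices)
    n_types = len(studies)

    expo: list[np.ndarray] = []
    cov: list[np.ndarray | None] = []
    n_obs = np.zeros((n_clusters, n_types), dtype=int)
    pmin_obs = np.full((n_clusters, n_types), np.nan)
    for t, study in enumerate(studies):
        e, c = _study_differences(matrix, study, probe_order)
        expo.append(e)
        cov.append(c)
        coef, p = _fit_probes(e, c)
        for ci, (_, sl) in enumerate(cluster_slices):
            ev = cluster_events(p[sl], coef[sl], alpha=alpha)
            n_obs[ci, t] = ev["N"]
            pmin_obs[ci, t] = ev["Pmin"]
    rec_obs = (n_obs >= 2).sum(axis=1)

    count_i = np.zeros((n_clusters, n_types), dtype=int)
    count_ii = np.zeros(n_clusters, dtype=int)
    for _ in range(n_perm):
        n_rnd = np.zeros((n_clusters, n_types), dtype=int)
        pmin_rnd = np.full((n_clusters, n_types), np.nan)
        for t, study in enumerate(studies):
            flips = np.where(rng.random(len(study.pairs)) < 0.5, 1.0, -1.0)
            e = expo[t] * flips[None, :]
            c = cov[t] * flips[:, None] if cov[t] is not None else None
            coef, p = _fit_probes(e, c)
            for ci, (_, sl) in enumerate(cluster_slices):
                ev = cluster_events(p[sl], coef[sl], alpha=alpha)
                n_rnd[ci, t] = ev["N"]
                pmin_rnd[ci, t] = ev["Pmin"]
        with np.errstate(invalid="ignore"):
            hit_i = (n_rnd >= n_obs) & (pmin_rnd <= pmin_obs)
        count_i += np.where(np.isnan(pmin_obs), 0, hit_i)
        rec_rnd = (n_rnd >= 2).sum(axis=1)
        count_ii += rec_rnd >= rec_obs

    p_i = (count_i + 1.0) / (n_perm + 1.0)
    p_i[np.isnan(pmin_obs)] = np.nan  # cluster never informative in this study
    p_ii = (count_ii + 1.0) / (n_perm + 1.0)
    size_by_id = {c.cluster_id: c.size for c in clusters}
    rows = []
    for ci, cid in enumerate(cluster_ids):
        for t, study in enumerate(studies):
            rows.append(
                {
                    "cluster_id": cid,
                    "cancer_type": study.cancer_type,
                    "n_probes": size_by_id[cid],
                    "n_obs": int(n_obs[ci, t]),
                    "pmin_obs": pmin_obs[ci, t],
                    "recurrence_obs": int(rec_obs[ci]),
                    "p_event_i": float(p_i[ci, t]),
                    "p_event_ii": float(p_ii[ci]),
                    "n_permutations": n_perm,
                }
            )
    return pd.DataFrame(rows)


def select_significant_clusters(
    results: pd.DataFrame,
    top_k: int = TOP_K_CLUSTERS,
    fdr: float = CLUSTER_FDR,
) -> pd.DataFrame:
    """FDR selection over the most CpG-rich clusters.

    Restricts to the ``top_k`` clusters by probe count (ties by cluster_id),
    BH-adjusts event-i p-values within each cancer type, and flags q < fdr.
    """
    sizes = (
        results[["cluster_id", "n_probes"]]
        .drop_duplicates()
        .sort_values(["n_probes", "cluster_id"], ascending=[False, True])
    )
    keep_ids = sizes["cluster_id"].head(top_k)
    subset = results[results["cluster_id"].isin(keep_ids)].copy()
    subset["q"] = np.nan
    for _, idx in subset.groupby("cancer_type").groups.items():
        subset.loc[idx, "q"] = bh_fdr(subset.loc[idx, "p_event_i"])
    subset["is_significant"] = subset["q"] < fdr
    return subset
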