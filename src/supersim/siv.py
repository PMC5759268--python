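"""Systemic interindividual variation (SIV) screening.

An individuals × tissues methylation panel spanning the three embryonic germ
layers separates two sources of variation at each probe: interindividual
variation (range of per-individual means taken across tissues) and
tissue-specific variation (range of per-tissue means taken across
individuals).  Probes where interindividual variation is large and dominates
tissue-specific variation vary systemically — consistent with methylation
established before gastrulation and maintained in all lineages.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethylationMatrix

logger = logging.getLogger("supersim.siv")

SIV_INTER_MIN = 0.2
SIV_TISSUE_RATIO_MAX = 1.0 / 3.0
INTERTISSUE_R2_MIN = 0.50
NEGATIVE_RANGE_MIN = 0.4
NEGATIVE_NORM_MZ_MIN = 0.5
NEGATIVE_TISSUE_FACTOR = 2.0


@dataclass
class TissuePanel:
    """Methylation matrix whose samples map to (individual, tissue) cells."""

    matrix: MethylationMatrix
    sample_map: pd.DataFrame  # index sample_id; columns individual_id, tissue

    def __post_init__(self) -> None:
        required = {"individual_id", "tissue"}
        if not required.issubset(self.sample_map.columns):
            raise ValueError(f"sample map needs columns {sorted(required)}")
        cells = self.sample_map[["individual_id", "tissue"]]
        if cells.duplicated().any():
            raise ValueError("each (individual, tissue) cell may occur at most once")
        if self.sample_map["individual_id"].nunique() < 2:
            raise ValueError("panel needs at least two individuals")
        if self.sample_map["tissue"].nunique() < 2:
            raise ValueError("panel needs at least two tissues")
        missing = set(self.sample_map.index) - set(self.matrix.sample_ids)
        if missing:
            raise ValueError(f"samples absent from matrix: {sorted(missing)[:5]}")

    @property
    def individuals(self) -> list:
        return sorted(self.sample_map["individual_id"].unique())

    @property
    def tissues(self) -> list:
        return sorted(self.sample_map["tissue"].unique())

    def cube(self) -> np.ndarray:
        """Betas as (probes, individuals, tissues); absent cells are NaN."""
        individuals = self.individuals
        tissues = self.tissues
        n_probes = self.matrix.shape[0]
        out = np.full((n_probes, len(individuals), len(tissues)), np.nan)
        ind_idx = {v: i for i, v in enumerate(individuals)}
        tis_idx = {v: i for i, v in enumerate(tissues)}
        values = self.matrix.beta
        for sample_id, row in self.sample_map.iterrows():
            out[:, ind_idx[row["individual_id"]], tis_idx[row["tissue"]]] = values[
                sample_id
            ].to_numpy(dtype=float)
        return out


def _ranges(cube: np.ndarray, axis_mean: int, complete_case: bool) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        means = np.nanmean(cube, axis=axis_mean)  # (probes, groups)
        if complete_case:
            incomplete = np.isnan(cube).any(axis=(1, 2))
            means[incomplete, :] = np.nan
        return np.nanmax(means, axis=1) - np.nanmin(means, axis=1)


def interindividual_variation(panel: TissuePanel, complete_case: bool = True) -> pd.Series:
    """Range across individuals of each individual's cross-tissue mean beta.

    With ``complete_case`` (the default, mirroring a strict all-samples
    filter) any probe missing a value in any panel cell is excluded (NaN).
    """
    with np.errstate(invalid="ignore"):
        out = _ranges(panel.cube(), axis_mean=2, complete_case=complete_case)
    return pd.Series(out, index=panel.matrix.beta.index, name="interindividual_var")


def tissue_variation(panel: TissuePanel, complete_case: bool = True) -> pd.Series:
    """Range across tissues of each tissue's cross-individual mean beta."""
    with np.errstate(invalid="ignore"):
        out = _ranges(panel.cube(), axis_mean=1, complete_case=complete_case)
    return pd.Series(out, index=panel.matrix.beta.index, name="tissue_var")


def classify_siv(
    interindividual_var,
    tissue_var,
    inter_min: float = SIV_INTER_MIN,
    tissue_ratio_max: float = SIV_TISSUE_RATIO_MAX,
):
    """SIV call: interindividual range strictly above ``inter_min`` and
    tissue-specific range strictly below ``tissue_ratio_max`` times it."""
    inter = np.asarray(interindividual_var, dtype=float)
    tis = np.asarray(tissue_var, dtype=float)
    ok = (inter > inter_min) & (tis < tissue_ratio_max * inter)
    result = np.where(np.isnan(inter) | np.isnan(tis), False, ok)
    return bool(result) if result.ndim == 0 else result.astype(bool)


def siv_screen(
    panel: TissuePanel,
    inter_min: float = SIV_INTER_MIN,
    tissue_ratio_max: float = SIV_TISSUE_RATIO_MAX,
    complete_case: bool = True,
) -> pd.DataFrame:
    """Per-probe SIV screen over a tissue panel."""
    inter = interindividual_variation(panel, complete_case=complete_case)
    tis = tissue_variation(panel, complete_case=complete_case)
    records = pd.DataFrame(
        {
            "probe_id": panel.matrix.beta.index,
            "interindividual_var": inter,
            "tissue_var": tis,
        },
        index=panel.matrix.beta.index,
    )
    records["is_siv"] = classify_siv(inter, tis, inter_min, tissue_ratio_max)
    logger.info("SIV screen: %d probes, %d SIV", len(records), int(records["is_siv"].sum()))
    return records


def select_negative_controls(
    twin_records: pd.DataFrame,
    siv_records: pd.DataFrame,
    range_min: float = NEGATIVE_RANGE_MIN,
    norm_mz_min: float = NEGATIVE_NORM_MZ_MIN,
    tissue_factor: float = NEGATIVE_TISSUE_FACTOR,
) -> pd.Index:
    """Negative-control probes: variable between individuals like ESS probes
    but with no evidence of supersimilarity or systemic variation.

    Criteria: interindividual beta range > ``range_min`` in the twin screen,
    normalized MZ MSE > ``norm_mz_min``, and tissue-specific variation at
    least ``tissue_factor`` times interindividual variation in the panel.
    """
    joined = twin_records.join(
        siv_records[["interindividual_var", "tissue_var"]], how="inner"
    )
    keep = (
        (joined["beta_range"] > range_min)
        & (joined["norm_mz"] > norm_mz_min)
        & (joined["tissue_var"] >= tissue_factor * joined["interindividual_var"])
    )
    return joined.index[keep.fillna(False)]


def intertissue_correlation_call(
    locus_means: pd.DataFrame,
    r2_min: float = INTERTISSUE_R2_MIN,
    require_all: bool = True,
) -> dict:
    """Targeted (pyrosequencing-style) SIV call from locus-average methylation.

    ``locus_means`` is individuals × tissues (locus-average methylation per
    cadaver and tissue).  Pearson correlations are computed for every tissue
    pair across individuals; the locus is called SIV-positive when the
    squared correlation exceeds ``r2_min`` for all pairs (or for at least one
    pair with ``require_all=False``).  A tissue with zero variance makes its
    correlations undefined and the call negative.
    """
    if locus_means.shape[0] < 3:
        raise ValueError("need at least 3 individuals for the correlation call")
    tissues = list(locus_means.columns)
    pairwise: dict[tuple, float] = {}
    undefined = False
    for t1, t2 in itertools.combinations(tissues, 2):
        x = locus_means[t1].to_numpy(dtype=float)
        y = locus_means[t2].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            pairwise[(t1, t2)] = np.nan
            undefined = True
            continue
        pairwise[(t1, t2)] = float(np.corrcoef(x, y)[0, 1])
    r2 = {k: v**2 for k, v in pairwise.items()}
    if undefined:
        call = False
    elif require_all:
        call = all(v > r2_min for v in r2.values())
    else:
        call = any(v > r2_min for v in r2.values())
    return {"pairwise_r": pairwise, "pairwise_r2": r2, "is_siv": call, "undefined": undefined}
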