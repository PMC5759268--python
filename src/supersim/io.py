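"""Tabular I/O and value transforms shared by every pipeline stage.

The universal container is the :class:`MethylationMatrix`: a probes × samples
matrix of beta values (fraction methylated, in [0, 1], missing permitted).
Probe annotations are BED-derived (0-based positions) and sample sheets carry
grouping labels (twin pairs, tissues, seasons, case-control matching) plus
numeric covariates.  Validation is fail-fast: out-of-range betas and duplicate
identifiers raise instead of being silently coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("supersim")

#: clamp width applied to beta values of exactly 0 or 1 before the M-transform
DEFAULT_EPSILON = 1e-6

#: tolerance for beta range validation on read (floating point slack only)
BETA_TOLERANCE = 1e-9

#: deterministic column order of the per-probe twin-screen table
SCREEN_COLUMNS = [
    "probe_id",
    "mse_mz",
    "mse_dz",
    "mse_rz",
    "norm_mz",
    "norm_dz",
    "variance",
    "beta_range",
    "is_top_variance",
    "is_ess",
    "is_negative_control",
]

ANNOTATION_COLUMNS = ["chrom", "pos", "probe_id", "cpg_island", "gene", "h2", "beta_snp"]


class MatrixFormatError(ValueError):
    """Structural problem in a tabular input (duplicate IDs, bad header)."""


@dataclass
class MethylationMatrix:
    """Probes × samples beta-value matrix.

    Parameters
    ----------
    beta
        DataFrame indexed by probe ID with sample-ID columns; values are
        fractions in [0, 1], NaN marks missing measurements.
    """

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            dupes = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate probe IDs: {dupes[:5]}")
        if self.beta.columns.has_duplicates:
            dupes = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample IDs: {dupes[:5]}")
        values = self.beta.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (
            finite.min() < -BETA_TOLERANCE or finite.max() > 1.0 + BETA_TOLERANCE
        ):
            raise ValueError(
                "beta values outside [0, 1]: "
                f"min={finite.min():.6g}, max={finite.max():.6g}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def values_for(self, sample_ids) -> np.ndarray:
        """Beta sub-matrix for the given samples, as a float array."""
        missing = [s for s in sample_ids if s not in self.beta.columns]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        return self.beta.loc[:, list(sample_ids)].to_numpy(dtype=float)


@dataclass
class PairSet:
    """Ordered list of sample-ID pairs sharing one pair class.

    ``pair_class`` is one of ``MZ`` (monozygotic), ``DZ`` (dizygotic),
    ``RZ`` (randomized pseudo-pairs of unrelated individuals) or ``CC``
    (matched case-control, ordered case first).
    """

    pairs: list[tuple[str, str]]
    pair_class: str = "MZ"

    def __post_init__(self) -> None:
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise ValueError(f"a sample appears twice in the {self.pair_class} PairSet")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def left(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def right(self) -> list[str]:
        return [b for _, b in self.pairs]


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    return "," if str(path).endswith(".csv") else "\t"


def read_methylation_matrix(path, dialect: str | None = None) -> MethylationMatrix:
    """Read a probes-as-rows beta matrix from TSV/CSV.

    First column holds probe IDs, header row holds sample IDs.  Empty fields
    and ``NA`` are missing.  Betas outside [0, 1] (beyond a 1e-9 slack) and
    duplicated IDs raise.
    """
    frame = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0, na_values=["NA"])
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    logger.info("read methylation matrix %s: %d probes x %d samples", path, *frame.shape)
    return MethylationMatrix(frame.astype(float))


def write_methylation_matrix(matrix: MethylationMatrix, path, dialect: str | None = None) -> None:
    matrix.beta.to_csv(path, sep=_sep_for(path, dialect), index_label="probe_id", na_rep="NA")


def read_probe_annotation(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a BED-derived probe annotation table.

    Expected columns: chrom, pos (0-based), probe_id, cpg_island, gene, h2,
    beta_snp — the latter three optional.  Returns a DataFrame indexed by
    probe_id.
    """
    frame = pd.read_csv(path, sep=_sep_for(path, dialect), na_values=["NA", "."])
    required = {"chrom", "pos", "probe_id"}
    if not required.issubset(frame.columns):
        raise MatrixFormatError(
            f"annotation must contain columns {sorted(required)}, got {list(frame.columns)}"
        )
    if frame["probe_id"].duplicated().any():
        raise MatrixFormatError("duplicate probe IDs in annotation")
    if (frame["pos"] < 0).any():
        raise ValueError("annotation positions must be non-negative")
    for col in ("h2", "beta_snp"):
        if col in frame and (frame[col].dropna() < 0).any():
            raise ValueError(f"annotation column {col} must be non-negative")
    if "cpg_island" in frame:
        frame["cpg_island"] = frame["cpg_island"].astype(bool)
    return frame.set_index("probe_id", drop=False)


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c in annotation.columns]
    annotation.to_csv(path, sep="\t", columns=cols, index=False, na_rep="NA")


def read_sample_sheet(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a sample sheet; sample_id must be unique, pair_id (if present)
    must occur exactly twice per pair."""
    frame = pd.read_csv(path, sep=_sep_for(path, dialect), na_values=["NA"])
    if "sample_id" not in frame.columns:
        raise MatrixFormatError("sample sheet must contain a sample_id column")
    frame["sample_id"] = frame["sample_id"].astype(str)
    if frame["sample_id"].duplicated().any():
        raise MatrixFormatError("duplicate sample IDs in sample sheet")
    if "pair_id" in frame.columns:
        counts = frame["pair_id"].dropna().value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise MatrixFormatError(
                f"pair_id values must occur exactly twice; offending: {bad.index.tolist()[:5]}"
            )
    return frame.set_index("sample_id", drop=False)


def beta_to_m(beta, epsilon: float | None = DEFAULT_EPSILON):
    """M-value transform, M = log2(beta / (1 - beta)).

    Betas of exactly 0 or 1 are clamped into [epsilon, 1 - epsilon] first;
    pass ``epsilon=None`` to disable clamping, in which case boundary values
    raise a domain error.  NaN propagates.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_domain = (arr <= 0.0) | (arr >= 1.0)
    if epsilon is None:
        if np.any(out_of_domain & np.isfinite(arr)):
            raise ValueError("beta outside open interval (0, 1) and clamping disabled")
        clamped = arr
    else:
        clamped = np.clip(arr, epsilon, 1.0 - epsilon)
    m = np.log2(clamped / (1.0 - clamped))
    return m if np.ndim(beta) else float(m)


def m_to_beta(m):
    """Inverse M-value transform, beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-arr))
    return beta if np.ndim(m) else float(beta)


def write_screen_table(records: pd.DataFrame, path) -> None:
    """Write a per-probe twin-screen table with deterministic column order."""
    frame = records.copy()
    for col in SCREEN_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame[SCREEN_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_screen_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("is_top_variance", "is_ess", "is_negative_control"):
        if col in frame.columns:
            frame[col] = frame[col].astype("boolean").astype(object)
    return frame


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the requested level."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


@dataclass
class ProbeScreenRecord:
    """One row of the twin-screen table (see :data:`SCREEN_COLUMNS`)."""

    probe_id: str
    mse_mz: float = np.nan
    mse_dz: float = np.nan
    mse_rz: float = np.nan
    norm_mz: float = np.nan
    norm_dz: float = np.nan
    variance: float = np.nan
    beta_range: float = np.nan
    is_top_variance: bool = False
    is_ess: bool = False
    is_negative_control: bool = False

    extras: dict = field(default_factory=dict, repr=False)
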