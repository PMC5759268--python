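"""Probe-set enrichment machinery: 2x2 folds and tests, genomic flags, FDR.

Enrichment of a probe set for a feature (SIV membership, CpG islands,
subtelomeric location, seasonal differential methylation, ...) is always
computed against a caller-supplied background — there is no implicit probe
universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

SUBTELOMERIC_WINDOW = 2_000_000  # bp from either chromosome end


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (a, b) = set with/without feature, (c, d) = background
    with/without feature.  The background is used exactly as supplied — pass
    the complement explicitly when the comparison is set vs non-set."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_sets(cls, probe_set, feature, background) -> "TwoByTwo":
        s, f, bg = set(probe_set), set(feature), set(background)
        a = len(s & f)
        b = len(s - f)
        c = len(bg & f)
        d = len(bg - f)
        return cls(a, b, c, d)


def fold_enrichment(t: TwoByTwo) -> float:
    """Rate ratio (a/(a+b)) / (c/(c+d)); +inf when the background rate is 0."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("both the set and the background must be non-empty")
    set_rate = t.a / (t.a + t.b)
    bg_rate = t.c / (t.c + t.d)
    if bg_rate == 0:
        return float("inf") if set_rate > 0 else float("nan")
    return set_rate / bg_rate


def chisq_enrichment(t: TwoByTwo) -> dict:
    """Pearson chi-squared on the 2x2 (no continuity correction), df = 1."""
    table = t.table
    if table.sum(axis=0).min() <= 0 or table.sum(axis=1).min() <= 0:
        raise ValueError("all margins must be positive")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 1:
        warnings.warn("expected cell count < 1; Fisher's exact test is recommended")
    statistic = float(((table - expected) ** 2 / expected).sum())
    return {"statistic": statistic, "p": float(stats.chi2.sf(statistic, df=1))}


def fisher_enrichment(t: TwoByTwo, sided: str = "greater") -> float:
    """Fisher's exact (hypergeometric) p-value; one-sided greater by default."""
    table = t.table.astype(int)
    if table.sum(axis=0).min() <= 0 or table.sum(axis=1).min() <= 0:
        raise ValueError("all margins must be positive")
    _, p = stats.fisher_exact(table, alternative=sided)
    return float(p)


def subtelomeric_flag(position: int, chrom_length: int, window: int = SUBTELOMERIC_WINDOW) -> bool:
    """True when the position lies strictly within ``window`` bp of either
    chromosome end."""
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    return bool(position < window or position > chrom_length - window)


def subtelomeric_flags(annotation, chrom_lengths: dict, window: int = SUBTELOMERIC_WINDOW):
    """Vectorized subtelomeric flag over an annotation table.

    Raises a lookup error for chromosomes absent from ``chrom_lengths``.
    """
    unknown = set(annotation["chrom"].unique()) - set(chrom_lengths)
    if unknown:
        raise KeyError(f"no length for chromosomes: {sorted(unknown)}")
    lengths = annotation["chrom"].map(chrom_lengths).to_numpy(dtype=float)
    pos = annotation["pos"].to_numpy(dtype=float)
    return (pos < window) | (pos > lengths - window)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        _, q_adj, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = q_adj
    return q
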