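"""Genotype-methylation association at candidate supersimilar loci.

Two complementary views: linear regression of locus-average methylation on
additively coded genotype (mean shift: the classical methylation QTL), and
Bartlett's test for unequal methylation variance between genotype classes
(variance shift: genotype modulating the spread of a stochastic methylation
distribution, the signature of genotype-dependent metastability).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SUBSTANTIAL_MQTL_THRESHOLD = 0.33


def mqtl_regression(genotype, methylation) -> dict:
    """OLS of methylation on additively coded genotype (allele count 0/1/2).

    Returns slope, intercept, two-sided p for the slope, and R² (the internal
    variance-explained estimate; distinct from an externally supplied
    beta_snp annotation).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(methylation, dtype=float)
    keep = np.isfinite(g) & np.isfinite(y)
    g, y = g[keep], y[keep]
    if g.size < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(g).size < 2:
        raise ValueError("degenerate design: a single genotype class present")
    fit = stats.linregress(g, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p": float(fit.pvalue),
        "r_squared": float(fit.rvalue**2),
    }


def variance_heterogeneity(*groups) -> dict:
    """Bartlett's test for equality of variances across genotype classes."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least two genotype classes")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every class needs at least two observations")
    if any(np.var(a, ddof=1) == 0 for a in arrays):
        raise ValueError(
            "zero within-class variance; Bartlett's test is undefined "
            "(consider a non-parametric spread comparison)"
        )
    statistic, _ = stats.bartlett(*arrays)
    # p from the chi-squared(k-1) reference directly: scipy's own p-value is
    # NaN for a statistic of exactly zero (identical sample variances)
    p = stats.chi2.sf(statistic, df=len(arrays) - 1)
    return {"bartlett_statistic": float(statistic), "p": float(p)}


def homozygote_variance_test(data: pd.DataFrame) -> dict:
    """Bartlett comparison restricted to the two homozygote classes (0 vs 2)."""
    groups = [
        data.loc[data["genotype"] == cls, "avg_methylation"].to_numpy()
        for cls in (0, 2)
    ]
    return variance_heterogeneity(*groups)


def flag_substantial_mqtl(beta_snp, threshold: float = SUBSTANTIAL_MQTL_THRESHOLD):
    """Substantial-mQTL flag: externally estimated variance explained by
    neighboring SNPs strictly above the threshold.  Missing values yield
    pandas NA (probe neither positive nor negative)."""
    arr = np.asarray(beta_snp, dtype=float)
    if np.ndim(beta_snp) == 0:
        if np.isnan(arr):
            return pd.NA
        return bool(arr > threshold)
    out = pd.array(arr > threshold, dtype="boolean")
    out[np.isnan(arr)] = pd.NA
    return out


def categorical_anova(genotype, methylation) -> dict:
    """One-way ANOVA across genotype classes (non-additive alternative)."""
    g = np.asarray(genotype)
    y = np.asarray(methylation, dtype=float)
    groups = [y[g == cls] for cls in np.unique(g)]
    if len(groups) < 2:
        raise ValueError("degenerate design: a single genotype class present")
    statistic, p = stats.f_oneway(*groups)
    return {"f_statistic": float(statistic), "p": float(p)}
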