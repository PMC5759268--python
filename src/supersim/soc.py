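"""Season-of-conception (SoC) EWAS stage.

In rural Gambia, conceptions at the peak of the rainy (July-September) versus
dry (February-April) season expose the periconceptional embryo to contrasting
maternal nutrition.  Each probe's beta value is modeled by robust (Huber)
linear regression on season with sex, principal-component scores and
cell-type proportions as covariates; probes at FDR < 10% are season-of-
conception differentially methylated probes (SoC-DMPs).  Probe sets are then
tested for SoC-DMP enrichment with Fisher's exact test.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .enrichment import TwoByTwo, bh_fdr, fisher_enrichment, fold_enrichment
from .io import MethylationMatrix

logger = logging.getLogger("supersim.soc")

DRY_MONTHS = (2, 3, 4)     # February-April
RAINY_MONTHS = (7, 8, 9)   # July-September
GESTATION_DAYS = 280
DMP_FDR = 0.10
HUBER_T = 1.345
RLM_TOL = 1e-8
RLM_MAXITER = 50


def assign_season(
    conception_date: dt.date | str | None = None,
    birth_date: dt.date | str | None = None,
    gestation_offset: int = GESTATION_DAYS,
) -> str:
    """DRY / RAINY / OUT_OF_WINDOW season of conception.

    Either the conception date is given directly, or it is inferred from the
    birth date minus a gestation offset (default 280 days).
    """
    if conception_date is None:
        if birth_date is None:
            raise ValueError("provide conception_date or birth_date")
        birth = _parse_date(birth_date)
        conception = birth - dt.timedelta(days=gestation_offset)
    else:
        conception = _parse_date(conception_date)
    if conception.month in DRY_MONTHS:
        return "DRY"
    if conception.month in RAINY_MONTHS:
        return "RAINY"
    return "OUT_OF_WINDOW"


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def robust_fit(y, design: pd.DataFrame) -> dict:
    """Huber M-estimation of one probe's beta values on a design matrix.

    IRLS with tuning constant 1.345 and MAD scale; normal-reference two-sided
    p-values per coefficient.  Non-convergence is flagged and yields NaN
    p-values; a constant response returns zero for every non-intercept
    coefficient.
    """
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    if y.size <= X.shape[1] + 2:
        raise ValueError("too few samples for the number of coefficients")
    names = list(X.columns)
    if np.ptp(y) == 0:
        coefs = {name: 0.0 for name in names}
        coefs["const"] = float(y[0])
        return {
            "coefficients": coefs,
            "robust_se": {name: np.nan for name in names},
            "p": {name: np.nan for name in names},
            "converged": True,
        }
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T))
    try:
        result = model.fit(
            scale_est="mad", maxiter=RLM_MAXITER, tol=RLM_TOL, conv="coefs"
        )
        converged = bool(getattr(result, "converged", True))
    except (np.linalg.LinAlgError, ValueError):
        nan = {name: np.nan for name in names}
        return {"coefficients": nan, "robust_se": nan, "p": nan, "converged": False}
    z = result.params / result.bse
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {
        "coefficients": dict(zip(names, map(float, result.params))),
        "robust_se": dict(zip(names, map(float, result.bse))),
        "p": dict(zip(names, map(float, p))),
        "converged": converged,
    }


def soc_scan(
    matrix: MethylationMatrix,
    design: pd.DataFrame,
    season_column: str = "season",
    fdr: float = DMP_FDR,
) -> pd.DataFrame:
    """Per-probe robust regression of beta on season with covariates.

    ``design`` is indexed by sample ID, with a ``season`` column coded
    DRY/RAINY (or 0/1) and any further numeric columns treated as covariates.
    The effect is the adjusted RAINY-minus-DRY beta difference.  BH FDR is
    computed across all tested probes; ``is_dmp`` flags q < ``fdr``.
    """
    samples = [s for s in matrix.sample_ids if s in design.index]
    if not samples:
        raise ValueError("no overlap between matrix samples and design")
    design = design.loc[samples]
    season = design[season_column]
    if season.dtype == object:
        season = season.map({"DRY": 0.0, "RAINY": 1.0})
        if season.isna().any():
            raise ValueError("season column must be DRY/RAINY (or numeric 0/1)")
    covars = design.drop(columns=[season_column]).select_dtypes("number")
    X = pd.concat([season.rename("season").astype(float), covars], axis=1)

    betas = matrix.beta.loc[:, samples].to_numpy(dtype=float)
    effects = np.full(betas.shape[0], np.nan)
    ses = np.full(betas.shape[0], np.nan)
    pvals = np.full(betas.shape[0], np.nan)
    flags = np.ones(betas.shape[0], dtype=bool)
    for i in range(betas.shape[0]):
        fit = robust_fit(betas[i], X)
        effects[i] = fit["coefficients"].get("season", np.nan)
        ses[i] = fit["robust_se"].get("season", np.nan)
        pvals[i] = fit["p"].get("season", np.nan)
        flags[i] = fit["converged"]
    q = bh_fdr(pvals)
    results = pd.DataFrame(
        {
            "probe_id": matrix.beta.index,
            "effect": effects,
            "se": ses,
            "p": pvals,
            "q": q,
            "converged": flags,
        },
        index=matrix.beta.index,
    )
    results["is_dmp"] = (results["q"] < fdr).fillna(False)
    logger.info(
        "SoC scan: %d probes, %d DMPs at FDR < %.0f%%",
        len(results), int(results["is_dmp"].sum()), 100 * fdr,
    )
    return results


def soc_enrichment(results: pd.DataFrame, probe_set, background) -> dict:
    """Enrichment of a probe set for SoC-DMPs against an explicit background."""
    probe_set = set(probe_set)
    background = set(background)
    if not probe_set:
        raise ValueError("probe set is empty")
    if not probe_set <= background:
        raise ValueError("probe set must be contained in the background")
    dmps = set(results.index[results["is_dmp"]])
    table = TwoByTwo.from_sets(probe_set, dmps, background)
    return {
        "fold": fold_enrichment(table),
        "fisher_p": fisher_enrichment(table, sided="greater"),
        "table": table,
    }
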