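"""Synthetic cohorts embodying the early-embryo establishment model.

Every generator follows the same mechanistic picture: at a locus, a
methylation *state* (one of a few preferred beta levels, trimodal
{0.1, 0.5, 0.9} by default) is assigned per individual and then observed
with Gaussian measurement noise on the beta scale, clipped to [0, 1].  What
differs between locus classes is *when* and *how* the state is drawn:

* ``EARLY_STOCHASTIC`` — the state is drawn once per zygote, before any
  cleavage: monozygotic (MZ) co-twins inherit the same state, dizygotic (DZ)
  co-twins (separate zygotes) draw independently.  This is the regime that
  produces epigenetic supersimilarity.
* ``LATE_STOCHASTIC`` — establishment happens after twinning; every
  individual draws independently.
* ``GENETIC`` — the state is a deterministic additive function of a diploid
  genotype; MZ twins share the genotype, DZ twins share each parental
  haplotype with probability 1/2.
* ``GENETIC_METASTABLE`` — the genotype sets the *spread* of the state
  distribution: one homozygote class is locked to a fixed state while the
  other classes draw from the full distribution (genotype-dependent
  metastability).

Each generator returns a :class:`SimulatedCohort` with complete ground-truth
labels so that every downstream screen can be scored for parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .cancer import ClusterDef, MatchedStudy
from .io import MethylationMatrix, PairSet
from .siv import TissuePanel

logger = logging.getLogger("supersim.simulate")

DEFAULT_STATE_LEVELS = (0.1, 0.5, 0.9)
DEFAULT_STATE_PROBS = (0.25, 0.5, 0.25)
DEFAULT_NOISE_SD = 0.03


class LocusClass(str, Enum):
    EARLY_STOCHASTIC = "EARLY_STOCHASTIC"
    LATE_STOCHASTIC = "LATE_STOCHASTIC"
    GENETIC = "GENETIC"
    GENETIC_METASTABLE = "GENETIC_METASTABLE"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class LocusSpec:
    """Generative description of one locus."""

    locus_class: LocusClass
    state_levels: tuple = DEFAULT_STATE_LEVELS
    state_probs: tuple = DEFAULT_STATE_PROBS
    allele_freq: float = 0.5
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        levels = np.asarray(self.state_levels, dtype=float)
        probs = np.asarray(self.state_probs, dtype=float)
        if levels.size != probs.size:
            raise ConfigError("state_levels and state_probs must align")
        if not np.all(np.diff(levels) > 0):
            raise ConfigError("state_levels must be strictly increasing")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError("state_probs must sum to 1")
        if np.any(probs < 0):
            raise ConfigError("state_probs must be non-negative")
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ConfigError("allele_freq must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    @property
    def span(self) -> float:
        levels = np.asarray(self.state_levels, dtype=float)
        return float(levels.max() - levels.min())

    def genotype_state(self, allele_count) -> np.ndarray:
        """Additive genotype-to-beta mapping: lowest level + count * span/2."""
        low = float(min(self.state_levels))
        return low + np.asarray(allele_count, dtype=float) * (self.span / 2.0)


@dataclass
class SimulatedCohort:
    """A synthetic data set plus the ground truth that generated it."""

    matrix: MethylationMatrix
    truth: pd.DataFrame
    seed: int
    pairs: dict = field(default_factory=dict)        # name -> PairSet
    samples: pd.DataFrame | None = None              # sample sheet
    genotypes: pd.DataFrame | None = None            # probes x samples allele counts
    extras: dict = field(default_factory=dict)


def _finish(values: np.ndarray, noise_sd, rng: np.random.Generator) -> np.ndarray:
    """Add measurement noise on the beta scale and clip into [0, 1]."""
    sd = np.asarray(noise_sd, dtype=float)
    if np.any(sd > 0):
        values = values + rng.normal(0.0, 1.0, size=values.shape) * sd.reshape(-1, 1)
    return np.clip(values, 0.0, 1.0)


def simulate_twin_cohort(
    n_mz: int,
    n_dz: int,
    loci: list[LocusSpec],
    seed: int,
) -> SimulatedCohort:
    """Twin cohort under the pre-/post-cleavage establishment model.

    Returns a cohort whose ``pairs`` dict holds the MZ and DZ pair sets, with
    per-probe truth labels, realized genotypes at genetic loci, and DZ
    haplotype-sharing indicators in ``extras['dz_allele_shared']``
    (probe -> boolean (n_dz, 2) array).
    """
    if n_mz <= 0 or n_dz <= 0:
        raise ConfigError("pair counts must be positive")
    if not loci:
        raise ConfigError("loci must be non-empty")
    rng = np.random.default_rng(seed)

    mz_pairs = [(f"MZ{i:04d}A", f"MZ{i:04d}B") for i in range(n_mz)]
    dz_pairs = [(f"DZ{i:04d}A", f"DZ{i:04d}B") for i in range(n_dz)]
    samples = [s for p in mz_pairs for s in p] + [s for p in dz_pairs for s in p]
    n_samples = len(samples)
    probe_ids = [f"probe{i:05d}" for i in range(len(loci))]

    beta = np.empty((len(loci), n_samples))
    genotype = np.full((len(loci), n_samples), np.nan)
    shared: dict[str, np.ndarray] = {}

    for j, spec in enumerate(loci):
        levels = np.asarray(spec.state_levels, dtype=float)
        probs = np.asarray(spec.state_probs, dtype=float)
        cls = LocusClass(spec.locus_class)
        if cls is LocusClass.EARLY_STOCHASTIC:
            mz_states = rng.choice(levels, size=n_mz, p=probs)
            dz_states = rng.choice(levels, size=(n_dz, 2), p=probs)
            row = np.concatenate([np.repeat(mz_states, 2), dz_states.ravel()])
        elif cls is LocusClass.LATE_STOCHASTIC:
            row = rng.choice(levels, size=n_samples, p=probs)
        else:
            # diploid genotypes: MZ share; DZ share each haplotype w.p. 1/2
            mz_alleles = rng.random((n_mz, 2)) < spec.allele_freq
            a_alleles = rng.random((n_dz, 2)) < spec.allele_freq
            share = rng.random((n_dz, 2)) < 0.5
            fresh = rng.random((n_dz, 2)) < spec.allele_freq
            b_alleles = np.where(share, a_alleles, fresh)
            counts = np.concatenate(
                [
                    np.repeat(mz_alleles.sum(axis=1), 2),
                    np.stack([a_alleles.sum(axis=1), b_alleles.sum(axis=1)], axis=1).ravel(),
                ]
            )
            genotype[j] = counts
            shared[probe_ids[j]] = share
            if cls is LocusClass.GENETIC:
                row = spec.genotype_state(counts)
            else:  # GENETIC_METASTABLE: locked homozygote vs metastable classes
                row = rng.choice(levels, size=n_samples, p=probs)
                row = np.where(counts == 2, levels[-1], row)
        beta[j] = row

    noise = np.array([spec.noise_sd for spec in loci])
    beta = _finish(beta, noise, rng)

    matrix = MethylationMatrix(pd.DataFrame(beta, index=probe_ids, columns=samples))
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "locus_class": [LocusClass(s.locus_class).value for s in loci],
            "noise_sd": noise,
        },
        index=probe_ids,
    )
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "pair_id": [s[:-1] for s in samples],
            "twin_role": [s[-1] for s in samples],
        }
    ).set_index("sample_id", drop=False)
    genotypes = (
        pd.DataFrame(genotype, index=probe_ids, columns=samples)
        if np.isfinite(genotype).any()
        else None
    )
    logger.info("simulated twin cohort: %d loci, %d MZ + %d DZ pairs", len(loci), n_mz, n_dz)
    return SimulatedCohort(
        matrix=matrix,
        truth=truth,
        seed=seed,
        pairs={"MZ": PairSet(mz_pairs, "MZ"), "DZ": PairSet(dz_pairs, "DZ")},
        samples=sheet,
        genotypes=genotypes,
        extras={"dz_allele_shared": shared},
    )


def simulate_multitissue_panel(
    n_individuals: int = 4,
    n_tissues: int = 3,
    systemic_loci: int = 100,
    tissue_specific_loci: int = 100,
    effect: float = 0.4,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> SimulatedCohort:
    """Multi-tissue, multi-individual panel with systemic vs tissue-specific
    structure.

    Systemic loci draw one state per *individual* (from levels
    0.5 ± effect with the usual trimodal weights) shared across all tissues;
    tissue-specific loci draw one state per *tissue* shared across all
    individuals.  The resulting panel is attached as ``extras['panel']``.
    """
    if n_individuals <= 0 or n_tissues <= 0:
        raise ConfigError("counts must be positive")
    if not 0.0 <= effect <= 1.0:
        raise ConfigError("effect must be a delta-beta in [0, 1]")
    rng = np.random.default_rng(seed)
    levels = np.clip(np.array([0.5 - effect, 0.5, 0.5 + effect]), 0.0, 1.0)
    probs = np.asarray(DEFAULT_STATE_PROBS)

    n_loci = systemic_loci + tissue_specific_loci
    individuals = [f"ind{i}" for i in range(n_individuals)]
    tissues = [f"tissue{t}" for t in range(n_tissues)]
    samples = [f"{ind}_{tis}" for ind in individuals for tis in tissues]
    probe_ids = [f"probe{i:05d}" for i in range(n_loci)]

    beta = np.empty((n_loci, len(samples)))
    for j in range(n_loci):
        if j < systemic_loci:
            per_ind = rng.choice(levels, size=n_individuals, p=probs)
            row = np.repeat(per_ind, n_tissues)
        else:
            per_tis = rng.choice(levels, size=n_tissues, p=probs)
            row = np.tile(per_tis, n_individuals)
        beta[j] = row
    beta = _finish(beta, np.full(n_loci, noise_sd), rng)

    matrix = MethylationMatrix(pd.DataFrame(beta, index=probe_ids, columns=samples))
    sample_map = pd.DataFrame(
        {
            "sample_id": samples,
            "individual_id": [s.split("_")[0] for s in samples],
            "tissue": [s.split("_")[1] for s in samples],
        }
    ).set_index("sample_id", drop=False)
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "locus_class": ["SYSTEMIC"] * systemic_loci
            + ["TISSUE_SPECIFIC"] * tissue_specific_loci,
        },
        index=probe_ids,
    )
    panel = TissuePanel(matrix=matrix, sample_map=sample_map)
    return SimulatedCohort(
        matrix=matrix, truth=truth, seed=seed, samples=sample_map, extras={"panel": panel}
    )


def panel_for_loci(
    truth: pd.DataFrame,
    n_individuals: int = 4,
    n_tissues: int = 3,
    effect: float = 0.4,
    noise_sd: float = 0.02,
    background_systemic_frac: float = 0.05,
    seed: int = 0,
) -> TissuePanel:
    """Tissue panel over an existing locus set: loci established before
    cleavage (``EARLY_STOCHASTIC``) vary systemically; other loci vary
    tissue-specifically except for a small fraction
    (``background_systemic_frac``) that is systemic without being
    supersimilar — systemic variation can arise from post-cleavage but
    pre-gastrulation establishment, so the two screens overlap imperfectly.
    Used to link the twin and multi-tissue screens on shared ground truth."""
    rng = np.random.default_rng(seed)
    levels = np.clip(np.array([0.5 - effect, 0.5, 0.5 + effect]), 0.0, 1.0)
    probs = np.asarray(DEFAULT_STATE_PROBS)
    individuals = [f"ind{i}" for i in range(n_individuals)]
    tissues = [f"tissue{t}" for t in range(n_tissues)]
    samples = [f"{ind}_{tis}" for ind in individuals for tis in tissues]

    n_loci = len(truth)
    beta = np.empty((n_loci, len(samples)))
    systemic = (truth["locus_class"] == LocusClass.EARLY_STOCHASTIC.value).to_numpy()
    systemic = systemic | (rng.random(n_loci) < background_systemic_frac)
    for j in range(n_loci):
        if systemic[j]:
            row = np.repeat(rng.choice(levels, size=n_individuals, p=probs), n_tissues)
        else:
            row = np.tile(rng.choice(levels, size=n_tissues, p=probs), n_individuals)
        beta[j] = row
    beta = _finish(beta, np.full(n_loci, noise_sd), rng)
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=truth.index, columns=samples)
    )
    sample_map = pd.DataFrame(
        {
            "sample_id": samples,
            "individual_id": [s.split("_")[0] for s in samples],
            "tissue": [s.split("_")[1] for s in samples],
        }
    ).set_index("sample_id", drop=False)
    return TissuePanel(matrix=matrix, sample_map=sample_map)


def simulate_soc_cohort(
    n: int = 128,
    n_loci: int = 1000,
    n_affected: int = 50,
    seasonal_delta: float = 0.05,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> SimulatedCohort:
    """Two-season cohort with additive season-of-conception effects.

    Affected loci have mean beta higher by ``seasonal_delta`` in
    rainy-conceived samples.  Sex, three principal-component scores, and six
    cell-type proportions are generated as nuisance covariates (no true
    effect) and recorded in the sample sheet.
    """
    if n_affected > n_loci:
        raise ConfigError("n_affected cannot exceed n_loci")
    if n < 4:
        raise ConfigError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    samples = [f"child{i:04d}" for i in range(n)]
    rainy = np.zeros(n, dtype=bool)
    rainy[n // 2 :] = True
    probe_ids = [f"probe{i:05d}" for i in range(n_loci)]

    affected = np.zeros(n_loci, dtype=bool)
    affected[rng.choice(n_loci, size=n_affected, replace=False)] = True
    baseline = rng.uniform(0.2, 0.7, size=n_loci)
    beta = np.tile(baseline[:, None], (1, n))
    beta[np.ix_(affected, rainy)] += seasonal_delta
    beta = _finish(beta, np.full(n_loci, noise_sd), rng)

    # five of the six proportions recorded: all six sum to one and would be
    # collinear with the regression intercept
    cell_props = rng.dirichlet(np.full(6, 8.0), size=n)
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "season": np.where(rainy, "RAINY", "DRY"),
            "sex": rng.integers(0, 2, size=n),
            "pc1": rng.normal(size=n),
            "pc2": rng.normal(size=n),
            "pc3": rng.normal(size=n),
        }
    ).set_index("sample_id", drop=False)
    for k in range(5):
        sheet[f"cell{k}"] = cell_props[:, k]

    matrix = MethylationMatrix(pd.DataFrame(beta, index=probe_ids, columns=samples))
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_affected": affected,
            "effect": np.where(affected, seasonal_delta, 0.0),
        },
        index=probe_ids,
    )
    return SimulatedCohort(matrix=matrix, truth=truth, seed=seed, samples=sheet)


def simulate_matched_casecontrol(
    n_pairs: int,
    clusters: list[ClusterDef],
    affected_clusters,
    delta: float = 0.1,
    noise_sd: float = DEFAULT_NOISE_SD,
    pair_effect_sd: float = 0.05,
    covariates: str = "full",
    cancer_type: str = "simulated_cancer",
    seed: int = 0,
) -> SimulatedCohort:
    """Matched case-control pairs with cluster-level case effects.

    Within each pair the case's methylation at every probe of an affected
    cluster is shifted upward by ``delta`` (delta-beta, concordant sign
    across the cluster).  A shared pair-level random effect models the
    matching structure; with ``covariates="full"`` cell proportions, BMI,
    alcohol and smoking are recorded as within-pair-varying nuisance
    covariates with no true effect (``"none"`` omits them — appropriate for
    toy studies where a nine-column model would be over-parameterized).
    The ready-to-fit :class:`MatchedStudy` is attached as
    ``extras['study']``.
    """
    if n_pairs < 2:
        raise ConfigError("need at least 2 pairs")
    cluster_ids = {c.cluster_id for c in clusters}
    affected = set(affected_clusters)
    if not affected <= cluster_ids:
        raise ConfigError("affected_clusters must be a subset of clusters")
    rng = np.random.default_rng(seed)

    probes = [p for c in clusters for p in c.probe_ids]
    probe_cluster = {p: c.cluster_id for c in clusters for p in c.probe_ids}
    n_probes = len(probes)
    cases = [f"case{i:04d}" for i in range(n_pairs)]
    controls = [f"ctrl{i:04d}" for i in range(n_pairs)]
    samples = cases + controls

    baseline = rng.uniform(0.3, 0.7, size=n_probes)
    pair_effect = rng.normal(0.0, pair_effect_sd, size=(n_probes, n_pairs))
    beta = np.concatenate(
        [baseline[:, None] + pair_effect, baseline[:, None] + pair_effect], axis=1
    )
    is_affected = np.array([probe_cluster[p] in affected for p in probes])
    beta[np.ix_(is_affected, np.arange(n_pairs))] += delta  # cases only
    beta = _finish(beta, np.full(n_probes, noise_sd), rng)

    if covariates == "full":
        cell_props = rng.dirichlet(np.full(6, 8.0), size=2 * n_pairs)
        covariate_table = pd.DataFrame(
            {
                "bmi": rng.normal(27.0, 4.0, size=2 * n_pairs),
                "alcohol": rng.integers(0, 2, size=2 * n_pairs).astype(float),
                "smoking": (rng.random(2 * n_pairs) < 0.3).astype(float),
            },
            index=samples,
        )
        for k in range(5):  # drop one proportion: the six sum to one
            covariate_table[f"cell{k}"] = cell_props[:, k]
    elif covariates == "none":
        covariate_table = None
    else:
        raise ConfigError("covariates must be 'full' or 'none'")

    matrix = MethylationMatrix(pd.DataFrame(beta, index=probes, columns=samples))
    pairs = PairSet(list(zip(cases, controls)), pair_class="CC")
    study = MatchedStudy(cancer_type=cancer_type, pairs=pairs, covariates=covariate_table)
    truth = pd.DataFrame(
        {
            "probe_id": probes,
            "cluster_id": [probe_cluster[p] for p in probes],
            "is_affected": is_affected,
            "delta": np.where(is_affected, delta, 0.0),
        },
        index=probes,
    )
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "pair_id": [f"pair{i:04d}" for i in range(n_pairs)] * 2,
            "case_control": ["case"] * n_pairs + ["control"] * n_pairs,
            "cancer_type": cancer_type,
        }
    ).set_index("sample_id", drop=False)
    return SimulatedCohort(
        matrix=matrix,
        truth=truth,
        seed=seed,
        pairs={"CC": pairs},
        samples=sheet,
        extras={"study": study},
    )


def default_twin_loci(
    n_early: int = 100,
    n_late: int = 800,
    n_genetic: int = 100,
    n_metastable: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[LocusSpec]:
    """The standard twin-cohort locus mix used across recovery analyses."""
    return (
        [LocusSpec(LocusClass.EARLY_STOCHASTIC, noise_sd=noise_sd)] * n_early
        + [LocusSpec(LocusClass.LATE_STOCHASTIC, noise_sd=noise_sd)] * n_late
        + [LocusSpec(LocusClass.GENETIC, noise_sd=noise_sd)] * n_genetic
        + [LocusSpec(LocusClass.GENETIC_METASTABLE, noise_sd=noise_sd)] * n_metastable
    )
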