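"""Synthetic multi-study generators with known ground truth.

Effects are planted on the standardized scale: case means are shifted by
theta * noise_sd so the true Hedges' g of each gene is known analytically.
All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import BasisMatrix, ExpressionStudy, SampleMetadata, StudyCollection
from .errors import ConfigError
from .landscape import FeatureLandscape


@dataclass
class SyntheticStudyConfig:
    """Generative parameters for one case-control study family."""

    n_genes: int
    n_case: int
    n_control: int
    true_effects: np.ndarray  # per-gene mu on the standardized scale
    tau2: float = 0.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_effects = np.asarray(self.true_effects, dtype=float)
        if self.true_effects.shape != (self.n_genes,):
            raise ConfigError(
                f"true_effects must have length n_genes={self.n_genes}, "
                f"got {self.true_effects.shape}"
            )
        if self.tau2 < 0:
            raise ConfigError("tau2 must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("n_case and n_control must be >= 2 (SE undefined below)")


@dataclass
class SyntheticLandscapeConfig:
    """Parameters for a block-correlated planted feature landscape."""

    n_features: int
    n_diseases: int
    module_assignment: np.ndarray  # module ids, contiguous from 1
    within_module_correlation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.shape != (self.n_features,):
            raise ConfigError("module_assignment must have length n_features")
        ids = np.unique(self.module_assignment)
        if ids[0] != 1 or not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ConfigError("module ids must be contiguous integers starting at 1")
        if not 0.0 <= self.within_module_correlation <= 1.0:
            raise ConfigError("within_module_correlation must lie in [0, 1]")
        if self.n_diseases < 4:
            raise ConfigError("need at least 4 diseases for rank correlations")


def _study_rng(seed: int, study_index: int) -> np.random.Generator:
    # deterministic per-study substream
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(study_index)]))


def generate_study(
    config: SyntheticStudyConfig,
    study_index: int = 0,
    disease: str = "disease",
    compartment: str = "blood",
    n_case: int | None = None,
    n_control: int | None = None,
) -> ExpressionStudy:
    """One study drawn from the random-effects generative model.

    Per gene g the study-level true effect is theta_kg = mu_g + zeta_kg with
    zeta_kg ~ N(0, tau2); controls ~ N(baseline_g, noise_sd^2) and cases ~
    N(baseline_g + theta_kg * noise_sd, noise_sd^2).  Deterministic given
    (config.seed, study_index).
    """
    n_case = config.n_case if n_case is None else n_case
    n_control = config.n_control if n_control is None else n_control
    if n_case < 2 or n_control < 2:
        raise ConfigError("n_case and n_control must be >= 2")
    rng = _study_rng(config.seed, study_index)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    zeta = rng.normal(0.0, np.sqrt(config.tau2), size=config.n_genes) if config.tau2 > 0 else 0.0
    theta = config.true_effects + zeta
    control = rng.normal(
        baseline[:, None], config.noise_sd, size=(config.n_genes, n_control)
    )
    case = rng.normal(
        (baseline + theta * config.noise_sd)[:, None],
        config.noise_sd,
        size=(config.n_genes, n_case),
    )
    matrix = np.concatenate([case, control], axis=1)
    study_id = f"study{study_index}"
    samples = [
        SampleMetadata(
            sample_id=f"{study_id}_s{i}",
            study_id=study_id,
            disease=disease,
            cls="case" if i < n_case else "control",
            compartment=compartment,
        )
        for i in range(n_case + n_control)
    ]
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    return ExpressionStudy(
        study_id=study_id, matrix=matrix, gene_ids=gene_ids, samples=samples, log_scale=True
    )


def generate_collection(
    config: SyntheticStudyConfig,
    n_studies: int,
    disease: str = "disease",
    compartment: str = "blood",
    size_jitter: float = 0.0,
    study_offset: int = 0,
) -> StudyCollection:
    """n_studies independent studies sharing mu and tau2, varying zeta.

    ``size_jitter`` scales group sizes by a uniform factor in
    [1 - jitter, 1 + jitter] (never below 2 samples per group).
    ``study_offset`` shifts study indices so collections for different
    strata draw disjoint substreams from the same seed.
    """
    if n_studies < 1:
        raise ConfigError("n_studies must be >= 1")
    if not 0.0 <= size_jitter < 1.0:
        raise ConfigError("size_jitter must lie in [0, 1)")
    studies = []
    for idx in range(study_offset, study_offset + n_studies):
        n_case, n_control = config.n_case, config.n_control
        if size_jitter > 0:
            jrng = _study_rng(config.seed, idx)  # jitter consumed before expression draws
            f1, f2 = jrng.uniform(1 - size_jitter, 1 + size_jitter, size=2)
            n_case = max(2, int(round(config.n_case * f1)))
            n_control = max(2, int(round(config.n_control * f2)))
        studies.append(
            generate_study(
                config,
                study_index=idx,
                disease=disease,
                compartment=compartment,
                n_case=n_case,
                n_control=n_control,
            )
        )
    return StudyCollection(studies)


def generate_planted_landscape(config: SyntheticLandscapeConfig) -> FeatureLandscape:
    """Feature landscape with block-correlated per-disease effect profiles.

    Features sharing a module mix a common latent disease profile with
    independent noise: profile_i = sqrt(c) * latent_m + sqrt(1-c) * eps_i,
    giving expected pairwise correlation c within modules and 0 between.
    The FDR matrix is all zeros so every feature passes significance
    filtering.
    """
    rng = np.random.default_rng(config.seed)
    c = config.within_module_correlation
    n_modules = int(config.module_assignment.max())
    latents = rng.normal(size=(n_modules, config.n_diseases))
    noise = rng.normal(size=(config.n_features, config.n_diseases))
    profiles = (
        np.sqrt(c) * latents[config.module_assignment - 1] + np.sqrt(1.0 - c) * noise
    )
    feature_ids = [f"F{i:04d}" for i in range(config.n_features)]
    diseases = [f"D{j:02d}" for j in range(config.n_diseases)]
    effect = pd.DataFrame(profiles, index=feature_ids, columns=diseases)
    fdr = pd.DataFrame(
        np.zeros_like(profiles), index=feature_ids, columns=diseases
    )
    return FeatureLandscape(effect=effect, fdr=fdr, compartment="blood")


@dataclass
class MixtureStudy:
    """A generated mixture study together with its ground-truth proportions."""

    study: ExpressionStudy
    proportions: pd.DataFrame  # celltypes x samples


def generate_mixture_study(
    basis: BasisMatrix,
    proportions: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    disease: str = "disease",
    compartment: str = "blood",
) -> MixtureStudy:
    """Bulk samples as basis-weighted cell-type mixtures plus truncated noise.

    ``proportions`` is celltypes x samples with columns summing to 1.  The
    resulting study is linear-scale (``log_scale=False``) since mixing is
    linear in abundance.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.ndim != 2 or proportions.shape[0] != len(basis.celltype_names):
        raise ConfigError("proportions must be celltypes x samples")
    if np.any(proportions < 0):
        raise ConfigError("proportions must be non-negative")
    sums = proportions.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ConfigError("each proportion column must sum to 1 within 1e-6")
    rng = np.random.default_rng(seed)
    expr = basis.matrix @ proportions
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    expr = np.maximum(expr, 0.0)
    n_samples = proportions.shape[1]
    study_id = "mixture"
    samples = [
        SampleMetadata(
            sample_id=f"{study_id}_s{i}",
            study_id=study_id,
            disease=disease,
            cls="case" if i % 2 == 0 else "control",
            compartment=compartment,
        )
        for i in range(n_samples)
    ]
    study = ExpressionStudy(
        study_id=study_id,
        matrix=expr,
        gene_ids=list(basis.gene_ids),
        samples=samples,
        log_scale=False,
    )
    truth = pd.DataFrame(
        proportions, index=basis.celltype_names, columns=study.sample_ids
    )
    return MixtureStudy(study=study, proportions=truth)
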