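"""Module scoring and validation: permutation nulls, AUC enrichment,
treatment-response prediction and severity correlation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .features import FeatureMatrix, stack_features
from .meta import EffectSizeRecord, fisher_combined_p, hedges_g
from .modules import ModuleSet

STABILITY_CAP = 100.0  # 1/SD capped at 1/0.01


@dataclass
class ModuleScoreMatrix:
    """Per-sample aggregate module activity (modules x samples)."""

    module_ids: list[int]
    sample_ids: list[str]
    scores: np.ndarray
    coverage: dict[int, int]  # module id -> number of features found

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=[f"module_{m}" for m in self.module_ids],
            columns=self.sample_ids,
        )


@dataclass
class AUCRecord:
    module_id: int | str
    study_id: str
    auc: float
    p: float
    n_case: int
    n_control: int
    direction: str = ""


@dataclass
class ModuleEnrichmentSummary:
    module_id: int | str
    disease: str
    compartment: str
    mean_auc: float
    sd_auc: float
    stability: float
    combined_p: float
    k_studies: int
    stability_flagged: bool


def zscale_rows(matrix: np.ndarray) -> np.ndarray:
    """Z-scale each row across samples; zero-variance rows become all zero."""
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    out = np.zeros_like(matrix, dtype=float)
    np.divide(matrix - mean, sd, out=out, where=sd > 0)
    return out


def module_scores(
    features: Sequence[FeatureMatrix] | FeatureMatrix, modules: ModuleSet
) -> ModuleScoreMatrix:
    """Per-sample module score = sum of the module's z-scaled feature rows.

    Features are z-scaled across the dataset's samples first; module
    features missing from the dataset are skipped (coverage logged per
    module); a module with no present feature scores NaN.
    """
    stacked = features if isinstance(features, FeatureMatrix) else stack_features(list(features))
    scaled = zscale_rows(stacked.matrix)
    index = {fid: i for i, fid in enumerate(stacked.feature_ids)}
    module_ids = sorted(modules.modules)
    scores = np.full((len(module_ids), len(stacked.sample_ids)), np.nan)
    coverage: dict[int, int] = {}
    for row, mid in enumerate(module_ids):
        present = [index[f] for f in modules.modules[mid] if f in index]
        coverage[mid] = len(present)
        if present:
            scores[row] = scaled[present].sum(axis=0)
    return ModuleScoreMatrix(
        module_ids=module_ids,
        sample_ids=list(stacked.sample_ids),
        scores=scores,
        coverage=coverage,
    )


def module_auc(
    scores: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    module_id: int | str = 0,
    study_id: str = "",
) -> AUCRecord:
    """AUC = P(case score > control score) + 0.5 P(tie); rank-sum p-value."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = scores[labels == "case"]
    control = scores[labels == "control"]
    if case.size == 0 or control.size == 0:
        raise ValueError("need at least one case and one control")
    res = stats.mannwhitneyu(case, control, alternative="two-sided")
    auc = float(res.statistic) / (case.size * control.size)
    return AUCRecord(
        module_id=module_id,
        study_id=study_id,
        auc=auc,
        p=float(res.pvalue),
        n_case=int(case.size),
        n_control=int(control.size),
    )


def aggregate_module_auc(
    records: Sequence[AUCRecord],
    disease: str = "",
    compartment: str = "",
) -> ModuleEnrichmentSummary:
    """Mean AUC over studies, 1/SD stability (capped) and Fisher-combined p."""
    if not records:
        raise ValueError("no AUC records to aggregate")
    module_ids = {r.module_id for r in records}
    if len(module_ids) != 1:
        raise ValueError(f"records span multiple modules: {module_ids}")
    aucs = np.array([r.auc for r in records])
    pvals = np.clip([r.p for r in records], np.finfo(float).tiny, 1.0)
    k = len(records)
    sd = float(aucs.std(ddof=1)) if k >= 2 else float("nan")
    flagged = k < 2 or sd < 1.0 / STABILITY_CAP
    stability = float("nan") if k < 2 else min(STABILITY_CAP, 1.0 / max(sd, 1e-12))
    return ModuleEnrichmentSummary(
        module_id=module_ids.pop(),
        disease=disease,
        compartment=compartment,
        mean_auc=float(aucs.mean()),
        sd_auc=sd,
        stability=stability,
        combined_p=fisher_combined_p(pvals),
        k_studies=k,
        stability_flagged=flagged,
    )


def _hedges_g_scores(scores: np.ndarray, case_mask: np.ndarray) -> float:
    case = scores[..., case_mask]
    control = scores[..., ~case_mask]
    n1, n2 = case.shape[-1], control.shape[-1]
    sp = np.sqrt(
        ((n1 - 1) * case.std(axis=-1, ddof=1) ** 2 + (n2 - 1) * control.std(axis=-1, ddof=1) ** 2)
        / (n1 + n2 - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = (case.mean(axis=-1) - control.mean(axis=-1)) / sp
    return smd * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))


def permutation_module_test(
    target_module: int,
    modules: ModuleSet,
    features: Sequence[FeatureMatrix] | FeatureMatrix,
    labels: Sequence[str] | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Size-matched random-module null for one module's case-control effect.

    The observed statistic is the Hedges' g of the target module's score
    between classes.  The null re-draws ``n_perm`` feature sets of the same
    size (without replacement within a draw) from the features of the other
    modules, scores them identically, and the observed effect is
    standardized against the null distribution (z and two-sided normal p);
    the empirical two-sided tail is reported alongside.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stacked = features if isinstance(features, FeatureMatrix) else stack_features(list(features))
    labels = np.asarray(labels)
    case_mask = labels == "case"
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError("need >= 2 cases and >= 2 controls")
    index = {fid: i for i, fid in enumerate(stacked.feature_ids)}
    target_rows = [index[f] for f in modules.modules[target_module] if f in index]
    if not target_rows:
        raise ValueError(f"module {target_module} has no feature in the dataset")
    pool = [
        index[f]
        for mid, feats in modules.modules.items()
        if mid != target_module
        for f in feats
        if f in index
    ]
    size = len(target_rows)
    if len(pool) < size:
        raise ValueError(
            f"pool of other-module features ({len(pool)}) smaller than module size ({size})"
        )
    scaled = zscale_rows(stacked.matrix)
    observed = float(_hedges_g_scores(scaled[target_rows].sum(axis=0), case_mask))
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool)
    draws = np.stack([rng.choice(pool_arr, size=size, replace=False) for _ in range(n_perm)])
    null_scores = scaled[draws].sum(axis=1)  # (n_perm, n_samples)
    null_effects = _hedges_g_scores(null_scores, case_mask)
    mu, sd = float(null_effects.mean()), float(null_effects.std(ddof=1))
    z = (observed - mu) / sd if sd > 0 else float("inf") * np.sign(observed - mu)
    p_normal = float(2.0 * stats.norm.sf(abs(z)))
    p_empirical = float(
        (1.0 + np.sum(np.abs(null_effects - mu) >= abs(observed - mu))) / (1.0 + n_perm)
    )
    return {
        "effect": observed,
        "z": float(z),
        "p": p_normal,
        "p_empirical": p_empirical,
        "null_mean": mu,
        "null_sd": sd,
        "n_perm": n_perm,
        "module_size": size,
    }


def predict_response(
    baseline_scores: np.ndarray,
    response: Sequence[str] | np.ndarray,
    module_id: int | str = 0,
    study_id: str = "",
) -> AUCRecord:
    """Directed AUC for responder status with its direction reported.

    The raw AUC is P(responder score > non-responder score); when it falls
    below 0.5 the record reports 1 - AUC with direction
    "lower_in_responders" instead of silently flipping.
    """
    scores = np.asarray(baseline_scores, dtype=float)
    response = np.asarray(response)
    resp = scores[response == "responder"]
    nonresp = scores[response == "non_responder"]
    if resp.size == 0 or nonresp.size == 0:
        raise ValueError("need at least one responder and one non-responder")
    res = stats.mannwhitneyu(resp, nonresp, alternative="two-sided")
    raw = float(res.statistic) / (resp.size * nonresp.size)
    if raw >= 0.5:
        auc, direction = raw, "higher_in_responders"
    else:
        auc, direction = 1.0 - raw, "lower_in_responders"
    return AUCRecord(
        module_id=module_id,
        study_id=study_id,
        auc=auc,
        p=float(res.pvalue),
        n_case=int(resp.size),
        n_control=int(nonresp.size),
        direction=direction,
    )


def severity_correlation(
    scores: np.ndarray, severity: np.ndarray
) -> tuple[float, float, int]:
    """Spearman rho of module score vs clinical severity, pairwise-complete."""
    scores = np.asarray(scores, dtype=float)
    severity = np.asarray(severity, dtype=float)
    keep = np.isfinite(scores) & np.isfinite(severity)
    if keep.sum() < 4:
        raise InsufficientDataError(f"only {int(keep.sum())} paired values; need >= 4")
    rho, p = stats.spearmanr(scores[keep], severity[keep])
    return float(rho), float(p), int(keep.sum())


def compare_groups(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum (Wilcoxon/Mann-Whitney) comparison of two groups."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
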