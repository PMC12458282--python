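"""Higher-order immune features from expression matrices.

Five feature families: cell proportions (basis-matrix deconvolution),
pathway / TF-regulon / miRNA-target activity (single-sample rank-based
enrichment) and cytokine-panel expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_model import BasisMatrix, ExpressionStudy, GeneSetCollection
from .errors import DegenerateInputError, InsufficientDataError, PipelineError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_OVERLAP = 5


@dataclass
class FeatureMatrix:
    """Features x samples scores for one family within one study."""

    feature_ids: list[str]
    feature_type: str  # cell_proportion | pathway | tf_regulon | mirna_targets | cytokine
    matrix: np.ndarray
    study_id: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("feature matrix shape does not match ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.feature_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# Single-sample gene-set scoring
# ---------------------------------------------------------------------------


def _rank_order(expression: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending order (stable among ties) and per-gene ascending ranks."""
    order = np.argsort(-expression, kind="stable")
    n = expression.size
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # top-expressed gene gets rank n
    return order, ranks


def ssgsea_score(
    expression: np.ndarray,
    gene_ids: Sequence[str],
    gene_set: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    method: str = "max",
) -> float:
    """Single-sample enrichment score for one gene set.

    Genes are ranked descending by expression; the weighted in-set ECDF
    (weights = rank^alpha) is compared to the unweighted out-of-set ECDF
    along the ranking.  ``method='max'`` returns the signed maximum
    deviation between the two running distributions (already normalized to
    [-1, 1] since both ECDFs live in [0, 1]); ``method='sum'`` returns the
    mean running difference.  Depends on expression only through ranks.
    """
    expression = np.asarray(expression, dtype=float)
    in_set = np.isin(np.asarray(gene_ids, dtype=object), list(gene_set))
    n = expression.size
    n_in = int(in_set.sum())
    if n_in == 0:
        raise DegenerateInputError("gene set has no overlap with the expression vector")
    if n_in == n:
        raise DegenerateInputError("gene set covers every measured gene")
    order, ranks = _rank_order(expression)
    in_ordered = in_set[order]
    weights = np.where(in_ordered, ranks[order] ** alpha, 0.0)
    ecdf_in = np.cumsum(weights) / weights.sum()
    ecdf_out = np.cumsum(~in_ordered) / (n - n_in)
    dev = ecdf_in - ecdf_out
    if method == "max":
        return _signed_max_deviation(dev)
    if method == "sum":
        return float(dev.sum() / n)
    raise ValueError(f"unknown method {method!r}; use 'max' or 'sum'")


def _signed_max_deviation(dev: np.ndarray, tol: float = 1e-9) -> float:
    """Larger-magnitude of the max positive / max negative running deviation.

    Exact |max| ties resolve to the positive branch; ``tol`` absorbs
    summation-order float noise so the convention is reproducible.
    """
    pos = float(dev.max())
    neg = float(dev.min())
    return pos if pos + neg >= -tol else neg


def featurize_gene_sets(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    method: str = "max",
) -> FeatureMatrix:
    """One enrichment-score row per gene set, one column per sample."""
    genes = np.asarray(study.gene_ids, dtype=object)
    kept: list[str] = []
    masks: list[np.ndarray] = []
    for name, members in sets.sets.items():
        mask = np.isin(genes, members)
        n_in = int(mask.sum())
        if n_in < min_overlap or n_in == len(genes):
            logger.warning(
                "gene set %r dropped (%d genes present, min_overlap=%d)",
                name, n_in, min_overlap,
            )
            continue
        kept.append(name)
        masks.append(mask)
    if not kept:
        raise PipelineError("all gene sets dropped by the overlap filter")
    scores = np.empty((len(kept), study.n_samples))
    n = study.n_genes
    for j in range(study.n_samples):
        order, ranks = _rank_order(study.matrix[:, j])
        rank_w = ranks[order] ** alpha
        for i, mask in enumerate(masks):
            in_ordered = mask[order]
            w = np.where(in_ordered, rank_w, 0.0)
            ecdf_in = np.cumsum(w) / w.sum()
            ecdf_out = np.cumsum(~in_ordered) / (n - in_ordered.sum())
            dev = ecdf_in - ecdf_out
            if method == "max":
                scores[i, j] = _signed_max_deviation(dev)
            else:
                scores[i, j] = dev.sum() / n
    return FeatureMatrix(
        feature_ids=kept,
        feature_type=sets.category,
        matrix=scores,
        study_id=study.study_id,
        sample_ids=study.sample_ids,
    )


# ---------------------------------------------------------------------------
# Cell-mixture deconvolution
# ---------------------------------------------------------------------------


def deconvolve_sample(
    expression: np.ndarray,
    gene_ids: Sequence[str],
    basis: BasisMatrix,
    delog: bool = True,
) -> np.ndarray:
    """Non-negative least-squares cell-type proportions for one sample.

    Solves expression ~ basis @ p on the shared genes (expression de-logged
    with 2^x - 1 when ``delog``), clips at 0 and renormalizes to sum to 1.
    """
    expression = np.asarray(expression, dtype=float)
    shared, expr_idx, basis_idx = np.intersect1d(
        np.asarray(gene_ids, dtype=object),
        np.asarray(basis.gene_ids, dtype=object),
        return_indices=True,
    )
    n_types = len(basis.celltype_names)
    if len(shared) < n_types:
        raise InsufficientDataError(
            f"only {len(shared)} genes shared with the basis matrix; need >= {n_types}"
        )
    y = expression[expr_idx]
    if delog:
        y = np.power(2.0, y) - 1.0
    coef, _ = nnls(basis.matrix[basis_idx], y)
    coef = np.clip(coef, 0.0, None)
    total = coef.sum()
    if total <= 0:
        # all-zero solution: no information, report uniform proportions
        logger.warning("NNLS returned an all-zero solution; reporting uniform proportions")
        return np.full(n_types, 1.0 / n_types)
    return coef / total


def featurize_cell_proportions(
    study: ExpressionStudy, basis: BasisMatrix, delog: bool | None = None
) -> FeatureMatrix:
    if delog is None:
        delog = study.log_scale
    props = np.column_stack(
        [
            deconvolve_sample(study.matrix[:, j], study.gene_ids, basis, delog=delog)
            for j in range(study.n_samples)
        ]
    )
    return FeatureMatrix(
        feature_ids=list(basis.celltype_names),
        feature_type="cell_proportion",
        matrix=props,
        study_id=study.study_id,
        sample_ids=study.sample_ids,
    )


# ---------------------------------------------------------------------------
# Cytokine panel
# ---------------------------------------------------------------------------


def cytokine_panel(study: ExpressionStudy, panel: Sequence[str]) -> FeatureMatrix:
    """Row-subset of the expression matrix restricted to panel genes."""
    panel = list(dict.fromkeys(panel))
    index = {g: i for i, g in enumerate(study.gene_ids)}
    present = [g for g in panel if g in index]
    if not present:
        raise DegenerateInputError("no panel gene present in the study")
    missing = len(panel) - len(present)
    if missing:
        logger.warning(
            "study %s: %d of %d panel genes absent", study.study_id, missing, len(panel)
        )
    rows = [index[g] for g in present]
    return FeatureMatrix(
        feature_ids=present,
        feature_type="cytokine",
        matrix=study.matrix[rows],
        study_id=study.study_id,
        sample_ids=study.sample_ids,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def featurize_study(
    study: ExpressionStudy,
    sets_by_category: Sequence[GeneSetCollection] = (),
    basis: BasisMatrix | None = None,
    panel: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[FeatureMatrix]:
    """All requested feature families for one study, sharing sample order."""
    out: list[FeatureMatrix] = []
    if basis is not None:
        try:
            out.append(featurize_cell_proportions(study, basis))
        except Exception as exc:
            raise type(exc)(f"[cell_proportion] {exc}") from exc
    for sets in sets_by_category:
        try:
            out.append(featurize_gene_sets(study, sets, alpha=alpha, min_overlap=min_overlap))
        except Exception as exc:
            raise type(exc)(f"[{sets.category}] {exc}") from exc
    if panel is not None:
        try:
            out.append(cytokine_panel(study, panel))
        except Exception as exc:
            raise type(exc)(f"[cytokine] {exc}") from exc
    return out


def stack_features(features: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate feature families (rows) sharing one sample ordering."""
    if not features:
        raise ValueError("no feature matrices to stack")
    sample_ids = features[0].sample_ids
    for fm in features[1:]:
        if fm.sample_ids != sample_ids:
            raise ValueError("feature matrices disagree on sample ordering")
    ids, rows = [], []
    for fm in features:
        ids.extend(f"{fm.feature_type}:{fid}" for fid in fm.feature_ids)
        rows.append(fm.matrix)
    return FeatureMatrix(
        feature_ids=ids,
        feature_type="mixed",
        matrix=np.vstack(rows),
        study_id=features[0].study_id,
        sample_ids=list(sample_ids),
    )
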