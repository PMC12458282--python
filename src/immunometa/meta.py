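"""Random-effects meta-analysis of standardized case-control differences.

Per-study effects are Hedges' g (bias-corrected standardized mean
difference); between-study variance tau^2 is estimated by the
DerSimonian-Laird moment method; pooling uses inverse-variance weights
1/(se_k^2 + tau^2).  Multiple testing is controlled with Benjamini-Hochberg
and p-values can be combined across strata with Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionStudy, StudyCollection
from .errors import DegenerateInputError, PipelineError


@dataclass
class EffectSizeRecord:
    """One study's Hedges' g with its standard error and group sizes."""

    study_id: str
    g: float
    se: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")
        if not np.isfinite(self.g):
            raise ValueError("effect size must be finite")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("both groups need at least 2 samples")


@dataclass
class PooledEffect:
    """Random-effects summary for one gene/feature."""

    estimate: float
    se: float
    tau2: float
    z: float
    p: float
    k: int
    fdr: float = float("nan")


def hedges_g(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    study_id: str = "",
) -> EffectSizeRecord:
    """Bias-corrected standardized mean difference of group 1 vs group 2.

    s_pooled^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    g = (mean1-mean2)/s_pooled * (1 - 3/(4n-9)) with n = n1+n2;
    se = sqrt((n1+n2)/(n1 n2) + g^2 / (2(n1+n2))).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("hedges_g requires n1, n2 >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise DegenerateInputError("pooled standard deviation is zero")
    n = n1 + n2
    smd = (mean1 - mean2) / s_pooled
    g = smd * (1.0 - 3.0 / (4.0 * n - 9.0))
    se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))
    return EffectSizeRecord(study_id=study_id, g=float(g), se=float(se), n1=n1, n2=n2)


def dersimonian_laird_tau2(effects: Sequence[EffectSizeRecord]) -> float:
    """Moment estimator of between-study variance.

    With fixed-effect weights w = 1/se^2 and Q = sum w (g - g_FE)^2:
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)).
    Returns 0 for a single study.
    """
    if len(effects) == 0:
        raise ValueError("no effects supplied")
    g = np.array([e.g for e in effects])
    se = np.array([e.se for e in effects])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    if len(effects) == 1:
        return 0.0
    w = 1.0 / se**2
    g_fe = np.sum(w * g) / np.sum(w)
    q = np.sum(w * (g - g_fe) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return float(max(0.0, (q - (len(effects) - 1)) / denom))


def pool_random_effects(
    effects: Sequence[EffectSizeRecord], tau2: float | None = None
) -> PooledEffect:
    """Inverse-variance pooling with weights 1/(se^2 + tau2).

    If ``tau2`` is not supplied, it is estimated with the DerSimonian-Laird
    method.  The two-sided p-value uses the normal approximation
    z = estimate/se.
    """
    if len(effects) == 0:
        raise ValueError("cannot pool an empty list of effects")
    if tau2 is None:
        tau2 = dersimonian_laird_tau2(effects)
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    g = np.array([e.g for e in effects])
    se = np.array([e.se for e in effects])
    w = 1.0 / (se**2 + tau2)
    estimate = float(np.sum(w * g) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    z = estimate / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PooledEffect(estimate=estimate, se=pooled_se, tau2=float(tau2), z=float(z), p=p, k=len(effects))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_combined_p(pvalues: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2m df (upper tail)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; clip zeros upstream")
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, df=2 * p.size))


# ---------------------------------------------------------------------------
# Vectorized study-collection meta-analysis
# ---------------------------------------------------------------------------


def _group_stats(matrix: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    sub = matrix[:, mask]
    return sub.mean(axis=1), sub.std(axis=1, ddof=1), int(mask.sum())


def _hedges_g_arrays(
    mean1: np.ndarray, sd1: np.ndarray, n1: int, mean2: np.ndarray, sd2: np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized hedges_g over per-gene summary arrays; NaN where degenerate."""
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    n = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = np.where(s_pooled > 0, (mean1 - mean2) / s_pooled, np.nan)
    g = smd * (1.0 - 3.0 / (4.0 * n - 9.0))
    se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))
    return g, se


def study_effect_table(
    study: ExpressionStudy,
    extractor: Callable[[ExpressionStudy], tuple[list[str], np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Per-row Hedges' g (case vs control) for one study."""
    if extractor is None:
        row_ids, matrix = study.gene_ids, study.matrix
    else:
        row_ids, matrix = extractor(study)
    case = study.class_mask("case")
    control = study.class_mask("control")
    m1, s1, n1 = _group_stats(matrix, case)
    m2, s2, n2 = _group_stats(matrix, control)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"study {study.study_id!r}: need >=2 cases and >=2 controls")
    g, se = _hedges_g_arrays(m1, s1, n1, m2, s2, n2)
    return pd.DataFrame({"g": g, "se": se, "n1": n1, "n2": n2}, index=pd.Index(row_ids))


def _pool_matrix(g: np.ndarray, se: np.ndarray) -> dict[str, np.ndarray]:
    """Row-wise DL tau2 + random-effects pool over a (rows x studies) grid.

    NaN marks a row absent from a study; each row pools over the studies
    carrying it.
    """
    present = np.isfinite(g) & np.isfinite(se)
    k = present.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(present, 1.0 / se**2, 0.0)
        sw = w.sum(axis=1)
        g0 = np.where(present, g, 0.0)
        g_fe = np.where(sw > 0, (w * g0).sum(axis=1) / sw, np.nan)
        q = (w * (g0 - g_fe[:, None]) ** 2 * present).sum(axis=1)
        denom = sw - (w**2).sum(axis=1) / np.where(sw > 0, sw, np.nan)
        tau2 = np.where(
            (k >= 2) & (denom > 0), np.maximum(0.0, (q - (k - 1)) / denom), 0.0
        )
        w_star = np.where(present, 1.0 / (se**2 + tau2[:, None]), 0.0)
        sw_star = w_star.sum(axis=1)
        estimate = (w_star * g0).sum(axis=1) / sw_star
        pooled_se = np.sqrt(1.0 / sw_star)
    z = estimate / pooled_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {"estimate": estimate, "se": pooled_se, "tau2": tau2, "z": z, "p": p, "k": k}


def meta_analyze(
    collection: StudyCollection,
    extractor: Callable[[ExpressionStudy], tuple[list[str], np.ndarray]] | None = None,
    min_studies: int = 1,
) -> pd.DataFrame:
    """Pool per-study effects across a stratum; BH-correct across rows.

    Returns a table indexed by row entity with columns estimate, se, tau2,
    z, p, fdr, k.  Rows absent from some studies are pooled over the studies
    that carry them.
    """
    if len(collection) == 0:
        raise PipelineError("empty study collection")
    tables = {s.study_id: study_effect_table(s, extractor) for s in collection}
    g = pd.DataFrame({sid: t["g"] for sid, t in tables.items()})
    se = pd.DataFrame({sid: t["se"] for sid, t in tables.items()})
    # drop the column ordering's influence: sort study columns by id
    g = g.sort_index(axis=1)
    se = se.loc[g.index, g.columns]
    valid = (g.notna() & se.notna()).sum(axis=1) >= max(1, min_studies)
    if not valid.any():
        raise PipelineError("no row present in the required number of studies")
    g, se = g.loc[valid], se.loc[valid]
    pooled = _pool_matrix(g.to_numpy(), se.to_numpy())
    out = pd.DataFrame(pooled, index=g.index)
    finite = np.isfinite(out["p"].to_numpy())
    fdr = np.full(len(out), np.nan)
    fdr[finite] = benjamini_hochberg(out.loc[finite, "p"].to_numpy())
    out["fdr"] = fdr
    out = out[["estimate", "se", "tau2", "z", "p", "fdr", "k"]]
    out.index.name = "entity"
    return out.sort_index()
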