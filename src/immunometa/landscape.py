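"""Cross-disease feature landscape: assembly, significance filtering and
blood-vs-tissue comparison."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, PipelineError


@dataclass
class FeatureLandscape:
    """Features x diseases matrices of pooled effects and FDRs.

    Missing (feature, disease) cells are NaN in both matrices — explicitly
    absent, never silently zero.
    """

    effect: pd.DataFrame
    fdr: pd.DataFrame
    compartment: str = "blood"
    feature_types: pd.Series | None = None
    k_studies: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.effect.shape != self.fdr.shape:
            raise ValueError("effect and fdr matrices must share a shape")
        if not self.effect.index.equals(self.fdr.index) or not self.effect.columns.equals(
            self.fdr.columns
        ):
            raise ValueError("effect and fdr matrices must share index and columns")
        with np.errstate(invalid="ignore"):
            bad = ((self.fdr < 0) | (self.fdr > 1)).to_numpy()
        if np.any(bad & np.isfinite(self.fdr.to_numpy())):
            raise ValueError("fdr entries must lie in [0, 1]")
        if self.feature_types is None:
            self.feature_types = pd.Series("feature", index=self.effect.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.effect.index)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.effect.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.effect.isna()


def build_landscape(
    pooled_tables: Mapping[str, pd.DataFrame],
    compartment: str = "blood",
    feature_types: Mapping[str, str] | pd.Series | None = None,
) -> FeatureLandscape:
    """Align per-disease pooled-effect tables into one landscape.

    ``pooled_tables`` maps disease -> table from :func:`meta.meta_analyze`.
    The feature axis is the union across diseases; cells absent from a
    disease stay NaN.
    """
    if len(pooled_tables) < 2:
        raise PipelineError("a landscape needs at least 2 diseases")
    for disease, table in pooled_tables.items():
        if table.empty:
            raise PipelineError(f"disease {disease!r} has an empty pooled table")
    diseases = sorted(pooled_tables)
    effect = pd.DataFrame({d: pooled_tables[d]["estimate"] for d in diseases})
    fdr = pd.DataFrame({d: pooled_tables[d]["fdr"] for d in diseases})
    k = pd.DataFrame({d: pooled_tables[d]["k"] for d in diseases})
    ft = None
    if feature_types is not None:
        ft = pd.Series(feature_types).reindex(effect.index).fillna("feature")
    return FeatureLandscape(
        effect=effect, fdr=fdr, compartment=compartment, feature_types=ft, k_studies=k
    )


def significant_features(landscape: FeatureLandscape, threshold: float = 0.05) -> FeatureLandscape:
    """Keep features significant (FDR < threshold) in at least one disease."""
    keep = (landscape.fdr < threshold).any(axis=1)
    if not keep.any():
        raise PipelineError(f"no feature significant at FDR < {threshold}")
    return replace(
        landscape,
        effect=landscape.effect.loc[keep],
        fdr=landscape.fdr.loc[keep],
        feature_types=landscape.feature_types.loc[keep],
        k_studies=None if landscape.k_studies is None else landscape.k_studies.loc[keep],
    )


def _significant_set(
    landscape: FeatureLandscape, disease: str, feature_type: str | None, threshold: float
) -> set[str]:
    if disease not in landscape.effect.columns:
        raise KeyError(f"disease {disease!r} absent from {landscape.compartment} landscape")
    fdr = landscape.fdr[disease]
    mask = fdr < threshold
    if feature_type is not None:
        mask &= landscape.feature_types == feature_type
    return set(fdr.index[mask])


def compartment_overlap(
    blood: FeatureLandscape,
    tissue: FeatureLandscape,
    disease: str,
    feature_type: str | None = None,
    threshold: float = 0.05,
) -> dict:
    """Shared / compartment-specific significant features for one disease.

    ``fraction_shared`` is |intersection| / |union|; per-compartment
    fractions are reported alongside.
    """
    b = _significant_set(blood, disease, feature_type, threshold)
    t = _significant_set(tissue, disease, feature_type, threshold)
    union = b | t
    shared = b & t
    return {
        "disease": disease,
        "feature_type": feature_type,
        "shared": len(shared),
        "blood_only": len(b - t),
        "tissue_only": len(t - b),
        "union": len(union),
        "fraction_shared": len(shared) / len(union) if union else float("nan"),
        "fraction_of_blood": len(shared) / len(b) if b else float("nan"),
        "fraction_of_tissue": len(shared) / len(t) if t else float("nan"),
    }


def compartment_concordance(
    blood: FeatureLandscape,
    tissue: FeatureLandscape,
    disease: str,
    feature_type: str | None = None,
    significant_in_both: bool = False,
    threshold: float = 0.05,
) -> tuple[float, float, int]:
    """Spearman correlation of blood vs tissue pooled effects for a disease."""
    for ls in (blood, tissue):
        if disease not in ls.effect.columns:
            raise KeyError(f"disease {disease!r} absent from {ls.compartment} landscape")
    b = blood.effect[disease]
    t = tissue.effect[disease]
    shared = b.index.intersection(t.index)
    if feature_type is not None:
        shared = shared[blood.feature_types.loc[shared] == feature_type]
    if significant_in_both:
        sig = (blood.fdr.loc[shared, disease] < threshold) & (
            tissue.fdr.loc[shared, disease] < threshold
        )
        shared = shared[sig]
    pairs = pd.DataFrame({"b": b.loc[shared], "t": t.loc[shared]}).dropna()
    if len(pairs) < 4:
        raise InsufficientDataError(
            f"only {len(pairs)} shared features for disease {disease!r}; need >= 4"
        )
    rho, p = stats.spearmanr(pairs["b"], pairs["t"])
    return float(rho), float(p), len(pairs)


# --- serialization ----------------------------------------------------------


def write_landscape(landscape: FeatureLandscape, prefix) -> None:
    landscape.effect.to_csv(f"{prefix}.effect.tsv", sep="\t", float_format="%.10g")
    landscape.fdr.to_csv(f"{prefix}.fdr.tsv", sep="\t", float_format="%.10g")
    landscape.feature_types.rename("feature_type").to_csv(
        f"{prefix}.feature_types.tsv", sep="\t"
    )


def read_landscape(prefix, compartment: str = "blood") -> FeatureLandscape:
    effect = pd.read_csv(f"{prefix}.effect.tsv", sep="\t", index_col=0)
    fdr = pd.read_csv(f"{prefix}.fdr.tsv", sep="\t", index_col=0)
    types = pd.read_csv(f"{prefix}.feature_types.tsv", sep="\t", index_col=0)["feature_type"]
    return FeatureLandscape(effect=effect, fdr=fdr, compartment=compartment, feature_types=types)
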