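"""Module discovery: feature-feature correlation, hierarchical clustering and
perturbation-based robustness of the cluster number."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .errors import InsufficientDataError
from .landscape import FeatureLandscape


@dataclass
class ModuleSet:
    """A partition of features into modules with optional free-text labels."""

    modules: dict[int, list[str]]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mid, feats in self.modules.items():
            if not feats:
                raise ValueError(f"module {mid} is empty")
            dup = seen.intersection(feats)
            if dup:
                raise ValueError(f"features in multiple modules: {sorted(dup)[:5]}")
            seen.update(feats)

    @property
    def k(self) -> int:
        return len(self.modules)

    @property
    def feature_ids(self) -> list[str]:
        return [f for feats in self.modules.values() for f in feats]

    def assignment(self, feature_order: list[str] | None = None) -> np.ndarray:
        """Module id per feature, in ``feature_order`` (default: module order)."""
        lookup = {f: mid for mid, feats in self.modules.items() for f in feats}
        order = feature_order if feature_order is not None else self.feature_ids
        return np.array([lookup[f] for f in order])

    def to_json(self, path) -> None:
        payload = {
            str(mid): {"features": feats, "label": self.labels.get(mid, "")}
            for mid, feats in sorted(self.modules.items())
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModuleSet":
        with open(path) as handle:
            payload = json.load(handle)
        modules = {int(mid): rec["features"] for mid, rec in payload.items()}
        labels = {int(mid): rec.get("label", "") for mid, rec in payload.items()}
        return cls(modules=modules, labels=labels)


def _spearman_full(effect: np.ndarray) -> np.ndarray:
    """Fast Spearman matrix for a complete (no-NaN) features x diseases array."""
    ranks = np.apply_along_axis(rankdata, 1, effect)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = np.nan
    corr = (ranks @ ranks.T) / np.outer(norms, norms)
    return np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)


def feature_correlation_matrix(landscape: FeatureLandscape) -> pd.DataFrame:
    """Pairwise Spearman correlations of per-disease effect profiles.

    Pairwise-complete over non-missing cells; pairs sharing fewer than 3
    diseases get 0.  Diagonal is 1.
    """
    effect = landscape.effect
    if effect.shape[1] < 4:
        raise InsufficientDataError("need >= 4 diseases for feature correlations")
    if effect.shape[0] < 2:
        raise InsufficientDataError("need >= 2 features")
    if not effect.isna().any().any():
        corr = _spearman_full(effect.to_numpy())
    else:
        corr = effect.T.corr(method="spearman", min_periods=3).to_numpy()
        corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=effect.index, columns=effect.index)


def cluster_features(
    corr: pd.DataFrame, k: int = 15, method: str = "ward"
) -> ModuleSet:
    """Cut an agglomerative dendrogram on distance 1 - rho into k modules.

    Ward linkage is the default: on planted block-correlated landscapes it
    recovers modules markedly better than average/complete (which remain
    available via ``method``).
    """
    n = corr.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    dist = 1.0 - corr.to_numpy()
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(np.maximum(dist, 0.0), checks=False), method=method)
    flat = fcluster(z, t=k, criterion="maxclust")
    modules: dict[int, list[str]] = {}
    for feature, mid in zip(corr.index, flat):
        modules.setdefault(int(mid), []).append(feature)
    # relabel 1..k in first-appearance order for stable output
    relabel = {mid: i + 1 for i, mid in enumerate(sorted(modules))}
    return ModuleSet(modules={relabel[mid]: feats for mid, feats in modules.items()})


def _cluster_effect(effect: np.ndarray, index: pd.Index, k: int, method: str) -> np.ndarray:
    corr = _spearman_full(effect)
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=index, columns=index)
    return cluster_features(frame, k=k, method=method).assignment(list(index))


def _stability(
    effect: np.ndarray,
    index: pd.Index,
    k: int,
    method: str,
    noise_sd: float,
    n_perturbations: int,
    rng: np.random.Generator,
) -> float:
    base = _cluster_effect(effect, index, k, method)
    aris = []
    for _ in range(n_perturbations):
        noisy = effect + rng.normal(0.0, noise_sd, size=effect.shape)
        aris.append(adjusted_rand_score(base, _cluster_effect(noisy, index, k, method)))
    return float(np.mean(aris))


def cluster_number_robustness(
    landscape: FeatureLandscape,
    k: int = 15,
    n_perturbations: int = 100,
    noise_sd_fraction: float = 0.1,
    seed: int = 0,
    n_null: int = 49,
    n_perturbations_null: int | None = None,
    method: str = "ward",
) -> tuple[float, float]:
    """Perturbation stability of the k-cluster partition and a shuffled-null p.

    Stability is the mean adjusted Rand index between the unperturbed
    partition and partitions of noise-perturbed landscapes (additive noise
    at ``noise_sd_fraction`` of the effect-matrix SD).  The null shuffles
    each feature's disease profile independently (destroying inter-feature
    correlation) and recomputes stability; p is the fraction of null
    stabilities >= the observed one (add-one corrected).

    ``n_perturbations_null`` (default max(20, n_perturbations // 5)) trades
    null-stability estimation noise for runtime; the mean-ARI estimator is
    unbiased in the number of perturbations, so the null location is
    unaffected and the extra spread only makes p conservative.
    """
    if n_perturbations < 20:
        raise ValueError("n_perturbations must be >= 20")
    effect = landscape.effect.to_numpy()
    if np.isnan(effect).any():
        raise ValueError("robustness analysis requires a complete landscape")
    if np.any(effect.std(axis=1) == 0):
        raise ValueError("landscape has constant feature rows")
    noise_sd = noise_sd_fraction * effect.std()
    rng = np.random.default_rng(seed)
    index = landscape.effect.index
    observed = _stability(effect, index, k, method, noise_sd, n_perturbations, rng)
    if noise_sd == 0:
        return observed, 1.0
    if n_perturbations_null is None:
        n_perturbations_null = max(20, n_perturbations // 5)
    null_stats = np.empty(n_null)
    for i in range(n_null):
        shuffled = np.array([rng.permutation(row) for row in effect])
        null_stats[i] = _stability(
            shuffled, index, k, method, noise_sd, n_perturbations_null, rng
        )
    p = (1.0 + np.sum(null_stats >= observed)) / (1.0 + n_null)
    return observed, float(p)
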