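"""End-to-end synthetic pipeline: simulate -> filter -> featurize ->
meta-analyze -> landscape -> modules -> scores -> validation -> enrichment.

Every stage writes deterministic TSV/JSON artifacts; a manifest records the
seed and parameters needed to reproduce them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .data_model import (
    BasisMatrix,
    GeneSetCollection,
    StudyCollection,
    filter_collection,
    write_basis_matrix,
    write_gene_sets,
)
from .enrichment import hypergeometric_enrichment
from .features import FeatureMatrix, featurize_study, stack_features
from .landscape import build_landscape, significant_features, write_landscape
from .meta import meta_analyze
from .modules import (
    cluster_features,
    cluster_number_robustness,
    feature_correlation_matrix,
)
from .synthetic import SyntheticStudyConfig, generate_collection
from .validation import aggregate_module_auc, module_auc, module_scores, permutation_module_test

logger = logging.getLogger(__name__)

_FLOAT = "%.10g"


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT)


def simulate_inputs(config: PipelineConfig, seed: int):
    """Generate study collections per disease plus gene sets, basis and panel."""
    s = config.synthetic
    root = np.random.SeedSequence([seed, 0xA11CE])
    gene_ids = [f"G{i:05d}" for i in range(s.n_genes)]
    resource_rng = np.random.default_rng(root.spawn(1)[0])

    collections: dict[str, StudyCollection] = {}
    signal_genes: dict[str, np.ndarray] = {}
    for d in range(s.n_diseases):
        disease = f"D{d:02d}"
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15, d]))
        idx = rng.choice(s.n_genes, size=s.n_signal_genes, replace=False)
        mu = np.zeros(s.n_genes)
        mu[idx] = s.effect_size * rng.choice([-1.0, 1.0], size=s.n_signal_genes)
        study_config = SyntheticStudyConfig(
            n_genes=s.n_genes,
            n_case=s.n_case,
            n_control=s.n_control,
            true_effects=mu,
            tau2=s.tau2,
            seed=seed,
        )
        collection = generate_collection(
            study_config,
            n_studies=s.n_studies_per_disease,
            disease=disease,
            compartment="blood",
            study_offset=d * s.n_studies_per_disease,
        )
        # study ids must be globally unique across diseases
        for study in collection:
            study.study_id = f"{disease}_{study.study_id}"
            for m in study.samples:
                m.study_id = study.study_id
        collections[disease] = collection
        signal_genes[disease] = np.array(gene_ids, dtype=object)[np.sort(idx)]

    def random_sets(n_sets: int, category: str, prefix: str) -> GeneSetCollection:
        sets = {}
        for i in range(n_sets):
            members = resource_rng.choice(gene_ids, size=s.set_size, replace=False)
            sets[f"{prefix}{i:02d}"] = sorted(members)
        return GeneSetCollection(sets=sets, category=category)

    pathway_sets = random_sets(s.n_pathway_sets, "pathway", "PW")
    # plant one pathway set on the first disease's signal genes so the feature
    # layer carries real case-control signal
    planted = sorted(signal_genes["D00"][: s.set_size])
    pathway_sets.sets["PW_planted"] = planted
    tf_sets = random_sets(s.n_tf_sets, "tf_regulon", "TF")
    mirna_sets = random_sets(s.n_mirna_sets, "mirna_targets", "MIR")
    basis = BasisMatrix(
        matrix=np.abs(resource_rng.lognormal(mean=2.0, sigma=1.0, size=(s.n_genes, s.n_celltypes))),
        gene_ids=gene_ids,
        celltype_names=[f"celltype_{i}" for i in range(s.n_celltypes)],
    )
    panel = sorted(resource_rng.choice(gene_ids, size=s.panel_size, replace=False))
    return collections, (pathway_sets, tf_sets, mirna_sets), basis, panel


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> Path:
    """Run every stage on synthetic data and write per-stage artifacts."""
    config.validate()
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ----------------------------------------------------------
    collections, set_collections, basis, panel = simulate_inputs(config, seed)
    resources = outdir / "resources"
    resources.mkdir(exist_ok=True)
    for sets in set_collections:
        write_gene_sets(sets, resources / f"{sets.category}.gmt")
    write_basis_matrix(basis, resources / "basis.tsv")
    (resources / "cytokine_panel.txt").write_text("\n".join(panel) + "\n")

    # --- filter ------------------------------------------------------------
    collections = {
        d: filter_collection(
            c,
            min_patients=config.filters.min_patients,
            baseline_only=config.filters.baseline_only,
            untreated_only=config.filters.untreated_only,
        )
        for d, c in collections.items()
    }

    # --- featurize ---------------------------------------------------------
    feature_cache: dict[str, tuple[list[str], np.ndarray]] = {}
    for collection in collections.values():
        for study in collection:
            stacked = stack_features(
                featurize_study(
                    study,
                    sets_by_category=set_collections,
                    basis=basis,
                    panel=panel,
                    alpha=config.features.alpha,
                    min_overlap=config.features.min_overlap,
                )
            )
            feature_cache[study.study_id] = (stacked.feature_ids, stacked.matrix)

    def feature_extractor(study):
        return feature_cache[study.study_id]

    # --- meta-analysis: genes and features ---------------------------------
    meta_dir = outdir / "meta"
    meta_dir.mkdir(exist_ok=True)
    gene_tables, feature_tables = {}, {}
    for disease, collection in sorted(collections.items()):
        gene_tables[disease] = meta_analyze(collection, min_studies=config.meta.min_studies)
        feature_tables[disease] = meta_analyze(
            collection, extractor=feature_extractor, min_studies=config.meta.min_studies
        )
        _write_tsv(gene_tables[disease], meta_dir / f"genes.{disease}.tsv")
        _write_tsv(feature_tables[disease], meta_dir / f"features.{disease}.tsv")

    # --- landscape ----------------------------------------------------------
    feature_types = {
        fid: fid.split(":", 1)[0]
        for ids, _ in feature_cache.values()
        for fid in ids
    }
    full_landscape = build_landscape(feature_tables, compartment="blood", feature_types=feature_types)
    sig_landscape = significant_features(full_landscape, threshold=config.meta.fdr_threshold)
    write_landscape(sig_landscape, outdir / "landscape")

    # --- modules ------------------------------------------------------------
    corr = feature_correlation_matrix(sig_landscape)
    _write_tsv(corr, outdir / "feature_correlation.tsv")
    k = min(config.modules.k, corr.shape[0])
    module_set = cluster_features(corr, k=k, method=config.modules.linkage)
    module_set.to_json(outdir / "modules.json")
    stability, robustness_p = cluster_number_robustness(
        sig_landscape,
        k=k,
        n_perturbations=config.modules.n_perturbations,
        noise_sd_fraction=config.modules.noise_sd_fraction,
        seed=seed,
        n_null=config.modules.n_null,
        method=config.modules.linkage,
    )

    # --- module scores and AUC validation -----------------------------------
    score_dir = outdir / "scores"
    score_dir.mkdir(exist_ok=True)
    auc_rows, summaries = [], []
    score_frames: dict[str, pd.DataFrame] = {}
    for disease, collection in sorted(collections.items()):
        per_module_records: dict[int, list] = {}
        for study in collection:
            ids, matrix = feature_cache[study.study_id]
            fm = FeatureMatrix(
                feature_ids=ids,
                feature_type="mixed",
                matrix=matrix,
                study_id=study.study_id,
                sample_ids=study.sample_ids,
            )
            scores = module_scores(fm, module_set)
            score_frames[study.study_id] = scores.to_frame()
            labels = np.array([s.cls for s in study.samples])
            for row, mid in enumerate(scores.module_ids):
                if not np.all(np.isfinite(scores.scores[row])):
                    continue
                rec = module_auc(scores.scores[row], labels, module_id=mid, study_id=study.study_id)
                per_module_records.setdefault(mid, []).append(rec)
                auc_rows.append(
                    {
                        "disease": disease,
                        "module_id": mid,
                        "study_id": study.study_id,
                        "auc": rec.auc,
                        "p": rec.p,
                        "n_case": rec.n_case,
                        "n_control": rec.n_control,
                    }
                )
        for mid, records in sorted(per_module_records.items()):
            summary = aggregate_module_auc(records, disease=disease, compartment="blood")
            summaries.append(summary.__dict__)
    for study_id, frame in sorted(score_frames.items()):
        _write_tsv(frame, score_dir / f"{study_id}.tsv")
    pd.DataFrame(auc_rows).to_csv(outdir / "module_auc.tsv", sep="\t", index=False, float_format=_FLOAT)
    pd.DataFrame(summaries).to_csv(
        outdir / "module_enrichment.tsv", sep="\t", index=False, float_format=_FLOAT
    )

    # --- permutation validation of the strongest module ---------------------
    module_effect = {
        mid: float(sig_landscape.effect.loc[[f for f in feats if f in sig_landscape.effect.index]].mean().mean())
        for mid, feats in module_set.modules.items()
    }
    target = max(module_effect, key=lambda m: abs(module_effect[m]))
    first_disease = sorted(collections)[0]
    study = collections[first_disease].studies[0]
    ids, matrix = feature_cache[study.study_id]
    fm = FeatureMatrix(
        feature_ids=ids,
        feature_type="mixed",
        matrix=matrix,
        study_id=study.study_id,
        sample_ids=study.sample_ids,
    )
    try:
        perm = permutation_module_test(
            target,
            module_set,
            fm,
            np.array([s.cls for s in study.samples]),
            n_perm=config.validation.n_perm,
            seed=seed,
        )
    except ValueError as exc:  # e.g. pool smaller than module
        perm = {"error": str(exc)}
    perm_out = {"target_module": target, **perm}

    # --- enrichment ---------------------------------------------------------
    table = gene_tables[first_disease]
    query = sorted(table.index[(table["fdr"] < config.meta.fdr_threshold) & (table["estimate"] > 0)])
    background = sorted(table.index)
    enrichment_table = None
    if query:
        enrichment_table = hypergeometric_enrichment(query, background, set_collections[0])
        _write_tsv(enrichment_table, outdir / "enrichment.tsv")

    # --- manifest -----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "diseases": sorted(collections),
        "n_studies": sum(len(c) for c in collections.values()),
        "n_samples": sum(c.n_samples for c in collections.values()),
        "n_significant_features": int(sig_landscape.effect.shape[0]),
        "module_k": k,
        "cluster_stability": stability,
        "cluster_robustness_p": robustness_p,
        "permutation_validation": perm_out,
        "enrichment_query_size": len(query),
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return outdir
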