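# immunometa

Cross-disease immune meta-analysis toolkit for bulk transcriptomics.
It implements an end-to-end, fully testable pipeline:

1. **Data model** — TSV expression matrices (genes × samples) with sample
   metadata, GMT gene sets, a cell-type basis matrix; log-scale
   harmonization (TPM for raw counts) and study/sample inclusion filters
   (≥4 patients, baseline-only, untreated-only).
2. **Synthetic data** — seeded generators for multi-study case–control
   collections with planted standardized effects and between-study
   heterogeneity, block-correlated feature landscapes, and ground-truth
   cell-type mixtures.
3. **Meta-analysis** — Hedges' g per study, DerSimonian–Laird τ², inverse
   variance random-effects pooling, Benjamini–Hochberg FDR and Fisher's
   combined p.
4. **Featurization** — five immune feature families: cell proportions
   (NNLS deconvolution against a basis matrix), pathway / TF-regulon /
   miRNA-target activity (single-sample rank-based enrichment scores), and
   cytokine-panel expression.
5. **Landscape** — features × diseases matrices of pooled effects with
   significance filtering and blood-vs-tissue overlap/concordance summaries.
6. **Module discovery** — pairwise Spearman correlation of feature effect
   profiles, hierarchical clustering (Ward by default) cut into k modules,
   and perturbation-based robustness of the cluster number with a
   shuffled-profile null.
7. **Module validation** — per-sample aggregate module scores (sum of
   z-scaled features), size-matched permutation nulls, per-study AUC with
   mean/1-over-SD stability summaries, treatment-response AUC with explicit
   directionality, and severity correlations.
8. **Enrichment** — hypergeometric over-representation with fold enrichment
   and BH FDR.

## CLI

```bash
# full synthetic pipeline (all stages, deterministic artifacts + manifest)
immunometa run --config config.yaml --seed 42 --outdir results/

# individual stages
immunometa simulate --n-genes 200 --n-studies 3 --seed 1 --outdir sim/
immunometa meta --study sim/study0.matrix.tsv sim/study0.metadata.tsv \
                --study sim/study1.matrix.tsv sim/study1.metadata.tsv \
                --out pooled.tsv
immunometa modules --landscape-prefix results/landscape --k 15 --out modules.json
immunometa enrich --query up.txt --background bg.txt --gmt pathways.gmt --out ora.tsv
```

The YAML config mirrors `immunometa.config.PipelineConfig`; any section or
key may be omitted to use defaults, e.g.:

```yaml
seed: 42
synthetic: {n_diseases: 10, n_studies_per_disease: 3, n_genes: 500}
modules: {k: 15, linkage: ward}
validation: {n_perm: 1000}
```

Re-running `immunometa run` with the same config and seed produces
byte-identical numeric artifacts.

## Real data

Expression matrices are plain TSV (first column gene id, header sample
ids); metadata needs columns `sample_id, study_id, disease, class,
compartment` (optional: `tissue_name, timepoint, treated, response,
severity`). Gene sets use GMT. A basis matrix is a genes × cell-types TSV.
Content collections (MSigDB, regulon or target databases, basis matrices,
cytokine panels) are user-supplied and not shipped.
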