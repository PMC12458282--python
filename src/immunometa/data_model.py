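"""Core data types, file I/O, harmonization and inclusion filters.

Expression matrices are tab-delimited with genes in rows (first column the
gene id, header row the sample ids).  Sample metadata is a TSV/CSV with one
row per sample.  Gene sets travel as GMT.  All downstream analysis assumes
log-scale expression; :func:`harmonize_study` enforces that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    ParseError,
    PipelineError,
    SchemaError,
)

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = ("sample_id", "study_id", "disease", "class", "compartment")
CLASS_VALUES = ("case", "control")
COMPARTMENT_VALUES = ("blood", "tissue")

#: matrices whose maximum exceeds this are assumed to be on a linear scale
DEFAULT_LOG_THRESHOLD = 50.0


@dataclass
class SampleMetadata:
    """Per-sample annotations; optional clinical fields may be ``None``."""

    sample_id: str
    study_id: str
    disease: str
    cls: str  # "case" | "control"
    compartment: str  # "blood" | "tissue"
    tissue_name: str | None = None
    timepoint: str | None = None
    treated: bool | None = None
    response: str | None = None  # "responder" | "non_responder"
    severity: float | None = None

    def __post_init__(self) -> None:
        if self.cls not in CLASS_VALUES:
            raise SchemaError(
                f"sample {self.sample_id!r}: class must be one of {CLASS_VALUES}, got {self.cls!r}"
            )
        if self.compartment not in COMPARTMENT_VALUES:
            raise SchemaError(
                f"sample {self.sample_id!r}: compartment must be one of "
                f"{COMPARTMENT_VALUES}, got {self.compartment!r}"
            )
        if self.severity is not None and not np.isfinite(self.severity):
            raise SchemaError(f"sample {self.sample_id!r}: severity must be finite")


@dataclass
class ExpressionStudy:
    """One case-control study: genes x samples matrix plus metadata."""

    study_id: str
    matrix: np.ndarray
    gene_ids: list[str]
    samples: list[SampleMetadata]
    platform: str = "microarray"
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise SchemaError("expression matrix must be 2-D")
        if self.matrix.shape != (len(self.gene_ids), len(self.samples)):
            raise ConsistencyError(
                f"study {self.study_id!r}: matrix shape {self.matrix.shape} does not "
                f"match {len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ConsistencyError(f"study {self.study_id!r}: duplicate gene ids")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ConsistencyError(f"study {self.study_id!r}: duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def class_mask(self, cls: str) -> np.ndarray:
        return np.array([s.cls == cls for s in self.samples], dtype=bool)

    def validate(self) -> None:
        """Check full invariants (finiteness, both classes present)."""
        if not np.all(np.isfinite(self.matrix)):
            raise ConsistencyError(f"study {self.study_id!r}: non-finite expression values")
        if not (self.class_mask("case").any() and self.class_mask("control").any()):
            raise ConsistencyError(
                f"study {self.study_id!r}: needs at least one case and one control"
            )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionStudy":
        keep = np.asarray(keep, dtype=bool)
        return replace(
            self,
            matrix=self.matrix[:, keep],
            samples=[s for s, k in zip(self.samples, keep) if k],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class StudyCollection:
    """A set of studies, each belonging to one (disease, compartment) stratum."""

    studies: list[ExpressionStudy]

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate study ids in collection")
        for study in self.studies:
            strata = {(m.disease, m.compartment) for m in study.samples}
            if len(strata) > 1:
                raise ConsistencyError(
                    f"study {study.study_id!r} spans multiple (disease, compartment) strata"
                )

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.studies)

    def stratum(self, study: ExpressionStudy) -> tuple[str, str]:
        m = study.samples[0]
        return (m.disease, m.compartment)

    def strata(self) -> dict[tuple[str, str], "StudyCollection"]:
        groups: dict[tuple[str, str], list[ExpressionStudy]] = {}
        for study in self.studies:
            groups.setdefault(self.stratum(study), []).append(study)
        return {key: StudyCollection(v) for key, v in groups.items()}


@dataclass
class GeneSetCollection:
    """Named gene sets of a single category (pathway, tf_regulon, ...)."""

    sets: dict[str, list[str]]
    category: str

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise SchemaError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise SchemaError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class BasisMatrix:
    """Reference expression profiles (genes x cell types) for deconvolution."""

    matrix: np.ndarray
    gene_ids: list[str]
    celltype_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.celltype_names)):
            raise ConsistencyError("basis matrix shape does not match gene/celltype names")
        if len(set(self.celltype_names)) != len(self.celltype_names):
            raise ConsistencyError("duplicate celltype names in basis matrix")
        if np.any(self.matrix < 0):
            raise ConsistencyError("basis matrix must be non-negative")
        if np.linalg.matrix_rank(self.matrix) < len(self.celltype_names):
            logger.warning("basis matrix is column-rank deficient; deconvolution may be unstable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.celltype_names)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_OPTIONAL_COLUMNS = ("tissue_name", "timepoint", "treated", "response", "severity")


def _metadata_from_row(row: Mapping) -> SampleMetadata:
    def opt(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return v

    treated = opt("treated")
    if treated is not None and not isinstance(treated, (bool, np.bool_)):
        treated = str(treated).strip().lower() in ("1", "true", "yes")
    severity = opt("severity")
    if severity is not None:
        severity = float(severity)
    return SampleMetadata(
        sample_id=str(row["sample_id"]),
        study_id=str(row["study_id"]),
        disease=str(row["disease"]),
        cls=str(row["class"]),
        compartment=str(row["compartment"]),
        tissue_name=opt("tissue_name"),
        timepoint=None if opt("timepoint") is None else str(opt("timepoint")),
        treated=treated,
        response=None if opt("response") is None else str(opt("response")),
        severity=severity,
    )


def read_metadata(metadata_path) -> list[SampleMetadata]:
    sep = "," if str(metadata_path).endswith(".csv") else "\t"
    table = pd.read_csv(metadata_path, sep=sep)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"metadata file {metadata_path} missing columns: {missing}")
    return [_metadata_from_row(row) for _, row in table.iterrows()]


def load_expression_study(matrix_path, metadata_path, platform: str = "microarray") -> ExpressionStudy:
    """Read a genes-in-rows TSV matrix plus its sample-metadata table.

    Matrix columns are reordered to follow the metadata row order; duplicate
    gene rows are collapsed by their mean.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = read_metadata(metadata_path)
    sample_ids = [s.sample_id for s in samples]
    missing = sorted(set(sample_ids) - set(map(str, frame.columns)))
    if missing:
        raise ConsistencyError(
            f"samples listed in metadata but absent from matrix header: {missing}"
        )
    frame.columns = frame.columns.map(str)
    frame = frame.loc[:, sample_ids]
    if frame.index.has_duplicates:
        frame = frame.groupby(level=0, sort=False).mean()
    study_ids = {s.study_id for s in samples}
    if len(study_ids) != 1:
        raise ConsistencyError(f"metadata spans multiple study ids: {sorted(study_ids)}")
    return ExpressionStudy(
        study_id=study_ids.pop(),
        matrix=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        samples=samples,
        platform=platform,
    )


def write_expression_study(study: ExpressionStudy, matrix_path, metadata_path) -> None:
    study.to_frame().to_csv(matrix_path, sep="\t", float_format="%.10g")
    rows = []
    for s in study.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "study_id": s.study_id,
                "disease": s.disease,
                "class": s.cls,
                "compartment": s.compartment,
                "tissue_name": s.tissue_name,
                "timepoint": s.timepoint,
                "treated": s.treated,
                "response": s.response,
                "severity": s.severity,
            }
        )
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def load_gene_sets(gmt_path, category: str = "pathway") -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...) into a collection."""
    sets: dict[str, list[str]] = {}
    with open(gmt_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{gmt_path}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                logger.warning("gene set %r at %s:%d is empty; dropped", name, gmt_path, lineno)
                continue
            sets[name] = genes
    return GeneSetCollection(sets=sets, category=category)


def write_gene_sets(collection: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w") as handle:
        for name, genes in collection.sets.items():
            handle.write("\t".join([name, collection.category, *genes]) + "\n")


def load_basis_matrix(path) -> BasisMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return BasisMatrix(
        matrix=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        celltype_names=[str(c) for c in frame.columns],
    )


def write_basis_matrix(basis: BasisMatrix, path) -> None:
    basis.to_frame().to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Harmonization and filtering
# ---------------------------------------------------------------------------


def tpm_normalize(counts: np.ndarray, gene_lengths_kb: np.ndarray) -> np.ndarray:
    """Transcripts-per-million from raw counts and gene lengths in kilobases."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths_kb, dtype=float).reshape(-1, 1)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    rate = counts / lengths
    total = rate.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(total > 0, rate / total * 1e6, 0.0)
    return tpm


def harmonize_study(
    study: ExpressionStudy,
    counts_are_raw: bool = False,
    gene_lengths_kb: Sequence[float] | None = None,
    log_threshold: float = DEFAULT_LOG_THRESHOLD,
) -> ExpressionStudy:
    """Bring a study onto log2 scale (TPM first for raw counts).

    Already-log data (max value <= ``log_threshold``) pass through unchanged,
    making the operation idempotent.
    """
    matrix = study.matrix
    if counts_are_raw:
        if np.any(matrix < 0):
            raise ValueError(f"study {study.study_id!r}: negative values in raw counts")
        if gene_lengths_kb is None:
            raise ValueError("gene_lengths_kb required for TPM normalization of raw counts")
        matrix = tpm_normalize(matrix, np.asarray(gene_lengths_kb))
        matrix = np.log2(matrix + 1.0)
    elif matrix.size and np.nanmax(matrix) > log_threshold:
        if np.any(matrix < 0):
            raise ValueError(
                f"study {study.study_id!r}: matrix looks linear-scale (max > "
                f"{log_threshold}) but has negative values"
            )
        matrix = np.log2(matrix + 1.0)
    return replace(study, matrix=matrix, log_scale=True)


def filter_collection(
    collection: StudyCollection,
    min_patients: int = 4,
    baseline_only: bool = True,
    untreated_only: bool = True,
) -> StudyCollection:
    """Apply study/sample inclusion filters.

    Keeps baseline samples in longitudinal studies, drops treated samples when
    treatment status is annotated, removes studies with fewer than
    ``min_patients`` subjects or without both classes.  Missing optional
    metadata passes with a logged warning.
    """
    kept: list[ExpressionStudy] = []
    attrition: list[dict] = []
    for study in collection:
        record = {"study_id": study.study_id, "n_in": study.n_samples}
        current = study
        if baseline_only:
            timepoints = {s.timepoint for s in current.samples if s.timepoint is not None}
            if len(timepoints) > 1:
                baseline = _baseline_timepoint(timepoints)
                keep = np.array(
                    [s.timepoint is None or s.timepoint == baseline for s in current.samples]
                )
                current = current.subset_samples(keep)
                record["baseline_kept"] = int(keep.sum())
            elif not timepoints:
                logger.debug("study %s: no timepoint info; baseline filter passes", study.study_id)
        if untreated_only:
            if any(s.treated is not None for s in current.samples):
                keep = np.array([s.treated is not True for s in current.samples])
                current = current.subset_samples(keep)
                record["untreated_kept"] = int(keep.sum())
            else:
                logger.debug("study %s: no treatment info; filter passes", study.study_id)
        record["n_after_sample_filters"] = current.n_samples
        if current.n_samples < min_patients:
            record["dropped"] = f"fewer than {min_patients} patients"
            attrition.append(record)
            continue
        if not (current.class_mask("case").any() and current.class_mask("control").any()):
            record["dropped"] = "missing case or control samples"
            attrition.append(record)
            continue
        attrition.append(record)
        kept.append(current)
    if not kept:
        raise PipelineError(f"all studies removed by filters; attrition: {attrition}")
    return StudyCollection(kept)


_BASELINE_NAMES = ("baseline", "t0", "week0", "day0", "pre", "pretreatment", "0")


def _baseline_timepoint(timepoints: Iterable[str]) -> str:
    named = [t for t in timepoints if t.strip().lower() in _BASELINE_NAMES]
    if named:
        return named[0]
    # fall back to lexicographically smallest (e.g. "week00" < "week12")
    return sorted(timepoints)[0]
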