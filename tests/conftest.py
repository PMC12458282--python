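import numpy as np
import pytest

from immunometa.data_model import (
    ExpressionStudy,
    SampleMetadata,
    StudyCollection,
)


def make_samples(study_id, n_case, n_control, disease="lupus", compartment="blood", **extra):
    samples = []
    for i in range(n_case + n_control):
        samples.append(
            SampleMetadata(
                sample_id=f"{study_id}_s{i}",
                study_id=study_id,
                disease=disease,
                cls="case" if i < n_case else "control",
                compartment=compartment,
                **{k: (v[i] if isinstance(v, (list, tuple)) else v) for k, v in extra.items()},
            )
        )
    return samples


def make_study(
    study_id="s1",
    n_genes=20,
    n_case=4,
    n_control=4,
    seed=0,
    disease="lupus",
    compartment="blood",
    **extra,
):
    rng = np.random.default_rng(seed)
    matrix = rng.normal(7.0, 1.0, size=(n_genes, n_case + n_control))
    return ExpressionStudy(
        study_id=study_id,
        matrix=matrix,
        gene_ids=[f"G{i:03d}" for i in range(n_genes)],
        samples=make_samples(study_id, n_case, n_control, disease, compartment, **extra),
    )


@pytest.fixture
def small_study():
    return make_study()


@pytest.fixture
def small_collection():
    return StudyCollection([make_study(f"s{i}", seed=i) for i in range(3)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
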