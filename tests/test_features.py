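import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunometa.data_model import BasisMatrix, GeneSetCollection
from immunometa.errors import DegenerateInputError, InsufficientDataError, PipelineError
from immunometa.features import (
    cytokine_panel,
    deconvolve_sample,
    featurize_cell_proportions,
    featurize_gene_sets,
    featurize_study,
    ssgsea_score,
    stack_features,
)
from immunometa.synthetic import generate_mixture_study

from conftest import make_study


def brute_force_ssgsea(expression, gene_ids, gene_set, alpha=0.0):
    """Independent enumeration of the running in/out ECDF difference."""
    order = sorted(range(len(expression)), key=lambda i: (-expression[i], i))
    n = len(order)
    in_set = [gene_ids[i] in set(gene_set) for i in order]
    ranks = {}
    for pos, idx in enumerate(order):
        ranks[idx] = n - pos  # top gene gets rank n
    total_w = sum(ranks[idx] ** alpha for idx, flag in zip(order, in_set) if flag)
    n_out = n - sum(in_set)
    devs, cum_in, cum_out = [], 0.0, 0.0
    for idx, flag in zip(order, in_set):
        if flag:
            cum_in += ranks[idx] ** alpha / total_w
        else:
            cum_out += 1.0 / n_out
        devs.append(cum_in - cum_out)
    pos, neg = max(devs), min(devs)
    # same tie convention as the implementation: exact |max| ties go positive
    return pos if pos + neg >= -1e-9 else neg


class TestSsgseaScore:
    def test_top_concentrated_set_scores_one(self):
        expr = np.array([9.0, 8.0, 7.0, 1.0, 0.5, 0.2])
        genes = list("abcdef")
        assert ssgsea_score(expr, genes, ["a", "b", "c"], alpha=0.0) == pytest.approx(1.0)

    def test_spec_example_six_genes(self):
        expr = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        genes = [f"g{i}" for i in range(1, 7)]
        score = ssgsea_score(expr, genes, ["g1", "g4"], alpha=0.0)
        assert score == pytest.approx(brute_force_ssgsea(expr, genes, ["g1", "g4"]))
        assert score == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_random(self, alpha, rng):
        genes = [f"g{i}" for i in range(8)]
        for _ in range(30):
            expr = rng.normal(size=8)
            size = rng.integers(1, 7)
            gene_set = list(rng.choice(genes, size=size, replace=False))
            assert ssgsea_score(expr, genes, gene_set, alpha=alpha) == pytest.approx(
                brute_force_ssgsea(expr, genes, gene_set, alpha=alpha), abs=1e-12
            )

    @given(
        st.lists(st.integers(-10_000, 10_000), min_size=5, max_size=12, unique=True),
        st.floats(0.01, 5.0),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, values, scale, power):
        # integer-valued expression keeps affine maps strictly monotone in floats
        expr = np.array(values, dtype=float)
        genes = [f"g{i}" for i in range(len(values))]
        gene_set = genes[:2]
        base = ssgsea_score(expr, genes, gene_set)
        # strictly monotone maps: affine and odd-power compositions
        shifted = ssgsea_score(scale * expr + 3.0, genes, gene_set)
        ranked = np.argsort(np.argsort(expr)).astype(float)
        powered = ssgsea_score(np.sign(ranked + 1) * (ranked + 1) ** power, genes, gene_set)
        assert base == pytest.approx(shifted, abs=1e-12)
        assert base == pytest.approx(powered, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        expr = np.arange(4.0)
        genes = list("abcd")
        with pytest.raises(DegenerateInputError):
            ssgsea_score(expr, genes, ["zz"])
        with pytest.raises(DegenerateInputError):
            ssgsea_score(expr, genes, genes)

    def test_sum_variant(self):
        expr = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        genes = [f"g{i}" for i in range(1, 7)]
        score = ssgsea_score(expr, genes, ["g1", "g4"], alpha=0.0, method="sum")
        # running devs: .5,.25,0,.5,.25,0 -> mean 0.25
        assert score == pytest.approx(0.25)


class TestFeaturizeGeneSets:
    def test_shape_contract(self):
        study = make_study(n_genes=30, n_case=1, n_control=1)
        sets = GeneSetCollection({"S1": study.gene_ids[:6]}, category="pathway")
        fm = featurize_gene_sets(study, sets)
        assert fm.matrix.shape == (1, 2)
        assert fm.feature_type == "pathway"

    def test_duplicated_sample_column_duplicates_score(self):
        study = make_study(n_genes=30, n_case=2, n_control=2, seed=3)
        study.matrix[:, 1] = study.matrix[:, 0]
        sets = GeneSetCollection({"S1": study.gene_ids[:8]}, category="pathway")
        fm = featurize_gene_sets(study, sets)
        assert fm.matrix[0, 0] == fm.matrix[0, 1]

    def test_small_sets_dropped(self):
        study = make_study(n_genes=30)
        sets = GeneSetCollection(
            {"big": study.gene_ids[:10], "small": study.gene_ids[:2]}, category="pathway"
        )
        fm = featurize_gene_sets(study, sets, min_overlap=5)
        assert fm.feature_ids == ["big"]

    def test_all_sets_dropped_raises(self):
        study = make_study(n_genes=30)
        sets = GeneSetCollection({"tiny": study.gene_ids[:2]}, category="pathway")
        with pytest.raises(PipelineError):
            featurize_gene_sets(study, sets)

    def test_matches_scalar_scores(self):
        study = make_study(n_genes=25, seed=6)
        sets = GeneSetCollection(
            {"S1": study.gene_ids[:7], "S2": study.gene_ids[5:15]}, category="pathway"
        )
        fm = featurize_gene_sets(study, sets, alpha=0.25)
        for i, name in enumerate(fm.feature_ids):
            for j in range(study.n_samples):
                expected = ssgsea_score(
                    study.matrix[:, j], study.gene_ids, sets.sets[name], alpha=0.25
                )
                assert fm.matrix[i, j] == pytest.approx(expected, abs=1e-12)


@pytest.fixture
def basis(rng):
    return BasisMatrix(
        matrix=rng.uniform(1.0, 20.0, size=(240, 4)),
        gene_ids=[f"G{i:03d}" for i in range(240)],
        celltype_names=["T", "B", "NK", "Mono"],
    )


class TestDeconvolution:
    def test_identity_mixture(self, basis):
        props = deconvolve_sample(basis.matrix[:, 2], basis.gene_ids, basis, delog=False)
        np.testing.assert_allclose(props, [0, 0, 1, 0], atol=1e-8)

    def test_equal_mix(self, basis):
        mixed = 0.5 * basis.matrix[:, 0] + 0.5 * basis.matrix[:, 1]
        props = deconvolve_sample(mixed, basis.gene_ids, basis, delog=False)
        np.testing.assert_allclose(props, [0.5, 0.5, 0, 0], atol=1e-8)

    def test_noisy_recovery(self, basis, rng):
        truth = rng.dirichlet(np.ones(4), size=12).T
        noise_sd = 0.1 * basis.matrix.mean()
        mix = generate_mixture_study(basis, truth, noise_sd=noise_sd, seed=5)
        fm = featurize_cell_proportions(mix.study, basis)
        err = np.abs(fm.matrix - truth).max()
        assert err < 0.05

    def test_proportions_sum_to_one(self, basis, rng):
        expr = rng.uniform(0, 30, size=240)
        props = deconvolve_sample(expr, basis.gene_ids, basis, delog=False)
        assert props.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(props >= 0)

    def test_insufficient_shared_genes(self, basis):
        with pytest.raises(InsufficientDataError):
            deconvolve_sample(np.ones(2), ["G000", "G001"], basis, delog=False)

    def test_delog_path(self, basis):
        # log2(x+1)-transformed mixture must deconvolve after de-logging
        mixed = 0.25 * basis.matrix[:, 0] + 0.75 * basis.matrix[:, 3]
        logged = np.log2(mixed + 1.0)
        props = deconvolve_sample(logged, basis.gene_ids, basis, delog=True)
        np.testing.assert_allclose(props, [0.25, 0, 0, 0.75], atol=1e-8)


class TestCytokinePanel:
    def test_pure_subset(self):
        study = make_study(n_genes=20)
        panel = study.gene_ids[3:8]
        fm = cytokine_panel(study, panel)
        assert fm.feature_ids == panel
        np.testing.assert_array_equal(fm.matrix, study.matrix[3:8])
        assert fm.feature_type == "cytokine"

    def test_partial_overlap(self):
        study = make_study(n_genes=20)
        panel = [study.gene_ids[0]] + [f"MISSING{i}" for i in range(274)]
        fm = cytokine_panel(study, panel)
        assert fm.matrix.shape == (1, study.n_samples)

    def test_zero_overlap_raises(self):
        study = make_study(n_genes=5)
        with pytest.raises(DegenerateInputError):
            cytokine_panel(study, ["NOPE"])


class TestFeaturizeStudy:
    def _inputs(self, rng):
        study = make_study(n_genes=80, n_case=3, n_control=3, seed=7)
        sets = [
            GeneSetCollection({"PW1": study.gene_ids[:10], "PW2": study.gene_ids[10:25]}, "pathway"),
            GeneSetCollection({"TF1": study.gene_ids[30:40]}, "tf_regulon"),
            GeneSetCollection({"MIR1": study.gene_ids[40:50]}, "mirna_targets"),
        ]
        basis = BasisMatrix(
            matrix=rng.uniform(1, 20, size=(80, 3)),
            gene_ids=study.gene_ids,
            celltype_names=["T", "B", "NK"],
        )
        panel = study.gene_ids[60:70]
        return study, sets, basis, panel

    def test_five_families_share_sample_order(self, rng):
        study, sets, basis, panel = self._inputs(rng)
        fms = featurize_study(study, sets_by_category=sets, basis=basis, panel=panel)
        assert [fm.feature_type for fm in fms] == [
            "cell_proportion", "pathway", "tf_regulon", "mirna_targets", "cytokine",
        ]
        for fm in fms:
            assert fm.sample_ids == study.sample_ids

    def test_optional_basis(self, rng):
        study, sets, _, panel = self._inputs(rng)
        fms = featurize_study(study, sets_by_category=sets, basis=None, panel=panel)
        assert "cell_proportion" not in {fm.feature_type for fm in fms}
        assert len(fms) == 4

    def test_deterministic(self, rng):
        study, sets, basis, panel = self._inputs(rng)
        a = stack_features(featurize_study(study, sets, basis, panel))
        b = stack_features(featurize_study(study, sets, basis, panel))
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_stack_rejects_mismatched_samples(self, rng):
        study, sets, basis, panel = self._inputs(rng)
        fms = featurize_study(study, sets, basis, panel)
        other = make_study(n_genes=80, n_case=2, n_control=2, study_id="other")
        fms2 = featurize_study(other, sets_by_category=sets[:1])
        with pytest.raises(ValueError, match="sample ordering"):
            stack_features([fms[0], fms2[0]])
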