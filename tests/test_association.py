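"""Per-disease L1-penalized logistic regression and source combination."""

import numpy as np
import pytest

import netrepos as nr
from netrepos.association import (
    build_association_matrix,
    combine_sources,
    fit_disease_model,
)


def membership(universe, rows, entities=None, provenance=("text", "degree")):
    rows = np.asarray(rows, dtype=bool)
    entities = entities or tuple(f"e{i}" for i in range(rows.shape[0]))
    return nr.MembershipMatrix(
        entity_ids=tuple(entities), universe=universe, values=rows, provenance=provenance
    )


@pytest.fixture(scope="module")
def planted_problem():
    """One drug's vector copied as the disease response among random drugs."""
    rng = np.random.default_rng(0)
    n_genes, n_drugs = 500, 21
    uni = nr.GeneUniverse(genes=tuple(f"g{i:03d}" for i in range(n_genes)))
    drug_rows = rng.random((n_drugs, n_genes)) < 0.15
    disease_row = drug_rows[0].copy()
    return uni, membership(uni, drug_rows), disease_row


class TestFitDiseaseModel:
    def test_true_predictor_gets_largest_positive_coefficient(self, planted_problem):
        uni, drug_m, disease_row = planted_problem
        coef, diag = fit_disease_model(disease_row, drug_m, penalty=0.5, seed=0)
        assert np.argmax(coef) == 0
        assert coef[0] > 0
        assert diag.converged

    def test_matches_single_predictor_logit_direction(self, planted_problem):
        """Sanity against the closed-form odds ratio of the one true predictor.

        With response == predictor the unpenalized single-predictor logistic
        slope diverges; the penalized slope must be large and positive while
        noise drugs stay near zero.
        """
        uni, drug_m, disease_row = planted_problem
        coef, _ = fit_disease_model(disease_row, drug_m, penalty=0.5, seed=0)
        assert coef[0] > 10 * max(1e-9, np.abs(np.delete(coef, 0)).max())

    def test_all_zero_response_degenerate(self, planted_problem):
        uni, drug_m, _ = planted_problem
        coef, diag = fit_disease_model(np.zeros(len(uni), dtype=bool), drug_m, penalty=1.0)
        assert not coef.any()
        assert diag.degenerate

    def test_all_zero_drug_matrix_intercept_is_logit_mean(self):
        uni = nr.GeneUniverse(genes=tuple(f"g{i}" for i in range(100)))
        drug_m = membership(uni, np.zeros((5, 100)))
        y = np.zeros(100, dtype=bool)
        y[:30] = True
        coef, diag = fit_disease_model(y, drug_m, penalty=1.0)
        assert not coef.any()
        assert diag.intercept == pytest.approx(np.log(0.3 / 0.7), abs=1e-9)

    def test_deterministic_given_seed(self, planted_problem):
        uni, drug_m, disease_row = planted_problem
        a, _ = fit_disease_model(disease_row, drug_m, penalty="path", seed=3)
        b, _ = fit_disease_model(disease_row, drug_m, penalty="path", seed=3)
        assert np.array_equal(a, b)

    def test_coefficients_vanish_as_penalty_grows(self, planted_problem):
        """Monotone nonzero count down the penalty grid; all zero at the end."""
        uni, drug_m, disease_row = planted_problem
        nnz = []
        for penalty in (0.1, 1.0, 10.0, 1000.0):
            coef, _ = fit_disease_model(disease_row, drug_m, penalty=penalty, seed=0)
            nnz.append(int((coef != 0).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))
        assert nnz[-1] == 0

    def test_dimension_mismatch_rejected(self, planted_problem):
        uni, drug_m, _ = planted_problem
        with pytest.raises(nr.ValidationError):
            fit_disease_model(np.zeros(7, dtype=bool), drug_m, penalty=1.0)


class TestBuildAssociationMatrix:
    def test_planted_pairs_recovered(self):
        rng = np.random.default_rng(1)
        n_genes, n_drugs = 400, 12
        uni = nr.GeneUniverse(genes=tuple(f"g{i:03d}" for i in range(n_genes)))
        drug_rows = rng.random((n_drugs, n_genes)) < 0.1
        disease_rows = np.stack([drug_rows[2], drug_rows[7]])
        drug_m = membership(uni, drug_rows, entities=[f"drug{i}" for i in range(n_drugs)])
        disease_m = membership(uni, disease_rows, entities=["disA", "disB"])
        assoc = build_association_matrix(
            disease_m, drug_m, nr.PipelineConfig(penalty=0.5, seed=1)
        )
        calls = assoc.calls
        assert calls[2, 0] and calls[7, 1]
        # the planted drug dominates every other call in its column
        assert np.argmax(assoc.scores[:, 0]) == 2
        assert np.argmax(assoc.scores[:, 1]) == 7

    def test_all_zero_disease_matrix(self):
        uni = nr.GeneUniverse(genes=tuple(f"g{i}" for i in range(50)))
        drug_m = membership(uni, np.random.default_rng(0).random((4, 50)) < 0.2)
        disease_m = membership(uni, np.zeros((3, 50)))
        assoc = build_association_matrix(disease_m, drug_m, nr.PipelineConfig(penalty=1.0))
        assert not assoc.scores.any()
        assert not assoc.calls.any()

    def test_drug_permutation_permutes_rows(self):
        rng = np.random.default_rng(2)
        uni = nr.GeneUniverse(genes=tuple(f"g{i:03d}" for i in range(200)))
        drug_rows = rng.random((6, 200)) < 0.2
        disease_m = membership(uni, [drug_rows[3]], entities=["dis"])
        ids = tuple(f"drug{i}" for i in range(6))
        perm = [4, 2, 0, 5, 1, 3]
        a = build_association_matrix(
            disease_m, membership(uni, drug_rows, entities=ids),
            nr.PipelineConfig(penalty=0.5, seed=0),
        )
        b = build_association_matrix(
            disease_m,
            membership(uni, drug_rows[perm], entities=[ids[i] for i in perm]),
            nr.PipelineConfig(penalty=0.5, seed=0),
        )
        for i, j in enumerate(perm):
            assert b.scores[i, 0] == pytest.approx(a.scores[j, 0], abs=1e-6)

    def test_calls_strictly_positive_only(self):
        uni = nr.GeneUniverse(genes=("g1", "g2"))
        assoc = nr.AssociationMatrix(
            drug_ids=("d1", "d2", "d3"), disease_ids=("x",),
            scores=np.array([[0.5], [0.0], [-0.3]]), diagnostics={},
        )
        assert assoc.calls.ravel().tolist() == [True, False, False]


class TestCombineSources:
    def _pair(self, uni, a, b):
        return (
            membership(uni, a, provenance=("text", "degree")),
            membership(uni, b, provenance=("expression", "degree")),
        )

    def test_elementwise_or(self):
        uni = nr.GeneUniverse(genes=("g1", "g2", "g3"))
        t, e = self._pair(uni, [[1, 0, 0]], [[0, 0, 1]])
        combined = combine_sources(t, e)
        assert combined.values.tolist() == [[True, False, True]]
        assert combined.provenance == ("combined", "degree")

    def test_idempotent_on_identical(self):
        uni = nr.GeneUniverse(genes=("g1", "g2", "g3"))
        t, e = self._pair(uni, [[1, 1, 0]], [[1, 1, 0]])
        assert combine_sources(t, e).values.tolist() == [[True, True, False]]

    def test_row_sums_dominate_sources(self):
        rng = np.random.default_rng(3)
        uni = nr.GeneUniverse(genes=tuple(f"g{i:02d}" for i in range(40)))
        t, e = self._pair(uni, rng.random((5, 40)) < 0.3, rng.random((5, 40)) < 0.3)
        combined = combine_sources(t, e)
        assert (combined.values.sum(1) >= t.values.sum(1)).all()
        assert (combined.values.sum(1) >= e.values.sum(1)).all()

    def test_measure_mismatch_rejected(self):
        uni = nr.GeneUniverse(genes=("g1",))
        t = membership(uni, [[1]], provenance=("text", "degree"))
        e = membership(uni, [[1]], provenance=("expression", "closeness"))
        with pytest.raises(nr.ValidationError):
            combine_sources(t, e)
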