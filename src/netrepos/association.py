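"""Drug-disease association by per-disease sparse logistic regression.

Each disease's Boolean gene vector (is the gene in the disease's
membership set?) is regressed on the drug membership matrix: genes are the
observations, drugs the predictors, and an L1 penalty keeps the linear
combination sparse — each disease is explained by a few drugs' gene
modules. The signed coefficient is the association score; only strictly
positive coefficients become calls, since a negative weight (a drug whose
module anti-predicts the disease genes) has no repositioning
interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple, Union

import numpy as np
from sklearn.linear_model import LogisticRegression

from .core import (
    MembershipMatrix,
    PipelineConfig,
    ValidationError,
    check_alignment,
)

logger = logging.getLogger("netrepos")

# L1 strengths tried when penalty="path"; C passed to the solver is 1/penalty.
PENALTY_GRID = (0.05, 0.2, 1.0, 5.0, 20.0)


@dataclass
class FitDiagnostics:
    penalty: float
    n_nonzero: int
    converged: bool
    n_iter: int
    intercept: float = 0.0
    degenerate: bool = False


@dataclass
class AssociationMatrix:
    """Real-valued drug x disease coefficient matrix with positive-score calls."""

    drug_ids: Tuple[str, ...]
    disease_ids: Tuple[str, ...]
    scores: np.ndarray
    diagnostics: Dict[str, FitDiagnostics]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValidationError("association matrix shape mismatch")

    @property
    def calls(self) -> np.ndarray:
        return np.isfinite(self.scores) & (self.scores > 0)

    def score_of(self, disease: str, drug: str) -> float:
        return float(
            self.scores[self.drug_ids.index(drug), self.disease_ids.index(disease)]
        )


def _fit_l1_logistic(X, y, penalty: float, seed: int):
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / penalty,
        solver="liblinear",
        max_iter=5000,
        tol=1e-8,
        random_state=seed,
    )
    model.fit(X, y)
    return model


def _held_out_deviance(X, y, penalty: float, seed: int) -> float:
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.permutation(n)
    n_test = max(1, n // 4)
    test, train = idx[:n_test], idx[n_test:]
    if len(np.unique(y[train])) < 2:
        return np.inf
    model = _fit_l1_logistic(X[train], y[train], penalty, seed)
    p = model.predict_proba(X[test])[:, 1]
    eps = 1e-12
    return float(-np.mean(y[test] * np.log(p + eps) + (1 - y[test]) * np.log(1 - p + eps)))


def fit_disease_model(
    disease_row: np.ndarray,
    drug_matrix: MembershipMatrix,
    penalty: Union[float, str] = "path",
    seed: int = 0,
) -> Tuple[np.ndarray, FitDiagnostics]:
    """L1-penalized logistic fit of one disease's gene vector on all drugs.

    Returns the per-drug coefficient vector and fit diagnostics. With
    penalty="path" the strength is chosen from a small grid by deviance on
    a seeded 25% gene holdout, then the model is refit on all genes.
    An all-constant response yields an intercept-only degenerate fit.
    """
    y = np.asarray(disease_row).astype(float)
    X = drug_matrix.values.T.astype(float)  # genes x drugs
    if y.shape[0] != X.shape[0]:
        raise ValidationError("gene dimension of disease row and drug matrix differ")
    n_drugs = X.shape[1]
    if len(np.unique(y)) < 2:
        logger.warning("all-constant disease response; returning intercept-only fit")
        p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return np.zeros(n_drugs), FitDiagnostics(
            penalty=np.nan, n_nonzero=0, converged=True, n_iter=0,
            intercept=float(np.log(p / (1 - p))), degenerate=True,
        )
    if not X.any():
        # no predictor carries any signal: unpenalized MLE is the intercept-only fit
        p = float(y.mean())
        return np.zeros(n_drugs), FitDiagnostics(
            penalty=np.nan, n_nonzero=0, converged=True, n_iter=0,
            intercept=float(np.log(p / (1 - p))), degenerate=True,
        )
    if isinstance(penalty, str):
        if penalty != "path":
            raise ValidationError("penalty must be a positive number or 'path'")
        deviances = [_held_out_deviance(X, y, p, seed) for p in PENALTY_GRID]
        chosen = float(PENALTY_GRID[int(np.argmin(deviances))])
    else:
        if penalty <= 0:
            raise ValidationError("penalty must be positive")
        chosen = float(penalty)
    model = _fit_l1_logistic(X, y, chosen, seed)
    coef = model.coef_.ravel()
    n_iter = int(np.max(model.n_iter_))
    converged = n_iter < model.max_iter
    if not converged:
        logger.warning("logistic fit did not converge (%d iterations)", n_iter)
    return coef, FitDiagnostics(
        penalty=chosen,
        n_nonzero=int(np.sum(coef != 0)),
        converged=converged,
        n_iter=n_iter,
        intercept=float(model.intercept_[0]),
    )


def build_association_matrix(
    disease_matrix: MembershipMatrix,
    drug_matrix: MembershipMatrix,
    config: PipelineConfig,
) -> AssociationMatrix:
    """One sparse logistic fit per disease; columns are coefficient vectors."""
    check_alignment(drug_matrix.universe, disease_matrix)
    n_drugs = len(drug_matrix.entity_ids)
    n_diseases = len(disease_matrix.entity_ids)
    scores = np.zeros((n_drugs, n_diseases))
    diagnostics: Dict[str, FitDiagnostics] = {}
    for j, disease in enumerate(disease_matrix.entity_ids):
        coef, diag = fit_disease_model(
            disease_matrix.values[j], drug_matrix, penalty=config.penalty, seed=config.seed
        )
        scores[:, j] = coef
        diagnostics[disease] = diag
    return AssociationMatrix(
        drug_ids=drug_matrix.entity_ids,
        disease_ids=disease_matrix.entity_ids,
        scores=scores,
        diagnostics=diagnostics,
    )


def combine_sources(text_m: MembershipMatrix, expr_m: MembershipMatrix) -> MembershipMatrix:
    """Element-wise OR of the text and expression membership matrices."""
    if text_m.entity_ids != expr_m.entity_ids:
        raise ValidationError("entity ids differ between sources")
    check_alignment(text_m.universe, expr_m)
    if text_m.provenance[1] != expr_m.provenance[1]:
        raise ValidationError(
            f"centrality provenance mismatch: {text_m.provenance} vs {expr_m.provenance}"
        )
    sources = {text_m.provenance[0], expr_m.provenance[0]}
    if sources != {"text", "expression"}:
        raise ValidationError(f"expected one text and one expression matrix, got {sources}")
    return MembershipMatrix(
        entity_ids=text_m.entity_ids,
        universe=text_m.universe,
        values=text_m.values | expr_m.values,
        provenance=("combined", text_m.provenance[1]),
    )
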