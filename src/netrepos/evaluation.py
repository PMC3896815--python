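"""ROC/AUC evaluation of predicted associations against a gold standard.

Positives are curated disease-drug indications; negatives are sampled
uniformly from pairs with zero literature co-occurrence. AUC is computed
as the Mann-Whitney pair-counting probability that a random positive
outscores a random negative, with ties counted 1/2 — equivalent to the
trapezoidal area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .core import ValidationError
from .association import AssociationMatrix

Pair = Tuple[str, str]  # (disease, drug)


@dataclass
class GoldStandard:
    positives: FrozenSet[Pair]
    negatives: FrozenSet[Pair]

    def __post_init__(self) -> None:
        self.positives = frozenset(self.positives)
        self.negatives = frozenset(self.negatives)
        if self.positives & self.negatives:
            raise ValidationError("positives and negatives overlap")


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def sample_negatives(candidates: Sequence[Pair], n: int, seed: int) -> FrozenSet[Pair]:
    """Uniform random n-subset of zero-co-occurrence pairs, reproducible by seed."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    cand = sorted(set(candidates))
    if n > len(cand):
        raise ValidationError(f"requested {n} negatives from {len(cand)} candidates")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cand), size=n, replace=False)
    return frozenset(cand[i] for i in idx)


def roc_auc(scores: Mapping[Pair, float], gold: GoldStandard) -> RocResult:
    """Pair-counting AUC plus the ROC curve itself."""
    if not gold.positives or not gold.negatives:
        raise ValidationError("gold standard needs at least one positive and one negative")
    for pair in gold.positives | gold.negatives:
        if pair not in scores:
            raise ValidationError(f"no score for gold pair {pair!r}")
    pos = np.array([scores[p] for p in sorted(gold.positives)])
    neg = np.array([scores[p] for p in sorted(gold.negatives)])
    # Mann-Whitney AUC with midrank tie handling
    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    # ROC curve over unique thresholds, descending
    all_scores = np.concatenate([pos, neg])
    thresholds = np.unique(all_scores)[::-1]
    tpr = np.array([np.mean(pos >= t) for t in thresholds])
    fpr = np.array([np.mean(neg >= t) for t in thresholds])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def pair_scores(assoc: AssociationMatrix) -> Dict[Pair, float]:
    """Flatten an association matrix into (disease, drug) -> score."""
    out: Dict[Pair, float] = {}
    for j, disease in enumerate(assoc.disease_ids):
        for i, drug in enumerate(assoc.drug_ids):
            out[(disease, drug)] = float(assoc.scores[i, j])
    return out


def compare_configurations(
    assoc_by_label: Mapping[str, AssociationMatrix], gold: GoldStandard
) -> Tuple[Tuple[str, float], ...]:
    """AUC per configuration label, sorted descending by AUC."""
    rows = []
    for label, assoc in assoc_by_label.items():
        result = roc_auc(pair_scores(assoc), gold)
        rows.append((label, result.auc))
    return tuple(sorted(rows, key=lambda r: (-r[1], r[0])))
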