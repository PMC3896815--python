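"""Literature co-occurrence scoring.

Abstract co-mention counts between an entity (drug or disease) and a gene
are turned into a regularized log-odds connectivity score. Two variants are
supported. The original corpus-size form is

    Connect_DG = ln(ABS_DG * N + λ) − ln(ABS_G * ABS_D + λ)

and the modified form, which drops the corpus size N in favour of the
larger marginal and the sum of marginals,

    Connect_DG = ln(ABS_DG * max(ABS_D, ABS_G) + λ) − ln(ABS_D + ABS_G + λ)

with λ a small positive regularizer (default 1). Positive scores mark
enriched entity-gene pairs; low-count cells are zeroed beforehand because
raw co-occurrence is vulnerable to false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Tuple

import numpy as np

from .core import (
    EntitySeedMap,
    GeneUniverse,
    PipelineConfig,
    ValidationError,
    check_alignment,
)

logger = logging.getLogger("netrepos")


@dataclass
class CooccurrenceTable:
    """Entity x gene abstract co-mention counts with marginals.

    abs_dg[d, g] -- abstracts co-mentioning entity d and gene g.
    abs_d[d] -- abstracts mentioning entity d; abs_g[g] -- gene g.
    n -- total abstracts in the corpus.
    """

    entity_ids: Tuple[str, ...]
    universe: GeneUniverse
    abs_dg: np.ndarray
    abs_d: np.ndarray
    abs_g: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.abs_dg = np.asarray(self.abs_dg, dtype=np.int64)
        self.abs_d = np.asarray(self.abs_d, dtype=np.int64)
        self.abs_g = np.asarray(self.abs_g, dtype=np.int64)
        if self.abs_dg.shape != (len(self.entity_ids), len(self.universe)):
            raise ValidationError("co-occurrence matrix shape mismatch")
        if self.abs_d.shape != (len(self.entity_ids),):
            raise ValidationError("entity marginal length mismatch")
        if self.abs_g.shape != (len(self.universe),):
            raise ValidationError("gene marginal length mismatch")
        if (self.abs_dg < 0).any() or (self.abs_d < 0).any() or (self.abs_g < 0).any():
            raise ValidationError("counts must be non-negative")

    def check_consistency(self, strict: bool = True) -> bool:
        """Check ABS_DG <= min(marginals) cell-wise and N >= all marginals.

        strict=True raises on violation (synthetic data must be consistent);
        strict=False logs a warning (real literature extractions can be
        inconsistent) and returns False.
        """
        cap = np.minimum(self.abs_d[:, None], self.abs_g[None, :])
        bad = int((self.abs_dg > cap).sum())
        n_bad_marginal = int((self.abs_d > self.n).sum() + (self.abs_g > self.n).sum())
        if bad or n_bad_marginal:
            msg = (
                f"inconsistent co-occurrence table: {bad} cells exceed their marginals, "
                f"{n_bad_marginal} marginals exceed the corpus size"
            )
            if strict:
                raise ValidationError(msg)
            logger.warning(msg)
            return False
        return True


@dataclass
class ConnectScoreMatrix:
    """Real-valued connectivity scores, same indexing as the source table."""

    entity_ids: Tuple[str, ...]
    universe: GeneUniverse
    scores: np.ndarray
    variant: str
    lambda_: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.entity_ids), len(self.universe)):
            raise ValidationError("score matrix shape mismatch")
        if not np.isfinite(self.scores).all():
            raise ValidationError("scores must be finite")


def filter_cooccurrence(table: CooccurrenceTable, min_count: int) -> CooccurrenceTable:
    """Zero every co-mention cell below ``min_count``; marginals and N unchanged."""
    if min_count < 0:
        raise ValidationError("min_count must be non-negative")
    filtered = np.where(table.abs_dg < min_count, 0, table.abs_dg)
    dropped = int((filtered != table.abs_dg).sum())
    logger.info(
        "co-occurrence filter (< %d): zeroed %d of %d cells",
        min_count, dropped, table.abs_dg.size,
    )
    return replace(table, abs_dg=filtered)


def connect_score(abs_dg, abs_d, abs_g, n=None, lambda_: float = 1.0, variant: str = "modified"):
    """Regularized log-odds connectivity score; vectorizes over array inputs.

    The modified variant ignores ``n``; the original variant requires it.
    """
    if lambda_ <= 0:
        raise ValidationError("lambda_ must be positive")
    abs_dg = np.asarray(abs_dg, dtype=float)
    abs_d = np.asarray(abs_d, dtype=float)
    abs_g = np.asarray(abs_g, dtype=float)
    if variant == "modified":
        out = np.log(abs_dg * np.maximum(abs_d, abs_g) + lambda_) - np.log(
            abs_d + abs_g + lambda_
        )
    elif variant == "original":
        if n is None:
            raise ValidationError("original variant requires the corpus size n")
        out = np.log(abs_dg * np.asarray(n, dtype=float) + lambda_) - np.log(
            abs_g * abs_d + lambda_
        )
    else:
        raise ValidationError(f"unknown variant {variant!r}")
    return out if out.ndim else float(out)


def score_table(table: CooccurrenceTable, config: PipelineConfig) -> ConnectScoreMatrix:
    """Element-wise connectivity score over a (pre-filtered) count table."""
    check_alignment(table.universe, table.abs_dg)
    scores = connect_score(
        table.abs_dg,
        table.abs_d[:, None],
        table.abs_g[None, :],
        n=table.n,
        lambda_=config.lambda_,
        variant=config.variant,
    )
    return ConnectScoreMatrix(
        entity_ids=table.entity_ids,
        universe=table.universe,
        scores=scores,
        variant=config.variant,
        lambda_=config.lambda_,
    )


def select_positive(scores: ConnectScoreMatrix, kind: str = "drug") -> EntitySeedMap:
    """Per entity, the genes with strictly positive connectivity score.

    Zero is excluded: under λ=1 a zero score is the no-information point.
    Entities with no positive gene are retained with an empty set (warned).
    """
    entries: Dict[str, FrozenSet[str]] = {}
    genes = np.array(scores.universe.genes)
    for i, entity in enumerate(scores.entity_ids):
        mask = scores.scores[i] > 0
        if not mask.any():
            logger.warning("entity %r has no positively scored gene", entity)
        entries[entity] = frozenset(map(str, genes[mask]))
    return EntitySeedMap(kind=kind, entries=entries)  # type: ignore[arg-type]
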