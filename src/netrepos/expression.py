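"""Expression-based gene signatures.

Drugs arrive as replicate rank lists over the gene universe (rank 1 = most
up-regulated, rank n = most down-regulated); replicates are merged by mean
rank (Borda aggregation). Diseases arrive as case/control expression
matrices and are scored with a SAM-style moderated d-statistic

    d_g = (mean_case - mean_control) / (s_g + s0)

where s_g is the pooled two-sample standard error and s0 a small
exchangeability constant (default: the median of s over genes). The
signature of an entity is the top-k plus bottom-k genes of its ranked
profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Sequence, Tuple, Union

import numpy as np

from .core import GeneUniverse, ValidationError


@dataclass
class RankedProfile:
    """A permutation rank of the universe for one entity (1 = most up)."""

    entity_id: str
    universe: GeneUniverse
    ranks: np.ndarray  # rank of gene at universe position i, values 1..n

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        n = len(self.universe)
        if self.ranks.shape != (n,):
            raise ValidationError("rank vector length must equal universe size")
        if not np.array_equal(np.sort(self.ranks), np.arange(1, n + 1)):
            raise ValidationError("ranks must be a permutation of 1..n")

    def rank_of(self, gene: str) -> int:
        return int(self.ranks[self.universe.index[gene]])


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with case/control labels."""

    universe: GeneUniverse
    values: np.ndarray
    labels: Tuple[str, ...]  # per-sample, "case" or "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.universe), len(self.labels)):
            raise ValidationError("expression matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")
        for lab in self.labels:
            if lab not in ("case", "control"):
                raise ValidationError(f"unknown sample label {lab!r}")
        if sum(l == "case" for l in self.labels) < 2 or sum(
            l == "control" for l in self.labels
        ) < 2:
            raise ValidationError("need at least 2 samples per label")


@dataclass
class SamScoreVector:
    """Per-gene moderated d-statistics plus the s0 actually used."""

    universe: GeneUniverse
    d: np.ndarray
    s0: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.universe),):
            raise ValidationError("d-statistic length mismatch")
        if not np.isfinite(self.d).all():
            raise ValidationError("d-statistics must be finite")
        if self.s0 < 0:
            raise ValidationError("s0 must be non-negative")


def _rank_descending(keys: np.ndarray, universe: GeneUniverse) -> np.ndarray:
    """Ranks 1..n by descending key; ties broken by lexicographic gene id."""
    genes = np.array(universe.genes)
    order = np.lexsort((genes, -keys))  # primary: key descending, secondary: gene id
    ranks = np.empty(len(genes), dtype=np.int64)
    ranks[order] = np.arange(1, len(genes) + 1)
    return ranks


def merge_ranked_lists(profiles: Sequence[RankedProfile], entity_id: str = None) -> RankedProfile:
    """Borda-merge replicate rank lists: re-rank genes by mean input rank."""
    if len(profiles) == 0:
        raise ValidationError("need at least one profile")
    universe = profiles[0].universe
    for p in profiles[1:]:
        if p.universe.genes != universe.genes:
            raise ValidationError("profiles are over different universes")
    mean_rank = np.mean([p.ranks for p in profiles], axis=0)
    # ascending mean rank == descending negated mean rank
    ranks = _rank_descending(-mean_rank, universe)
    return RankedProfile(
        entity_id=entity_id or profiles[0].entity_id, universe=universe, ranks=ranks
    )


def normalize_ranks(profile: RankedProfile) -> np.ndarray:
    """Map rank r to (r-1)/(n-1) in [0, 1]; a single-gene universe maps to 0."""
    n = len(profile.universe)
    if n == 1:
        return np.zeros(1)
    return (profile.ranks - 1) / (n - 1)


def sam_score(m: ExpressionMatrix, s0: Union[float, str] = "auto") -> SamScoreVector:
    """SAM-style d-statistic per gene; positive d = up-regulated in case."""
    labels = np.array(m.labels)
    case = m.values[:, labels == "case"]
    control = m.values[:, labels == "control"]
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least 2 samples per group")
    diff = case.mean(axis=1) - control.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    if isinstance(s0, str):
        if s0 != "auto":
            raise ValidationError("s0 must be a non-negative number or 'auto'")
        s0_val = float(np.median(s))
    else:
        s0_val = float(s0)
        if s0_val < 0:
            raise ValidationError("s0 must be non-negative")
    denom = s + s0_val
    if (denom == 0).any():
        # genes with zero variance in both groups and s0 = 0: define d = 0
        d = np.where(denom == 0, 0.0, diff / np.where(denom == 0, 1.0, denom))
    else:
        d = diff / denom
    return SamScoreVector(universe=m.universe, d=d, s0=s0_val)


def rank_from_scores(scores: SamScoreVector, entity_id: str = "") -> RankedProfile:
    """Rank genes 1..n by descending d-statistic; ties lexicographic."""
    ranks = _rank_descending(scores.d, scores.universe)
    return RankedProfile(entity_id=entity_id, universe=scores.universe, ranks=ranks)


def select_signature(profile: RankedProfile, k: int) -> FrozenSet[str]:
    """The k highest- and k lowest-ranked genes (2k genes, or all n if n < 2k)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    n = len(profile.universe)
    mask = (profile.ranks <= k) | (profile.ranks > n - k)
    return frozenset(map(str, np.array(profile.universe.genes)[mask]))


def restrict_profile(profile: RankedProfile, genes: Iterable[str]) -> RankedProfile:
    """Re-rank a profile over a gene subset, preserving relative order.

    Used when an entity's signature is chosen among its extended gene list
    only, while profiles are stored over the full universe.
    """
    subset = sorted(set(genes))
    if not subset:
        raise ValidationError("cannot restrict a profile to an empty gene set")
    sub_universe = GeneUniverse(genes=tuple(subset))
    old = np.array([profile.rank_of(g) for g in subset])
    order = np.argsort(old)
    ranks = np.empty(len(subset), dtype=np.int64)
    ranks[order] = np.arange(1, len(subset) + 1)
    return RankedProfile(entity_id=profile.entity_id, universe=sub_universe, ranks=ranks)
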