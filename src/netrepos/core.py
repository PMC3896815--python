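"""Shared domain types for the drug-repositioning pipeline.

Every matrix produced anywhere in the pipeline is indexed by one
:class:`GeneUniverse`, whose gene order defines column order everywhere.
A dimension/alignment check (:func:`check_alignment`) is called at every
stage boundary so mismatched universes fail loudly rather than silently
misalign columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Literal, Mapping, Sequence, Tuple, Union

import numpy as np

logger = logging.getLogger("netrepos")

EntityKind = Literal["drug", "disease"]
Provenance = Tuple[str, str]  # (source in {text, expression, combined}, centrality measure)

VALID_SOURCES = ("text", "expression", "combined")
VALID_MEASURES = ("degree", "betweenness", "closeness")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class GeneUniverse:
    """An ordered, duplicate-free collection of gene identifiers.

    The order is stable and defines the column order of all matrices in
    the pipeline. Identifiers are opaque case-sensitive strings.
    """

    genes: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError("gene universe must be non-empty")
        seen = set()
        for g in self.genes:
            if g in seen:
                raise ValidationError(f"duplicate gene identifier: {g!r}")
            seen.add(g)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    @property
    def index(self) -> Dict[str, int]:
        return self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def positions(self, genes: Iterable[str]) -> np.ndarray:
        """Column positions of ``genes``; unknown genes raise."""
        try:
            return np.array([self.index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"gene {exc.args[0]!r} not in universe") from exc


@dataclass
class EntitySeedMap:
    """Per-entity seed gene sets (drug targets or disease genes)."""

    kind: EntityKind
    entries: Dict[str, FrozenSet[str]]

    def validate(self, universe: GeneUniverse, allow_empty: bool = False) -> "EntitySeedMap":
        for entity, genes in self.entries.items():
            if not genes and not allow_empty:
                raise ValidationError(f"{self.kind} {entity!r} has an empty gene set")
            for g in genes:
                if g not in universe:
                    raise ValidationError(
                        f"{self.kind} {entity!r} references gene {g!r} outside the universe"
                    )
        return self

    @property
    def entity_ids(self) -> Tuple[str, ...]:
        return tuple(self.entries)


@dataclass
class InteractionNetwork:
    """Undirected gene-gene interaction network from one evidence source.

    Edges are unordered pairs stored as sorted tuples; self-loops are
    disallowed by construction.
    """

    source: str
    edges: FrozenSet[Tuple[str, str]]

    @staticmethod
    def from_pairs(source: str, pairs: Iterable[Tuple[str, str]]) -> "InteractionNetwork":
        edges = set()
        for a, b in pairs:
            if a == b:
                continue
            edges.add((a, b) if a < b else (b, a))
        return InteractionNetwork(source=source, edges=frozenset(edges))

    def validate(self, universe: GeneUniverse) -> "InteractionNetwork":
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in universe or b not in universe:
                raise ValidationError(f"edge ({a!r}, {b!r}) has endpoint outside the universe")
        return self

    def adjacency(self) -> Dict[str, set]:
        adj: Dict[str, set] = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class MembershipMatrix:
    """Boolean entity x gene matrix (one of the six networks per source/measure)."""

    entity_ids: Tuple[str, ...]
    universe: GeneUniverse
    values: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValidationError("membership values must be strictly Boolean")
            self.values = self.values.astype(bool)
        if self.values.shape != (len(self.entity_ids), len(self.universe)):
            raise ValidationError(
                f"membership shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.universe)} genes"
            )
        src, measure = self.provenance
        if src not in VALID_SOURCES or measure not in VALID_MEASURES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValidationError("duplicate entity ids")

    def row(self, entity: str) -> np.ndarray:
        return self.values[self.entity_ids.index(entity)]

    def selected(self, entity: str) -> FrozenSet[str]:
        mask = self.row(entity)
        return frozenset(g for g, m in zip(self.universe.genes, mask) if m)


@dataclass
class PipelineConfig:
    """Tunable pipeline settings; defaults reproduce the published procedure.

    lambda_ -- regularizer inside the log-odds connectivity score (λ = 1).
    min_cooccurrence -- co-mention counts below this are zeroed (5).
    tail_k -- genes taken from each tail of a ranked profile (25).
    variant -- connectivity-score formula, "modified" (default) or "original".
    centrality -- which centrality measure drives gene selection.
    penalty -- L1 strength for the logistic fits; a positive float, or
        "path" to pick one per disease from a small grid by held-out deviance.
    n_negatives -- sampled zero-co-occurrence negatives for evaluation.
    seed -- master seed for every randomized step.
    """

    lambda_: float = 1.0
    min_cooccurrence: int = 5
    tail_k: int = 25
    variant: str = "modified"
    centrality: str = "degree"
    penalty: Union[float, str] = "path"
    n_negatives: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValidationError("lambda_ must be positive")
        if self.min_cooccurrence < 0:
            raise ValidationError("min_cooccurrence must be non-negative")
        if self.tail_k <= 0:
            raise ValidationError("tail_k must be positive")
        if self.variant not in ("original", "modified"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.centrality not in VALID_MEASURES:
            raise ValidationError(f"unknown centrality {self.centrality!r}")
        if isinstance(self.penalty, str):
            if self.penalty != "path":
                raise ValidationError("penalty must be a positive number or 'path'")
        elif self.penalty <= 0:
            raise ValidationError("penalty must be positive")


def check_alignment(universe: GeneUniverse, *objects) -> None:
    """Assert that every object is indexed by exactly this universe.

    Accepts MembershipMatrix-like objects (with a ``universe`` attribute)
    and arrays whose last dimension must equal the universe size. Called at
    every stage boundary.
    """
    for obj in objects:
        other = getattr(obj, "universe", None)
        if other is not None:
            if other.genes != universe.genes:
                raise ValidationError("gene universe mismatch between pipeline stages")
        elif hasattr(obj, "shape"):
            if obj.shape[-1] != len(universe):
                raise ValidationError(
                    f"array trailing dimension {obj.shape[-1]} != universe size {len(universe)}"
                )
        else:
            raise ValidationError(f"cannot check alignment of {type(obj).__name__}")
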