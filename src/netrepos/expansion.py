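"""Seed expansion through the protein interaction network.

Each entity's seed genes (drug targets, disease genes) are extended by
their direct network neighbors — exactly one hop, never transitive
closure. Seeds absent from the network are kept with no neighbors, since
curated seed genes are retained regardless of interactome coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Literal, Tuple

from .core import EntitySeedMap, GeneUniverse, InteractionNetwork, ValidationError

logger = logging.getLogger("netrepos")

Flag = Literal["seed", "neighbor"]


@dataclass
class ExtendedSeedMap:
    """Seed map extended by direct neighbors, with per-gene provenance flags."""

    kind: str
    entries: Dict[str, Dict[str, Flag]]  # entity -> gene -> flag

    def genes_of(self, entity: str) -> FrozenSet[str]:
        return frozenset(self.entries[entity])

    def seeds_of(self, entity: str) -> FrozenSet[str]:
        return frozenset(g for g, f in self.entries[entity].items() if f == "seed")

    @property
    def entity_ids(self) -> Tuple[str, ...]:
        return tuple(self.entries)

    def as_seed_map(self) -> EntitySeedMap:
        return EntitySeedMap(
            kind=self.kind,  # type: ignore[arg-type]
            entries={e: frozenset(genes) for e, genes in self.entries.items()},
        )


def expand_seeds(seeds: EntitySeedMap, network: InteractionNetwork) -> ExtendedSeedMap:
    """Add direct network neighbors of every seed gene, per entity.

    One hop only: a neighbor's neighbors are not pulled in. Deterministic.
    """
    adj = network.adjacency()
    entries: Dict[str, Dict[str, Flag]] = {}
    for entity, seed_genes in seeds.entries.items():
        if not seed_genes:
            raise ValidationError(f"entity {entity!r} has an empty seed set")
        flags: Dict[str, Flag] = {g: "seed" for g in sorted(seed_genes)}
        for g in seed_genes:
            for nb in adj.get(g, ()):
                flags.setdefault(nb, "neighbor")
        entries[entity] = flags
    total_in = sum(len(s) for s in seeds.entries.values())
    total_out = sum(len(f) for f in entries.values())
    logger.info("seed expansion: %d seed genes -> %d extended genes", total_in, total_out)
    return ExtendedSeedMap(kind=seeds.kind, entries=entries)


def union_universe(
    drug_seeds: EntitySeedMap,
    disease_seeds: EntitySeedMap,
    network: InteractionNetwork,
) -> GeneUniverse:
    """The lexicographically ordered union of all extended gene lists."""
    genes = set()
    for seed_map in (drug_seeds, disease_seeds):
        extended = expand_seeds(seed_map, network)
        for entity in extended.entity_ids:
            genes |= extended.genes_of(entity)
    if not genes:
        raise ValidationError("union of extended gene lists is empty")
    return GeneUniverse(genes=tuple(sorted(genes)))
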