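"""Entity-specific gene subnetworks (gene modules).

A drug's or disease's signature genes are looked up in a source-specific
reference network; the subnetwork is the full induced subgraph over the
signature genes plus their direct neighbors. Neighbor-neighbor edges are
kept because downstream centrality is meant to reflect the local topology.
Signature genes missing from the reference survive as isolated nodes so
centrality sees them with score zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Literal, Sequence, Tuple

from .core import InteractionNetwork, ValidationError


@dataclass
class Subnetwork:
    """Induced subgraph over one entity's signature genes and their neighbors."""

    entity_id: str
    source: str
    nodes: Dict[str, str]  # gene -> flag in {"signature", "neighbor"}
    edges: FrozenSet[Tuple[str, str]]

    def node_set(self) -> FrozenSet[str]:
        return frozenset(self.nodes)

    def signature_nodes(self) -> FrozenSet[str]:
        return frozenset(g for g, f in self.nodes.items() if f == "signature")

    def __len__(self) -> int:
        return len(self.nodes)


def merge_reference_networks(nets: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Edge-set union of reference networks (e.g. functional PPI + signaling)."""
    if len(nets) == 0:
        raise ValidationError("need at least one network")
    edges = frozenset().union(*(n.edges for n in nets))
    label = "+".join(n.source for n in nets)
    return InteractionNetwork(source=label, edges=edges)


def induce_subnetwork(
    entity_id: str,
    signature: Iterable[str],
    reference: InteractionNetwork,
    source: str = "text",
) -> Subnetwork:
    """Signature genes plus direct neighbors, with all induced reference edges."""
    sig = frozenset(signature)
    if not sig:
        raise ValidationError(f"empty signature for entity {entity_id!r}")
    adj = reference.adjacency()
    nodes: Dict[str, str] = {g: "signature" for g in sig}
    for g in sig:
        for nb in adj.get(g, ()):
            nodes.setdefault(nb, "neighbor")
    node_set = set(nodes)
    edges = frozenset(
        (a, b) for a, b in reference.edges if a in node_set and b in node_set
    )
    return Subnetwork(entity_id=entity_id, source=source, nodes=nodes, edges=edges)
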