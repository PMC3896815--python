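"""Centrality-based gene prioritization on entity subnetworks.

Three measures are supported: degree (incident edge count), unnormalized
shortest-path betweenness, and component-wise closeness, matching Gephi's
conventions as closely as the defaults allow. The selection rule keeps
genes whose centrality strictly exceeds the mean over the subnetwork;
because x > mean-of-others is algebraically equivalent to x > overall
mean, the two readings of the rule coincide, and the strict-mean rule is
scale-invariant per subnetwork, so normalization choices cannot change
which genes are selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping

import networkx as nx
import numpy as np

from .core import GeneUniverse, MembershipMatrix, ValidationError
from .subnetwork import Subnetwork


@dataclass
class CentralityVector:
    """Non-negative centrality score for every node of one subnetwork."""

    entity_id: str
    measure: str
    scores: Dict[str, float]

    def __post_init__(self) -> None:
        for node, s in self.scores.items():
            if not np.isfinite(s) or s < 0:
                raise ValidationError(f"invalid centrality {s!r} for node {node!r}")


def _to_graph(s: Subnetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(s.nodes)
    g.add_edges_from(s.edges)
    return g


def degree_centrality(s: Subnetwork) -> CentralityVector:
    g = _to_graph(s)
    return CentralityVector(
        entity_id=s.entity_id, measure="degree",
        scores={n: float(d) for n, d in g.degree()},
    )


def betweenness_centrality(s: Subnetwork) -> CentralityVector:
    """Exact unnormalized betweenness: sum over unordered pairs of σ_st(v)/σ_st."""
    g = _to_graph(s)
    scores = nx.betweenness_centrality(g, normalized=False)
    return CentralityVector(
        entity_id=s.entity_id, measure="betweenness",
        scores={n: float(v) for n, v in scores.items()},
    )


def closeness_centrality(s: Subnetwork) -> CentralityVector:
    """Component-wise closeness (c-1)/Σ distances; isolated nodes score 0."""
    g = _to_graph(s)
    scores = nx.closeness_centrality(g, wf_improved=False)
    return CentralityVector(
        entity_id=s.entity_id, measure="closeness",
        scores={n: float(v) for n, v in scores.items()},
    )


_MEASURES = {
    "degree": degree_centrality,
    "betweenness": betweenness_centrality,
    "closeness": closeness_centrality,
}


def compute_centrality(s: Subnetwork, measure: str) -> CentralityVector:
    try:
        return _MEASURES[measure](s)
    except KeyError:
        raise ValidationError(f"unknown centrality measure {measure!r}") from None


def select_above_average(c: CentralityVector) -> FrozenSet[str]:
    """Nodes whose score strictly exceeds the subnetwork mean (may be empty)."""
    if not c.scores:
        raise ValidationError("empty centrality vector")
    vals = np.array(list(c.scores.values()))
    mean = vals.mean()
    return frozenset(n for n, s in c.scores.items() if s > mean)


def build_membership_matrix(
    selections: Mapping[str, FrozenSet[str]],
    universe: GeneUniverse,
    provenance=("text", "degree"),
) -> MembershipMatrix:
    """Boolean entity x gene matrix: cell true iff the gene was selected."""
    entity_ids = tuple(selections)
    values = np.zeros((len(entity_ids), len(universe)), dtype=bool)
    for i, entity in enumerate(entity_ids):
        genes = selections[entity]
        if genes:
            values[i, universe.positions(genes)] = True
    return MembershipMatrix(
        entity_ids=entity_ids, universe=universe, values=values, provenance=tuple(provenance)
    )
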