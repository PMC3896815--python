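"""End-to-end orchestration: seeds -> signatures -> subnetworks -> centrality
-> membership matrices -> sparse logistic association -> ROC evaluation.

The pipeline mirrors the two-source design: a text route (co-occurrence
scores, positive-score selection, text-mining reference network) and an
expression route (rank merging or SAM scoring, top/bottom-k signatures,
functional PPI + signaling reference), each yielding per-centrality
Boolean membership matrices that are optionally OR-combined before the
regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Sequence, Tuple

from .association import AssociationMatrix, build_association_matrix, combine_sources
from .centrality import build_membership_matrix, compute_centrality, select_above_average
from .core import (
    EntitySeedMap,
    GeneUniverse,
    InteractionNetwork,
    MembershipMatrix,
    PipelineConfig,
    check_alignment,
)
from .evaluation import GoldStandard, RocResult, pair_scores, roc_auc
from .expansion import ExtendedSeedMap, expand_seeds
from .expression import (
    merge_ranked_lists,
    rank_from_scores,
    restrict_profile,
    sam_score,
    select_signature,
)
from .literature import filter_cooccurrence, score_table, select_positive
from .subnetwork import induce_subnetwork, merge_reference_networks
from .synthetic import SyntheticWorld

logger = logging.getLogger("netrepos")


@dataclass
class PipelineResult:
    memberships: Dict[Tuple[str, str], Dict[str, MembershipMatrix]]
    # (source, measure) -> {"drug": m, "disease": m}
    associations: Dict[Tuple[str, str], AssociationMatrix]
    aucs: Dict[Tuple[str, str], float]


def text_signatures(
    cooccur, extended: ExtendedSeedMap, config: PipelineConfig
) -> Dict[str, FrozenSet[str]]:
    """Positive-connectivity genes per entity, within its extended gene list."""
    filtered = filter_cooccurrence(cooccur, config.min_cooccurrence)
    scores = score_table(filtered, config)
    positive = select_positive(scores, kind=extended.kind)
    return {
        e: positive.entries[e] & extended.genes_of(e) for e in cooccur.entity_ids
    }


def drug_expression_signatures(
    profiles: Mapping[str, Sequence], extended: ExtendedSeedMap, config: PipelineConfig
) -> Dict[str, FrozenSet[str]]:
    """Merge replicate rank lists, restrict to the extended list, take the tails."""
    out = {}
    for entity, reps in profiles.items():
        merged = merge_ranked_lists(list(reps), entity_id=entity)
        restricted = restrict_profile(merged, extended.genes_of(entity))
        out[entity] = select_signature(restricted, config.tail_k)
    return out


def disease_expression_signatures(
    matrices: Mapping[str, object], extended: ExtendedSeedMap, config: PipelineConfig
) -> Dict[str, FrozenSet[str]]:
    """SAM-score case vs control, rank, restrict to the extended list, take tails."""
    out = {}
    for entity, m in matrices.items():
        scores = sam_score(m, s0="auto")
        profile = rank_from_scores(scores, entity_id=entity)
        restricted = restrict_profile(profile, extended.genes_of(entity))
        out[entity] = select_signature(restricted, config.tail_k)
    return out


def membership_from_signatures(
    signatures: Mapping[str, FrozenSet[str]],
    reference: InteractionNetwork,
    universe: GeneUniverse,
    source: str,
    measure: str,
) -> MembershipMatrix:
    """Induce each entity's subnetwork, prioritize by centrality, build the matrix.

    Entities with an empty signature get an all-zero row (with a warning)
    rather than aborting the batch.
    """
    selections: Dict[str, FrozenSet[str]] = {}
    for entity, sig in signatures.items():
        if not sig:
            logger.warning("entity %r has an empty %s signature; zero row", entity, source)
            selections[entity] = frozenset()
            continue
        subnet = induce_subnetwork(entity, sig, reference, source=source)
        vector = compute_centrality(subnet, measure)
        selections[entity] = select_above_average(vector)
    return build_membership_matrix(selections, universe, provenance=(source, measure))


def run_pipeline(
    world: SyntheticWorld,
    config: PipelineConfig,
    sources: Sequence[str] = ("text", "expression", "combined"),
    measures: Sequence[str] = ("degree", "betweenness", "closeness"),
) -> PipelineResult:
    """Run every requested (source, measure) configuration on a synthetic world."""
    universe = world.universe
    check_alignment(universe, world.drug_cooccur, world.disease_cooccur)

    drug_ext = expand_seeds(world.drug_seeds, world.ppi)
    disease_ext = expand_seeds(world.disease_seeds, world.ppi)

    need_text = "text" in sources or "combined" in sources
    need_expr = "expression" in sources or "combined" in sources

    sigs: Dict[str, Dict[str, FrozenSet[str]]] = {}
    if need_text:
        sigs["text.drug"] = text_signatures(world.drug_cooccur, drug_ext, config)
        sigs["text.disease"] = text_signatures(world.disease_cooccur, disease_ext, config)
    if need_expr:
        sigs["expression.drug"] = drug_expression_signatures(
            world.drug_profiles, drug_ext, config
        )
        sigs["expression.disease"] = disease_expression_signatures(
            world.disease_expression, disease_ext, config
        )

    expr_reference = merge_reference_networks([world.ppi, world.signaling])
    reference = {"text": world.text_net, "expression": expr_reference}

    memberships: Dict[Tuple[str, str], Dict[str, MembershipMatrix]] = {}
    for measure in measures:
        for source in ("text", "expression"):
            if f"{source}.drug" not in sigs:
                continue
            memberships[(source, measure)] = {
                role: membership_from_signatures(
                    sigs[f"{source}.{role}"], reference[source], universe, source, measure
                )
                for role in ("drug", "disease")
            }
        if "combined" in sources:
            memberships[("combined", measure)] = {
                role: combine_sources(
                    memberships[("text", measure)][role],
                    memberships[("expression", measure)][role],
                )
                for role in ("drug", "disease")
            }

    associations: Dict[Tuple[str, str], AssociationMatrix] = {}
    aucs: Dict[Tuple[str, str], float] = {}
    for (source, measure), pair in memberships.items():
        if source not in sources:
            continue
        assoc = build_association_matrix(pair["disease"], pair["drug"], config)
        associations[(source, measure)] = assoc
        aucs[(source, measure)] = roc_auc(pair_scores(assoc), world.gold).auc
        logger.info("AUC[%s, %s] = %.3f", source, measure, aucs[(source, measure)])

    return PipelineResult(memberships=memberships, associations=associations, aucs=aucs)
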