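"""Synthetic benchmark world with planted drug-disease associations.

Generates every input the pipeline consumes — gene universe, seed maps,
reference interaction networks, literature co-occurrence counts, drug rank
profiles, disease case/control expression — plus ground truth: a set of
planted (disease, drug) pairs, each sharing a gene module that receives
enriched co-mention counts with both entities and a coherent expression
shift (half the module up-, half down-regulated).

Design notes:

* Reference networks are preferential-attachment (scale-free-like) graphs,
  one per evidence source, augmented with intra-module edges so planted
  modules are locally cohesive; module genes are biased toward the
  high-degree region so centrality-based selection has signal to find.
* Co-occurrence counts are overdispersed (negative-binomial) draws; a
  planted cell's mean is the base mean times the enrichment factor, so
  enrichment 1.0 reproduces the null distribution exactly.
* Each planted pair can carry signal in both sources, text only, or
  expression only; the latter two build complementary-signal scenarios.
* Everything derives from one seed; the same seed yields a bit-identical
  world.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

import networkx as nx
import numpy as np

from .core import (
    EntitySeedMap,
    GeneUniverse,
    InteractionNetwork,
    ValidationError,
)
from .expression import ExpressionMatrix, RankedProfile
from .evaluation import GoldStandard, Pair, sample_negatives
from .literature import CooccurrenceTable


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults mirror the study's scale where stated."""

    n_genes: int = 2343
    n_drugs: int = 50
    n_diseases: int = 8
    n_planted_pairs: int = 10
    module_size: int = 20
    attachment_m: int = 3          # preferential-attachment edges per new node
    hub_bias: float = 0.7          # prob. a module gene is drawn from the top-degree decile
    module_edge_prob: float = 0.3  # extra intra-module edge probability, per source
    cooccurrence_base_mean: float = 0.8
    cooccurrence_dispersion: float = 2.0   # negative-binomial r
    enrichment: float = 20.0       # planted-cell mean multiplier (1.0 = null)
    expression_shift: float = 4.0  # planted up/down shift in noise-sd units (0 = null)
    noise_scale: float = 1.0
    n_case: int = 4
    n_control: int = 4
    n_drug_replicates: int = 3
    n_random_seeds: int = 10       # random seed genes per entity, beyond planted modules
    n_negatives: int = 100         # gold-standard negatives sampled from unplanted pairs
    frac_text_only: float = 0.0    # planted pairs with literature signal only
    frac_expr_only: float = 0.0    # planted pairs with expression signal only
    rng_seed: int = 0

    def validate(self) -> "WorldConfig":
        if self.n_planted_pairs > self.n_drugs * self.n_diseases:
            raise ValidationError("more planted pairs than drug-disease combinations")
        if self.module_size > self.n_genes:
            raise ValidationError("module size exceeds universe size")
        if self.frac_text_only + self.frac_expr_only > 1.0:
            raise ValidationError("source-mode fractions exceed 1")
        if self.n_negatives > self.n_drugs * self.n_diseases - self.n_planted_pairs:
            raise ValidationError("not enough unplanted pairs for the requested negatives")
        if self.enrichment < 1.0 or self.expression_shift < 0:
            raise ValidationError("enrichment must be >= 1 and shift >= 0")
        if not (0 <= self.hub_bias <= 1 and 0 <= self.module_edge_prob <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        return self


@dataclass
class SyntheticWorld:
    config: WorldConfig
    universe: GeneUniverse
    drug_seeds: EntitySeedMap
    disease_seeds: EntitySeedMap
    ppi: InteractionNetwork            # functional PPI: expansion + expression reference
    signaling: InteractionNetwork      # second expression reference source
    text_net: InteractionNetwork       # text-mining gene-gene reference
    drug_cooccur: CooccurrenceTable
    disease_cooccur: CooccurrenceTable
    drug_profiles: Dict[str, List[RankedProfile]]
    disease_expression: Dict[str, ExpressionMatrix]
    gold: GoldStandard
    planted: Dict[Pair, FrozenSet[str]]        # (disease, drug) -> shared module
    planted_source: Dict[Pair, str]            # "both" | "text" | "expression"

    @property
    def drug_ids(self) -> Tuple[str, ...]:
        return tuple(self.drug_seeds.entries)

    @property
    def disease_ids(self) -> Tuple[str, ...]:
        return tuple(self.disease_seeds.entries)


def _pa_network(n: int, m: int, source: str, seed: int) -> nx.Graph:
    return nx.barabasi_albert_graph(n, m, seed=seed)


def _nb_counts(rng, mean: float, r: float, shape) -> np.ndarray:
    """Overdispersed counts with the given mean (negative binomial, size r)."""
    if mean <= 0:
        return np.zeros(shape, dtype=np.int64)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=shape).astype(np.int64)


def generate(config: WorldConfig) -> SyntheticWorld:
    """Build a fully consistent synthetic world from the configuration seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    width = len(str(config.n_genes - 1))
    genes = tuple(f"g{i:0{width}d}" for i in range(config.n_genes))
    universe = GeneUniverse(genes=genes)
    gene_arr = np.array(genes)

    drug_ids = tuple(f"drug{i:03d}" for i in range(config.n_drugs))
    disease_ids = tuple(f"dis{i:02d}" for i in range(config.n_diseases))

    # --- reference networks (independent scale-free graphs per source) ---
    g_ppi = _pa_network(config.n_genes, config.attachment_m, "ppi", int(rng.integers(2**31)))
    g_sig = _pa_network(
        config.n_genes, max(1, config.attachment_m - 1), "signaling", int(rng.integers(2**31))
    )
    g_txt = _pa_network(config.n_genes, config.attachment_m, "text", int(rng.integers(2**31)))

    # --- planted pairs and their shared modules ---
    all_pairs = [(d, r) for d in disease_ids for r in drug_ids]
    pair_idx = rng.choice(len(all_pairs), size=config.n_planted_pairs, replace=False)
    planted_pairs = [all_pairs[i] for i in sorted(pair_idx)]

    degree = np.array([g_ppi.degree(i) for i in range(config.n_genes)])
    top_decile = np.argsort(degree)[-max(1, config.n_genes // 10):]
    planted: Dict[Pair, FrozenSet[str]] = {}
    planted_source: Dict[Pair, str] = {}
    n_txt = int(round(config.frac_text_only * config.n_planted_pairs))
    n_expr = int(round(config.frac_expr_only * config.n_planted_pairs))
    modes = ["text"] * n_txt + ["expression"] * n_expr
    modes += ["both"] * (config.n_planted_pairs - len(modes))
    # A planted pair only has generative consequences through its active
    # signal channels: text (enrichment > 1) and/or expression (shift > 0).
    # With enrichment 1 and shift 0 nothing distinguishes planted pairs from
    # background — the null world carries no recoverable signal by design.
    def _active(mode: str) -> bool:
        text_on = config.enrichment > 1.0 and mode in ("both", "text")
        expr_on = config.expression_shift > 0 and mode in ("both", "expression")
        return text_on or expr_on

    for pair, mode in zip(planted_pairs, modes):
        module_idx: set = set()
        while len(module_idx) < config.module_size:
            if rng.random() < config.hub_bias:
                module_idx.add(int(rng.choice(top_decile)))
            else:
                module_idx.add(int(rng.integers(config.n_genes)))
        planted[pair] = frozenset(map(str, gene_arr[sorted(module_idx)]))
        planted_source[pair] = mode
        if not _active(mode):
            continue
        # intra-module cohesion edges, sampled independently per source graph
        idx = sorted(module_idx)
        for graph in (g_ppi, g_txt):
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    if rng.random() < config.module_edge_prob:
                        graph.add_edge(idx[a], idx[b])

    def _to_network(g: nx.Graph, source: str) -> InteractionNetwork:
        return InteractionNetwork.from_pairs(
            source, ((gene_arr[a], gene_arr[b]) for a, b in g.edges())
        )

    ppi = _to_network(g_ppi, "ppi")
    signaling = _to_network(g_sig, "signaling")
    text_net = _to_network(g_txt, "string-text")

    # --- seed maps: planted modules plus random seed genes ---
    def _seeds(entity_ids, axis) -> Dict[str, FrozenSet[str]]:
        entries = {}
        for eid in entity_ids:
            s = set()
            for (dis, drg), module in planted.items():
                if (dis if axis == "disease" else drg) == eid and _active(
                    planted_source[(dis, drg)]
                ):
                    s |= set(module)
            s |= set(
                map(str, gene_arr[rng.choice(config.n_genes, config.n_random_seeds, replace=False)])
            )
            entries[eid] = frozenset(s)
        return entries

    drug_seeds = EntitySeedMap(kind="drug", entries=_seeds(drug_ids, "drug"))
    disease_seeds = EntitySeedMap(kind="disease", entries=_seeds(disease_ids, "disease"))

    # --- literature co-occurrence counts ---
    def _cooccur(entity_ids, axis) -> CooccurrenceTable:
        base = config.cooccurrence_base_mean
        r = config.cooccurrence_dispersion
        counts = _nb_counts(rng, base, r, (len(entity_ids), config.n_genes))
        for (dis, drg), module in planted.items():
            eid = dis if axis == "disease" else drg
            if planted_source[(dis, drg)] == "expression" or config.enrichment <= 1.0:
                continue  # no literature signal for this pair
            i = entity_ids.index(eid)
            cols = universe.positions(module)
            counts[i, cols] = _nb_counts(rng, base * config.enrichment, r, len(cols))
        return counts

    drug_counts = _cooccur(drug_ids, "drug")
    disease_counts = _cooccur(disease_ids, "disease")
    # marginals consistent by construction: cell sums plus independent extra mentions
    abs_g = (
        drug_counts.sum(axis=0)
        + disease_counts.sum(axis=0)
        + rng.poisson(50, config.n_genes)
    )
    abs_d_drug = drug_counts.sum(axis=1) + rng.poisson(200, len(drug_ids))
    abs_d_dis = disease_counts.sum(axis=1) + rng.poisson(200, len(disease_ids))
    n_corpus = int(abs_g.sum() + abs_d_drug.sum() + abs_d_dis.sum())

    drug_cooccur = CooccurrenceTable(
        entity_ids=drug_ids, universe=universe, abs_dg=drug_counts,
        abs_d=abs_d_drug, abs_g=abs_g, n=n_corpus,
    )
    disease_cooccur = CooccurrenceTable(
        entity_ids=disease_ids, universe=universe, abs_dg=disease_counts,
        abs_d=abs_d_dis, abs_g=abs_g, n=n_corpus,
    )
    drug_cooccur.check_consistency(strict=True)
    disease_cooccur.check_consistency(strict=True)

    # --- expression: signed shift vector per planted entity ---
    def _shift_vector(eid, axis) -> np.ndarray:
        shift = np.zeros(config.n_genes)
        for (dis, drg), module in planted.items():
            if (dis if axis == "disease" else drg) != eid:
                continue
            if planted_source[(dis, drg)] == "text" or config.expression_shift <= 0:
                continue  # no expression signal for this pair
            cols = universe.positions(sorted(module))
            half = len(cols) // 2
            shift[cols[:half]] += config.expression_shift
            shift[cols[half:]] -= config.expression_shift
        return shift

    drug_profiles: Dict[str, List[RankedProfile]] = {}
    for eid in drug_ids:
        shift = _shift_vector(eid, "drug")
        reps = []
        for rep in range(config.n_drug_replicates):
            latent = shift + rng.normal(0, config.noise_scale, config.n_genes)
            order = np.lexsort((gene_arr, -latent))
            ranks = np.empty(config.n_genes, dtype=np.int64)
            ranks[order] = np.arange(1, config.n_genes + 1)
            reps.append(RankedProfile(entity_id=eid, universe=universe, ranks=ranks))
        drug_profiles[eid] = reps

    disease_expression: Dict[str, ExpressionMatrix] = {}
    n_samples = config.n_case + config.n_control
    labels = ("case",) * config.n_case + ("control",) * config.n_control
    for eid in disease_ids:
        shift = _shift_vector(eid, "disease")
        baseline = rng.normal(0, 1, config.n_genes)
        values = baseline[:, None] + rng.normal(
            0, config.noise_scale, (config.n_genes, n_samples)
        )
        values[:, : config.n_case] += shift[:, None]
        disease_expression[eid] = ExpressionMatrix(
            universe=universe, values=values, labels=labels
        )

    # --- gold standard: planted positives, sampled unplanted negatives ---
    positives = frozenset(planted)
    candidates = [p for p in all_pairs if p not in positives]
    negatives = sample_negatives(candidates, config.n_negatives, int(rng.integers(2**31)))
    gold = GoldStandard(positives=positives, negatives=negatives)

    return SyntheticWorld(
        config=config,
        universe=universe,
        drug_seeds=drug_seeds,
        disease_seeds=disease_seeds,
        ppi=ppi,
        signaling=signaling,
        text_net=text_net,
        drug_cooccur=drug_cooccur,
        disease_cooccur=disease_cooccur,
        drug_profiles=drug_profiles,
        disease_expression=disease_expression,
        gold=gold,
        planted=planted,
        planted_source=planted_source,
    )


def world_report(w: SyntheticWorld) -> Dict[str, float]:
    """Deterministic summary counts of a generated world."""
    module_sizes = [len(m) for m in w.planted.values()]
    return {
        "n_genes": len(w.universe),
        "n_drugs": len(w.drug_ids),
        "n_diseases": len(w.disease_ids),
        "n_ppi_edges": len(w.ppi),
        "n_signaling_edges": len(w.signaling),
        "n_text_edges": len(w.text_net),
        "n_planted_pairs": len(w.planted),
        "mean_module_size": float(np.mean(module_sizes)) if module_sizes else 0.0,
        "n_gold_positives": len(w.gold.positives),
        "n_gold_negatives": len(w.gold.negatives),
    }
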