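"""TSV readers and writers for all pipeline artifacts.

Conventions: tab-separated, UTF-8, lines starting with ``#`` are comments.
Every writer composed with its reader is the identity on valid objects.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, FrozenSet, List, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .association import AssociationMatrix
from .core import (
    EntitySeedMap,
    GeneUniverse,
    InteractionNetwork,
    MembershipMatrix,
    PipelineConfig,
    ValidationError,
)
from .evaluation import GoldStandard
from .expression import ExpressionMatrix, RankedProfile
from .literature import CooccurrenceTable

logger = logging.getLogger("netrepos")

PathLike = Union[str, Path]


def _data_lines(path: PathLike) -> List[Tuple[int, str]]:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lines.append((lineno, line))
    return lines


def read_gene_universe(path: PathLike) -> GeneUniverse:
    """One gene identifier per line; order preserved; duplicates rejected."""
    genes = [line.strip() for _, line in _data_lines(path)]
    if not genes:
        raise ValidationError(f"empty gene universe file: {path}")
    return GeneUniverse(genes=tuple(genes))


def write_gene_universe(universe: GeneUniverse, path: PathLike) -> None:
    Path(path).write_text("\n".join(universe.genes) + "\n", encoding="utf-8")


def read_edge_list(path: PathLike, universe: GeneUniverse, source: str = "") -> InteractionNetwork:
    """Two-column TSV of gene pairs; self-loops and out-of-universe edges dropped."""
    edges = set()
    n_self = n_out = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected two tab-separated columns")
        a, b = parts[0].strip(), parts[1].strip()
        if a == b:
            n_self += 1
            continue
        if a not in universe or b not in universe:
            n_out += 1
            continue
        edges.add((a, b) if a < b else (b, a))
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    if n_out:
        logger.info("%s: dropped %d edge(s) with endpoints outside the universe", path, n_out)
    return InteractionNetwork(source=source or str(path), edges=frozenset(edges))


def write_edge_list(network: InteractionNetwork, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def read_seed_map(path: PathLike, kind: str, universe: GeneUniverse = None) -> EntitySeedMap:
    """Two-column TSV entity<TAB>gene; one row per (entity, gene)."""
    entries: Dict[str, set] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: expected entity<TAB>gene")
        entries.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    seed_map = EntitySeedMap(kind=kind, entries={e: frozenset(g) for e, g in entries.items()})  # type: ignore[arg-type]
    if universe is not None:
        seed_map.validate(universe)
    return seed_map


def write_seed_map(seeds: EntitySeedMap, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entity, genes in seeds.entries.items():
            for g in sorted(genes):
                fh.write(f"{entity}\t{g}\n")


def write_extended_seed_map(extended, path: PathLike) -> None:
    """Three columns: entity, gene, flag in {seed, neighbor}."""
    with open(path, "w", encoding="utf-8") as fh:
        for entity, flags in extended.entries.items():
            for g in sorted(flags):
                fh.write(f"{entity}\t{g}\t{flags[g]}\n")


def read_membership_matrix(
    path: PathLike, provenance=("text", "degree")
) -> MembershipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    universe = GeneUniverse(genes=tuple(df.columns))
    return MembershipMatrix(
        entity_ids=tuple(df.index.astype(str)),
        universe=universe,
        values=df.to_numpy().astype(bool),
        provenance=tuple(provenance),
    )


def write_membership_matrix(m: MembershipMatrix, path: PathLike) -> None:
    """Header row of gene ids, first column entity ids, cells 0/1."""
    df = pd.DataFrame(
        m.values.astype(int), index=list(m.entity_ids), columns=list(m.universe.genes)
    )
    df.index.name = "entity"
    df.to_csv(path, sep="\t")


def read_cooccurrence(
    counts_path: PathLike,
    entity_marginals_path: PathLike,
    gene_marginals_path: PathLike,
    corpus_size: int,
) -> CooccurrenceTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    universe = GeneUniverse(genes=tuple(counts.columns))
    abs_d = pd.read_csv(
        entity_marginals_path, sep="\t", index_col=0, comment="#", header=None
    ).iloc[:, 0]
    abs_g = pd.read_csv(
        gene_marginals_path, sep="\t", index_col=0, comment="#", header=None
    ).iloc[:, 0]
    table = CooccurrenceTable(
        entity_ids=tuple(counts.index.astype(str)),
        universe=universe,
        abs_dg=counts.to_numpy(),
        abs_d=abs_d.reindex(counts.index).to_numpy(),
        abs_g=abs_g.reindex(counts.columns).to_numpy(),
        n=corpus_size,
    )
    table.check_consistency(strict=False)
    return table


def write_cooccurrence(table: CooccurrenceTable, prefix: PathLike) -> None:
    """Writes <prefix>.counts.tsv, .entity_marginals.tsv, .gene_marginals.tsv, .corpus.txt."""
    prefix = str(prefix)
    pd.DataFrame(
        table.abs_dg, index=list(table.entity_ids), columns=list(table.universe.genes)
    ).rename_axis("entity").to_csv(prefix + ".counts.tsv", sep="\t")
    with open(prefix + ".entity_marginals.tsv", "w", encoding="utf-8") as fh:
        for e, v in zip(table.entity_ids, table.abs_d):
            fh.write(f"{e}\t{v}\n")
    with open(prefix + ".gene_marginals.tsv", "w", encoding="utf-8") as fh:
        for g, v in zip(table.universe.genes, table.abs_g):
            fh.write(f"{g}\t{v}\n")
    Path(prefix + ".corpus.txt").write_text(str(table.n) + "\n", encoding="utf-8")


def read_ranked_profile(path: PathLike, universe: GeneUniverse, entity_id: str = "") -> RankedProfile:
    """Two-column TSV gene<TAB>rank covering the whole universe."""
    ranks = np.zeros(len(universe), dtype=np.int64)
    seen = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected gene<TAB>rank")
        g, r = parts[0].strip(), int(parts[1])
        ranks[universe.index[g]] = r
        seen += 1
    if seen != len(universe):
        raise ValidationError(f"{path}: {seen} ranks for a universe of {len(universe)}")
    return RankedProfile(entity_id=entity_id or str(path), universe=universe, ranks=ranks)


def write_ranked_profile(profile: RankedProfile, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g, r in zip(profile.universe.genes, profile.ranks):
            fh.write(f"{g}\t{r}\n")


def read_expression_matrix(matrix_path: PathLike, labels_path: PathLike) -> ExpressionMatrix:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    labels = {}
    for lineno, line in _data_lines(labels_path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{labels_path}:{lineno}: expected sample<TAB>label")
        labels[parts[0].strip()] = parts[1].strip()
    universe = GeneUniverse(genes=tuple(df.index.astype(str)))
    return ExpressionMatrix(
        universe=universe,
        values=df.to_numpy(),
        labels=tuple(labels[s] for s in df.columns),
    )


def write_expression_matrix(m: ExpressionMatrix, matrix_path: PathLike, labels_path: PathLike) -> None:
    samples = [f"s{i}" for i in range(len(m.labels))]
    pd.DataFrame(m.values, index=list(m.universe.genes), columns=samples).rename_axis(
        "gene"
    ).to_csv(matrix_path, sep="\t")
    with open(labels_path, "w", encoding="utf-8") as fh:
        for s, lab in zip(samples, m.labels):
            fh.write(f"{s}\t{lab}\n")


def read_gold_standard(path: PathLike) -> GoldStandard:
    """Three columns: disease, drug, label in {positive, negative}."""
    pos, neg = set(), set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3 or parts[2] not in ("positive", "negative"):
            raise ValidationError(
                f"{path}:{lineno}: expected disease<TAB>drug<TAB>positive|negative"
            )
        (pos if parts[2] == "positive" else neg).add((parts[0].strip(), parts[1].strip()))
    return GoldStandard(positives=frozenset(pos), negatives=frozenset(neg))


def write_gold_standard(gold: GoldStandard, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for dis, drg in sorted(gold.positives):
            fh.write(f"{dis}\t{drg}\tpositive\n")
        for dis, drg in sorted(gold.negatives):
            fh.write(f"{dis}\t{drg}\tnegative\n")


def read_association_matrix(path: PathLike) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return AssociationMatrix(
        drug_ids=tuple(df.index.astype(str)),
        disease_ids=tuple(df.columns),
        scores=df.to_numpy(),
        diagnostics={},
    )


def write_association_matrix(assoc: AssociationMatrix, path: PathLike) -> None:
    pd.DataFrame(
        assoc.scores, index=list(assoc.drug_ids), columns=list(assoc.disease_ids)
    ).rename_axis("drug").to_csv(path, sep="\t")


def read_config(path: PathLike) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def write_config(config: PipelineConfig, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.__dict__, fh)
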