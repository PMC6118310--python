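"""Tandem duplicate cluster construction and interleaved-cassette detection.

A tandem duplicate cluster is a connected component of the graph whose edges
are proximal gene pairs (at most ``max_intervening`` genes apart in
chromosome order) with adjusted pairwise similarity at or above threshold.
A cassette is a group of at least two clusters whose gene coordinates
interleave (A1 B1 A2 B2); a cluster fully nested inside another's span is
not a cassette member by that relation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .core_io import Gene, GenesByChrom, SubgenomeBlock
from .similarity import SimilarityScore, score_gene_pair

DEFAULT_MAX_INTERVENING = 15
DEFAULT_MIN_ADJUSTED = 0.3


@dataclass(frozen=True)
class TandemCluster:
    """An ordered set of proximal genes linked by pairwise similarity."""

    id: str
    chromosome: str
    genes: tuple[Gene, ...]
    subgenome: str = "nonsyntenic"

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"cluster {self.id}: needs >=2 genes")
        if any(g.chromosome != self.chromosome for g in self.genes):
            raise ValueError(f"cluster {self.id}: genes span chromosomes")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"cluster {self.id}: genes not sorted by start")

    @property
    def span(self) -> tuple[int, int]:
        return (self.genes[0].start, max(g.end for g in self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.genes)


@dataclass(frozen=True)
class Cassette:
    """At least two tandem clusters whose gene coordinates interleave."""

    id: str
    clusters: tuple[TandemCluster, ...]

    def __post_init__(self) -> None:
        if len(self.clusters) < 2:
            raise ValueError(f"cassette {self.id}: needs >=2 clusters")

    @property
    def span(self) -> tuple[int, int]:
        return (min(c.span[0] for c in self.clusters),
                max(c.span[1] for c in self.clusters))


ScoredPair = tuple[Gene, Gene, SimilarityScore]


def candidate_pairs(
    genes: GenesByChrom | Sequence[Gene],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> Iterator[tuple[Gene, Gene]]:
    """Yield same-chromosome gene pairs with at most ``max_intervening`` genes between.

    Genes must carry chromosome-order ranks; a pair (g_i, g_j), i < j, is a
    candidate iff j - i - 1 <= max_intervening.
    """
    chrom_lists = genes.values() if isinstance(genes, Mapping) else [genes]
    for chrom_genes in chrom_lists:
        ordered = sorted(chrom_genes, key=lambda g: g.rank)
        n = len(ordered)
        for i in range(n):
            for j in range(i + 1, min(i + max_intervening + 2, n)):
                yield ordered[i], ordered[j]


def score_candidate_pairs(
    genes: GenesByChrom,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[ScoredPair]:
    """Score every candidate pair; untranslatable genes are skipped."""
    out = []
    for a, b in candidate_pairs(genes, max_intervening=max_intervening):
        score = score_gene_pair(a, b)
        if score is not None:
            out.append((a, b, score))
    return out


def _majority_subgenome(genes: Sequence[Gene], blocks: Sequence[SubgenomeBlock] | None) -> str:
    """Majority label of member-gene midpoints; ties or no coverage -> nonsyntenic."""
    if not blocks:
        return "nonsyntenic"
    votes: Counter[str] = Counter()
    for g in genes:
        for blk in blocks:
            if blk.chromosome == g.chromosome and blk.start <= g.midpoint < blk.end:
                votes[blk.label] += 1
                break
    if not votes:
        return "nonsyntenic"
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "nonsyntenic"
    return ranked[0][0]


def _components_to_clusters(
    components: Iterable[set[Gene]],
    blocks: Sequence[SubgenomeBlock] | None,
    prefix: str = "cluster",
) -> list[TandemCluster]:
    comps = [sorted(c, key=lambda g: (g.chromosome, g.start, g.end, g.id))
             for c in components if len(c) >= 2]
    comps.sort(key=lambda genes: (genes[0].chromosome, genes[0].start, genes[0].id))
    return [
        TandemCluster(
            id=f"{prefix}_{i:04d}",
            chromosome=genes[0].chromosome,
            genes=tuple(genes),
            subgenome=_majority_subgenome(genes, blocks),
        )
        for i, genes in enumerate(comps)
    ]


def build_clusters(
    scored_pairs: Iterable[ScoredPair],
    min_adjusted: float = DEFAULT_MIN_ADJUSTED,
    blocks: Sequence[SubgenomeBlock] | None = None,
) -> list[TandemCluster]:
    """Connected components of the similarity graph at the given threshold.

    Pairs with ``adjusted >= min_adjusted`` form edges; singletons are
    discarded.  Cluster ids are assigned deterministically by genomic
    position.
    """
    graph = nx.Graph()
    for a, b, score in scored_pairs:
        if score.adjusted >= min_adjusted:
            graph.add_edge(a, b)
    return _components_to_clusters(nx.connected_components(graph), blocks)


def validate_candidate_clusters(
    candidates: Mapping[str, Sequence[str]],
    scored_pairs: Iterable[ScoredPair],
    genes: GenesByChrom,
    min_adjusted: float = DEFAULT_MIN_ADJUSTED,
    blocks: Sequence[SubgenomeBlock] | None = None,
) -> list[TandemCluster]:
    """Filter externally supplied candidate clusters by the similarity rule.

    Within each candidate, genes connected by at least one edge with
    ``adjusted >= min_adjusted`` (to any member of the candidate) are kept as
    connected components; components below two genes are dropped.  The
    result is merged with :func:`build_clusters` output, de-duplicating
    clusters that share any gene (union).
    """
    by_id = {g.id: g for chrom_genes in genes.values() for g in chrom_genes}
    unknown = sorted({gid for members in candidates.values() for gid in members} - set(by_id))
    if unknown:
        raise KeyError(f"candidate clusters name unknown gene ids: {unknown}")

    score_lookup = {}
    for a, b, score in scored_pairs:
        score_lookup[frozenset((a.id, b.id))] = score.adjusted

    graph = nx.Graph()
    # edges from the de-novo adjacency scan
    for key, adj in score_lookup.items():
        if adj >= min_adjusted:
            a, b = sorted(key)
            graph.add_edge(by_id[a], by_id[b])
    # edges inside candidate clusters (any-member linkage)
    for members in candidates.values():
        members = list(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                adj = score_lookup.get(frozenset((members[i], members[j])))
                if adj is not None and adj >= min_adjusted:
                    graph.add_edge(by_id[members[i]], by_id[members[j]])
    return _components_to_clusters(nx.connected_components(graph), blocks)


def _interleaved(a: TandemCluster, b: TandemCluster) -> bool:
    """True iff at least one gene of each cluster lies strictly between two genes of the other."""
    a_starts = [g.start for g in a.genes]
    b_starts = [g.start for g in b.genes]
    b_inside_a = any(min(a_starts) < s < max(a_starts) for s in b_starts)
    a_inside_b = any(min(b_starts) < s < max(b_starts) for s in a_starts)
    return b_inside_a and a_inside_b


def _nested(a: TandemCluster, b: TandemCluster) -> bool:
    """True iff one cluster's span is fully inside the other's."""
    (a0, a1), (b0, b1) = a.span, b.span
    return (a0 <= b0 and b1 <= a1) or (b0 <= a0 and a1 <= b1)


def _spans_overlap(a: TandemCluster, b: TandemCluster) -> bool:
    (a0, a1), (b0, b1) = a.span, b.span
    return a0 < b1 and b0 < a1


def detect_cassettes(clusters: Sequence[TandemCluster]) -> list[Cassette]:
    """Group interleaved clusters into cassettes.

    Overlapping cluster pairs on a chromosome are classified as nested (one
    span fully inside the other; excluded) or interleaved; cassettes are the
    connected components of the interleaved relation with >=2 clusters.
    """
    by_chrom: dict[str, list[TandemCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chromosome, []).append(c)

    cassettes = []
    for chrom in sorted(by_chrom):
        chrom_clusters = sorted(by_chrom[chrom], key=lambda c: c.span[0])
        graph = nx.Graph()
        graph.add_nodes_from(chrom_clusters)
        for i, a in enumerate(chrom_clusters):
            for b in chrom_clusters[i + 1:]:
                if b.span[0] >= a.span[1]:
                    break  # sorted by span start; no further overlaps with a
                if _spans_overlap(a, b) and not _nested(a, b) and _interleaved(a, b):
                    graph.add_edge(a, b)
        for comp in nx.connected_components(graph):
            if len(comp) >= 2:
                members = tuple(sorted(comp, key=lambda c: c.span[0]))
                cassettes.append(members)
    cassettes.sort(key=lambda ms: (ms[0].chromosome, ms[0].span[0]))
    return [Cassette(id=f"cassette_{i:04d}", clusters=ms) for i, ms in enumerate(cassettes)]
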