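"""Cross-genotype comparison of tandem clusters and cassettes.

Clusters from two genotypes are linked when at least one homologous gene
pair connects them; linked clusters are "shared", the rest "private".
Shared fractions are reported per genotype (they can differ under
many-to-many linkage).  Cluster-size concordance is tabulated per link, and
cassettes are compared through their member-cluster links.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Gene, HomologyMap
from .clusters import Cassette, TandemCluster


@dataclass(frozen=True)
class ClusterLink:
    cluster_a: str
    cluster_b: str
    n_linked_genes: int


@dataclass
class ShareCounts:
    shared_a: int
    private_a: int
    shared_b: int
    private_b: int

    @property
    def shared_fraction_a(self) -> float:
        total = self.shared_a + self.private_a
        return self.shared_a / total if total else float("nan")

    @property
    def shared_fraction_b(self) -> float:
        total = self.shared_b + self.private_b
        return self.shared_b / total if total else float("nan")


def link_clusters(
    clusters_a: Sequence[TandemCluster],
    clusters_b: Sequence[TandemCluster],
    homology: HomologyMap,
) -> tuple[list[ClusterLink], ShareCounts]:
    """Link clusters across genotypes through homologous gene pairs."""
    gene_to_a = {g: c.id for c in clusters_a for g in c.gene_ids}
    gene_to_b = {g: c.id for c in clusters_b for g in c.gene_ids}
    pair_counts: Counter[tuple[str, str]] = Counter()
    for ga, gb in homology.pairs:
        ca, cb = gene_to_a.get(ga), gene_to_b.get(gb)
        if ca is not None and cb is not None:
            pair_counts[(ca, cb)] += 1
    links = [ClusterLink(ca, cb, n) for (ca, cb), n in sorted(pair_counts.items())]
    linked_a = {l.cluster_a for l in links}
    linked_b = {l.cluster_b for l in links}
    counts = ShareCounts(
        shared_a=len(linked_a), private_a=len(clusters_a) - len(linked_a),
        shared_b=len(linked_b), private_b=len(clusters_b) - len(linked_b),
    )
    return links, counts


def size_concordance(
    links: Iterable[ClusterLink],
    clusters_a: Sequence[TandemCluster],
    clusters_b: Sequence[TandemCluster],
) -> pd.DataFrame:
    """Counts of linked cluster pairs indexed by (size in A, size in B).

    One increment per link; diagonal mass is the size-concordant fraction.
    """
    size_a = {c.id: c.size for c in clusters_a}
    size_b = {c.id: c.size for c in clusters_b}
    links = list(links)
    max_size = max([2] + [size_a[l.cluster_a] for l in links]
                   + [size_b[l.cluster_b] for l in links])
    mat = pd.DataFrame(
        np.zeros((max_size - 1, max_size - 1), dtype=int),
        index=pd.Index(range(2, max_size + 1), name="size_a"),
        columns=pd.Index(range(2, max_size + 1), name="size_b"),
    )
    for l in links:
        mat.loc[size_a[l.cluster_a], size_b[l.cluster_b]] += 1
    return mat


@dataclass(frozen=True)
class CassetteMatch:
    cassette_a: str
    cassette_b: str
    n_linked_clusters: int
    composition_differs: bool


def compare_cassettes(
    cassettes_a: Sequence[Cassette],
    cassettes_b: Sequence[Cassette],
    links: Iterable[ClusterLink],
    min_linked_clusters: int = 2,
) -> tuple[list[CassetteMatch], dict[str, int]]:
    """Shared cassettes (>= ``min_linked_clusters`` member clusters linked)
    plus per-genotype private counts.

    A composition difference is flagged when the matched cassettes differ in
    member-cluster count or in the sizes of linked member clusters.
    """
    link_set = {(l.cluster_a, l.cluster_b) for l in links}
    matches = []
    for ca in cassettes_a:
        ids_a = {c.id: c.size for c in ca.clusters}
        for cb in cassettes_b:
            ids_b = {c.id: c.size for c in cb.clusters}
            linked = [(a, b) for (a, b) in link_set if a in ids_a and b in ids_b]
            if len({a for a, _ in linked}) >= min_linked_clusters:
                differs = (len(ids_a) != len(ids_b)
                           or any(ids_a[a] != ids_b[b] for a, b in linked))
                matches.append(CassetteMatch(ca.id, cb.id, len(linked), differs))
    shared_a = {m.cassette_a for m in matches}
    shared_b = {m.cassette_b for m in matches}
    counts = {
        "shared_a": len(shared_a),
        "private_a": len(cassettes_a) - len(shared_a),
        "shared_b": len(shared_b),
        "private_b": len(cassettes_b) - len(shared_b),
    }
    return matches, counts


def gene_summary_stats(
    genes: Iterable[Gene],
    tandem_gene_ids: set[str],
    clusters: Sequence[TandemCluster] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene exon counts and gene-model lengths, tandem vs non-tandem,
    plus per-cluster single-exon composition flags.

    Gene length is the full annotated gene-model span; exon count comes from
    the longest transcript.
    """
    gene_df = pd.DataFrame([
        {"gene_id": g.id, "exon_count": g.longest_transcript.exon_count,
         "length": g.length, "is_tandem": g.id in tandem_gene_ids}
        for g in genes
    ])
    cluster_rows = []
    for c in clusters:
        exons = [g.longest_transcript.exon_count for g in c.genes]
        has_single = any(e == 1 for e in exons)
        cluster_rows.append({
            "cluster_id": c.id,
            "has_single_exon": has_single,
            "mixed_exon": has_single and any(e > 1 for e in exons),
        })
    return gene_df, pd.DataFrame(cluster_rows)
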