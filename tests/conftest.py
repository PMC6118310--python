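from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from tandemdup.clusters import TandemCluster
from tandemdup.core_io import Gene, TranscriptCDS

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_gene(gene_id, chrom="chr1", start=0, end=None, rank=0,
              cds="ATGGCTGCTGCT", exon_count=1, strand="+"):
    end = end if end is not None else start + 1000
    tx = TranscriptCDS(id=f"{gene_id}_T01", cds=cds, exon_count=exon_count)
    return Gene(id=gene_id, chromosome=chrom, start=start, end=end,
                strand=strand, transcripts=(tx,), rank=rank)


def toy_cluster(cid, starts, chrom="chr1", gene_len=10):
    """A cluster from bare gene start coordinates (spans start+gene_len)."""
    genes = tuple(
        make_gene(f"{cid}_g{i}", chrom, s, s + gene_len, rank=i)
        for i, s in enumerate(sorted(starts))
    )
    return TandemCluster(id=cid, chromosome=chrom, genes=genes)


def brute_force_cassettes(clusters):
    """Independent cassette classifier by direct coordinate enumeration.

    For each cluster pair: spans overlapping, not fully nested, and there
    exist genes a_i < b_k < a_j and b_l < a_m < b_n (checked by looping over
    all gene triples).  Cassettes are BFS components of that relation with
    at least two members, returned as frozensets of cluster ids.
    """
    def span(c):
        return min(g.start for g in c.genes), max(g.end for g in c.genes)

    def between(inner, outer):
        return any(
            outer.genes[i].start < g.start < outer.genes[j].start
            for g in inner.genes
            for i in range(len(outer.genes))
            for j in range(len(outer.genes))
        )

    edges = {c.id: set() for c in clusters}
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            if a.chromosome != b.chromosome:
                continue
            (a0, a1), (b0, b1) = span(a), span(b)
            if not (a0 < b1 and b0 < a1):
                continue
            if (a0 <= b0 and b1 <= a1) or (b0 <= a0 and a1 <= b1):
                continue  # fully nested
            if between(b, a) and between(a, b):
                edges[a.id].add(b.id)
                edges[b.id].add(a.id)
    seen, groups = set(), []
    for c in clusters:
        if c.id in seen:
            continue
        stack, comp = [c.id], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(edges[x])
        seen |= comp
        if len(comp) >= 2:
            groups.append(frozenset(comp))
    return set(groups)


@pytest.fixture(scope="session")
def sim_default():
    from tandemdup.simulate import SimConfig, simulate_genotypes
    return simulate_genotypes(SimConfig(seed=11))


@pytest.fixture(scope="session")
def scored_sim(sim_default):
    from tandemdup.clusters import score_candidate_pairs
    bundle_a, _, _ = sim_default
    return score_candidate_pairs(bundle_a.genes)
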