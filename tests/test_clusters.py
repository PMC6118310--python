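"""Candidate-pair generation, cluster construction and cassette detection."""

import random

import pytest

from conftest import brute_force_cassettes, make_gene, toy_cluster
from tandemdup.clusters import (Cassette, build_clusters, candidate_pairs,
                                detect_cassettes, validate_candidate_clusters)
from tandemdup.core_io import SubgenomeBlock
from tandemdup.similarity import SimilarityScore


def _score(adj):
    return SimilarityScore(adj, 1.0, adj)


def _gene_row(n, chrom="chr1", spacing=1000):
    return [make_gene(f"g{i}", chrom, i * spacing, i * spacing + 100, rank=i)
            for i in range(n)]


class TestCandidatePairs:
    def test_intervening_boundary(self):
        genes = _gene_row(18)
        pairs = {(a.id, b.id) for a, b in candidate_pairs(genes)}
        assert ("g0", "g16") in pairs  # 15 intervening genes: allowed
        assert ("g0", "g17") not in pairs  # 16 intervening: excluded

    def test_three_consecutive_genes_give_three_pairs(self):
        genes = _gene_row(3)
        assert len(list(candidate_pairs(genes))) == 3

    def test_pairs_emitted_once_in_rank_order(self):
        genes = _gene_row(5)
        pairs = list(candidate_pairs(genes, max_intervening=1))
        assert all(a.rank < b.rank for a, b in pairs)
        assert len(pairs) == len(set((a.id, b.id) for a, b in pairs))

    def test_chromosomes_do_not_mix(self):
        genes = {"chr1": _gene_row(3), "chr2": _gene_row(3, chrom="chr2")}
        assert all(a.chromosome == b.chromosome for a, b in candidate_pairs(genes))


class TestBuildClusters:
    def test_single_pair(self):
        g1, g2 = _gene_row(2)
        clusters = build_clusters([(g1, g2, _score(0.95))])
        assert len(clusters) == 1
        assert clusters[0].gene_ids == ("g0", "g1")

    def test_transitive_chain(self):
        g1, g2, g3 = _gene_row(3)
        clusters = build_clusters([
            (g1, g2, _score(0.4)), (g2, g3, _score(0.4)), (g1, g3, _score(0.1)),
        ])
        assert len(clusters) == 1
        assert clusters[0].gene_ids == ("g0", "g1", "g2")

    def test_below_threshold_discarded(self):
        g1, g2 = _gene_row(2)
        assert build_clusters([(g1, g2, _score(0.29))]) == []

    def test_threshold_is_inclusive(self):
        g1, g2 = _gene_row(2)
        assert len(build_clusters([(g1, g2, _score(0.3))])) == 1

    def test_components_match_bfs_oracle(self):
        rng = random.Random(7)
        genes = _gene_row(30)
        edges = [(i, j) for i in range(30) for j in range(i + 1, 30)
                 if rng.random() < 0.05]
        scored = [(genes[i], genes[j], _score(0.9)) for i, j in edges]
        clusters = build_clusters(scored)
        # independent BFS over the same edge list
        adj = {i: set() for i in range(30)}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        seen, comps = set(), []
        for i in range(30):
            if i in seen or not adj[i]:
                continue
            stack, comp = [i], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x])
            seen |= comp
            comps.append(frozenset(f"g{k}" for k in comp))
        assert {frozenset(c.gene_ids) for c in clusters} == set(comps)

    def test_subgenome_majority_and_tie(self):
        genes = _gene_row(2)  # midpoints 50 and 1050
        blocks = [SubgenomeBlock("chr1", 0, 1000, "maize1"),
                  SubgenomeBlock("chr1", 1000, 2000, "maize2")]
        cluster = build_clusters([(genes[0], genes[1], _score(0.9))], blocks=blocks)[0]
        assert cluster.subgenome == "nonsyntenic"  # 1-1 tie
        blocks_m1 = [SubgenomeBlock("chr1", 0, 5000, "maize1")]
        cluster = build_clusters([(genes[0], genes[1], _score(0.9))], blocks=blocks_m1)[0]
        assert cluster.subgenome == "maize1"


class TestValidateCandidates:
    def test_partial_candidate_filtered(self):
        g1, g2, g3 = genes = _gene_row(3)
        scored = [(g1, g2, _score(0.8)), (g2, g3, _score(0.1)), (g1, g3, _score(0.1))]
        out = validate_candidate_clusters({"c1": ["g0", "g1", "g2"]}, scored,
                                          {"chr1": genes})
        assert len(out) == 1
        assert out[0].gene_ids == ("g0", "g1")

    def test_all_below_threshold_dropped(self):
        g1, g2 = genes = _gene_row(2)
        out = validate_candidate_clusters({"c1": ["g0", "g1"]},
                                          [(g1, g2, _score(0.2))], {"chr1": genes})
        assert out == []

    def test_candidate_identical_to_adjacency_cluster_deduplicated(self):
        g1, g2 = genes = _gene_row(2)
        scored = [(g1, g2, _score(0.9))]
        out = validate_candidate_clusters({"c1": ["g0", "g1"]}, scored, {"chr1": genes})
        assert len(out) == 1

    def test_unknown_gene_id_raises(self):
        genes = _gene_row(2)
        with pytest.raises(KeyError, match="nope"):
            validate_candidate_clusters({"c1": ["g0", "nope"]}, [], {"chr1": genes})


class TestCassettes:
    def test_interleaved_pair_found(self):
        a = toy_cluster("A", [100, 300])
        b = toy_cluster("B", [200, 400])
        cassettes = detect_cassettes([a, b])
        assert len(cassettes) == 1
        assert {c.id for c in cassettes[0].clusters} == {"A", "B"}

    def test_nested_cluster_excluded(self):
        a = toy_cluster("A", [100, 400])
        b = toy_cluster("B", [200, 300])
        assert detect_cassettes([a, b]) == []

    def test_disjoint_clusters_no_cassette(self):
        a = toy_cluster("A", [100, 200])
        b = toy_cluster("B", [300, 400])
        assert detect_cassettes([a, b]) == []

    def test_nested_but_alternating_still_excluded(self):
        # B's span sits fully inside A's: nested wins over interleaving
        a = toy_cluster("A", [100, 250, 400])
        b = toy_cluster("B", [200, 300])
        assert detect_cassettes([a, b]) == []

    def test_three_way_chain(self):
        a = toy_cluster("A", [100, 300])
        b = toy_cluster("B", [200, 400])
        c = toy_cluster("C", [350, 500])
        cassettes = detect_cassettes([a, b, c])
        assert len(cassettes) == 1
        assert {cl.id for cl in cassettes[0].clusters} == {"A", "B", "C"}

    def test_matches_brute_force_on_random_arrangements(self):
        rng = random.Random(3)
        for _ in range(100):
            n_clusters = rng.randint(2, 5)
            labels = []
            for k in range(n_clusters):
                labels += [k] * rng.randint(2, 4)
            rng.shuffle(labels)
            positions = {}
            for pos, lab in enumerate(labels):
                positions.setdefault(lab, []).append(pos * 10 + 10)
            clusters = [toy_cluster(f"c{k}", starts, gene_len=3)
                        for k, starts in positions.items()]
            got = {frozenset(c.id for c in cas.clusters)
                   for cas in detect_cassettes(clusters)}
            assert got == brute_force_cassettes(clusters)

    def test_cassette_requires_two_clusters(self):
        with pytest.raises(ValueError):
            Cassette(id="x", clusters=(toy_cluster("A", [1, 50]),))
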