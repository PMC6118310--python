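"""Synthetic-genome generator: determinism, divergence control, truth ledger."""

import numpy as np
import pytest

from tandemdup.similarity import score_gene_pair
from tandemdup.simulate import (GenomeBundle, PackingError, PlantedCluster,
                                SimConfig, plant_te_configurations,
                                simulate_genotypes)


def _small_config(**kw):
    defaults = dict(
        seed=5, n_chromosomes=1, chromosome_length=2_000_000,
        n_background_genes=30,
        planted_clusters=[PlantedCluster(id="pc00", age_my=1.0),
                          PlantedCluster(id="pc01", age_my=11.0, size=3)],
        te_density_per_class={},
        shared_fraction=1.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        a1, b1, t1 = simulate_genotypes(_small_config())
        a2, b2, t2 = simulate_genotypes(_small_config())
        assert a1.genes == a2.genes
        assert b1.genes == b2.genes
        assert a1.tes == a2.tes
        assert t1.clusters.equals(t2.clusters)
        assert t1.homology.pairs == t2.homology.pairs

    def test_different_seed_differs(self):
        a1, _, _ = simulate_genotypes(_small_config(seed=5))
        a2, _, _ = simulate_genotypes(_small_config(seed=6))
        assert a1.genes != a2.genes


class TestDivergenceControl:
    def test_age_zero_gives_identical_copies(self):
        cfg = _small_config(
            planted_clusters=[PlantedCluster(id="pc00", age_my=0.0)],
            within_species_my=0.0)
        a, _, truth = simulate_genotypes(cfg)
        by_id = a.gene_by_id()
        g1, g2 = truth.genes_of("pc00", "A")
        cds1 = by_id[g1].longest_transcript.cds
        cds2 = by_id[g2].longest_transcript.cds
        assert cds1 == cds2
        assert score_gene_pair(by_id[g1], by_id[g2]).adjusted == 1.0

    def test_pairwise_divergence_matches_jukes_cantor_expectation(self):
        # 100 independent duplicate pairs at one age pool into a binomial
        # with per-site difference probability (3/4)(1 - e^(-8rt/3))
        age, rate, length = 4.0, 0.0065, 450
        clusters = [PlantedCluster(id=f"pc{i:02d}", age_my=age, intervening=0)
                    for i in range(100)]
        cfg = SimConfig(seed=2, n_chromosomes=2, chromosome_length=5_000_000,
                        n_background_genes=10, planted_clusters=clusters,
                        te_density_per_class={}, shared_fraction=1.0,
                        substitution_rate=rate, cds_length=length)
        a, _, truth = simulate_genotypes(cfg)
        by_id = a.gene_by_id()
        diffs = 0
        for pc in clusters:
            g1, g2 = truth.genes_of(pc.id, "A")
            s1, s2 = by_id[g1].longest_transcript.cds, by_id[g2].longest_transcript.cds
            diffs += sum(c1 != c2 for c1, c2 in zip(s1, s2))
        n = 100 * length
        p = 0.75 * (1 - np.exp(-8 * rate * age / 3))
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(diffs - n * p) < 5 * sigma

    def test_outgroup_divergence_independent_of_age(self):
        from tandemdup.dating import jc_distance
        cfg = _small_config()
        a, _, truth = simulate_genotypes(cfg)
        by_id = a.gene_by_id()
        for pc_id in ("pc00", "pc01"):
            genes = truth.genes_of(pc_id, "A")
            d = np.mean([jc_distance(by_id[g].longest_transcript.cds,
                                     truth.outgroup_cds[pc_id]) for g in genes])
            expected = 2 * cfg.substitution_rate * cfg.calibration_my
            assert d == pytest.approx(expected, rel=0.45)


class TestTruthLedger:
    def test_all_ledger_genes_exist(self, sim_default):
        a, b, truth = sim_default
        ids_a, ids_b = set(a.gene_by_id()), set(b.gene_by_id())
        for _, row in truth.clusters.iterrows():
            for g in filter(None, row.genes_a.split(",") if row.genes_a else []):
                assert g in ids_a
            for g in filter(None, row.genes_b.split(",") if row.genes_b else []):
                assert g in ids_b

    def test_shared_clusters_in_both_genotypes_with_homology(self, sim_default):
        _, _, truth = sim_default
        shared = truth.clusters[truth.clusters.presence == "shared"]
        assert len(shared) > 0
        for _, row in shared.iterrows():
            ga = row.genes_a.split(",")
            gb = row.genes_b.split(",")
            assert len(ga) == len(gb) == row["size"]
            for x, y in zip(ga, gb):
                assert (x, y) in truth.homology.pairs

    def test_private_clusters_absent_from_other_genotype(self, sim_default):
        _, _, truth = sim_default
        priv_a = truth.clusters[truth.clusters.presence == "private_a"]
        assert (priv_a.genes_b == "").all()

    def test_cassette_plantings_interleave(self, sim_default):
        a, _, truth = sim_default
        by_id = a.gene_by_id()
        cassette = truth.clusters[(truth.clusters.cassette_with != "")
                                  & (truth.clusters.presence != "private_b")]
        assert len(cassette) > 0
        seen_pairs = set()
        for _, row in cassette.iterrows():
            pair = frozenset((row.cluster_id, row.cassette_with))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            partner = truth.clusters.set_index("cluster_id").loc[row.cassette_with]
            starts_x = sorted(by_id[g].start for g in row.genes_a.split(","))
            starts_y = sorted(by_id[g].start for g in partner.genes_a.split(","))
            # alternating pattern: X1 < Y1 < X2 < Y2 ...
            interleaved = (starts_x[0] < starts_y[0] < starts_x[1]
                           or starts_y[0] < starts_x[0] < starts_y[1])
            assert interleaved

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            simulate_genotypes(_small_config(
                chromosome_length=100_000, n_background_genes=500))


class TestTEPlanting:
    def test_planted_configurations_are_exact(self, sim_default):
        a, _, truth = sim_default
        by_id = a.gene_by_id()
        tes = {t.id: t for t in a.tes}
        assert len(truth.te_placements) > 0
        for _, row in truth.te_placements.iterrows():
            gene, te = by_id[row.gene_id], tes[row.te_id]
            assert te.te_class == row.te_class
            if row.relation == "contains":
                assert gene.start < te.start and te.end < gene.end
            elif row.relation == "captured":
                assert te.start < gene.start and gene.end < te.end
            else:  # partial: overlaps but neither contains
                overlap = min(gene.end, te.end) - max(gene.start, te.start)
                assert 0 < overlap < gene.length

    def test_background_tes_do_not_touch_genes(self, sim_default):
        a, _, truth = sim_default
        planted = set(truth.te_placements.te_id)
        genes = a.all_genes()
        for te in a.tes:
            if te.id in planted:
                continue
            for g in genes:
                if g.chromosome == te.chromosome:
                    assert te.end <= g.start or g.end <= te.start

    def test_requested_counts_honored(self):
        cfg = _small_config()
        a, _, truth = simulate_genotypes(cfg)
        bundle, placements = plant_te_configurations(
            GenomeBundle(genotype="A", genes=a.genes, tes=[], blocks=a.blocks,
                         chrom_lengths=a.chrom_lengths),
            placements={("LTR", "contains"): 5, ("TIR", "captured"): 3},
            rng=np.random.default_rng(0), te_density_per_class=None)
        counts = placements.groupby(["te_class", "relation"]).size()
        assert counts[("LTR", "contains")] == 5
        assert counts[("TIR", "captured")] == 3
        assert len({r.gene_id for r in placements.itertuples()}) == 8
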