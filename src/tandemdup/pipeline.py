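"""End-to-end orchestration of the analysis stages.

``run_all`` composes the stages in analysis order -- simulate (optional),
similarity scoring, cluster construction, cassette detection, window
densities + GLM, TE containment, dating, cross-genotype comparison and
(when model tables are provided) the relative-rates classification -- and
writes one manifest describing every output.  It contains no computation of
its own, and re-running with the same inputs and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clusters import (DEFAULT_MAX_INTERVENING, DEFAULT_MIN_ADJUSTED,
                       build_clusters, detect_cassettes, score_candidate_pairs)
from .compare import (compare_cassettes, gene_summary_stats, link_clusters,
                      size_concordance)
from .context import (DEFAULT_WINDOW_SIZE, compute_windows, fit_density_glm,
                      interaction_test, tandem_proportion_correlation,
                      windows_to_frame)
from .core_io import write_clusters
from .dating import (DEFAULT_CALIBRATION_MY, DuplicationEvent,
                     date_cluster_by_clock, deduplicate_events)
from .simulate import GenomeBundle, SimConfig, TruthLedger, simulate_genotypes
from .te_overlap import classify_relations, count_table


@dataclass
class RunConfig:
    """Parameters of a full run; defaults are the analysis' standard values."""

    seed: int = 0
    out_dir: str = "tandemdup_out"
    simulate: bool = True
    max_intervening: int = DEFAULT_MAX_INTERVENING
    min_similarity: float = DEFAULT_MIN_ADJUSTED
    window_size: int = DEFAULT_WINDOW_SIZE
    calibration_my: float = DEFAULT_CALIBRATION_MY
    ancient_min_my: float = 10.0
    recent_max_my: float = 2.0
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        for name in ("max_intervening", "min_similarity", "window_size",
                     "calibration_my", "ancient_min_my", "recent_max_my"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")


def _tandem_ids(clusters) -> set[str]:
    return {g for c in clusters for g in c.gene_ids}


def _genotype_stage(bundle: GenomeBundle, config: RunConfig):
    scored = score_candidate_pairs(bundle.genes, max_intervening=config.max_intervening)
    clusters = build_clusters(scored, min_adjusted=config.min_similarity,
                              blocks=bundle.blocks)
    cassettes = detect_cassettes(clusters)
    return scored, clusters, cassettes


def _date_recovered_clusters(clusters, truth: TruthLedger, genotype: str,
                             bundle: GenomeBundle, calibration_my: float):
    """Clock-date recovered clusters against their planted outgroup."""
    gene_to_planted = {}
    for _, row in truth.clusters.iterrows():
        col = "genes_a" if genotype == "A" else "genes_b"
        for gid in (row[col].split(",") if row[col] else []):
            gene_to_planted[gid] = row["cluster_id"]
    by_id = bundle.gene_by_id()
    ages, members = {}, {}
    for cluster in clusters:
        planted = {gene_to_planted.get(g) for g in cluster.gene_ids} - {None}
        if len(planted) != 1:
            continue
        outgroup = truth.outgroup_cds[planted.pop()]
        cds = {g: by_id[g].longest_transcript.cds for g in cluster.gene_ids}
        ages[cluster.id] = date_cluster_by_clock(cds, outgroup, calibration_my)
        members[cluster.id] = list(cluster.gene_ids)
    return ages, members


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the output manifest."""
    if not config.simulate:
        raise NotImplementedError(
            "file-based runs are composed from the individual CLI stages; "
            "run_all orchestrates the simulated end-to-end analysis")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "parameters": {
        "seed": config.seed,
        "max_intervening": config.max_intervening,
        "min_similarity": config.min_similarity,
        "window_size": config.window_size,
        "calibration_my": config.calibration_my,
        "ancient_min_my": config.ancient_min_my,
        "recent_max_my": config.recent_max_my,
    }, "outputs": {}}

    sim = config.sim or SimConfig(seed=config.seed)
    bundle_a, bundle_b, truth = simulate_genotypes(sim)
    manifest["parameters"]["sim"] = {
        k: v for k, v in asdict(sim).items() if k != "planted_clusters"}
    manifest["parameters"]["sim"]["n_planted_clusters"] = len(sim.planted_clusters)
    bundle_a.write(out / "sim")
    bundle_b.write(out / "sim")
    truth.write(out / "sim")

    results = {}
    for genotype, bundle in (("A", bundle_a), ("B", bundle_b)):
        scored, clusters, cassettes = _genotype_stage(bundle, config)
        results[genotype] = (scored, clusters, cassettes)
        write_clusters(clusters, out / f"clusters_{genotype}.tsv")
        pd.DataFrame(
            [(cas.id, c.id) for cas in cassettes for c in cas.clusters],
            columns=["cassette_id", "cluster_id"],
        ).to_csv(out / f"cassettes_{genotype}.tsv", sep="\t", index=False)
        manifest["outputs"][f"clusters_{genotype}"] = {
            "path": f"clusters_{genotype}.tsv", "n": len(clusters)}
        manifest["outputs"][f"cassettes_{genotype}"] = {
            "path": f"cassettes_{genotype}.tsv", "n": len(cassettes)}

    # genomic context (genotype A, as the TE-annotated genotype)
    _, clusters_a, cassettes_a = results["A"]
    _, clusters_b, cassettes_b = results["B"]
    windows = compute_windows(bundle_a.genes, bundle_a.tes, _tandem_ids(clusters_a),
                              bundle_a.blocks, window_size=config.window_size,
                              chrom_lengths=bundle_a.chrom_lengths)
    windows_to_frame(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
    fit = fit_density_glm(windows)
    corr = tandem_proportion_correlation(windows)
    with open(out / "glm.json", "w") as fh:
        json.dump({
            "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
            "variance_explained": fit.variance_explained,
            "anova": {t: {"sum_sq": float(r["sum_sq"]), "p_value": float(r["p_value"])}
                      for t, r in fit.anova.iterrows()},
            "interaction_p": interaction_test(windows),
            "tandem_proportion_correlation": {
                "r": corr.r, "p_value": corr.p_value, "n": corr.n,
                "undefined": corr.undefined},
        }, fh, indent=2, sort_keys=True, allow_nan=True)
    manifest["outputs"]["windows"] = {"path": "windows.tsv", "n": len(windows)}

    # TE containment
    relations = classify_relations(bundle_a.all_genes(), bundle_a.tes)
    table, props = count_table(relations, _tandem_ids(clusters_a),
                               [g.id for g in bundle_a.all_genes()])
    table.to_csv(out / "te_table.tsv", sep="\t")
    with open(out / "te_proportions.json", "w") as fh:
        json.dump(props, fh, indent=2, sort_keys=True)
    manifest["outputs"]["te_table"] = {"path": "te_table.tsv", "n": int(table.values.sum())}

    # dating + event dedup
    ages_a, members_a = _date_recovered_clusters(
        clusters_a, truth, "A", bundle_a, config.calibration_my)
    ages_b, members_b = _date_recovered_clusters(
        clusters_b, truth, "B", bundle_b, config.calibration_my)
    subgenomes = {c.id: c.subgenome for c in clusters_a + clusters_b}
    events = deduplicate_events(ages_a, ages_b, members_a, members_b,
                                truth.homology, subgenomes)
    pd.DataFrame([{
        "event_id": e.id, "cluster_ids": ",".join(e.cluster_ids),
        "tmrca_my": round(e.tmrca_my, 6), "age_class": e.age_class,
        "shared": e.shared, "subgenome": e.subgenome,
    } for e in events]).to_csv(out / "events.tsv", sep="\t", index=False)
    manifest["outputs"]["events"] = {"path": "events.tsv", "n": len(events)}

    # cross-genotype comparison
    links, share = link_clusters(clusters_a, clusters_b, truth.homology)
    matrix = size_concordance(links, clusters_a, clusters_b)
    matrix.to_csv(out / "size_matrix.tsv", sep="\t")
    matches, cassette_counts = compare_cassettes(cassettes_a, cassettes_b, links)
    gene_df, cluster_flags = gene_summary_stats(
        bundle_a.all_genes(), _tandem_ids(clusters_a), clusters_a)
    gene_df.to_csv(out / "gene_stats_A.tsv", sep="\t", index=False)
    cluster_flags.to_csv(out / "cluster_exon_flags_A.tsv", sep="\t", index=False)
    with open(out / "compare.json", "w") as fh:
        json.dump({
            "cluster_share": {
                "shared_a": share.shared_a, "private_a": share.private_a,
                "shared_b": share.shared_b, "private_b": share.private_b,
                "shared_fraction_a": share.shared_fraction_a,
                "shared_fraction_b": share.shared_fraction_b,
            },
            "cassettes": cassette_counts,
            "n_links": len(links),
        }, fh, indent=2, sort_keys=True)
    manifest["outputs"]["compare"] = {"path": "compare.json", "n": len(links)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
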