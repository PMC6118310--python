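"""Two related synthetic genotypes with planted tandem duplicates.

The generator emulates the study design every downstream stage needs:
two genotypes of one species carrying tandem duplicate clusters of
controlled age (hence controlled sequence divergence), interleaved cassette
pairs, intervening genes, subgenome blocks, TE features in contains /
captured / partial configurations, and a cross-genotype homology map.  A
truth ledger records what was planted so recovery can be scored exactly.

Sequence evolution is Jukes-Cantor on CDS positions, applied independently
to each lineage from a common ancestor, with no indels: for substitution
rate ``r`` (substitutions/site/MY) and duplication age ``t`` MY the expected
proportion of sites differing between two copies is ``(3/4)(1 - e^{-8rt/3})``,
which gives a closed-form oracle for the generator itself and puts planted
divergence fully under control of (rate, age).  An outgroup sequence
diverged at the calibration age (maize/Sorghum, 12 MY) is emitted per
cluster for dating.  Background genes are independent random-codon
sequences, so unrelated gene pairs sit far below the 0.3 similarity
threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (Gene, GenesByChrom, HomologyMap, SubgenomeBlock,
                      TEFeature, TranscriptCDS, rank_genes)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                 if "".join(c) not in _STOPS]

#: Genome-wide subgenome composition the block layout reproduces
#: (maize1 / maize2 / nonsyntenic fractions of the genome).
SUBGENOME_FRACTIONS = (("maize1", 0.377), ("maize2", 0.240), ("nonsyntenic", 0.383))

#: Default TE plantings: (class, relation) -> count.  'partial' placements
#: overlap half the gene and must never be classified by the containment
#: rules downstream.
DEFAULT_TE_PLACEMENTS: dict[tuple[str, str], int] = {
    ("LTR", "contains"): 6,
    ("LTR", "captured"): 2,
    ("LINE", "captured"): 1,
    ("SINE", "captured"): 2,
    ("TIR", "captured"): 3,
    ("TIR", "contains"): 1,
    ("LTR", "partial"): 3,
}

_TE_LENGTHS = {"LTR": 8000, "LINE": 4000, "SINE": 300, "TIR": 3000}


class PackingError(ValueError):
    """The requested genes do not fit on the chromosomes."""


@dataclass(frozen=True)
class PlantedCluster:
    """Specification of one planted tandem duplicate cluster."""

    id: str
    size: int = 2
    age_my: float = 1.0
    intervening: int = 0
    cassette_partner: str | None = None
    single_exon: bool = False

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"{self.id}: cluster size must be >=2")
        if self.age_my < 0:
            raise ValueError(f"{self.id}: age must be >=0")


def default_planted_clusters(n: int = 30, n_cassette_pairs: int = 2) -> list[PlantedCluster]:
    """A mixed cohort: mostly 2-copy clusters, some 3-copy, recent (1 MY)
    and ancient (11 MY) ages, 0-2 intervening genes, a few single-exon
    clusters, and interleaved cassette pairs at the end."""
    out = []
    for i in range(n):
        cid = f"pc{i:02d}"
        is_cassette = i >= n - 2 * n_cassette_pairs
        partner = None
        if is_cassette:
            j = i - 1 if (i - (n - 2 * n_cassette_pairs)) % 2 else i + 1
            partner = f"pc{j:02d}"
        out.append(PlantedCluster(
            id=cid,
            size=3 if (i % 5 == 4 and not is_cassette) else 2,
            age_my=11.0 if i % 2 else 1.0,
            intervening=0 if is_cassette else i % 3,
            cassette_partner=partner,
            single_exon=(i % 4 == 0),
        ))
    return out


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_background_genes: int = 200
    planted_clusters: list[PlantedCluster] = field(default_factory=default_planted_clusters)
    te_density_per_class: dict[str, float] = field(
        default_factory=lambda: {"LTR": 0.20, "LINE": 0.01, "SINE": 0.005, "TIR": 0.05})
    subgenome_layout: list[SubgenomeBlock] | None = None
    shared_fraction: float = 0.5
    substitution_rate: float = 0.0065  # substitutions/site/MY (grass-like clock)
    cds_length: int = 450  # bp; must be a multiple of 3
    calibration_my: float = 12.0
    within_species_my: float = 0.1  # divergence between the two genotypes

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")
        for cls, d in self.te_density_per_class.items():
            if not 0 <= d <= 1:
                raise ValueError(f"TE density for {cls} must be in [0, 1]")


@dataclass
class GenomeBundle:
    """One genotype's annotation + sequences, consumable with or without files."""

    genotype: str
    genes: GenesByChrom
    tes: list[TEFeature]
    blocks: list[SubgenomeBlock]
    chrom_lengths: dict[str, int]

    def all_genes(self) -> list[Gene]:
        return [g for chrom in sorted(self.genes) for g in self.genes[chrom]]

    def gene_by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.all_genes()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_gff3": outdir / f"{self.genotype}.genes.gff3",
            "cds_fasta": outdir / f"{self.genotype}.cds.fa",
            "te_gff3": outdir / f"{self.genotype}.te.gff3",
            "blocks": outdir / f"{self.genotype}.blocks.tsv",
        }
        with open(paths["genes_gff3"], "w") as gff:
            gff.write("##gff-version 3\n")
            for gene in self.all_genes():
                s, e = gene.start + 1, gene.end
                gff.write(f"{gene.chromosome}\ttandemdup\tgene\t{s}\t{e}\t.\t"
                          f"{gene.strand}\t.\tID={gene.id}\n")
                for tx in gene.transcripts:
                    gff.write(f"{gene.chromosome}\ttandemdup\tmRNA\t{s}\t{e}\t.\t"
                              f"{gene.strand}\t.\tID={tx.id};Parent={gene.id}\n")
                    for cs, ce in _exon_layout(gene.start, gene.end, len(tx.cds),
                                               tx.exon_count):
                        gff.write(f"{gene.chromosome}\ttandemdup\tCDS\t{cs + 1}\t{ce}\t.\t"
                                  f"{gene.strand}\t0\tID={tx.id}.cds;Parent={tx.id}\n")
        with open(paths["cds_fasta"], "w") as fa:
            for gene in self.all_genes():
                for tx in gene.transcripts:
                    fa.write(f">{tx.id}\n{tx.cds}\n")
        with open(paths["te_gff3"], "w") as gff:
            gff.write("##gff-version 3\n")
            for te in sorted(self.tes, key=lambda t: (t.chromosome, t.start, t.id)):
                type_name = {"LTR": "LTR_retrotransposon", "LINE": "LINE_element",
                             "SINE": "SINE_element",
                             "TIR": "terminal_inverted_repeat_element"}[te.te_class]
                gff.write(f"{te.chromosome}\ttandemdup\t{type_name}\t{te.start + 1}\t"
                          f"{te.end}\t.\t+\t.\tID={te.id}\n")
        with open(paths["blocks"], "w") as fh:
            for b in self.blocks:
                fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\t{b.label}\n")
        return paths


@dataclass
class TruthLedger:
    """What was planted: cluster membership, ages, sharing, TEs, homology."""

    clusters: pd.DataFrame  # cluster_id, chromosome, size, age_my, presence, cassette_with, single_exon, genes_a, genes_b
    homology: HomologyMap
    outgroup_cds: dict[str, str]  # planted cluster id -> outgroup CDS
    te_placements: pd.DataFrame  # te_id, gene_id, te_class, relation

    def genes_of(self, cluster_id: str, genotype: str) -> list[str]:
        row = self.clusters.set_index("cluster_id").loc[cluster_id]
        ids = row["genes_a"] if genotype == "A" else row["genes_b"]
        return ids.split(",") if ids else []

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clusters.to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)
        self.te_placements.to_csv(outdir / "truth_te_placements.tsv", sep="\t", index=False)
        with open(outdir / "homology.tsv", "w") as fh:
            for a, b in sorted(self.homology.pairs):
                fh.write(f"{a}\t{b}\n")
        with open(outdir / "outgroup.fa", "w") as fh:
            for cid in sorted(self.outgroup_cds):
                fh.write(f">{cid}\n{self.outgroup_cds[cid]}\n")


def _exon_layout(start: int, end: int, cds_len: int, exon_count: int) -> list[tuple[int, int]]:
    """Place exon_count CDS segments of total length cds_len inside a span."""
    base = cds_len // exon_count
    sizes = [base + (1 if i < cds_len - base * exon_count else 0) for i in range(exon_count)]
    span = end - start
    gap = max(0, (span - cds_len) // (exon_count + 1))
    out, pos = [], start + gap
    for sz in sizes:
        out.append((pos, pos + sz))
        pos += sz + gap
    return out


def _random_cds(rng: np.random.Generator, length: int) -> np.ndarray:
    codons = rng.integers(0, len(_SENSE_CODONS), size=length // 3)
    seq = "".join(_SENSE_CODONS[i] for i in codons)
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _evolve(seq: np.ndarray, t_my: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor draw over t_my MY at `rate` subs/site/MY."""
    p = 0.75 * (1.0 - np.exp(-4.0 * rate * t_my / 3.0))
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def _default_blocks(config: SimConfig) -> list[SubgenomeBlock]:
    blocks = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        # rotate label order per chromosome so both subgenomes see gene-dense
        # and gene-sparse stretches
        order = [SUBGENOME_FRACTIONS[(c + i) % 3] for i in range(3)]
        pos = 0
        for i, (label, frac) in enumerate(order):
            end = config.chromosome_length if i == 2 else pos + int(frac * config.chromosome_length)
            blocks.append(SubgenomeBlock(chrom, pos, end, label))
            pos = end
    return blocks


@dataclass
class _Unit:
    """One gene slot in the master layout."""

    base_id: str
    role: str  # 'background' or 'duplicate'
    cluster_id: str | None
    seq_a: str | None
    seq_b: str | None
    exon_count: int
    start: int = 0
    end: int = 0
    chromosome: str = ""


def _assign_presence(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Assign shared / private_a / private_b per planted cluster.

    Cassette partners always receive the same status so a planted cassette
    is observable as a cassette wherever it is present.
    """
    groups: list[tuple[str, ...]] = []
    seen: set[str] = set()
    for pc in config.planted_clusters:
        if pc.id in seen:
            continue
        if pc.cassette_partner:
            groups.append((pc.id, pc.cassette_partner))
            seen.update((pc.id, pc.cassette_partner))
        else:
            groups.append((pc.id,))
            seen.add(pc.id)
    n_shared = round(config.shared_fraction * len(groups))
    order = rng.permutation(len(groups))
    presence: dict[str, str] = {}
    private_flip = 0
    for pos, gi in enumerate(order):
        if pos < n_shared:
            status = "shared"
        else:
            status = "private_a" if private_flip % 2 == 0 else "private_b"
            private_flip += 1
        for cid in groups[gi]:
            presence[cid] = status
    return presence


def simulate_genotypes(config: SimConfig) -> tuple[GenomeBundle, GenomeBundle, TruthLedger]:
    """Generate both genotypes plus the truth ledger.

    Both genotypes are laid out from one master arrangement so shared genes
    have identical coordinates; a genotype simply lacks the slots of
    clusters private to the other.  Raises :class:`PackingError` if the
    genes cannot fit on the chromosomes.
    """
    rng = np.random.default_rng(config.seed)
    clusters = {pc.id: pc for pc in config.planted_clusters}
    presence = _assign_presence(config, rng)

    # --- sequences -------------------------------------------------------
    r, cal, delta = config.substitution_rate, config.calibration_my, config.within_species_my
    outgroup_cds: dict[str, str] = {}
    cluster_units: dict[str, list[_Unit]] = {}
    counter = itertools.count(1)
    for pc in config.planted_clusters:
        root = _random_cds(rng, config.cds_length)
        outgroup_cds[pc.id] = _to_str(_evolve(root, cal, r, rng))
        t = min(pc.age_my, cal)
        anc = _evolve(root, cal - t, r, rng)
        d_inner = max(0.0, t - delta)
        d_tip = t - d_inner  # = delta, or t when t < delta
        units = []
        for _ in range(pc.size):
            copy_anc = _evolve(anc, d_inner, r, rng)
            seq_a = _to_str(_evolve(copy_anc, d_tip, r, rng))
            seq_b = _to_str(_evolve(copy_anc, d_tip, r, rng))
            units.append(_Unit(
                base_id=f"g{next(counter):04d}", role="duplicate", cluster_id=pc.id,
                seq_a=seq_a if presence[pc.id] != "private_b" else None,
                seq_b=seq_b if presence[pc.id] != "private_a" else None,
                exon_count=1 if pc.single_exon else int(rng.integers(2, 9)),
            ))
        cluster_units[pc.id] = units

    background_units = []
    for _ in range(config.n_background_genes):
        root = _random_cds(rng, config.cds_length)
        background_units.append(_Unit(
            base_id=f"g{next(counter):04d}", role="background", cluster_id=None,
            seq_a=_to_str(_evolve(root, delta, r, rng)),
            seq_b=_to_str(_evolve(root, delta, r, rng)),
            exon_count=int(rng.integers(1, 11)),
        ))

    # --- master layout ---------------------------------------------------
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    chrom_background: dict[str, list[_Unit]] = {c: [] for c in chrom_names}
    for i, u in enumerate(background_units):
        chrom_background[chrom_names[i % len(chrom_names)]].append(u)

    # cassette pairs form one interleaved block; others a tandem run with
    # `intervening` background spacers between consecutive copies
    block_specs: list[tuple[str, list[str]]] = []  # (chrom, cluster ids)
    seen: set[str] = set()
    for i, pc in enumerate(config.planted_clusters):
        if pc.id in seen:
            continue
        ids = [pc.id] + ([pc.cassette_partner] if pc.cassette_partner else [])
        seen.update(ids)
        block_specs.append((chrom_names[len(block_specs) % len(chrom_names)], ids))

    layout: dict[str, list[_Unit]] = {}
    for chrom in chrom_names:
        pool = list(chrom_background[chrom])
        blocks: list[list[_Unit]] = []
        for bchrom, ids in block_specs:
            if bchrom != chrom:
                continue
            if len(ids) == 2:  # cassette: A1 B1 A2 B2 ...
                ua, ub = cluster_units[ids[0]], cluster_units[ids[1]]
                block = [u for pair in itertools.zip_longest(ua, ub) for u in pair
                         if u is not None]
            else:
                pc = clusters[ids[0]]
                block = []
                for k, u in enumerate(cluster_units[ids[0]]):
                    if k > 0:
                        n_spacers = min(pc.intervening, len(pool))
                        block.extend(pool.pop() for _ in range(n_spacers))
                    block.append(u)
            blocks.append(block)
        items: list[list[_Unit]] = blocks + [[u] for u in pool]
        order = rng.permutation(len(items))
        layout[chrom] = [u for idx in order for u in items[idx]]

    # --- coordinates -----------------------------------------------------
    min_span, max_span = 2000, 6000
    for chrom in chrom_names:
        units = layout[chrom]
        spacing = config.chromosome_length // (len(units) + 1)
        if spacing < 2 * max_span:
            raise PackingError(
                f"{chrom}: {len(units)} genes do not fit in "
                f"{config.chromosome_length} bp at safe spacing")
        jitter_max = max(1, spacing // 5)
        for i, u in enumerate(units):
            span = int(rng.integers(min_span, max_span + 1))
            jitter = int(rng.integers(-jitter_max, jitter_max + 1))
            u.chromosome = chrom
            u.start = (i + 1) * spacing + jitter
            u.end = u.start + span

    all_units = [u for chrom in chrom_names for u in layout[chrom]]

    # --- bundles ---------------------------------------------------------
    blocks = config.subgenome_layout or _default_blocks(config)
    chrom_lengths = {c: config.chromosome_length for c in chrom_names}
    bundles = {}
    for genotype in ("A", "B"):
        recs = []
        for u in all_units:
            seq = u.seq_a if genotype == "A" else u.seq_b
            if seq is None:
                continue
            gid = f"{genotype}_{u.base_id}"
            tx = TranscriptCDS(id=f"{gid}_T01", cds=seq, exon_count=u.exon_count)
            recs.append((gid, u.chromosome, u.start, u.end, "+", (tx,)))
        bundles[genotype] = GenomeBundle(
            genotype=genotype, genes=rank_genes(recs), tes=[],
            blocks=list(blocks), chrom_lengths=dict(chrom_lengths))

    # --- truth ledger ----------------------------------------------------
    homology = HomologyMap()
    for u in all_units:
        if u.seq_a is not None and u.seq_b is not None:
            homology.pairs.add((f"A_{u.base_id}", f"B_{u.base_id}"))
    rows = []
    for pc in config.planted_clusters:
        units = cluster_units[pc.id]
        rows.append({
            "cluster_id": pc.id,
            "chromosome": units[0].chromosome,
            "size": pc.size,
            "age_my": pc.age_my,
            "presence": presence[pc.id],
            "cassette_with": pc.cassette_partner or "",
            "single_exon": pc.single_exon,
            "genes_a": ",".join(f"A_{u.base_id}" for u in units
                                if presence[pc.id] != "private_b"),
            "genes_b": ",".join(f"B_{u.base_id}" for u in units
                                if presence[pc.id] != "private_a"),
        })
    truth = TruthLedger(
        clusters=pd.DataFrame(rows),
        homology=homology,
        outgroup_cds=outgroup_cds,
        te_placements=pd.DataFrame(columns=["te_id", "gene_id", "te_class", "relation"]),
    )

    # TEs: planted configurations plus background coverage, genotype A only
    # (the TE analysis is single-genotype)
    bundles["A"], placements = plant_te_configurations(
        bundles["A"], truth, rng=np.random.default_rng(config.seed + 1),
        te_density_per_class=config.te_density_per_class)
    truth.te_placements = placements
    return bundles["A"], bundles["B"], truth


def plant_te_configurations(
    bundle: GenomeBundle,
    truth: TruthLedger | None = None,
    placements: Mapping[tuple[str, str], int] = DEFAULT_TE_PLACEMENTS,
    rng: np.random.Generator | None = None,
    te_density_per_class: Mapping[str, float] | None = None,
) -> tuple[GenomeBundle, pd.DataFrame]:
    """Add TE features in known configurations and background coverage.

    For each requested (class, relation, count): 'contains' places the TE
    strictly inside a distinct gene, 'captured' places the gene strictly
    inside the TE, and 'partial' overlaps exactly half the gene span.
    Background TEs are confined to intergenic space until each class's
    coverage target is met, so the planted placements are the only gene/TE
    containments in the bundle.  Returns the updated bundle and a placement
    table (also folded into ``truth`` when given).
    """
    rng = rng or np.random.default_rng(0)
    genes = bundle.all_genes()
    tandem_ids: set[str] = set()
    if truth is not None:
        for _, row in truth.clusters.iterrows():
            col = "genes_a" if bundle.genotype == "A" else "genes_b"
            if row[col]:
                tandem_ids.update(row[col].split(","))
    tandem_pool = [g for g in genes if g.id in tandem_ids]
    backgr_pool = [g for g in genes if g.id not in tandem_ids]
    used: set[str] = set()
    tes: list[TEFeature] = list(bundle.tes)
    rows = []
    counter = itertools.count(len(tes) + 1)

    def take_gene(prefer_tandem: bool) -> Gene:
        for pool in ((tandem_pool, backgr_pool) if prefer_tandem else (backgr_pool, tandem_pool)):
            for g in pool:
                if g.id not in used:
                    used.add(g.id)
                    return g
        raise PackingError("plant_te_configurations: ran out of target genes")

    for i, ((te_class, relation), count) in enumerate(sorted(placements.items())):
        for k in range(count):
            gene = take_gene(prefer_tandem=(k % 2 == 0))
            quarter = gene.length // 4
            if relation == "contains":
                start, end = gene.start + quarter, gene.end - quarter
            elif relation == "captured":
                start, end = gene.start - 500, gene.end + 500
            elif relation == "partial":
                half = gene.length // 2
                start, end = gene.start - half, gene.start + half
            else:
                raise ValueError(f"unknown TE relation {relation!r}")
            te = TEFeature(id=f"te{next(counter):04d}", chromosome=gene.chromosome,
                           start=max(0, start), end=end, te_class=te_class)
            tes.append(te)
            rows.append({"te_id": te.id, "gene_id": gene.id,
                         "te_class": te_class, "relation": relation})

    if te_density_per_class:
        margin = 600  # keep clear of captured-TE overhangs
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom in sorted(bundle.chrom_lengths):
            length = bundle.chrom_lengths[chrom]
            spans = sorted((g.start, g.end) for g in by_chrom.get(chrom, []))
            gaps, prev = [], 0
            for s, e in spans:
                if s - margin > prev + margin:
                    gaps.append((prev + margin, s - margin))
                prev = max(prev, e)
            if prev + margin < length:
                gaps.append((prev + margin, length))
            for te_class in sorted(te_density_per_class):
                target = te_density_per_class[te_class] * length
                te_len = _TE_LENGTHS[te_class]
                placed = 0
                usable = [g for g in gaps if g[1] - g[0] >= te_len + 2]
                attempts = 200 * max(1, len(usable))
                while usable and placed < target and attempts > 0:
                    attempts -= 1
                    g0, g1 = usable[int(rng.integers(0, len(usable)))]
                    start = int(rng.integers(g0, g1 - te_len))
                    tes.append(TEFeature(id=f"te{next(counter):04d}", chromosome=chrom,
                                         start=start, end=start + te_len,
                                         te_class=te_class))
                    placed += te_len
    out = replace(bundle, tes=tes)
    placements_df = pd.DataFrame(rows, columns=["te_id", "gene_id", "te_class", "relation"])
    if truth is not None:
        truth.te_placements = placements_df
    return out, placements_df
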