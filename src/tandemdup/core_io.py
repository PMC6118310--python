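"""Domain types and readers/writers shared across the pipeline.

All intervals held in memory are 0-based half-open ``[start, end)``.  GFF3 is
1-based closed on disk; the conversion happens only in the readers/writers in
this module, so length arithmetic elsewhere is simply ``end - start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SUBGENOME_LABELS = ("maize1", "maize2", "nonsyntenic")

#: GFF3 feature types / classification strings mapped onto the four TE
#: classes used throughout the analysis.  Anything not mappable is dropped
#: (with a logged count) -- e.g. helitrons.
TE_CLASS_MAP = {
    "LTR_retrotransposon": "LTR",
    "LTR": "LTR",
    "retrotransposon": "LTR",
    "LINE_element": "LINE",
    "LINE": "LINE",
    "SINE_element": "SINE",
    "SINE": "SINE",
    "terminal_inverted_repeat_element": "TIR",
    "TIR": "TIR",
    "TIR_transposon": "TIR",
    "DNA_transposon": "TIR",
}

#: LTR/LINE/SINE are class 1 (RNA) elements; TIR are class 2 (DNA) elements.
RNA_TE_CLASSES = frozenset({"LTR", "LINE", "SINE"})
DNA_TE_CLASSES = frozenset({"TIR"})


class MissingCDSError(KeyError):
    """An annotated transcript has no CDS sequence in the FASTA."""


class MalformedGFF3Error(ValueError):
    """A GFF3 data line does not have nine tab-separated columns."""


@dataclass(frozen=True)
class TranscriptCDS:
    """A transcript's concatenated coding sequence (5'->3')."""

    id: str
    cds: str
    exon_count: int

    def __post_init__(self) -> None:
        if not self.cds:
            raise ValueError(f"transcript {self.id}: empty CDS")
        bad = set(self.cds.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"transcript {self.id}: non-nucleotide symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.cds)


@dataclass(frozen=True)
class Gene:
    """An annotated gene with its transcripts and chromosome-order rank."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcripts: tuple[TranscriptCDS, ...]
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start {self.start} >= end {self.end}")
        if not self.transcripts:
            raise ValueError(f"gene {self.id}: no transcripts")

    @property
    def length(self) -> int:
        """Full annotated gene-model span in bp."""
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def longest_transcript(self) -> TranscriptCDS:
        return max(self.transcripts, key=lambda t: (len(t.cds), t.id))


@dataclass(frozen=True)
class TEFeature:
    """A transposable-element interval with one of four class labels."""

    id: str
    chromosome: str
    start: int
    end: int
    te_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"TE {self.id}: start >= end")
        if self.te_class not in ("LTR", "LINE", "SINE", "TIR"):
            raise ValueError(f"TE {self.id}: unknown class {self.te_class!r}")


@dataclass(frozen=True)
class SubgenomeBlock:
    """A syntenic block assigned to maize1, maize2 or nonsyntenic."""

    chromosome: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("block: start >= end")
        if self.label not in SUBGENOME_LABELS:
            raise ValueError(f"block: unknown subgenome label {self.label!r}")


@dataclass
class HomologyMap:
    """Cross-genotype gene homology as a set of (geneA id, geneB id) pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def partners_of_a(self, gene_a: str) -> set[str]:
        return {b for a, b in self.pairs if a == gene_a}

    def partners_of_b(self, gene_b: str) -> set[str]:
        return {a for a, b in self.pairs if b == gene_b}

    def __len__(self) -> int:
        return len(self.pairs)


GenesByChrom = dict[str, list[Gene]]


def _validate_gff3_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise MalformedGFF3Error(f"{path}: malformed GFF3 line {lineno}: {line!r}")


def rank_genes(unranked: Iterable[tuple[str, str, int, int, str, tuple[TranscriptCDS, ...]]]) -> GenesByChrom:
    """Assign per-chromosome ranks by (start, end, id) and return sorted genes."""
    by_chrom: dict[str, list[tuple]] = {}
    for rec in unranked:
        by_chrom.setdefault(rec[1], []).append(rec)
    out: GenesByChrom = {}
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r[2], r[3], r[0]))
        out[chrom] = [
            Gene(id=r[0], chromosome=r[1], start=r[2], end=r[3], strand=r[4],
                 transcripts=r[5], rank=i)
            for i, r in enumerate(recs)
        ]
    return out


def read_genes(gff3_path: str | Path, cds_fasta_path: str | Path) -> GenesByChrom:
    """Read gene models from GFF3 plus their CDS sequences from FASTA.

    The FASTA must be keyed by transcript (mRNA) id.  Genes are returned
    sorted by start within each chromosome with 0-based ranks assigned in
    sort order; ties broken by (end, id).

    Raises
    ------
    MissingCDSError
        If an annotated transcript has no sequence in the FASTA.
    MalformedGFF3Error
        If a GFF3 data line is malformed (reported with its line number).
    """
    _validate_gff3_lines(gff3_path)
    cds_index = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    unranked = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            n_cds = len(list(db.children(mrna, featuretype="CDS")))
            if mrna.id not in cds_index:
                raise MissingCDSError(
                    f"transcript {mrna.id} (gene {gene.id}) has no CDS sequence in FASTA"
                )
            transcripts.append(
                TranscriptCDS(id=mrna.id, cds=cds_index[mrna.id], exon_count=max(n_cds, 1))
            )
        if not transcripts:
            logger.warning("gene %s has no mRNA children; skipped", gene.id)
            continue
        unranked.append(
            (gene.id, gene.seqid, gene.start - 1, gene.end, gene.strand, tuple(transcripts))
        )
    return rank_genes(unranked)


def read_te_features(gff3_path: str | Path) -> list[TEFeature]:
    """Read TE annotations, mapping feature types onto {LTR, LINE, SINE, TIR}.

    Records whose type (or ``Classification=`` attribute) does not map to one
    of the four classes are dropped; the dropped count is logged.
    """
    _validate_gff3_lines(gff3_path)
    tes: list[TEFeature] = []
    dropped = 0
    with open(gff3_path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            te_class = TE_CLASS_MAP.get(cols[2])
            if te_class is None:
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                te_class = TE_CLASS_MAP.get(attrs.get("Classification", ""))
            if te_class is None:
                dropped += 1
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            te_id = attrs.get("ID", f"te_{i}")
            tes.append(
                TEFeature(id=te_id, chromosome=cols[0], start=int(cols[3]) - 1,
                          end=int(cols[4]), te_class=te_class)
            )
    if dropped:
        logger.info("read_te_features: dropped %d records with unmappable TE class", dropped)
    return tes


def read_subgenome_blocks(path: str | Path) -> list[SubgenomeBlock]:
    """Read a BED-like table (chrom, start, end, label); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "label"], comment="#")
    return [
        SubgenomeBlock(r.chromosome, int(r.start), int(r.end), r.label)
        for r in df.itertuples(index=False)
    ]


def read_homology(path: str | Path) -> HomologyMap:
    """Read a two-column gene-id homology table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"], comment="#")
    return HomologyMap(pairs={(str(a), str(b)) for a, b in zip(df.gene_a, df.gene_b)})


def write_clusters(clusters: Sequence, path: str | Path) -> None:
    """Write clusters one row per gene, ordered by cluster id then gene rank.

    Columns: cluster_id, gene_id, chromosome, start, end, rank, subgenome
    (start/end 0-based half-open, matching the in-memory convention).
    """
    rows = []
    for cluster in sorted(clusters, key=lambda c: c.id):
        for gene in cluster.genes:
            rows.append((cluster.id, gene.id, gene.chromosome, gene.start,
                         gene.end, gene.rank, cluster.subgenome))
    df = pd.DataFrame(rows, columns=["cluster_id", "gene_id", "chromosome",
                                     "start", "end", "rank", "subgenome"])
    df.to_csv(path, sep="\t", index=False)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    """Read a cluster table as written by :func:`write_clusters`."""
    return pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "gene_id": str,
                                              "chromosome": str})


def clusters_from_table(df: pd.DataFrame, genes: GenesByChrom) -> list:
    """Rebuild TandemCluster objects from a membership table and loaded genes."""
    from .clusters import TandemCluster  # local import to avoid a cycle

    by_id = {g.id: g for chrom_genes in genes.values() for g in chrom_genes}
    missing = sorted(set(df.gene_id) - set(by_id))
    if missing:
        raise KeyError(f"cluster table names unknown gene ids: {missing}")
    out = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        members = sorted((by_id[g] for g in grp.gene_id), key=lambda g: g.start)
        subgenome = grp.subgenome.iloc[0] if "subgenome" in grp else "nonsyntenic"
        out.append(TandemCluster(id=str(cid), chromosome=members[0].chromosome,
                                 genes=tuple(members), subgenome=subgenome))
    return out
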