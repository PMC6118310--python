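"""Gene / transposable-element containment at overlap fraction 1.0.

A gene *contains* a TE when the TE interval lies entirely within the gene
span; a gene is *captured* when its entire span lies inside a TE.  Partial
overlaps are not classified.  Counts are tabulated per TE class split by
tandem-duplicate status, deduplicated at the gene level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core_io import Gene, TEFeature

TE_CLASSES = ("LTR", "LINE", "SINE", "TIR")
RELATIONS = ("contains", "captured")


@dataclass(frozen=True)
class GeneTERelation:
    gene_id: str
    te_id: str
    te_class: str
    relation: str  # 'contains' or 'captured'


def classify_relations(
    genes: Iterable[Gene], tes: Sequence[TEFeature]
) -> list[GeneTERelation]:
    """Emit every full-containment gene/TE relation on shared chromosomes.

    Identical intervals resolve to 'contains'.  Interval-tree queries keep
    this sub-quadratic; the result is defined to match a naive double loop.
    """
    trees: dict[str, IntervalTree] = {}
    for te in tes:
        trees.setdefault(te.chromosome, IntervalTree()).addi(te.start, te.end, te)
    out = []
    for gene in genes:
        tree = trees.get(gene.chromosome)
        if tree is None:
            continue
        for iv in tree.overlap(gene.start, gene.end):
            te = iv.data
            if gene.start <= te.start and te.end <= gene.end:
                out.append(GeneTERelation(gene.id, te.id, te.te_class, "contains"))
            elif te.start <= gene.start and gene.end <= te.end:
                out.append(GeneTERelation(gene.id, te.id, te.te_class, "captured"))
    out.sort(key=lambda r: (r.gene_id, r.te_id, r.relation))
    return out


def count_table(
    relations: Iterable[GeneTERelation],
    tandem_gene_ids: set[str],
    all_gene_ids: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Gene-level deduplicated counts per (TE class, tandem status, relation).

    Returns the count matrix (rows = TE class, columns = the four
    status/relation cells) and, when ``all_gene_ids`` is given, the two
    headline proportions: fraction of tandem and of non-tandem genes that
    contain an LTR.
    """
    cells: dict[tuple[str, str, str], set[str]] = {
        (cls, status, rel): set()
        for cls in TE_CLASSES for status in ("tandem", "non_tandem") for rel in RELATIONS
    }
    for r in relations:
        status = "tandem" if r.gene_id in tandem_gene_ids else "non_tandem"
        cells[(r.te_class, status, r.relation)].add(r.gene_id)

    table = pd.DataFrame(
        {f"{status}_{rel}": [len(cells[(cls, status, rel)]) for cls in TE_CLASSES]
         for status in ("tandem", "non_tandem") for rel in RELATIONS},
        index=pd.Index(TE_CLASSES, name="te_class"),
    )

    proportions: dict[str, float] = {}
    if all_gene_ids is not None:
        all_ids = set(all_gene_ids)
        n_tandem = len(all_ids & tandem_gene_ids)
        n_non = len(all_ids - tandem_gene_ids)
        ltr_tandem = cells[("LTR", "tandem", "contains")]
        ltr_non = cells[("LTR", "non_tandem", "contains")]
        proportions["tandem_contains_ltr"] = len(ltr_tandem) / n_tandem if n_tandem else float("nan")
        proportions["non_tandem_contains_ltr"] = len(ltr_non) / n_non if n_non else float("nan")
    return table, proportions


def nearest_te_distance(
    gene: Gene, tes: Sequence[TEFeature]
) -> dict[str, int | None]:
    """Distance in bp from the gene to the nearest TE of each class.

    0 when overlapping; None when no TE of that class exists on the gene's
    chromosome.  Distances are between closest interval boundaries,
    strand-agnostic.
    """
    out: dict[str, int | None] = {cls: None for cls in TE_CLASSES}
    for te in tes:
        if te.chromosome != gene.chromosome:
            continue
        if te.start < gene.end and gene.start < te.end:
            d = 0
        elif te.start >= gene.end:
            d = te.start - gene.end
        else:
            d = gene.start - te.end
        cur = out[te.te_class]
        if cur is None or d < cur:
            out[te.te_class] = d
    return out
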