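"""Duplication-age estimation and age classification.

Two dating modes are supported, mirroring the two framings of the analysis:

* *tree mode* — trees already dated (node heights in MY, e.g. from a
  Bayesian molecular-clock run) are parsed for the TMRCA of two duplicate
  copies;
* *clock mode* — raw pairwise substitution distances are calibrated against
  the divergence of the duplicates from an outgroup of known age
  (maize/Sorghum, ~12 MY):  ``age = calibration * d_pair / d_outgroup``.

Events shared between two genotypes (homologous clusters duplicated in
both) are deduplicated into a single duplication event whose age is the
mean of the per-genotype estimates.  Ages >=10 MY are classed ancient,
<=2 MY recent, otherwise intermediate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .core_io import HomologyMap

DEFAULT_CALIBRATION_MY = 12.0
ANCIENT_MIN_MY = 10.0
RECENT_MAX_MY = 2.0

#: Subgenome-divergence prior used by the original Bayesian dating analysis;
#: recorded as metadata only, nothing here samples from it.
SUBGENOME_DIVERGENCE_PRIOR = ("normal", 11.9, 1.0)


@dataclass(frozen=True)
class DuplicationEvent:
    """A deduplicated duplication with an estimated age."""

    id: str
    cluster_ids: tuple[str, ...]  # per-genotype cluster ids involved
    tmrca_my: float
    shared: bool
    subgenome: str = "nonsyntenic"

    @property
    def age_class(self) -> str:
        return classify_age(self.tmrca_my)


def classify_age(tmrca_my: float,
                 ancient_min: float = ANCIENT_MIN_MY,
                 recent_max: float = RECENT_MAX_MY) -> str:
    if tmrca_my >= ancient_min:
        return "ancient"
    if tmrca_my <= recent_max:
        return "recent"
    return "intermediate"


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor corrected substitutions/site between two aligned sequences.

    Columns containing a gap or N in either sequence are skipped.  Raises if
    the observed difference proportion reaches the JC saturation bound (3/4).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("jc_distance: sequences must be aligned (equal length)")
    valid = diffs = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in "-N" or b in "-N":
            continue
        valid += 1
        if a != b:
            diffs += 1
    if valid == 0:
        raise ValueError("jc_distance: no comparable columns")
    p = diffs / valid
    if p >= 0.75:
        raise ValueError(f"jc_distance: saturated (p={p:.3f} >= 0.75)")
    return -0.75 * math.log(1 - 4 * p / 3)


def clock_calibrated_age(
    d_pair: float, d_outgroup: float, calibration_my: float = DEFAULT_CALIBRATION_MY
) -> float:
    """Age of a duplication from its substitution distance relative to the outgroup."""
    if d_outgroup <= 0:
        raise ValueError("clock_calibrated_age: outgroup distance must be positive")
    return max(0.0, calibration_my * d_pair / d_outgroup)


def date_cluster_by_clock(
    member_cds: Mapping[str, str],
    outgroup_cds: str,
    calibration_my: float = DEFAULT_CALIBRATION_MY,
) -> float:
    """Clock-calibrated age for a cluster from aligned member and outgroup CDS.

    ``d_pair`` is the mean JC distance over all member pairs; ``d_outgroup``
    the mean JC distance from members to the outgroup.  All sequences must
    be positionally aligned (equal length, gaps allowed).
    """
    ids = sorted(member_cds)
    if len(ids) < 2:
        raise ValueError("date_cluster_by_clock: need >=2 members")
    d_pair = float(np.mean([
        jc_distance(member_cds[a], member_cds[b])
        for a, b in itertools.combinations(ids, 2)]))
    d_out = float(np.mean([jc_distance(member_cds[g], outgroup_cds) for g in ids]))
    return clock_calibrated_age(d_pair, d_out, calibration_my)


def tmrca_from_dated_tree(tree: dendropy.Tree, tip_a: str, tip_b: str) -> float:
    """Age (MY) of the most recent common ancestor of two tips on a dated tree.

    The tree must be ultrametric with branch lengths in age units; node age
    is its distance to a descendant tip.
    """
    taxa = {t.label for t in tree.taxon_namespace}
    missing = [t for t in (tip_a, tip_b) if t not in taxa]
    if missing:
        raise KeyError(f"tmrca_from_dated_tree: tips not in tree: {missing}")
    tree.is_rooted = True
    mrca = tree.mrca(taxon_labels=[tip_a, tip_b])
    # node age = tree depth minus node depth (ultrametric age-mode tree)
    return float(tree.max_distance_from_root() - mrca.distance_from_root())


def deduplicate_events(
    ages_a: Mapping[str, float],
    ages_b: Mapping[str, float],
    members_a: Mapping[str, Sequence[str]],
    members_b: Mapping[str, Sequence[str]],
    homology: HomologyMap,
    subgenomes: Mapping[str, str] | None = None,
) -> list[DuplicationEvent]:
    """Collapse homologous duplications present in both genotypes into one event.

    Clusters from the two genotypes are linked when any of their member
    genes are homologous; each connected component of that link graph with
    clusters from both genotypes becomes one shared event (age = mean of
    the per-genotype ages), and unlinked clusters become private events.
    Sharing requires only a shared duplication state (both clusters have
    >=2 members, which cluster objects guarantee); copy-number differences
    do not break sharing.
    """
    gene_to_cluster_a = {g: c for c, genes in members_a.items() for g in genes}
    gene_to_cluster_b = {g: c for c, genes in members_b.items() for g in genes}
    graph = nx.Graph()
    graph.add_nodes_from(("A", c) for c in ages_a)
    graph.add_nodes_from(("B", c) for c in ages_b)
    for ga, gb in homology.pairs:
        ca, cb = gene_to_cluster_a.get(ga), gene_to_cluster_b.get(gb)
        if ca in ages_a and cb in ages_b:
            graph.add_edge(("A", ca), ("B", cb))

    subgenomes = subgenomes or {}
    events = []
    comps = sorted(nx.connected_components(graph),
                   key=lambda comp: min(comp))
    for i, comp in enumerate(sorted(comps, key=lambda c: sorted(c)[0])):
        comp = sorted(comp)
        cluster_ids = tuple(c for _, c in comp)
        sides = {side for side, _ in comp}
        ages = [ages_a[c] if side == "A" else ages_b[c] for side, c in comp]
        events.append(DuplicationEvent(
            id=f"event_{i:04d}",
            cluster_ids=cluster_ids,
            tmrca_my=float(np.mean(ages)),
            shared=(sides == {"A", "B"}),
            subgenome=subgenomes.get(cluster_ids[0], "nonsyntenic"),
        ))
    return events


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N bases excluded from the denominator."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("gc_content: no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def age_distribution(
    events: Iterable[DuplicationEvent], bin_width_my: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of event ages plus counts by (shared, subgenome, age class)."""
    events = list(events)
    if not events:
        return (pd.DataFrame(columns=["bin_start", "bin_end", "count"]),
                pd.DataFrame(columns=["shared", "subgenome", "age_class", "count"]))
    ages = np.array([e.tmrca_my for e in events])
    top = math.ceil(ages.max() / bin_width_my) * bin_width_my or bin_width_my
    edges = np.arange(0, top + bin_width_my / 2, bin_width_my)
    counts, _ = np.histogram(ages, bins=edges)
    hist = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})
    cross = (pd.DataFrame([
        {"shared": e.shared, "subgenome": e.subgenome, "age_class": e.age_class}
        for e in events])
        .value_counts().rename("count").reset_index()
        .sort_values(["shared", "subgenome", "age_class"]).reset_index(drop=True))
    return hist, cross
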