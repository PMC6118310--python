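"""Gap-adjusted pairwise similarity between candidate duplicate genes.

The longest transcript of each gene is translated, the two proteins are
globally aligned (Needleman–Wunsch, BLOSUM62, affine gaps), the alignment is
back-translated to codons, and similarity is the amino-acid identity within
ungapped columns multiplied by the fraction of columns that are ungapped:

    adjusted = (n_identical / n_ungapped) * (n_ungapped / n_columns)

Down-weighting by the ungapped fraction penalises gene pairs that align well
only over a short conserved stretch: identity is undefined in gapped regions,
so a pair with mostly un-alignable sequence should not score highly just
because a domain matches.  If every column is gapped the adjusted similarity
is 0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .core_io import Gene, TranscriptCDS

logger = logging.getLogger(__name__)

GAP = "-"

# Needleman-Wunsch scoring; recorded here so runs are reproducible.
SCORING = {"matrix": "BLOSUM62", "open_gap": -10.0, "extend_gap": -0.5}


class UntranslatableGeneError(ValueError):
    """No transcript of the gene has a CDS translatable in frame."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise protein alignment with column bookkeeping."""

    seq_a: str  # aligned row with gaps
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.seq_a)

    @property
    def n_ungapped(self) -> int:
        return sum(1 for a, b in zip(self.seq_a, self.seq_b) if a != GAP and b != GAP)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for a, b in zip(self.seq_a, self.seq_b)
            if a != GAP and b != GAP and a == b
        )

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.seq_a, self.seq_b))


@dataclass(frozen=True)
class SimilarityScore:
    """Raw identity, ungapped fraction and their product."""

    raw_identity: float
    ungapped_fraction: float
    adjusted: float


@lru_cache(maxsize=1)
def _default_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="global")
    aligner.substitution_matrix = substitution_matrices.load(SCORING["matrix"])
    aligner.open_gap_score = SCORING["open_gap"]
    aligner.extend_gap_score = SCORING["extend_gap"]
    return aligner


def translate_cds(cds: str, label: str = "?") -> str:
    """Translate an in-frame CDS; trim a single trailing stop, internal stops -> X.

    Raises :class:`UntranslatableGeneError` if the length is not a multiple
    of three.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise UntranslatableGeneError(f"{label}: CDS length {len(cds)} not a multiple of 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        logger.debug("%s: %d internal stop codon(s) translated as X", label, protein.count("*"))
        protein = protein.replace("*", "X")
    if not protein:
        raise UntranslatableGeneError(f"{label}: empty translation")
    return protein


def longest_transcript_protein(gene: Gene) -> tuple[str, TranscriptCDS]:
    """Translate the longest in-frame transcript of a gene.

    Transcripts whose CDS is not a multiple of three are skipped; if none is
    translatable the gene is flagged by raising
    :class:`UntranslatableGeneError` (callers log and exclude it rather than
    crash).
    """
    for tx in sorted(gene.transcripts, key=lambda t: (-len(t.cds), t.id)):
        try:
            return translate_cds(tx.cds, label=tx.id), tx
        except UntranslatableGeneError:
            continue
    raise UntranslatableGeneError(f"gene {gene.id}: no transcript translatable in frame")


def align_pair(a: str, b: str, aligner: PairwiseAligner | None = None) -> PairwiseAlignment:
    """Globally align two protein sequences; deterministic for fixed inputs.

    The pair is aligned in a canonical order internally (ties among
    optimal alignments are broken by the DP traversal, which is not
    symmetric in its arguments), so the column bookkeeping -- and hence
    the similarity -- is exactly symmetric.
    """
    if not a or not b:
        raise ValueError("align_pair: empty input sequence")
    aligner = aligner or _default_aligner()
    if a <= b:
        aln = aligner.align(a, b)[0]
        return PairwiseAlignment(seq_a=str(aln[0]), seq_b=str(aln[1]))
    aln = aligner.align(b, a)[0]
    return PairwiseAlignment(seq_a=str(aln[1]), seq_b=str(aln[0]))


def back_translate(alignment: PairwiseAlignment, cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Map each protein alignment column back to its source codons.

    Gap columns become ``---``.  Each CDS must be exactly 3x its row's
    residue count, or 3 longer (a trimmed trailing stop codon).
    """
    out = []
    for row, cds, name in ((alignment.seq_a, cds_a.upper(), "A"), (alignment.seq_b, cds_b.upper(), "B")):
        n_res = sum(1 for c in row if c != GAP)
        if len(cds) not in (3 * n_res, 3 * n_res + 3):
            raise ValueError(
                f"back_translate: row {name} has {n_res} residues but CDS length {len(cds)}"
            )
        codons, pos = [], 0
        for c in row:
            if c == GAP:
                codons.append("---")
            else:
                codons.append(cds[pos:pos + 3])
                pos += 3
        out.append(codons)
    return list(zip(out[0], out[1]))


def adjusted_similarity(alignment: PairwiseAlignment) -> SimilarityScore:
    """Identity within ungapped columns x fraction of ungapped columns."""
    n_cols = alignment.n_columns
    if n_cols == 0:
        raise ValueError("adjusted_similarity: empty alignment")
    n_ungapped = alignment.n_ungapped
    if n_ungapped == 0:
        return SimilarityScore(0.0, 0.0, 0.0)
    raw = alignment.n_identical / n_ungapped
    ungapped_frac = n_ungapped / n_cols
    return SimilarityScore(raw, ungapped_frac, raw * ungapped_frac)


def score_gene_pair(
    gene_a: Gene, gene_b: Gene, aligner: PairwiseAligner | None = None
) -> SimilarityScore | None:
    """Adjusted similarity for a gene pair, or None if either is untranslatable."""
    try:
        prot_a, _ = longest_transcript_protein(gene_a)
        prot_b, _ = longest_transcript_protein(gene_b)
    except UntranslatableGeneError as exc:
        logger.info("score_gene_pair: %s; pair (%s, %s) skipped", exc, gene_a.id, gene_b.id)
        return None
    return adjusted_similarity(align_pair(prot_a, prot_b, aligner=aligner))
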