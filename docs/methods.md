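# Methods

## Similarity model

Candidate duplicate pairs are same-chromosome gene pairs separated by at
most `max_intervening` (default 15) genes in chromosome order. For each
pair the longest in-frame transcript is translated (a single trailing stop
trimmed; internal stops kept as `X` and scored as mismatches), the
proteins are globally aligned with Needleman–Wunsch (BLOSUM62, gap open
−10, gap extend −0.5) and the alignment is back-translated to codons. The
score is

    adjusted = (n_identical / n_ungapped) · (n_ungapped / n_columns)
             = n_identical / n_columns,

i.e. strict amino-acid identity inside ungapped columns, down-weighted by
the gapped fraction of the alignment. Identity is undefined in gapped
regions, so an alignment in which every column is gapped scores 0 by
convention. Identity rather than a matrix-weighted similarity is used; the
choice is isolated in `similarity.SCORING` together with the alignment
parameters. Dynamic-programming tie-breaks are not symmetric in the two
sequences, so the pair is aligned in a canonical order internally — the
score is then exactly symmetric. A deterministic pairwise aligner is used
rather than a progressive multiple-aligner because only two sequences are
ever aligned at a time; iterative refinement has no effect in that case.

Genes with no transcript translatable in frame are flagged, logged and
excluded from scoring rather than failing the run.

## Clusters and cassettes

Pairs with adjusted similarity ≥ `min_adjusted` (default 0.3) are edges;
clusters are connected components with ≥ 2 genes. Transitive chaining can
link genes more than 15 ranks apart end-to-end; this is intentional — each
individual link still satisfies the proximity rule. Externally supplied
candidate clusters are filtered with the same threshold using any-member
linkage, then merged with the de-novo components (union on shared genes).
A cluster's subgenome is the majority block label of its members'
midpoints; ties and uncovered genes resolve to `nonsyntenic`.

Two clusters interleave when at least one gene of each lies strictly
between two genes of the other (on start coordinates, which are distinct
by construction). Pairs whose spans are fully nested are excluded even
when the inner cluster alternates with genes of the outer one — nesting
wins. Cassettes are connected components of the interleaved relation with
≥ 2 clusters. The implementation is defined to agree with a brute-force
classifier that enumerates gene coordinates directly; that equivalence is
exercised exhaustively over all distinct label arrangements for 2–4
clusters of 2–4 genes and on random arrangements at larger sizes.

## Window densities and the GLM

Densities are computed in fixed windows (default 1 Mb; the trailing
partial window is normalised by its real width) as the proportion of
window bases covered by the base-level union of the feature class —
union, not summed lengths, so proportions are bounded by 1 and
Σ(width × density) over windows equals total covered bases exactly.
Tandem density uses tandem-duplicate gene spans and therefore can never
exceed gene density (asserted). RNA TEs are LTR + LINE + SINE; DNA TEs are
TIR. A window's subgenome is the label covering the most block bases; no
coverage or a tie gives `nonsyntenic`.

The density model is ordinary least squares with subgenome as a
categorical (maize1 reference). Per-term significance comes from ANOVA of
nested models (drop-one; the optional gene-density × subgenome interaction
is dropped together with its main effect). Rank-deficient designs raise an
error naming the collinear columns. Windows are treated as independent; no
spatial autocorrelation is modelled. The tandem-proportion correlation is
Pearson's r between window genic proportion and the tandem share of genic
bases, over windows with nonzero gene density; zero variance in either
variable is reported as undefined rather than r = 0.

## TE containment

Gene/TE relations require full containment (overlap fraction 1.0):
`contains` when the TE lies inside the gene span, `captured` when the gene
lies inside the TE. Partial overlaps are never classified. Identical
intervals resolve to `contains` (arbitrary, logged in code). Counts are
deduplicated at the gene level per (class, relation) cell. Queries go
through an interval tree; the output contract is exact agreement with the
naive quadratic double loop, which the tests enforce on random layouts.
Nearest-TE distances are boundary-to-boundary, strand-agnostic, 0 when
overlapping, and flagged missing when a chromosome has no TE of the class.

## Dating

Two modes. *Tree mode* reads an ultrametric dated tree (ages in MY) and
returns the TMRCA of two tips as tree depth minus MRCA depth. *Clock mode*
computes Jukes–Cantor-corrected distances on the codon alignment
(gap/N columns skipped) and calibrates

    age = calibration_my · d_pair / d_outgroup,   calibration_my = 12 (maize–Sorghum),

clamped at 0; d_pair is the mean over member pairs and d_outgroup the mean
member–outgroup distance. The estimator is scale-invariant in the
substitution rate. Ages ≥ 10 MY are "ancient", ≤ 2 MY "recent", and the
band between is reported as "intermediate" rather than forced into either
extreme. The N(11.9, 1) subgenome-divergence prior used by Bayesian dating
of the real assemblies is carried as metadata only; no MCMC runs here.

Events shared between genotypes are connected components of the
cluster-homology link graph (clusters linked when any member genes are
homologous and both are duplicated, i.e. both are clusters); a component
spanning both genotypes is one shared event with age equal to the mean of
the per-genotype estimates, and copy-number differences do not break
sharing. GC content is (G+C)/(A+C+G+T) with N excluded.

## Selection-test scaffolding

The likelihood engines (codon clade models, HKA maximum likelihood) are
upstream; this package owns the rules applied to their output tables.
Orthogroups are retained at 10–75 genes when they contain tandem
duplicates and no member cluster is split across groups. Codon columns are
dropped atomically when gapped in more than 50% of sequences or ungapped
in fewer than 8; the filter is idempotent. LRTs use 2ΔlnL clamped at 0
with df from the parameter-count difference in the input table (not
hard-coded); the best model is the significant alternative with the
highest likelihood, else the null. Constraint classification: foreground
ω > 10 → untestable (dS too small), ω above/below background → weaker /
stronger constraint. For model 3 the fitted model's own background-class ω
is the comparator. The HKA power rule applies before the LRT: a selection
model with larger |lnL| than the neutral model means the window lacks
power; otherwise the LRT uses the window's tandem-gene count as df at
α = 0.05. No multiple-testing correction is applied across groups or
windows, matching the analysis design.

## Synthetic genomes

The generator emulates the study conditions: two genotypes of one species,
2 chromosomes × 5 Mb, 200 shared background genes and 30 planted clusters
(mostly 2-copy, some 3-copy; ages alternating 1 and 11 MY; 0–2 intervening
genes; a quarter single-exon; two interleaved cassette pairs), half of the
cluster groups shared between genotypes, with subgenome blocks laid out at
the genome-wide maize1/maize2/nonsyntenic proportions (0.377/0.240/0.383).

Sequence evolution is Jukes–Cantor on CDS positions with no indels, at a
grass-like clock of 0.0065 substitutions/site/MY, applied independently
per lineage from a random sense-codon ancestor; expected pairwise
divergence between copies of age *t* is (3/4)(1 − e^(−8rt/3)), the
generator's closed-form oracle. An outgroup sequence diverged at the 12 MY
calibration is emitted per cluster; member–outgroup separation is 24 MY of
rate regardless of duplication age, so calibrated ages are unbiased by
construction. The two genotypes diverge by 0.1 MY on shared genes. Both
genotypes come from one master layout, so shared genes have identical
coordinates and private clusters simply leave gaps in the other genotype.

Default CDS length is 450 bp (150 aa): long enough that unrelated
random-codon genes score far below the 0.3 threshold (empirically ≤ ~0.26,
versus ≥ ~0.65 for the oldest planted duplicates), short enough that a
full two-genotype detection run stays cheap; dating experiments use
3000 bp (1000 codons) where age precision matters. Intron sequence is not
materialised — exon counts are metadata on the concatenated CDS. TEs are
intervals with class labels, no sequence: planted configurations place TEs
strictly inside genes (contains), strictly around genes (captured) or
overlapping half a gene (partial), on genotype A only (the TE analysis is
single-genotype), and background TEs fill intergenic space to per-class
coverage targets without ever touching a gene, so the planted placements
are the only containments and the truth ledger predicts the count table
exactly.

What the generator does **not** emulate — indels and alignment ambiguity,
gene conversion, realistic TE sequence/nesting, uneven gene spacing,
annotation errors — bounds what passing tests show: they validate the
rules and estimators under the stated model, not robustness to real
annotation noise. Gap handling in similarity is therefore tested on
hand-built alignments rather than simulated ones.

## Numerical and degenerate-input choices

- Gene sort tie-break (start, end, id); ranks are a permutation per
  chromosome.
- n_ungapped = 0 → adjusted similarity 0; all-N sequences and saturated
  (p ≥ 3/4) JC distances raise flagged errors instead of returning numbers.
- Gene length is the full annotated gene-model span (UTRs included when
  annotated); exon counts come from CDS segment counts of the longest
  transcript.
- Problem sizes in the test battery: 50 seeded genomes for recovery,
  ~4.6k exhaustive + 400 random cassette arrangements, 200 replicates of
  n = 500 windows for GLM calibration, 100 clusters of 1000 codons for
  dating — sizes chosen so every check is a sharp statistical test while
  the whole battery runs on a laptop in minutes.
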