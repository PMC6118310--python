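# tandemdup

Detection and evolutionary characterization of **tandem gene duplicate
clusters** in annotated plant genomes, built around the maize
(B73 / PH207) study design: two related genotypes, a paleopolyploid
subgenome structure (maize1 / maize2 / nonsyntenic), heavy transposable
element content, and a *Sorghum*-calibrated molecular clock.

## What it does

1. **Cluster detection.** The longest transcript of each gene is
   translated, proximal gene pairs (up to 15 intervening genes) are
   globally aligned (Needleman–Wunsch, BLOSUM62, affine gaps) and
   back-translated, and each pair receives a gap-adjusted similarity

   *adjusted = (identity in ungapped columns) × (fraction of columns ungapped)*,

   which penalises pairs that align only over a short conserved stretch.
   Pairs with adjusted similarity ≥ 0.3 form edges; tandem duplicate
   clusters are the connected components. Externally supplied candidate
   clusters (e.g. from a synteny tool) can be validated with the same rule.
2. **Cassettes.** Clusters whose gene coordinates interleave
   (A1 B1 A2 B2) are grouped into duplication cassettes; fully nested
   clusters are excluded.
3. **Genomic context.** Per-1-Mb-window densities (base-level union
   coverage) of tandem duplicates, all genes, RNA TEs (LTR/LINE/SINE) and
   DNA TEs (TIR), with a subgenome label per window, feed the linear model
   `Y = β0 + β1 g + β2 r + β3 d + β4 s + ε` with drop-one nested-model
   ANOVA, plus the correlation of window genic content with the tandem
   proportion of genic bases.
4. **TE containment.** Genes *containing* a TE and genes *captured* by a
   TE at overlap fraction 1.0, tabulated per TE class and tandem status.
5. **Dating.** Duplication ages from dated trees (TMRCA) or by clock
   calibration `age = 12 MY × d_pair / d_outgroup` against the
   maize–*Sorghum* split; homologous duplications present in both
   genotypes are deduplicated into single events; ages ≥ 10 MY are
   "ancient", ≤ 2 MY "recent".
6. **Genotype comparison.** Shared/private clusters and cassettes,
   cluster-size concordance, exon-count and gene-length summaries.
7. **Relative-rates scaffolding.** Orthogroup (10–75 genes) and
   alignment-column (≤ 50% gaps, ≥ 8 species) filters, clade-model
   likelihood-ratio tests, ω-based constraint classification (ω > 10
   untestable), and the HKA window decision with df = number of tandem
   genes.

A seeded **synthetic-genome generator** (`tandemdup.simulate`) produces two
genotypes with planted duplicates of controlled age (Jukes–Cantor
divergence), cassettes, TE configurations and subgenome blocks, plus a
truth ledger, so the whole pipeline is testable without genome downloads.

## Worked example

```python
from tandemdup import (SimConfig, simulate_genotypes, score_candidate_pairs,
                       build_clusters, detect_cassettes)

bundle_a, bundle_b, truth = simulate_genotypes(SimConfig(seed=1))
scored = score_candidate_pairs(bundle_a.genes)      # proximal pairs, adjusted similarity
clusters = build_clusters(scored, blocks=bundle_a.blocks)
cassettes = detect_cassettes(clusters)
print(len(clusters), "clusters;", len(cassettes), "cassettes")
print(clusters[0].gene_ids, f"subgenome={clusters[0].subgenome}")
```

prints

```
23 clusters; 2 cassettes
('A_g0001', 'A_g0002') subgenome=maize1
```

— the 23 planted clusters present in genotype A are recovered (each a
connected component of the ≥ 0.3 similarity graph), two planted
interleaved cassette pairs are detected, and the first cluster's two gene
copies fall in a maize1 block. The same objects drive the window GLM, TE
table, clock dating and cross-genotype comparison; or from the shell:

```bash
tandemdup run-all --simulate --seed 1 --out out/
```

writes cluster/cassette tables for both genotypes, `windows.tsv` +
`glm.json`, `te_table.tsv`, `events.tsv` (dated, deduplicated duplication
events) and `compare.json`, plus a manifest. Each stage is also its own
subcommand (`simulate`, `similarity`, `find-clusters`, `cassettes`,
`densities`, `glm`, `te-overlap`, `date`, `compare`, `rates`) operating on
standard GFF3/FASTA/TSV files.

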