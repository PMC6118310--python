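"""Genomic-context analysis: window densities, the density GLM, and the
tandem-proportion correlation.

Density of a feature class in a window is the proportion of window bases
covered by the base-level union of that class's intervals.  Tandem-duplicate
density is regressed on gene density (g), RNA TE density (r), DNA TE density
(d) and subgenome assignment (s):

    Y = b0 + b1*g + b2*r + b3*d + b4*s + e

with subgenome entering as a categorical (maize1 reference) and per-term
significance from ANOVA of nested (drop-one) models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core_io import (DNA_TE_CLASSES, RNA_TE_CLASSES, GenesByChrom,
                      SubgenomeBlock, TEFeature)

DEFAULT_WINDOW_SIZE = 1_000_000


class CollinearTermsError(ValueError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class GenomeWindow:
    """A fixed-width genomic bin with feature densities and a subgenome label."""

    chromosome: str
    start: int
    end: int
    tandem_density: float
    gene_density: float
    rna_te_density: float
    dna_te_density: float
    subgenome: str

    @property
    def width(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Base-level union of half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _covered_in_window(merged: Sequence[tuple[int, int]], w0: int, w1: int) -> int:
    return sum(max(0, min(e, w1) - max(s, w0)) for s, e in merged if s < w1 and e > w0)


def compute_windows(
    genes: GenesByChrom,
    tes: Sequence[TEFeature],
    tandem_gene_ids: set[str],
    blocks: Sequence[SubgenomeBlock],
    window_size: int = DEFAULT_WINDOW_SIZE,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomeWindow]:
    """Tile each chromosome with fixed windows and compute union densities.

    The trailing partial window is normalised by its actual width.  A
    window's subgenome is the label covering the majority of its block
    bases; no coverage or a tie gives nonsyntenic.
    """
    chroms = sorted(set(genes) | {t.chromosome for t in tes} | {b.chromosome for b in blocks})
    windows = []
    for chrom in chroms:
        chrom_genes = genes.get(chrom, [])
        gene_iv = merge_intervals((g.start, g.end) for g in chrom_genes)
        tandem_iv = merge_intervals(
            (g.start, g.end) for g in chrom_genes if g.id in tandem_gene_ids)
        rna_iv = merge_intervals(
            (t.start, t.end) for t in tes
            if t.chromosome == chrom and t.te_class in RNA_TE_CLASSES)
        dna_iv = merge_intervals(
            (t.start, t.end) for t in tes
            if t.chromosome == chrom and t.te_class in DNA_TE_CLASSES)
        block_iv = {lab: merge_intervals(
            (b.start, b.end) for b in blocks if b.chromosome == chrom and b.label == lab)
            for lab in ("maize1", "maize2", "nonsyntenic")}

        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            ends = ([iv[-1][1] for iv in (gene_iv, rna_iv, dna_iv) if iv]
                    + [iv[-1][1] for iv in block_iv.values() if iv])
            length = max(ends) if ends else 0
        for w0 in range(0, length, window_size):
            w1 = min(w0 + window_size, length)
            width = w1 - w0
            cover = {lab: _covered_in_window(iv, w0, w1) for lab, iv in block_iv.items()}
            best = max(cover.values())
            winners = [lab for lab, c in cover.items() if c == best]
            subgenome = winners[0] if (best > 0 and len(winners) == 1) else "nonsyntenic"
            windows.append(GenomeWindow(
                chromosome=chrom, start=w0, end=w1,
                tandem_density=_covered_in_window(tandem_iv, w0, w1) / width,
                gene_density=_covered_in_window(gene_iv, w0, w1) / width,
                rna_te_density=_covered_in_window(rna_iv, w0, w1) / width,
                dna_te_density=_covered_in_window(dna_iv, w0, w1) / width,
                subgenome=subgenome,
            ))
    for w in windows:
        assert w.tandem_density <= w.gene_density + 1e-12, \
            "tandem genes are genes; tandem density cannot exceed gene density"
    return windows


def windows_to_frame(windows: Sequence[GenomeWindow]) -> pd.DataFrame:
    df = pd.DataFrame([w.__dict__ for w in windows])
    df["subgenome"] = pd.Categorical(
        df["subgenome"], categories=["maize1", "maize2", "nonsyntenic"])
    return df


_BASE_TERMS = ["gene_density", "rna_te_density", "dna_te_density", "subgenome"]


@dataclass
class DensityGLMFit:
    """OLS fit of tandem-duplicate density on genomic covariates.

    ``anova`` holds one row per model term with its drop-one sum of squares
    (deviance), F statistic and p-value.
    """

    coefficients: pd.Series
    residuals: pd.Series
    fitted: pd.Series
    variance_explained: float
    anova: pd.DataFrame
    results: object  # underlying statsmodels RegressionResults

    def summary(self):
        return self.results.summary()


def _formula(include_interaction: bool) -> str:
    rhs = "gene_density + rna_te_density + dna_te_density + C(subgenome, Treatment('maize1'))"
    if include_interaction:
        rhs += " + gene_density:C(subgenome, Treatment('maize1'))"
    return "tandem_density ~ " + rhs


def fit_density_glm(
    windows: Sequence[GenomeWindow] | pd.DataFrame,
    include_interaction: bool = False,
) -> DensityGLMFit:
    """Ordinary least squares fit with drop-one nested-model ANOVA per term."""
    df = windows if isinstance(windows, pd.DataFrame) else windows_to_frame(windows)
    full = smf.ols(_formula(include_interaction), data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        names = full.model.exog_names
        x = full.model.exog
        culprits = [n for i, n in enumerate(names)
                    if np.linalg.matrix_rank(np.delete(x, i, axis=1))
                    == np.linalg.matrix_rank(x)]
        raise CollinearTermsError(f"rank-deficient design; collinear terms: {culprits}")

    terms = list(_BASE_TERMS)
    if include_interaction:
        terms.append("gene_density:subgenome")
    rows = []
    for term in terms:
        keep = [t for t in terms if t != term]
        # interaction requires its main effects; dropping a main effect drops it too
        if term in ("gene_density", "subgenome") and "gene_density:subgenome" in keep:
            keep.remove("gene_density:subgenome")
        rhs_parts = []
        for t in keep:
            if t == "subgenome":
                rhs_parts.append("C(subgenome, Treatment('maize1'))")
            elif t == "gene_density:subgenome":
                rhs_parts.append("gene_density:C(subgenome, Treatment('maize1'))")
            else:
                rhs_parts.append(t)
        reduced = smf.ols("tandem_density ~ " + (" + ".join(rhs_parts) or "1"), data=df).fit()
        tbl = anova_lm(reduced, full)
        rows.append({
            "term": term,
            "sum_sq": float(tbl["ss_diff"].iloc[1]),
            "df": float(tbl["df_diff"].iloc[1]),
            "F": float(tbl["F"].iloc[1]),
            "p_value": float(tbl["Pr(>F)"].iloc[1]),
        })
    anova = pd.DataFrame(rows).set_index("term")
    return DensityGLMFit(
        coefficients=full.params,
        residuals=full.resid,
        fitted=full.fittedvalues,
        variance_explained=float(full.rsquared),
        anova=anova,
        results=full,
    )


def interaction_test(windows: Sequence[GenomeWindow] | pd.DataFrame) -> float:
    """Nested-model ANOVA p-value for the gene-density x subgenome interaction."""
    df = windows if isinstance(windows, pd.DataFrame) else windows_to_frame(windows)
    base = smf.ols(_formula(False), data=df).fit()
    inter = smf.ols(_formula(True), data=df).fit()
    return float(anova_lm(base, inter)["Pr(>F)"].iloc[1])


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    undefined: bool = False


def tandem_proportion_correlation(
    windows: Sequence[GenomeWindow],
) -> CorrelationResult:
    """Pearson correlation of window genic proportion vs the proportion of
    genic bases that lie in tandem duplicates.

    Windows with zero gene density carry no information about the tandem
    proportion and are excluded.  Zero variance in either variable makes the
    correlation undefined (flagged, r = NaN).
    """
    xs, ys = [], []
    for w in windows:
        if w.gene_density > 0:
            xs.append(w.gene_density)
            ys.append(w.tandem_density / w.gene_density)
    if len(xs) < 3:
        raise ValueError("tandem_proportion_correlation: need >=3 windows with genes")
    if np.std(xs) == 0 or np.std(ys) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(xs), undefined=True)
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(float(r), float(p), len(xs))
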