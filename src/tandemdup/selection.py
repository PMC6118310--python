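"""Relative-rates scaffolding: orthogroup and alignment filters, clade-model
LRTs, omega-based constraint classification, and the HKA window decision.

The likelihood engines themselves (codon-model and HKA maximum-likelihood
fits) are upstream of this module; their per-model log-likelihoods,
parameter counts and omega estimates arrive as tables.  This module owns
the filtering rules, the model-selection scheme and the classification
logic applied to those results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

DEFAULT_MIN_GROUP = 10
DEFAULT_MAX_GROUP = 75
DEFAULT_MAX_GAP_FRACTION = 0.5
DEFAULT_MIN_SPECIES = 8
DEFAULT_ALPHA = 0.05
OMEGA_UNTESTABLE = 10.0


@dataclass(frozen=True)
class Orthogroup:
    """An orthologous gene group with tandem-duplicate bookkeeping."""

    id: str
    member_ids: tuple[str, ...]
    contains_tandem: bool
    tandem_cluster_complete: bool

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class CladeModelResult:
    """One clade model's fit for one orthogroup.

    Model 1 is the null (all branches one rate); models 2-4 mark different
    foreground sets (all maize; maize tandem duplicates vs everything;
    maize tandem duplicates vs other maize).
    """

    model: int
    lnl: float
    n_params: int
    omega_foreground: float | None = None
    omega_background: float | None = None


@dataclass(frozen=True)
class HKAWindowResult:
    """Likelihoods of the selection and neutral models for one gene window."""

    window_id: str
    lnl_selection: float
    lnl_neutral: float
    n_tandem: int


def filter_orthogroups(
    groups: Iterable[Orthogroup],
    min_size: int = DEFAULT_MIN_GROUP,
    max_size: int = DEFAULT_MAX_GROUP,
) -> list[Orthogroup]:
    """Retain groups of 10-75 genes that contain complete tandem clusters.

    Larger groups are likely long-diverged gene families; smaller ones lack
    branches for rate tests.  Groups whose tandem cluster is split across
    orthogroups are excluded.
    """
    return [g for g in groups
            if min_size <= g.size <= max_size
            and g.contains_tandem and g.tandem_cluster_complete]


def filter_alignment_columns(
    alignment: Sequence[str],
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
    min_species: int = DEFAULT_MIN_SPECIES,
) -> list[str]:
    """Drop codon columns with too many gaps.

    ``alignment`` is a list of equal-length codon-aligned nucleotide
    sequences (length a multiple of 3).  A sequence is gapped at a codon
    column if the codon contains ``-``.  A column is kept iff its gap
    fraction is at most ``max_gap_fraction`` and at least ``min_species``
    sequences are ungapped.  Codon columns are removed atomically.
    """
    if not alignment:
        return []
    n_cols = len(alignment[0])
    if any(len(s) != n_cols for s in alignment):
        raise ValueError("filter_alignment_columns: unequal sequence lengths")
    if n_cols % 3 != 0:
        raise ValueError("filter_alignment_columns: length not a multiple of 3")
    n_seq = len(alignment)
    keep = []
    for c in range(0, n_cols, 3):
        gaps = sum(1 for s in alignment if "-" in s[c:c + 3])
        if gaps / n_seq <= max_gap_fraction and (n_seq - gaps) >= min_species:
            keep.append(c)
    return ["".join(s[c:c + 3] for c in keep) for s in alignment]


def lrt_vs_null(null: CladeModelResult, alt: CladeModelResult) -> float:
    """Likelihood-ratio p-value of an alternative clade model against the null.

    Statistic 2*(lnL_alt - lnL_null) clamped at 0; chi-squared df = the
    parameter-count difference.
    """
    if alt.n_params <= null.n_params:
        raise ValueError("lrt_vs_null: alternative model is not nested above the null")
    statistic = max(0.0, 2.0 * (alt.lnl - null.lnl))
    if statistic == 0.0:
        return 1.0
    return float(stats.chi2.sf(statistic, df=alt.n_params - null.n_params))


def select_best_model(
    results: Sequence[CladeModelResult], alpha: float = DEFAULT_ALPHA
) -> CladeModelResult:
    """Best-fitting clade model by LRT against the null.

    Among alternative models that significantly improve on the null, the
    one with the highest log-likelihood wins; otherwise the null stands.
    """
    by_model = {r.model: r for r in results}
    if 1 not in by_model:
        raise ValueError("select_best_model: null model (1) missing")
    null = by_model[1]
    significant = [r for m, r in sorted(by_model.items()) if m != 1
                   and lrt_vs_null(null, r) < alpha]
    if not significant:
        return null
    return max(significant, key=lambda r: r.lnl)


def classify_constraint(result: CladeModelResult) -> str:
    """Classify tandem-duplicate constraint from foreground vs background omega.

    omega > 10 in the foreground means dS is too small to test
    ('untestable'); otherwise higher foreground omega than background means
    weaker purifying constraint, lower means stronger, equal is a tie.
    """
    if result.model not in (3, 4):
        raise ValueError("classify_constraint: only models 3/4 distinguish tandem branches")
    fg, bg = result.omega_foreground, result.omega_background
    if fg is None or bg is None:
        raise ValueError("classify_constraint: omegas missing")
    if fg > OMEGA_UNTESTABLE:
        return "untestable"
    if fg > bg:
        return "weaker"
    if fg < bg:
        return "stronger"
    return "tie"


def hka_window_decision(result: HKAWindowResult, alpha: float = DEFAULT_ALPHA) -> str:
    """Decide a window's HKA outcome: different_rate, same_rate or no_power.

    The power rule applies first: when the absolute log-likelihood of the
    selection model exceeds the neutral model's, the window lacks power.
    Otherwise an LRT with df equal to the number of tandem genes in the
    window is applied at ``alpha``.
    """
    if result.n_tandem < 1:
        raise ValueError(f"window {result.window_id}: no tandem genes; should not be tested")
    if abs(result.lnl_selection) > abs(result.lnl_neutral):
        return "no_power"
    statistic = max(0.0, 2.0 * (result.lnl_selection - result.lnl_neutral))
    p = 1.0 if statistic == 0.0 else float(stats.chi2.sf(statistic, df=result.n_tandem))
    return "different_rate" if p < alpha else "same_rate"
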