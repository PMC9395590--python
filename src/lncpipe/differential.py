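"""Pairwise stage comparisons and shared/unique (Venn) set algebra.

The DE procedure is a documented stand-in with three exposed knobs: a Welch
two-sample t-test on log2(FPKM + pseudocount) replicate values, BH adjustment
across transcripts within each comparison, and a fold-change gate. A
transcript is called ``up`` iff log2FC >= +lfc_threshold and q < alpha
(``down`` symmetric), so the up/down counts always sum to the DE total.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression import ExpressionMatrix

__all__ = [
    "ComparisonResult",
    "SetReport",
    "compare_stages",
    "venn_sets",
    "updown_totals",
    "stage_pairs",
]


@dataclass
class ComparisonResult:
    """Per-transcript DE calls for one (stageA, stageB) comparison.

    ``table`` is indexed by transcript id with columns ``log2fc`` (B vs A),
    ``p``, ``q`` and ``call`` in {up, down, ns}.
    """

    stage_a: str
    stage_b: str
    table: pd.DataFrame
    alpha: float
    lfc_threshold: float

    @property
    def comparison(self) -> str:
        return f"{self.stage_b}_vs_{self.stage_a}"

    def de_ids(self) -> set[str]:
        return set(self.table.index[self.table["call"] != "ns"])

    def up_ids(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    def down_ids(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])


def _log_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t on log values; degenerate zero-variance cases resolved exactly."""
    if np.allclose(a.var(), 0.0) and np.allclose(b.var(), 0.0):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return float(p) if np.isfinite(p) else 1.0


def compare_stages(
    m: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudocount: float = 0.1,
) -> ComparisonResult:
    """Call differential expression between two stages (B relative to A)."""
    for stage in (stage_a, stage_b):
        if stage not in m.stages:
            raise ValidationError(f"stage {stage!r} not present in matrix")
        if len(m.samples_for_stage(stage)) < 2:
            raise ValidationError(f"stage {stage!r} has fewer than 2 replicates")

    va = m.values.loc[m.samples_for_stage(stage_a)].to_numpy(dtype=float)
    vb = m.values.loc[m.samples_for_stage(stage_b)].to_numpy(dtype=float)
    log_a = np.log2(va + pseudocount)
    log_b = np.log2(vb + pseudocount)

    log2fc = np.log2(vb.mean(axis=0) + pseudocount) - np.log2(va.mean(axis=0) + pseudocount)
    pvals = np.array(
        [_log_ttest(log_a[:, j], log_b[:, j]) for j in range(log_a.shape[1])]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]

    call = np.where(
        (qvals < alpha) & (log2fc >= lfc_threshold), "up",
        np.where((qvals < alpha) & (log2fc <= -lfc_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "q": qvals, "call": call},
        index=m.values.columns,
    )
    return ComparisonResult(stage_a, stage_b, table, alpha, lfc_threshold)


def stage_pairs(stages) -> list[tuple[str, str]]:
    """All ordered pairwise comparisons (earlier stage first)."""
    return list(combinations(stages, 2))


@dataclass
class SetReport:
    """Region algebra over several DE id sets.

    ``region_counts`` maps a frozenset of comparison names (the Venn region:
    members of exactly those sets) to its element count. Regions partition
    the union, so region counts sum to the union size.
    """

    sets: dict[str, set[str]]
    union: set[str]
    all_intersection: set[str]
    region_counts: dict[frozenset, int]
    unique_counts: dict[str, int]


def venn_sets(results) -> SetReport:
    """Exact shared/unique set algebra over >=2 DE comparisons.

    ``results`` is either a list of ComparisonResult (DE ids are taken per
    comparison) or a mapping name -> id set.
    """
    if isinstance(results, dict):
        sets = {k: set(v) for k, v in results.items()}
    else:
        sets = {r.comparison: r.de_ids() for r in results}
    if len(sets) < 2:
        raise ValidationError("venn_sets requires at least 2 comparisons")

    union: set[str] = set().union(*sets.values())
    region_counts: dict[frozenset, int] = {}
    for item in union:
        region = frozenset(name for name, s in sets.items() if item in s)
        region_counts[region] = region_counts.get(region, 0) + 1
    all_inter = set.intersection(*sets.values()) if sets else set()
    unique = {
        name: region_counts.get(frozenset({name}), 0) for name in sets
    }
    return SetReport(
        sets=sets,
        union=union,
        all_intersection=all_inter,
        region_counts=region_counts,
        unique_counts=unique,
    )


def updown_totals(r) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) with n_total = n_up + n_down exactly.

    Accepts a ComparisonResult or a bare ``(n_up, n_down)`` pair of counts.
    """
    if isinstance(r, ComparisonResult):
        n_up = int((r.table["call"] == "up").sum())
        n_down = int((r.table["call"] == "down").sum())
    else:
        n_up, n_down = int(r[0]), int(r[1])
    return n_up, n_down, n_up + n_down
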