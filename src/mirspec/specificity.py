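"""Cancer-type specificity of differential miRNAs.

A miRNA that is differential in cancer C1 is *specific* to C1 when (a) its
improved fold change there is strong (|IFC| > t2) and (b) the sum over the
other cancer types of |IFC_C1 - IFC_Cj|, counting only cancers where the
miRNA's mean tumor expression does not exceed its C1 level (the delta
factor), exceeds t1 * t2 * (k - 1).  With the default t1 = 0.75, t2 = 0.5
and k = 8 cancer types the score threshold is 2.625.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ExpressionMatrix
from .diffexp import DEResult, DESummary, round_ratio
from .foldchange import FoldChangeRecord

DEFAULT_T1 = 0.75
DEFAULT_T2 = 0.5


@dataclass
class SpecificityResult:
    mirna_id: str
    target_cancer: str
    ifc_by_cancer: dict[str, float]
    delta_by_cancer: dict[str, int]
    score: float
    threshold: float
    specific: bool

    @property
    def direction(self) -> str:
        return "up" if self.ifc_by_cancer[self.target_cancer] > 0 else "down"


def delta_factor(mean_expr_target: float, mean_expr_other: float) -> int:
    """1 when the target cancer's mean expression is at least the other's.

    Zeroes out comparisons against cancers where the miRNA is expressed
    higher than in the target, filtering low-expression candidates.
    """
    if mean_expr_target < 0 or mean_expr_other < 0:
        raise ValueError("mean expression values must be nonnegative")
    return 1 if mean_expr_target >= mean_expr_other else 0


def specificity_score(ifc_target: float, ifc_others, deltas) -> float:
    """Delta-weighted sum of IFC distances to the other cancer types."""
    others = np.asarray(ifc_others, dtype=float)
    dl = np.asarray(deltas, dtype=float)
    if others.shape != dl.shape:
        raise ValueError("ifc_others and deltas must have the same length")
    return float(np.sum(np.abs(ifc_target - others) * dl))


def is_specific(
    ifc_target: float,
    score: float,
    k: int,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> bool:
    """Both specificity inequalities, strict: |IFC| > t2 and score > t1*t2*(k-1)."""
    if k < 2:
        raise ValueError("need at least 2 cancer types")
    return abs(ifc_target) > t2 and score > t1 * t2 * (k - 1)


def specificity_table(
    matrix: ExpressionMatrix,
    fc_tables: dict[str, list[FoldChangeRecord]],
    de_results: dict[str, list[DEResult]],
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> list[SpecificityResult]:
    """Score every differential miRNA of every cancer type for specificity.

    The candidate universe per target cancer is its differential set; IFC
    values for the other cancers come from those cancers' own tumor/normal
    fold-change tables, and delta factors compare mean tumor expression
    between the target and each other cancer.
    """
    cancers = sorted(fc_tables)
    k = len(cancers)
    ifc = {
        c: {rec.mirna_id: rec.ifc for rec in fc_tables[c]} for c in cancers
    }
    mean_tumor = {
        c: matrix.values[matrix.samples_of(c, "tumor")].mean(axis=1) for c in cancers
    }
    threshold = t1 * t2 * (k - 1)
    out: list[SpecificityResult] = []
    for c1 in cancers:
        selected = [r.mirna_id for r in de_results[c1] if r.selected]
        for mid in selected:
            others = [c for c in cancers if c != c1]
            ifc_t = ifc[c1][mid]
            ifc_o = [ifc[c][mid] for c in others]
            deltas = [
                delta_factor(float(mean_tumor[c1][mid]), float(mean_tumor[c][mid]))
                for c in others
            ]
            score = specificity_score(ifc_t, ifc_o, deltas)
            out.append(
                SpecificityResult(
                    mirna_id=mid,
                    target_cancer=c1,
                    ifc_by_cancer={c: ifc[c][mid] for c in cancers},
                    delta_by_cancer=dict(zip(others, deltas)),
                    score=score,
                    threshold=threshold,
                    specific=is_specific(ifc_t, score, k, t1, t2),
                )
            )
    return out


def summarize_specific(results: list[SpecificityResult], cancer_type: str) -> DESummary:
    """Up/down/total counts of specific miRNAs for one cancer type."""
    rel = [r for r in results if r.target_cancer == cancer_type and r.specific]
    n_up = sum(1 for r in rel if r.direction == "up")
    n_down = len(rel) - n_up
    return DESummary(
        cancer_type=cancer_type,
        n_up=n_up,
        n_down=n_down,
        n_all=len(rel),
        ratio_up_down=round_ratio(n_up, n_down),
    )
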