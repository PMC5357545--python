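"""Paired differential-expression calls: Wilcoxon signed-rank + BH FDR + IFC.

A miRNA is called differential in a cancer type when its improved fold
change exceeds 0.5 in magnitude and its Benjamini-Hochberg adjusted paired
Wilcoxon p-value falls below 0.05 (both strict, both configurable).
Multiple-testing correction is applied per cancer type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionMatrix
from .foldchange import FoldChangeRecord

#: largest n for which the exact sign-enumeration null is used
EXACT_N_MAX = 12


def wilcoxon_signed_rank(tumor, normal, method: str = "auto") -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention); ties among the
    absolute differences receive mid-ranks.  For n <= 12 nonzero pairs the
    p-value is exact, from full enumeration of the 2^n sign assignments of
    the (possibly tied) ranks; beyond that a normal approximation with tie
    and continuity corrections is used.  ``method`` forces "exact" or
    "approx".  Returns (W+, p) where W+ is the sum of ranks of positive
    differences.
    """
    t = np.asarray(tumor, dtype=float)
    u = np.asarray(normal, dtype=float)
    if t.shape != u.shape or t.ndim != 1:
        raise ValueError("tumor and normal must be equal-length 1-D vectors")
    d = t - u
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError(f"need >= 5 nonzero paired differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_N_MAX)
    if use_exact and n > 24:
        raise ValueError("exact enumeration is limited to n <= 24 pairs")
    if use_exact:
        # every subset of pairs flipped positive: W+ of each sign pattern
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        sums = masks @ ranks
        p = float(np.mean(np.abs(sums - mu) >= abs(w_pos - mu) - 1e-9))
    else:
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = (n * (n + 1) * (2 * n + 1) - ((tie_counts**3 - tie_counts).sum()) / 2.0) / 24.0
        dev = w_pos - mu
        z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return w_pos, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    mirna_id: str
    cancer_type: str
    statistic: float
    p_value: float
    q_value: float
    ifc: float
    direction: str  # "up", "down" or "none"
    selected: bool


@dataclass
class DESummary:
    cancer_type: str
    n_up: int
    n_down: int
    n_all: int
    ratio_up_down: float | None  # None when n_down == 0


def round_ratio(n_up: int, n_down: int) -> float | None:
    """up/down ratio rounded half away from zero to 3 decimals; None if n_down=0."""
    if n_down == 0:
        return None
    r = Decimal(n_up) / Decimal(n_down)
    return float(r.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def select_de(
    records: list[FoldChangeRecord],
    p_values,
    ifc_threshold: float = 0.5,
    q_threshold: float = 0.05,
) -> list[DEResult]:
    """Joint IFC / FDR differential-expression call for one cancer type.

    ``p_values`` aligns with ``records`` (one paired-test p per miRNA); each
    entry may be a (statistic, p) pair or a bare p.  Selection requires
    |IFC| > ifc_threshold and BH q < q_threshold, both strict.
    """
    if len(records) != len(p_values):
        raise ValueError("one p-value per fold-change record is required")
    stats_p = []
    for entry in p_values:
        if np.isscalar(entry):
            stats_p.append((math.nan, float(entry)))
        else:
            stats_p.append((float(entry[0]), float(entry[1])))
    q = bh_fdr([p for _, p in stats_p])
    out = []
    for rec, (w, p), qv in zip(records, stats_p, q):
        selected = abs(rec.ifc) > ifc_threshold and qv < q_threshold
        direction = "none" if not selected else ("up" if rec.ifc > 0 else "down")
        out.append(
            DEResult(
                mirna_id=rec.mirna_id,
                cancer_type=rec.cancer_type,
                statistic=w,
                p_value=p,
                q_value=float(qv),
                ifc=rec.ifc,
                direction=direction,
                selected=selected,
            )
        )
    return out


def de_test_matrix(matrix: ExpressionMatrix, cancer_type: str) -> list[tuple[float, float]]:
    """Paired Wilcoxon test of every miRNA for one cancer type.

    Pairs tumor and normal columns by patient id; miRNAs whose differences
    are all zero (untestable) receive p = 1.
    """
    tumor_ids, normal_ids = matrix.paired_samples(cancer_type)
    if len(tumor_ids) < 5:
        raise ValueError(f"cancer type {cancer_type!r} has {len(tumor_ids)} pairs; need >= 5")
    t = matrix.values[tumor_ids].to_numpy()
    u = matrix.values[normal_ids].to_numpy()
    results = []
    for i in range(t.shape[0]):
        try:
            results.append(wilcoxon_signed_rank(t[i], u[i]))
        except ValueError:
            results.append((math.nan, 1.0))
    return results


def filter_stage(matrix: ExpressionMatrix, stage_label: str = "Stage I") -> ExpressionMatrix:
    """Restrict tumors to one pathologic stage, keeping their paired normals."""
    md = matrix.metadata
    keep: list[str] = []
    tumors = md[(md["status"] == "tumor") & (md["stage"] == stage_label)]
    patients = set(tumors["patient_id"])
    for sid, row in md.iterrows():
        if row["status"] == "tumor":
            if row["stage"] == stage_label:
                keep.append(sid)
        elif row["patient_id"] in patients:
            keep.append(sid)
    if not keep:
        raise ValueError(f"no samples remain after filtering to stage {stage_label!r}")
    return matrix.subset_samples(keep)


def summarize_de(results: list[DEResult], cancer_type: str) -> DESummary:
    """Up/down/total counts and the rounded up/down ratio for one cancer."""
    rel = [r for r in results if r.cancer_type == cancer_type and r.selected]
    n_up = sum(1 for r in rel if r.direction == "up")
    n_down = sum(1 for r in rel if r.direction == "down")
    return DESummary(
        cancer_type=cancer_type,
        n_up=n_up,
        n_down=n_down,
        n_all=n_up + n_down,
        ratio_up_down=round_ratio(n_up, n_down),
    )
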