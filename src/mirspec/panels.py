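"""k-miRNA biomarker panels ranked by LDA/LOOCV accuracy.

Specific, up-regulated miRNAs that appear in the plasma/serum part of a
circulating-miRNA catalog are candidate biomarkers.  All subsets of size
1..5 of the strongest candidates are evaluated by two leave-one-out
cross-validated linear-discriminant accuracies:

* accuracy 1 — tumor vs. paired normal samples of the target cancer, on RPM
  expression of the panel;
* accuracy 2 — the target cancer's patient pairs vs. all other cancers'
  pairs, on per-pair fold-change profiles of the panel.

Panels are ranked by the mean of the two accuracies.  The discriminant uses
a pooled within-class covariance with a small ridge term, so collinear
panels remain well defined, and LOOCV is computed with an exact rank-one
downdate of the class means and pooled scatter (refitting nothing), which
makes the exhaustive search cheap and deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix
from .foldchange import DEFAULT_PSEUDOCOUNT, per_quantile_fold_change

DEFAULT_RIDGE = 1e-6
PLASMA_SERUM = ("plasma", "serum")


@dataclass
class CombinationResult:
    cancer_type: str
    mirna_ids: tuple[str, ...]
    accuracy1: float
    accuracy2: float

    @property
    def mean_accuracy(self) -> float:
        return (self.accuracy1 + self.accuracy2) / 2.0


@dataclass
class LDAModel:
    classes: np.ndarray
    means: np.ndarray  # (n_classes, d)
    covariance: np.ndarray  # pooled within-class + ridge, (d, d)
    priors: np.ndarray


def filter_circulating(specific_up_mirnas: set[str], catalog: dict[str, str]) -> set[str]:
    """Intersect candidates with catalog entries labeled plasma or serum."""
    return {m for m in specific_up_mirnas if catalog.get(m) in PLASMA_SERUM}


def pair_fold_change_features(
    matrix: ExpressionMatrix,
    cancer_type: str,
    mirna_ids: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-patient-pair fold-change profiles (one row per pair).

    The entry for pair p and miRNA i applies the signed quantile fold-change
    formula to the pair's (tumor RPM, normal RPM) scalar values.
    """
    tumor_ids, normal_ids = matrix.paired_samples(cancer_type)
    if not tumor_ids:
        raise ValueError(f"no complete tumor/normal pairs for {cancer_type!r}")
    t = matrix.values.loc[mirna_ids, tumor_ids].to_numpy()
    u = matrix.values.loc[mirna_ids, normal_ids].to_numpy()
    fc = per_quantile_fold_change(t, u, pseudocount)
    patients = [matrix.metadata.loc[s, "patient_id"] for s in tumor_ids]
    return pd.DataFrame(fc.T, index=patients, columns=mirna_ids)


def lda_fit(features, labels, ridge: float = DEFAULT_RIDGE) -> LDAModel:
    """Two-class linear discriminant with pooled covariance + ridge."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 observations")
    d = X.shape[1]
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for c, mu in zip(classes, means):
        r = X[y == c] - mu
        scatter += r.T @ r
    cov = scatter / max(X.shape[0] - 2, 1) + ridge * np.eye(d)
    return LDAModel(classes=classes, means=means, covariance=cov, priors=counts / counts.sum())


def lda_predict(model: LDAModel, features) -> np.ndarray:
    """Class with the larger linear discriminant score for each row."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    inv = np.linalg.inv(model.covariance)
    scores = np.empty((X.shape[0], len(model.classes)))
    for j, (mu, pi) in enumerate(zip(model.means, model.priors)):
        w = inv @ mu
        scores[:, j] = X @ w - 0.5 * mu @ w + np.log(pi)
    return model.classes[np.argmax(scores, axis=1)]


def loocv_accuracy(features, labels, ridge: float = DEFAULT_RIDGE) -> float:
    """Leave-one-out overall accuracy (TP + TN) / N of the LDA classifier.

    Every sample is held out exactly once.  Class means and the pooled
    scatter are downdated exactly for the held-out sample, so the result is
    identical to refitting on each N-1 subset but costs O(N d^2); it is
    invariant to row order.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    n, d = X.shape
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 observations")
    cls_idx = np.searchsorted(classes, y)
    sums = np.vstack([X[cls_idx == j].sum(axis=0) for j in range(2)])
    means = sums / counts[:, None]
    scatter = np.zeros((d, d))
    for j in range(2):
        r = X[cls_idx == j] - means[j]
        scatter += r.T @ r

    # exact downdate per held-out sample, vectorized over samples
    nc = counts[cls_idx].astype(float)  # class size of each sample's class
    resid = X - means[cls_idx]  # x - mu_c
    mean_own = (sums[cls_idx] - X) / (nc - 1)[:, None]
    down = (nc / (nc - 1))[:, None, None] * (resid[:, :, None] * resid[:, None, :])
    cov = (scatter[None, :, :] - down) / max(n - 1 - 2, 1) + ridge * np.eye(d)[None, :, :]
    inv = np.linalg.inv(cov)

    # per-sample training means and priors for the two classes
    mu0 = np.where((cls_idx == 0)[:, None], mean_own, np.broadcast_to(means[0], (n, d)))
    mu1 = np.where((cls_idx == 1)[:, None], mean_own, np.broadcast_to(means[1], (n, d)))
    n0 = np.where(cls_idx == 0, counts[0] - 1, counts[0]).astype(float)
    n1 = np.where(cls_idx == 1, counts[1] - 1, counts[1]).astype(float)

    def score(mu, prior):
        w = np.einsum("nij,nj->ni", inv, mu)
        return np.einsum("ni,ni->n", X, w) - 0.5 * np.einsum("ni,ni->n", mu, w) + np.log(prior)

    pred = np.where(score(mu1, n1 / (n - 1)) > score(mu0, n0 / (n - 1)), 1, 0)
    return float(np.mean(pred == cls_idx))


def evaluate_combination(
    matrix: ExpressionMatrix,
    cancer_type: str,
    mirna_ids,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ridge: float = DEFAULT_RIDGE,
) -> CombinationResult:
    """Both LOOCV accuracies of one candidate panel.

    Accuracy 1 classifies the cancer's tumor vs. normal samples on RPM
    expression; accuracy 2 classifies the cancer's pairs against all other
    cancers' pairs on fold-change profiles.
    """
    ids = sorted(mirna_ids)
    if not 1 <= len(ids) <= 5:
        raise ValueError("panel size must be between 1 and 5")
    missing = [m for m in ids if m not in matrix.values.index]
    if missing:
        raise ValueError(f"panel miRNAs absent from matrix: {missing}")
    tumor_ids, normal_ids = matrix.paired_samples(cancer_type)
    X1 = matrix.values.loc[ids, tumor_ids + normal_ids].to_numpy().T
    y1 = np.array([1] * len(tumor_ids) + [0] * len(normal_ids))
    acc1 = loocv_accuracy(X1, y1, ridge)

    blocks, labels = [], []
    for c in matrix.cancer_types:
        feats = pair_fold_change_features(matrix, c, ids, pseudocount)
        blocks.append(feats.to_numpy())
        labels.extend([1 if c == cancer_type else 0] * len(feats))
    acc2 = loocv_accuracy(np.vstack(blocks), np.array(labels), ridge)
    return CombinationResult(
        cancer_type=cancer_type, mirna_ids=tuple(ids), accuracy1=acc1, accuracy2=acc2
    )


def search_combinations(
    matrix: ExpressionMatrix,
    cancer_type: str,
    candidates,
    candidate_scores: dict[str, float] | None = None,
    k_max: int = 5,
    candidate_cap: int = 20,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ridge: float = DEFAULT_RIDGE,
) -> list[CombinationResult]:
    """Exhaustively rank panels of size 1..k_max from the top candidates.

    Candidates beyond ``candidate_cap`` are dropped after ranking by
    |score| (typically |IFC|) descending; without scores the lexicographic
    order decides.  Results are sorted by mean accuracy descending, then by
    smaller panel, then lexicographically — rerunning is deterministic.
    """
    cand = sorted(set(candidates))
    if not cand:
        raise ValueError("candidate set is empty")
    if not 1 <= k_max <= 5:
        raise ValueError("k_max must be in [1, 5]")
    if candidate_scores:
        cand.sort(key=lambda m: (-abs(candidate_scores.get(m, 0.0)), m))
    cand = cand[:candidate_cap]

    # features computed once; panels slice columns
    tumor_ids, normal_ids = matrix.paired_samples(cancer_type)
    expr = matrix.values.loc[cand, tumor_ids + normal_ids].to_numpy().T
    y1 = np.array([1] * len(tumor_ids) + [0] * len(normal_ids))
    blocks, labels = [], []
    for c in matrix.cancer_types:
        feats = pair_fold_change_features(matrix, c, cand, pseudocount)
        blocks.append(feats.to_numpy())
        labels.extend([1 if c == cancer_type else 0] * len(feats))
    fc_feats = np.vstack(blocks)
    y2 = np.array(labels)

    results = []
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(range(len(cand)), k):
            ids = tuple(sorted(cand[i] for i in combo))
            cols = list(combo)
            acc1 = loocv_accuracy(expr[:, cols], y1, ridge)
            acc2 = loocv_accuracy(fc_feats[:, cols], y2, ridge)
            results.append(
                CombinationResult(
                    cancer_type=cancer_type, mirna_ids=ids, accuracy1=acc1, accuracy2=acc2
                )
            )
    results.sort(key=lambda r: (-r.mean_accuracy, len(r.mirna_ids), r.mirna_ids))
    return results
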