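"""Tab-separated readers/writers for matrices, catalogs and stage reports."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import CATALOG_SOURCES, ExpressionMatrix
from .diffexp import DEResult, DESummary
from .foldchange import FoldChangeRecord
from .panels import CombinationResult
from .specificity import SpecificityResult

METADATA_COLUMNS = ["cancer_type", "status", "patient_id", "stage"]


def write_matrix(matrix: ExpressionMatrix, path, metadata_path=None) -> None:
    """Write the RPM matrix and its metadata sidecar as TSV.

    The matrix file has miRNA ids in the first column and one column per
    sample; the sidecar (default: ``<path>.meta.tsv``) is keyed by sample id.
    Values round-trip at full float precision.
    """
    path = Path(path)
    metadata_path = Path(metadata_path) if metadata_path else path.with_suffix(path.suffix + ".meta.tsv")
    matrix.values.to_csv(path, sep="\t", index_label="mirna_id", float_format="%.17g")
    matrix.metadata[METADATA_COLUMNS].to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_matrix(path, metadata_path=None) -> ExpressionMatrix:
    """Read a TSV expression matrix plus metadata sidecar (see write_matrix)."""
    path = Path(path)
    metadata_path = Path(metadata_path) if metadata_path else path.with_suffix(path.suffix + ".meta.tsv")
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate miRNA ids in {path}: {dups}")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index.name = None
    missing = [s for s in values.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata {metadata_path}: {missing}")
    if (values.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return ExpressionMatrix(values=values, metadata=metadata)


def write_catalog(catalog: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tsource\n")
        for mid in sorted(catalog):
            fh.write(f"{mid}\t{catalog[mid]}\n")


def read_catalog(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["mirna_id", "source"]:
        raise ValueError(f"catalog {path} must have columns mirna_id, source")
    bad = set(df["source"]) - set(CATALOG_SOURCES)
    if bad:
        raise ValueError(f"unknown catalog sources in {path}: {sorted(bad)}")
    return dict(zip(df["mirna_id"].astype(str), df["source"]))


def fold_change_frame(records: list[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "cancer_type": [r.cancer_type for r in records],
            "ofc": [r.ofc for r in records],
            "sigma_cq": [r.sigma_cq for r in records],
            "sigma_nq": [r.sigma_nq for r in records],
            "ifc": [r.ifc for r in records],
        }
    )


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in results],
            "cancer_type": [r.cancer_type for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "ifc": [r.ifc for r in results],
            "direction": [r.direction for r in results],
            "selected": [r.selected for r in results],
        }
    )


def summary_frame(summaries: list[DESummary]) -> pd.DataFrame:
    """Summary rows in the layout cancer_type, up, down, all, ratio."""
    return pd.DataFrame(
        {
            "cancer_type": [s.cancer_type for s in summaries],
            "up": [s.n_up for s in summaries],
            "down": [s.n_down for s in summaries],
            "all": [s.n_all for s in summaries],
            "ratio": ["NA" if s.ratio_up_down is None else f"{s.ratio_up_down:.3f}" for s in summaries],
        }
    )


def specificity_frame(results: list[SpecificityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in results],
            "cancer_type": [r.target_cancer for r in results],
            "ifc_target": [r.ifc_by_cancer[r.target_cancer] for r in results],
            "score": [r.score for r in results],
            "threshold": [r.threshold for r in results],
            "specific": [r.specific for r in results],
        }
    )


def combination_frame(results: list[CombinationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cancer_type": [r.cancer_type for r in results],
            "panel": ["+".join(r.mirna_ids) for r in results],
            "accuracy1": [r.accuracy1 for r in results],
            "accuracy2": [r.accuracy2 for r in results],
            "mean": [r.mean_accuracy for r in results],
        }
    )
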