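"""End-to-end orchestration with reproducible run manifests.

``run_pipeline`` executes the four analysis stages in order — fold change,
differential expression, specificity, biomarker panels — writing every stage
table, a summary per cancer type, a JSON manifest (config, seed, row counts)
and a log under the output directory.  The same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .cohort import CohortConfig, ExpressionMatrix, generate_circulating_catalog, generate_cohort
from .diffexp import de_test_matrix, filter_stage, select_de, summarize_de
from .foldchange import DEFAULT_PSEUDOCOUNT, DEFAULT_SIGMA_FLOOR, fold_change_table
from .panels import filter_circulating, search_combinations
from .specificity import specificity_table, summarize_specific

logger = logging.getLogger("mirspec")


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    matrix_path: str | None = None
    metadata_path: str | None = None
    catalog_path: str | None = None
    cohort: CohortConfig | None = None  # synthetic mode when set
    catalog_frac_covered: float = 0.8
    q: int = 100
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    ifc_variant: str = "signed_square_ratio"
    sigma_floor: float = DEFAULT_SIGMA_FLOOR
    ifc_threshold: float = 0.5
    q_threshold: float = 0.05
    t1: float = 0.75
    t2: float = 0.5
    k_max: int = 5
    candidate_cap: int = 20
    stage_label: str = "Stage I"
    seed: int = 0
    out_dir: str = "mirspec_run"

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if not 1 <= self.k_max <= 5:
            raise ValueError("k_max must be in [1, 5]")
        for name in ("ifc_threshold", "q_threshold", "t1", "t2", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def validate_inputs(
    matrix: ExpressionMatrix, catalog: dict[str, str] | None = None
) -> list[dict]:
    """Machine-readable input sanity report (empty list = no issues).

    Checks RPM scaling of every sample, tumor/normal pairing, presence of
    stage labels, and catalog coverage.
    """
    issues: list[dict] = []
    sums = matrix.values.sum(axis=0)
    off = sums[(sums - 1e6).abs() > 1.0]
    for sid, s in off.items():
        issues.append({"kind": "not_rpm_scaled", "sample": sid, "column_sum": float(s)})
    md = matrix.metadata
    for c in matrix.cancer_types:
        sub = md[md["cancer_type"] == c]
        normals_by_patient = set(sub[sub["status"] == "normal"]["patient_id"])
        for sid, row in sub[sub["status"] == "tumor"].iterrows():
            if row["patient_id"] not in normals_by_patient:
                issues.append(
                    {"kind": "unpaired_tumor", "sample": sid, "patient_id": row["patient_id"]}
                )
    if md["stage"].isna().any():
        issues.append({"kind": "missing_stage_labels", "n": int(md["stage"].isna().sum())})
    if catalog is not None:
        known = set(matrix.mirna_ids)
        unknown = sorted(set(catalog) - known)
        if unknown:
            issues.append({"kind": "catalog_ids_not_in_matrix", "n": len(unknown)})
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    manifest: dict = {"config": _config_dict(config), "stages": {}}
    if config.cohort is not None:
        matrix, truth = generate_cohort(config.cohort)
        catalog = generate_circulating_catalog(
            truth, config.catalog_frac_covered, seed=config.cohort.seed + 1
        )
        manifest["ground_truth"] = {
            "n_de": {c: len(v) for c, v in truth.de_mirnas.items()},
            "n_specific": {c: len(v) for c, v in truth.specific_mirnas.items()},
            "n_circulating": len(truth.circulating_ids),
        }
        mio.write_matrix(matrix, out / "cohort.tsv")
        mio.write_catalog(catalog, out / "catalog.tsv")
        logger.info("simulated cohort: %d miRNAs x %d samples", *matrix.values.shape)
    else:
        if not (config.matrix_path and config.catalog_path):
            raise ValueError("either a cohort config or matrix+catalog paths are required")
        matrix = mio.read_matrix(config.matrix_path, config.metadata_path)
        catalog = mio.read_catalog(config.catalog_path)
        truth = None

    issues = validate_inputs(matrix, catalog)
    (out / "validation.json").write_text(json.dumps(issues, indent=2))
    if issues:
        logger.warning("validation found %d issues", len(issues))
    manifest["stages"]["validation"] = {"n_issues": len(issues)}

    matrix = filter_stage(matrix, config.stage_label)
    logger.info("stage filter '%s': %d samples retained", config.stage_label, len(matrix.sample_ids))

    cancers = matrix.cancer_types
    fc_tables, de_by_cancer, de_summaries = {}, {}, []
    for c in cancers:
        fc_tables[c] = fold_change_table(
            matrix, c, q=config.q, pseudocount=config.pseudocount,
            variant=config.ifc_variant, sigma_floor=config.sigma_floor,
        )
        tests = de_test_matrix(matrix, c)
        de_by_cancer[c] = select_de(
            fc_tables[c], tests, config.ifc_threshold, config.q_threshold
        )
        de_summaries.append(summarize_de(de_by_cancer[c], c))
        logger.info(
            "%s: %d up / %d down differential miRNAs",
            c, de_summaries[-1].n_up, de_summaries[-1].n_down,
        )
    mio.fold_change_frame([r for c in cancers for r in fc_tables[c]]).to_csv(
        out / "fold_change.tsv", sep="\t", index=False, float_format="%.6g"
    )
    mio.de_frame([r for c in cancers for r in de_by_cancer[c]]).to_csv(
        out / "de_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    mio.summary_frame(de_summaries).to_csv(out / "de_summary.tsv", sep="\t", index=False)
    manifest["stages"]["differential_expression"] = {
        s.cancer_type: {"up": s.n_up, "down": s.n_down} for s in de_summaries
    }

    spec_results = specificity_table(matrix, fc_tables, de_by_cancer, config.t1, config.t2)
    spec_summaries = [summarize_specific(spec_results, c) for c in cancers]
    mio.specificity_frame(spec_results).to_csv(
        out / "specificity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    mio.summary_frame(spec_summaries).to_csv(out / "specificity_summary.tsv", sep="\t", index=False)
    for s in spec_summaries:
        logger.info("%s: %d up / %d down specific miRNAs", s.cancer_type, s.n_up, s.n_down)
    manifest["stages"]["specificity"] = {
        s.cancer_type: {"up": s.n_up, "down": s.n_down} for s in spec_summaries
    }

    top_rows, rankings = [], {}
    for c in cancers:
        spec_up = {
            r.mirna_id for r in spec_results
            if r.target_cancer == c and r.specific and r.direction == "up"
        }
        candidates = filter_circulating(spec_up, catalog)
        if not candidates:
            logger.warning("%s: no circulating specific up-regulated candidates", c)
            rankings[c] = []
            continue
        scores = {r.mirna_id: r.ifc for r in fc_tables[c]}
        ranked = search_combinations(
            matrix, c, candidates, candidate_scores=scores,
            k_max=config.k_max, candidate_cap=config.candidate_cap,
            pseudocount=config.pseudocount,
        )
        rankings[c] = [
            {
                "panel": list(r.mirna_ids),
                "accuracy1": r.accuracy1,
                "accuracy2": r.accuracy2,
                "mean": r.mean_accuracy,
            }
            for r in ranked
        ]
        top_rows.append(ranked[0])
        logger.info(
            "%s: best panel %s mean accuracy %.4f",
            c, "+".join(ranked[0].mirna_ids), ranked[0].mean_accuracy,
        )
    if top_rows:
        mio.combination_frame(top_rows).to_csv(
            out / "panel_report.tsv", sep="\t", index=False, float_format="%.4f"
        )
    (out / "panel_rankings.json").write_text(json.dumps(rankings, indent=2))
    manifest["stages"]["panels"] = {c: len(v) for c, v in rankings.items()}

    if truth is not None:
        manifest["recovery"] = _recovery_report(truth, de_by_cancer, spec_results)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _recovery_report(truth, de_by_cancer, spec_results) -> dict:
    """Sensitivity/false-discovery of the DE and specificity calls vs. truth."""
    de_sens, de_fdr, sp_sens = [], [], []
    for c, results in de_by_cancer.items():
        planted = truth.de_ids(c)
        called = {r.mirna_id for r in results if r.selected}
        if planted:
            de_sens.append(len(called & planted) / len(planted))
        if called:
            de_fdr.append(len(called - planted) / len(called))
        planted_spec = truth.specific_mirnas.get(c, set())
        called_spec = {
            r.mirna_id for r in spec_results if r.target_cancer == c and r.specific
        }
        if planted_spec:
            sp_sens.append(len(called_spec & planted_spec) / len(planted_spec))
    return {
        "de_sensitivity": float(np.mean(de_sens)) if de_sens else None,
        "de_false_discovery_rate": float(np.mean(de_fdr)) if de_fdr else None,
        "specific_sensitivity": float(np.mean(sp_sens)) if sp_sens else None,
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
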