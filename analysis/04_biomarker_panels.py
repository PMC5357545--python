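"""Circulating k-miRNA biomarker panels (k = 1..5) per cancer type, ranked by
the mean of two LDA/LOOCV accuracies (tumor-vs-normal within the cancer and
one-vs-rest across cancers on per-pair fold-change profiles).

Writes the best panel per cancer to results/panel_report.tsv and the full
rankings to results/panel_rankings.json.
"""

import json
from pathlib import Path

from mirspec.diffexp import de_test_matrix, select_de
from mirspec.foldchange import fold_change_table
from mirspec.io import combination_frame, read_catalog, read_matrix
from mirspec.panels import filter_circulating, search_combinations
from mirspec.specificity import specificity_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    matrix = read_matrix(SCRATCH / "cohort" / "cohort.tsv")
    catalog = read_catalog(SCRATCH / "cohort" / "catalog.tsv")
    fc, de = {}, {}
    for c in matrix.cancer_types:
        fc[c] = fold_change_table(matrix, c)
        de[c] = select_de(fc[c], de_test_matrix(matrix, c))
    spec = specificity_table(matrix, fc, de)

    top, rankings = [], {}
    for c in matrix.cancer_types:
        spec_up = {
            r.mirna_id for r in spec
            if r.target_cancer == c and r.specific and r.direction == "up"
        }
        candidates = filter_circulating(spec_up, catalog)
        if not candidates:
            print(f"{c}: no circulating specific up-regulated candidates")
            rankings[c] = []
            continue
        scores = {r.mirna_id: r.ifc for r in fc[c]}
        ranked = search_combinations(
            matrix, c, candidates, candidate_scores=scores, candidate_cap=12
        )
        top.append(ranked[0])
        rankings[c] = [
            {"panel": list(r.mirna_ids), "accuracy1": r.accuracy1,
             "accuracy2": r.accuracy2, "mean": r.mean_accuracy}
            for r in ranked[:10]
        ]
    frame = combination_frame(top)
    frame.to_csv(RESULTS / "panel_report.tsv", sep="\t", index=False, float_format="%.4f")
    (RESULTS / "panel_rankings.json").write_text(json.dumps(rankings, indent=2))
    print("best circulating panel per cancer type:")
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
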