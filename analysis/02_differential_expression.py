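"""Differential expression per cancer type: quantile fold change (q=100),
paired Wilcoxon signed-rank with BH FDR, joint |IFC| > 0.5 & q < 0.05 call.

Reads the cohort written by 01_simulate_cohort.py, writes the full
fold-change and call tables to scratch/ and the up/down summary table
(one row per cancer) to results/de_summary.tsv.
"""

from pathlib import Path

from mirspec.diffexp import de_test_matrix, select_de, summarize_de
from mirspec.foldchange import fold_change_table
from mirspec.io import de_frame, fold_change_frame, read_matrix, summary_frame

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    matrix = read_matrix(SCRATCH / "cohort" / "cohort.tsv")
    fc_all, de_all, summaries = [], [], []
    for c in matrix.cancer_types:
        records = fold_change_table(matrix, c)
        results = select_de(records, de_test_matrix(matrix, c))
        fc_all.extend(records)
        de_all.extend(results)
        summaries.append(summarize_de(results, c))
    fold_change_frame(fc_all).to_csv(
        SCRATCH / "fold_change.tsv", sep="\t", index=False, float_format="%.6g"
    )
    de_frame(de_all).to_csv(
        SCRATCH / "de_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    table = summary_frame(summaries)
    table.to_csv(RESULTS / "de_summary.tsv", sep="\t", index=False)
    print("differentially expressed miRNAs per cancer type (up / down / all / up:down):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
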