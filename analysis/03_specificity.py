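"""Cancer-type-specific differential miRNAs: delta-weighted IFC distance to
the other seven cancers, thresholds t1=0.75, t2=0.5.

Writes the per-miRNA specificity table to scratch/ and the per-cancer
up/down summary to results/specificity_summary.tsv.
"""

from pathlib import Path

from mirspec.diffexp import de_test_matrix, select_de
from mirspec.foldchange import fold_change_table
from mirspec.io import read_matrix, specificity_frame, summary_frame
from mirspec.specificity import specificity_table, summarize_specific

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    matrix = read_matrix(SCRATCH / "cohort" / "cohort.tsv")
    fc, de = {}, {}
    for c in matrix.cancer_types:
        fc[c] = fold_change_table(matrix, c)
        de[c] = select_de(fc[c], de_test_matrix(matrix, c))
    results = specificity_table(matrix, fc, de)
    specificity_frame(results).to_csv(
        SCRATCH / "specificity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    table = summary_frame([summarize_specific(results, c) for c in matrix.cancer_types])
    table.to_csv(RESULTS / "specificity_summary.tsv", sep="\t", index=False)
    print("specific differential miRNAs per cancer type (up / down / all / up:down):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
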