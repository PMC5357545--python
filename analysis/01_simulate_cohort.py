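"""Simulate the study cohort: eight cancer types, 30 tumor/normal pairs each,
500 miRNAs with planted differential and cancer-specific effects, plus a
plasma/serum circulating-miRNA catalog covering 80% of the planted specifics.

Writes the full RPM matrix and catalog under scratch/cohort/ (large,
regenerable) and a small ground-truth summary under results/.
"""

import json
from pathlib import Path

from mirspec import CohortConfig, generate_circulating_catalog, generate_cohort
from mirspec.io import write_catalog, write_matrix

SEED = 7

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    matrix, truth = generate_cohort(cfg)
    catalog = generate_circulating_catalog(truth, frac_covered=0.8, seed=SEED + 1)

    write_matrix(matrix, SCRATCH / "cohort.tsv")
    write_catalog(catalog, SCRATCH / "catalog.tsv")
    (SCRATCH / "ground_truth.json").write_text(json.dumps({
        "de_mirnas": {c: sorted(v) for c, v in truth.de_mirnas.items()},
        "specific_mirnas": {c: sorted(v) for c, v in truth.specific_mirnas.items()},
        "circulating_ids": sorted(truth.circulating_ids),
    }, indent=2))
    summary = {
        "config": cfg.__dict__,
        "n_mirnas": matrix.values.shape[0],
        "n_samples": matrix.values.shape[1],
        "planted_de_per_cancer": {c: len(v) for c, v in truth.de_mirnas.items()},
        "planted_specific_per_cancer": {c: len(v) for c, v in truth.specific_mirnas.items()},
        "catalog_size": len(catalog),
        "plasma_serum_entries": sum(1 for s in catalog.values() if s in ("plasma", "serum")),
    }
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"cohort: {summary['n_mirnas']} miRNAs x {summary['n_samples']} samples")
    print(f"planted differential per cancer: {summary['planted_de_per_cancer']}")
    print(f"planted specific per cancer:     {summary['planted_specific_per_cancer']}")
    print(f"catalog: {summary['catalog_size']} entries, "
          f"{summary['plasma_serum_entries']} plasma/serum")


if __name__ == "__main__":
    main()
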