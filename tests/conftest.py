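import numpy as np
import pytest

from mirspec import CohortConfig, generate_cohort, generate_circulating_catalog
from mirspec.diffexp import de_test_matrix, select_de
from mirspec.foldchange import fold_change_table
from mirspec.specificity import specificity_table


@pytest.fixture(scope="session")
def small_cohort():
    """Two cancer types, 10 pairs, 120 miRNAs — cheap structural fixture."""
    cfg = CohortConfig(
        n_cancer_types=2, n_pairs_per_type=10, n_mirnas=120,
        frac_de=0.2, frac_specific=0.05, seed=11,
    )
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def study_cohort():
    """Full study conditions: 8 cancer types, 30 pairs, 500 miRNAs."""
    cfg = CohortConfig(seed=7)
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def study_analysis(study_cohort):
    """Fold-change tables, differential calls and specificity results for the
    full study cohort, computed once per session."""
    cfg, matrix, truth = study_cohort
    fc_tables, de_results = {}, {}
    for c in matrix.cancer_types:
        fc_tables[c] = fold_change_table(matrix, c)
        de_results[c] = select_de(fc_tables[c], de_test_matrix(matrix, c))
    spec = specificity_table(matrix, fc_tables, de_results)
    catalog = generate_circulating_catalog(truth, frac_covered=0.8, seed=8)
    return {
        "config": cfg,
        "matrix": matrix,
        "truth": truth,
        "fc_tables": fc_tables,
        "de_results": de_results,
        "specificity": spec,
        "catalog": catalog,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
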