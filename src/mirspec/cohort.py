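"""Synthetic multi-cancer paired tumor/normal miRNA cohorts with planted truth.

The generator emulates the structure of a TCGA-style miRNA-seq collection:
for each cancer type a set of patients contributes one tumor and one normal
sample, counts follow a negative-binomial model with a log-normal baseline
per miRNA and a shared per-patient log-normal profile factor (the source of
within-pair correlation), and each sample is normalized to reads-per-million
(RPM).  Differential miRNAs receive a multiplicative ``2**effect_log2fc``
shift on tumor samples; cancer-specific miRNAs are differential in exactly
one cancer type, background differential miRNAs in all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cancer-type labels used for cohorts of up to eight types
DEFAULT_CANCER_LABELS = ["BRCA", "CRAD", "KIDC", "LIHC", "LUNG", "PRAD", "STAD", "THCA"]

#: extracellular source categories of the circulating-miRNA catalog
CATALOG_SOURCES = ("plasma", "serum", "exosome", "Ago2", "HDL")

# standard deviation of the shared per-patient log-normal miRNA profile
# factor; survives RPM normalization and drives tumor/normal pair correlation
_PATIENT_PROFILE_SD = 0.3
# log-normal sigma of per-miRNA baseline abundances
_BASELINE_SIGMA = 1.5
# planted differential miRNAs are drawn from this abundance-quantile band:
# dominant miRNAs would shift the whole RPM composition, and near-zero ones
# are unrecoverable by any method, so neither makes a usable ground truth
_DE_ABUNDANCE_BAND = (0.3, 0.9)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``effect_log2fc`` is the planted log2 effect magnitude, ``dispersion``
    the negative-binomial overdispersion (variance = mu + dispersion * mu^2),
    ``library_size_mean`` the expected raw read total per sample.
    """

    n_cancer_types: int = 8
    n_pairs_per_type: int = 30
    n_mirnas: int = 500
    frac_de: float = 0.2
    frac_specific: float = 0.08
    effect_log2fc: float = 2.0
    dispersion: float = 0.2
    library_size_mean: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cancer_types, self.n_pairs_per_type, self.n_mirnas) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("frac_de", "frac_specific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_specific > self.frac_de:
            raise ValueError("frac_specific must not exceed frac_de")
        if self.effect_log2fc <= 0 or self.dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("effect_log2fc, dispersion and library_size_mean must be positive")


@dataclass
class ExpressionMatrix:
    """miRNA x sample RPM matrix plus per-sample metadata.

    ``values`` is indexed by miRNA accession with one column per sample;
    ``metadata`` is indexed by sample id with columns ``cancer_type``,
    ``status`` ("tumor"/"normal"), ``patient_id`` and ``stage``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.metadata = self.metadata.loc[list(self.values.columns)]
        self.values.index.name = None
        self.values.columns.name = None
        self.metadata.index.name = None

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.metadata["cancer_type"].unique())

    def samples_of(self, cancer_type: str, status: str) -> list[str]:
        md = self.metadata
        sel = md[(md["cancer_type"] == cancer_type) & (md["status"] == status)]
        return list(sel.index)

    def paired_samples(self, cancer_type: str) -> tuple[list[str], list[str]]:
        """Tumor and normal sample ids of a cancer type, aligned by patient.

        Only patients contributing both a tumor and a normal sample are
        returned; both lists are ordered by patient id.
        """
        md = self.metadata[self.metadata["cancer_type"] == cancer_type]
        by_patient: dict[str, dict[str, str]] = {}
        for sid, row in md.iterrows():
            by_patient.setdefault(row["patient_id"], {}).setdefault(row["status"], sid)
        patients = sorted(p for p, d in by_patient.items() if "tumor" in d and "normal" in d)
        tumor_ids = [by_patient[p]["tumor"] for p in patients]
        normal_ids = [by_patient[p]["normal"] for p in patients]
        return tumor_ids, normal_ids

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
        )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    de_mirnas: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    specific_mirnas: dict[str, set[str]] = field(default_factory=dict)
    circulating_ids: set[str] = field(default_factory=set)

    def de_ids(self, cancer_type: str) -> set[str]:
        return {m for m, _ in self.de_mirnas.get(cancer_type, set())}


def _cancer_labels(n: int) -> list[str]:
    if n <= len(DEFAULT_CANCER_LABELS):
        return DEFAULT_CANCER_LABELS[:n]
    extra = [f"CT{i:02d}" for i in range(len(DEFAULT_CANCER_LABELS) + 1, n + 1)]
    return DEFAULT_CANCER_LABELS + extra


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a paired multi-cancer RPM matrix with known planted effects.

    Counts for miRNA i in a sample of patient p are drawn from a negative
    binomial with mean ``library * a_i * u_{p,i} * effect`` where ``a_i`` is a
    log-normal relative abundance, ``u_{p,i}`` a per-patient log-normal
    profile factor shared between the patient's tumor and normal sample, and
    ``effect = 2**(+-effect_log2fc)`` on tumor samples of planted miRNAs.
    Columns are then scaled to sum to 1e6 (RPM).  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_mirnas
    cancers = _cancer_labels(config.n_cancer_types)
    mirna_ids = [f"MIMAT{i:07d}" for i in range(1, m + 1)]

    baseline = rng.lognormal(mean=0.0, sigma=_BASELINE_SIGMA, size=m)
    abundance = baseline / baseline.sum()

    # plant differential structure into the mid-abundance band
    n_de = int(round(config.frac_de * m))
    n_spec = min(int(round(config.frac_specific * m)), n_de)
    lo, hi = np.quantile(baseline, _DE_ABUNDANCE_BAND)
    eligible = np.flatnonzero((baseline >= lo) & (baseline < hi))
    if n_de > eligible.size:
        rest = np.setdiff1d(np.arange(m), eligible)
        eligible = np.concatenate([eligible, rest])
    de_pool = rng.permutation(eligible)[:n_de]
    spec_pool, shared_pool = de_pool[:n_spec], de_pool[n_spec:]

    truth = GroundTruth(
        de_mirnas={c: set() for c in cancers},
        specific_mirnas={c: set() for c in cancers},
    )
    # effect multiplier per (miRNA, cancer) applied to tumor samples
    log2_effect = np.zeros((m, len(cancers)))
    per_cancer_count: dict[str, int] = {c: 0 for c in cancers}
    # specific miRNAs are planted up-regulated: the delta factor removes
    # down-shifted targets by construction, and the panel stage looks for
    # up-regulated circulating markers
    for idx, mi in enumerate(spec_pool):
        c = cancers[idx % len(cancers)]
        per_cancer_count[c] += 1
        log2_effect[mi, cancers.index(c)] = config.effect_log2fc
        truth.de_mirnas[c].add((mirna_ids[mi], "up"))
        truth.specific_mirnas[c].add(mirna_ids[mi])
    # background differential miRNAs: shifted in every cancer, balanced signs
    shared_signs = rng.permutation(
        np.resize(np.array([1.0, -1.0]), len(shared_pool))
    )
    for mi, sign in zip(shared_pool, shared_signs):
        direction = "up" if sign > 0 else "down"
        log2_effect[mi, :] = sign * config.effect_log2fc
        for c in cancers:
            truth.de_mirnas[c].add((mirna_ids[mi], direction))

    columns, col_meta = [], []
    counts = np.empty((m, 2 * config.n_pairs_per_type * len(cancers)), dtype=float)
    col = 0
    for ci, c in enumerate(cancers):
        effect_mult = 2.0 ** log2_effect[:, ci]
        for p in range(config.n_pairs_per_type):
            patient = f"{c}-P{p + 1:03d}"
            profile = rng.lognormal(mean=0.0, sigma=_PATIENT_PROFILE_SD, size=m)
            for status in ("tumor", "normal"):
                lib = config.library_size_mean * rng.lognormal(0.0, 0.25)
                mu = abundance * profile * lib
                if status == "tumor":
                    mu = mu * effect_mult
                r = 1.0 / config.dispersion
                counts[:, col] = rng.negative_binomial(r, r / (r + mu))
                columns.append(f"{patient}-{'01T' if status == 'tumor' else '11N'}")
                col_meta.append(
                    {
                        "sample_id": columns[-1],
                        "cancer_type": c,
                        "status": status,
                        "patient_id": patient,
                        "stage": "Stage I",
                    }
                )
                col += 1

    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1.0
    rpm = counts / colsum * 1e6
    values = pd.DataFrame(rpm, index=mirna_ids, columns=columns)
    metadata = pd.DataFrame(col_meta).set_index("sample_id")
    return ExpressionMatrix(values=values, metadata=metadata), truth


def generate_circulating_catalog(
    ground_truth: GroundTruth, frac_covered: float, seed: int, background_frac: float = 0.2
) -> dict[str, str]:
    """Emulate a plasma/serum circulating-miRNA catalog.

    Exactly ``round(frac_covered * n_specific)`` of the planted specific
    miRNAs are labeled plasma or serum; the rest of the specific miRNAs enter
    the catalog under non-blood sources, and a ``background_frac`` sample of
    the remaining planted-differential miRNAs is added with mixed labels.
    Returns a mapping miRNA id -> source category.
    """
    if not 0.0 <= frac_covered <= 1.0:
        raise ValueError("frac_covered must be in [0, 1]")
    rng = np.random.default_rng(seed)
    specific = sorted(set().union(*ground_truth.specific_mirnas.values())) if ground_truth.specific_mirnas else []
    n_cov = int(round(frac_covered * len(specific)))
    order = rng.permutation(len(specific))
    catalog: dict[str, str] = {}
    for j, idx in enumerate(order):
        if j < n_cov:
            catalog[specific[idx]] = "plasma" if j % 2 == 0 else "serum"
        else:
            catalog[specific[idx]] = str(rng.choice(["exosome", "Ago2", "HDL"]))
    others = sorted(
        {m for c in ground_truth.de_mirnas for m in ground_truth.de_ids(c)} - set(specific)
    )
    for mid in others:
        if rng.random() < background_frac:
            catalog[mid] = str(rng.choice(list(CATALOG_SOURCES)))
    ground_truth.circulating_ids = {m for m, s in catalog.items() if s in ("plasma", "serum")}
    return catalog
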