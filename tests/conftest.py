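import numpy as np
import pandas as pd
import pytest

from autosig.abundance_io import TaxonomicProfile
from autosig.synthetic_data import SimulationConfig, generate_cohort

#: One-point tuning grids used to keep simulation-heavy tests fast; the
#: tuning machinery itself is exercised separately with multi-point grids.
SINGLE_POINT_GRIDS = {
    "random_forest": {"max_features": ["sqrt"]},
    "gradient_boosting": {"learning_rate": [0.3], "max_depth": [6], "n_estimators": [100]},
    "ridge_logistic": {"logit__C": [1.0]},
    "svm_rfe": {"C": [1.0], "gamma": ["scale"]},
}


def lineages(n: int, prefix: str = "G") -> list[str]:
    return [f"k__Bacteria;p__P;c__C;o__O;f__F{i % 5};g__{prefix}{i:03d}" for i in range(n)]


def make_profile(values, sample_ids=None, taxa=None, kind="counts") -> TaxonomicProfile:
    values = np.asarray(values)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    taxa = taxa or lineages(values.shape[1])
    return TaxonomicProfile(pd.DataFrame(values, index=sample_ids, columns=taxa), kind)


def make_metadata(sample_ids, study="st1", disease="healthy", age=30.0, subject=None, time=0):
    rows = []
    for i, sid in enumerate(sample_ids):
        rows.append(
            {
                "study_id": study if isinstance(study, str) else study[i],
                "subject_id": (subject[i] if subject else sid),
                "time_index": time if isinstance(time, int) else time[i],
                "disease": disease if isinstance(disease, str) else disease[i],
                "age_years": age if isinstance(age, (int, float)) else age[i],
            }
        )
    from autosig.abundance_io import validate_metadata

    return validate_metadata(pd.DataFrame(rows, index=list(sample_ids)))


@pytest.fixture(scope="session")
def planted_cohort():
    """A two-class cohort with a strong planted 15-taxon signature
    (effect fold 8, 150 samples per class over 2 studies, 200 taxa)."""
    cfg = SimulationConfig(
        seed=11,
        n_studies=2,
        samples_per_study=75,
        disease_labels=("healthy", "disease"),
        shared_signature_size=15,
        per_disease_signature_size=0,
        effect_fold=8.0,
    )
    profile, metadata, truth = generate_cohort(cfg)
    return cfg, profile, metadata, truth
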