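import numpy as np
import pandas as pd
import pytest

from dosepair.dosage_add import compute_add_frame
from dosepair.episode_builder import build_episodes, merge_readmissions
from dosepair.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort (multiple drugs, PN/VAO
    courses, missing doses, readmissions)."""
    cfg = CohortConfig(n_patients=300, n_drugs=6, seed=5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_episodes(small_cohort):
    add = compute_add_frame(small_cohort.prescriptions)
    return build_episodes(small_cohort.prescriptions, add)


@pytest.fixture(scope="session")
def small_admissions(small_cohort):
    return merge_readmissions(small_cohort.admissions)


def make_rx_frame(rows):
    """Prescriptions table from (admission, patient, drug, start_day,
    end_day, dose, freq, rx_type) tuples; one prescription per row, daily
    interval, times in minutes."""
    recs = []
    for i, (adm, pat, drug, s, e, dose, freq, rx_type) in enumerate(rows):
        recs.append({
            "rx_id": f"T{i:05d}", "admission_id": adm, "patient_id": pat,
            "drug_atc": drug, "start": s * 1440.0, "end": e * 1440.0,
            "dose": dose, "unit": "mg", "freq": freq, "interval_hours": 24.0,
            "rx_type": rx_type, "strength": np.nan, "volume": np.nan,
        })
    return pd.DataFrame(recs)
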