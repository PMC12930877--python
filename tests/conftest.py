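import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slecrit import Cohort, CohortConfig, FeatureSet, PatientRecord, FEATURES, generate

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# planted single-class cohorts legitimately trigger the one-class warning
warnings.filterwarnings("ignore", message="cohort contains a single reference class")


def make_record(present=(), *, patient_id="p1", reference_sle=True, sex="female",
                duration=2.0, ana_titer=None, ln_class=None, unattributable=()):
    """Convenience record factory for engine/unit tests."""
    fs = FeatureSet.from_present(present, ln_class=ln_class, unattributable=unattributable)
    if ana_titer is None:
        ana_titer = "1:160" if fs.present("ana_positive") else "negative"
    return PatientRecord(
        patient_id=patient_id, reference_sle=reference_sle, sex=sex,
        age_at_enrollment=30.0 + duration, age_at_onset=30.0,
        disease_duration=duration, features=fs, ana_titer=ana_titer)


def random_record(rng: np.random.Generator, p: float = 0.3, patient_id="r1"):
    """Random record with iid Bernoulli(p) feature flags and a consistent titer."""
    present = [f for f in FEATURES if rng.random() < p]
    titer = rng.choice(["1:80", "1:160", "1:320"]) if "ana_positive" in present else "negative"
    ln_class = rng.choice(["II_V", "III_IV"]) if "lupus_nephritis_biopsy" in present else None
    return make_record(present, patient_id=patient_id, ana_titer=str(titer),
                       ln_class=ln_class)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default-profile cohort shared across tests."""
    return generate(CohortConfig.default(), seed=20260921)


@pytest.fixture(scope="session")
def default_classifications(default_cohort):
    from slecrit import classify_all
    return classify_all(default_cohort)


@pytest.fixture()
def tiny_cohort():
    recs = [
        make_record(FEATURES, patient_id="case_full", duration=0.5),
        make_record(["ana_positive", "acute_cutaneous", "arthritis", "proteinuria"],
                    patient_id="case_mid", duration=3.0),
        make_record(["arthritis"], patient_id="ctrl_ra", reference_sle=False, duration=6.0),
        make_record([], patient_id="ctrl_none", reference_sle=False, duration=1.5),
    ]
    return Cohort(records=recs, provenance={"source": "synthetic", "seed": 0})
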