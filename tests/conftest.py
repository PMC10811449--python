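import pandas as pd
import pytest

import oculink as ol
from oculink.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """300-patient cohort with no missingness/contamination/registry gaps."""
    cfg = SyntheticConfig(
        n_patients=300, seed=11, p_registry_absent=0.0,
        p_missing={"mrn": 0.0, "gender": 0.0, "birthdate": 0.0, "name": 0.0},
        contamination={"p_numeric_name": 0.0, "p_abnormal_dob": 0.0,
                       "p_test_name": 0.0})
    registry, metadata, truth = generate_cohort(cfg)
    return cfg, registry, metadata, truth


@pytest.fixture(scope="session")
def messy_cohort():
    """500-patient cohort with contamination and registry-absent patients."""
    cfg = SyntheticConfig(
        n_patients=500, seed=23, p_registry_absent=0.12,
        contamination={"p_numeric_name": 0.05, "p_abnormal_dob": 0.02,
                       "p_test_name": 0.02})
    registry, metadata, truth = generate_cohort(cfg)
    return cfg, registry, metadata, truth


@pytest.fixture(scope="session")
def messy_run(messy_cohort):
    """Consolidated + normalized + flagged + linked view of the messy cohort."""
    cfg, registry, metadata, truth = messy_cohort
    patients, images = ol.consolidate_patients(metadata)
    patients = ol.apply_exclusions(ol.normalize_patients(patients),
                                   cfg.date_range[1])
    registry_n = ol.normalize_patients(registry)
    edges = ol.build_candidate_edges(patients, registry_n)
    result = ol.resolve_matching(
        edges, all_patient_keys=patients["patient_key"],
        all_registry_ids=registry_n["registry_id"])
    return dict(cfg=cfg, registry=registry_n, patients=patients,
                images=images, truth=truth, edges=edges, result=result)


def identity_from_row(row, location_id=None) -> ol.NormalizedIdentity:
    from oculink.extraction import parse_dicom_date
    return ol.NormalizedIdentity(
        name_norm=row["name_norm"],
        birthdate=parse_dicom_date(row["birthdate_norm"]),
        gender=row["gender_norm"],
        mrn_norm=row["mrn_norm"],
        location_id=row.get("location_id", location_id or ""),
    )
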