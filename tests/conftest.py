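import datetime as dt

import pandas as pd
import pytest

from opiclaims.claims import ClaimsBundle, default_code_map, default_drug_dictionary


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


def make_bundle(patients, diagnoses=(), prescriptions=(), dictionary=None):
    """Build a small bundle from tuples.

    patients: (pid, sex, birth_year, end_of_data_iso)
    diagnoses: (pid, icd10, date_iso)
    prescriptions: (pid, drug_code, start_iso, days_supplied, daily_dose_mg[, n_units])
    """
    pat = pd.DataFrame(
        [
            {"patient_id": p, "sex": s, "birth_year": by, "end_of_data": d(e)}
            for p, s, by, e in patients
        ],
        columns=["patient_id", "sex", "birth_year", "end_of_data"],
    )
    dx = pd.DataFrame(
        [{"patient_id": p, "icd10_code": c, "date": d(dte)} for p, c, dte in diagnoses],
        columns=["patient_id", "icd10_code", "date"],
    )
    rx = pd.DataFrame(
        [
            {
                "patient_id": r[0],
                "drug_code": r[1],
                "start_date": d(r[2]),
                "days_supplied": r[3],
                "daily_dose_mg": float(r[4]),
                "n_units": r[5] if len(r) > 5 else 1,
            }
            for r in prescriptions
        ],
        columns=["patient_id", "drug_code", "start_date", "days_supplied",
                 "daily_dose_mg", "n_units"],
    )
    return ClaimsBundle(
        pat, dx, rx, dictionary or default_drug_dictionary(), default_code_map()
    ).validate()


@pytest.fixture
def tiny_bundle():
    """Three patients: an eligible case-like patient, a control, an ineligible one."""
    return make_bundle(
        patients=[
            ("A", "male", 1950, "2015-01-01"),
            ("B", "female", 1960, "2015-01-01"),
            ("C", "male", 1970, "2010-06-01"),
        ],
        diagnoses=[
            ("A", "C50", "2010-01-01"),
            ("B", "C18", "2010-02-01"),
            ("C", "C34", "2010-01-01"),
        ],
        prescriptions=[
            ("A", "MOR_OR", "2010-01-10", 30, 150.0),
            ("A", "MOR_OR", "2010-02-09", 200, 150.0),
            ("B", "OXY_OR", "2010-03-01", 14, 20.0),
            ("C", "MOR_OR", "2010-02-01", 14, 30.0),  # only ~120 days follow-up
        ],
    )
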