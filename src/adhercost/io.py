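"""CSV reading helpers for the pipeline's tabular interfaces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DATE_COLUMNS = {
    "patients.csv": ["birth_date", "death_date", "index_date", "dmp_cad_enrollment",
                     "insurance_start", "insurance_end"],
    "hospital_stays.csv": ["admit_date", "discharge_date"],
    "dispensations.csv": ["dispense_date"],
    "costs.csv": ["service_date"],
    "dmp_docs.csv": ["doc_date"],
    "periods.csv": ["start", "end"],
    "cohort.csv": ["birth_date", "death_date", "index_date", "dmp_cad_enrollment"],
}


def read_table(path) -> pd.DataFrame:
    """Read one of the pipeline CSVs, parsing its known date columns."""
    path = Path(path)
    date_cols = [c for c in DATE_COLUMNS.get(path.name, [])]
    df = pd.read_csv(path)
    for c in date_cols:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
    return df


def spells_from_patients(patients: pd.DataFrame) -> pd.DataFrame:
    """Insurance spells from the single-spell columns of patients.csv.

    Real-data inputs with several spells per patient can instead supply a
    long table with ``patient_id, start, end`` directly.
    """
    return pd.DataFrame({
        "patient_id": patients["patient_id"],
        "start": patients["insurance_start"],
        "end": patients["insurance_end"],
    })
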