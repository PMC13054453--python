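import numpy as np
import pandas as pd
import pytest

from icsignal.simulate import GeneratorConfig, demo_config, generate_database
from icsignal.store import IcsrDatabase


def _reports(rows):
    return pd.DataFrame(
        rows,
        columns=["report_id", "country", "report_year", "reporter_type",
                 "serious", "age_years", "sex"],
    )


@pytest.fixture
def tiny_db() -> IcsrDatabase:
    """Ten hand-built reports with known counts.

    Narrow case PT is RP; PI and CH extend the broad definition.  Drug DC
    is a treatment-class (excluded) drug and appears concomitantly in the
    case R2.  Suspect/interacting marginals: DA in R1, R5, R8; DB in R3,
    R4, R9; DD in R7, R10 (DB in R6 is concomitant only).
    """
    reports = _reports([
        ("R1", "US", 2020, "health_professional", 1, 40.0, "F"),
        ("R2", "US", 2020, "consumer", 0, 55.0, "F"),
        ("R3", "FR", 2021, "health_professional", 0, 60.0, "M"),
        ("R4", "FR", 2021, "consumer", 0, 30.0, "F"),
        ("R5", "GB", 2019, "health_professional", 0, 70.0, "M"),
        ("R6", "GB", 2019, "consumer", 1, np.nan, "F"),
        ("R7", "US", 2022, "health_professional", 0, 25.0, "F"),
        ("R8", "US", 2022, "consumer", 0, 45.0, "M"),
        ("R9", "DE", 2023, "health_professional", 1, 50.0, "F"),
        ("R10", "DE", 2023, "unknown", 0, 65.0, "unknown"),
    ])
    report_drugs = pd.DataFrame(
        [
            ("R1", "DA", "suspect", 2020, 1, 1),
            ("R2", "DA", "suspect", 2020, 3, np.nan),
            ("R2", "DC", "concomitant", np.nan, np.nan, np.nan),
            ("R3", "DB", "suspect", 2021, 6, 1),
            ("R4", "DB", "suspect", 2021, np.nan, np.nan),
            ("R5", "DA", "interacting", 2019, 2, 10),
            ("R6", "DB", "concomitant", np.nan, np.nan, np.nan),
            ("R7", "DD", "suspect", 2022, 8, 1),
            ("R8", "DA", "suspect", 2022, 5, 15),
            ("R9", "DB", "suspect", 2023, 1, 1),
            ("R10", "DD", "suspect", 2023, 2, np.nan),
        ],
        columns=["report_id", "drug_id", "role", "start_year", "start_month", "start_day"],
    )
    report_events = pd.DataFrame(
        [
            ("R1", "RP", 2020, 1, 31),
            ("R2", "RP", 2020, 4, np.nan),
            ("R3", "RP", 2021, 6, 20),
            ("R4", "PI", np.nan, np.nan, np.nan),
            ("R5", "PT_A", 2019, 3, 1),
            ("R6", "PT_A", np.nan, np.nan, np.nan),
            ("R7", "CH", 2022, 9, 1),
            ("R8", "PT_B", 2022, 6, 1),
            ("R9", "PT_B", 2023, 2, 1),
            ("R10", "PT_A", 2023, 3, np.nan),
        ],
        columns=["report_id", "pt_code", "onset_year", "onset_month", "onset_day"],
    )
    drug_dictionary = pd.DataFrame(
        [
            ("DA", "alphalol", "C07AA01", 0, "beta_blocker"),
            ("DB", "betafetamine", "N06BA01", 0, "amphetamine_like"),
            ("DC", "gammadipine", "C08CA05", 1, "rp_treatment"),
            ("DD", "deltatriptan", "N02CC01", 0, "antimigraine"),
        ],
        columns=["drug_id", "name", "atc_codes", "rp_treatment", "class_tags"],
    )
    event_dictionary = pd.DataFrame(
        [
            ("RP", "Raynaud's phenomenon", "HLT1", "SOC1"),
            ("PI", "Peripheral ischaemia", "HLT1", "SOC1"),
            ("CH", "Chilblains", "HLT1", "SOC1"),
            ("PT_A", "Event A", "HLT2", "SOC2"),
            ("PT_B", "Event B", "HLT2", "SOC2"),
        ],
        columns=["pt_code", "pt_name", "hlt", "soc"],
    )
    return IcsrDatabase(
        reports=reports,
        report_drugs=report_drugs,
        report_events=report_events,
        drug_dictionary=drug_dictionary,
        event_dictionary=event_dictionary,
    )


@pytest.fixture(scope="session")
def null_db():
    """Medium null database (no planted structure), shared read-only."""
    db, truth = generate_database(GeneratorConfig(n_reports=20_000, seed=11))
    return db, truth


@pytest.fixture(scope="session")
def demo_db():
    """Demo scenario: planted signals of graded strength plus clusters."""
    db, truth = generate_database(demo_config(seed=5))
    return db, truth
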