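"""Data model and I/O for spontaneous-report (ICSR) databases.

The database is held as five tidy tables mirroring the on-disk TSV layout:
one row per report, per report-drug link, per report-event link, plus the
drug and event dictionaries.  All analysis stages consume this container.

Case selection, the treatment-drug exclusion rule, and per-drug case
summaries live here because they are properties of the data model, not of
any particular statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .dates import PartialDate, compute_tto, impute_ymd_arrays
from .vocab import (
    AGE_BAND_LABELS,
    DEFAULT_AGE_BAND_EDGES,
    DRUG_ROLES,
    REPORTER_TYPES,
    SEX_LEVELS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IcsrDatabase",
    "CaseSummary",
    "read_database",
    "read_database_dir",
    "write_database",
    "select_cases",
    "apply_exclusion",
    "summarize_cases",
    "drug_indicator",
    "event_indicator",
    "age_band",
]

REPORT_COLUMNS = ["report_id", "country", "report_year", "reporter_type", "serious", "age_years", "sex"]
DRUG_LINK_COLUMNS = ["report_id", "drug_id", "role", "start_year", "start_month", "start_day"]
EVENT_LINK_COLUMNS = ["report_id", "pt_code", "onset_year", "onset_month", "onset_day"]
DRUG_DICT_COLUMNS = ["drug_id", "name", "atc_codes", "rp_treatment", "class_tags"]
EVENT_DICT_COLUMNS = ["pt_code", "pt_name", "hlt", "soc"]

ANALYSIS_ROLES = ("suspect", "interacting")  # roles counted toward drug marginals


@dataclass
class IcsrDatabase:
    """Normalised store of reports, link tables, and dictionaries."""

    reports: pd.DataFrame
    report_drugs: pd.DataFrame
    report_events: pd.DataFrame
    drug_dictionary: pd.DataFrame
    event_dictionary: pd.DataFrame
    load_log: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.reports) == 0:
            raise ValueError("database contains zero valid reports")
        if self.reports["report_id"].duplicated().any():
            raise ValueError("duplicate report_id in reports table")

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def report_ids(self) -> pd.Series:
        return self.reports["report_id"]

    def drug_classes(self, class_tag: str) -> set:
        """Drug ids whose dictionary entry carries ``class_tag``."""
        tags = self.drug_dictionary["class_tags"].fillna("")
        mask = tags.str.split(";").apply(lambda t: class_tag in t)
        return set(self.drug_dictionary.loc[mask, "drug_id"])


# ---------------------------------------------------------------------------
# reading / writing

def _read_tsv(path, columns):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[columns]


def read_database(
    reports_path,
    drugs_path,
    events_path,
    drug_dict_path,
    event_dict_path,
) -> IcsrDatabase:
    """Load and validate the five TSV tables.

    Rows violating referential integrity (unknown report, drug, or PT keys,
    invalid role or enum values) are skipped; their file and line numbers
    are collected on ``db.load_log`` and counted in a single warning.
    Reports left without at least one drug and one event row are dropped.
    """
    log: list[str] = []

    reports = _read_tsv(reports_path, REPORT_COLUMNS)
    drugs = _read_tsv(drugs_path, DRUG_LINK_COLUMNS)
    events = _read_tsv(events_path, EVENT_LINK_COLUMNS)
    drug_dict = _read_tsv(drug_dict_path, DRUG_DICT_COLUMNS)
    event_dict = _read_tsv(event_dict_path, EVENT_DICT_COLUMNS)

    drug_dict["rp_treatment"] = pd.to_numeric(drug_dict["rp_treatment"]).astype(int)
    drug_dict["atc_codes"] = drug_dict["atc_codes"].fillna("")
    drug_dict["class_tags"] = drug_dict["class_tags"].fillna("")
    event_dict = event_dict.drop_duplicates("pt_code")
    drug_dict = drug_dict.drop_duplicates("drug_id")

    # -- reports ----------------------------------------------------------
    reports = reports.dropna(subset=["report_id"])
    reports["report_year"] = pd.to_numeric(reports["report_year"], errors="coerce").astype("Int64")
    reports["serious"] = pd.to_numeric(reports["serious"], errors="coerce").fillna(0).astype(int)
    reports["age_years"] = pd.to_numeric(reports["age_years"], errors="coerce")
    bad_age = reports["age_years"].notna() & ~reports["age_years"].between(0, 120)
    for i in reports.index[bad_age]:
        log.append(f"reports line {i + 2}: age out of [0,120], set missing")
    reports.loc[bad_age, "age_years"] = np.nan
    reports["sex"] = reports["sex"].where(reports["sex"].isin(SEX_LEVELS), "unknown")
    reports["reporter_type"] = reports["reporter_type"].where(
        reports["reporter_type"].isin(REPORTER_TYPES), "unknown"
    )
    dup = reports["report_id"].duplicated(keep="first")
    for i in reports.index[dup]:
        log.append(f"reports line {i + 2}: duplicate report_id, skipped")
    reports = reports[~dup]

    known_reports = set(reports["report_id"])
    known_drugs = set(drug_dict["drug_id"])
    known_pts = set(event_dict["pt_code"])

    # -- link tables ------------------------------------------------------
    for col in ("start_year", "start_month", "start_day"):
        drugs[col] = pd.to_numeric(drugs[col], errors="coerce")
    bad = (
        ~drugs["report_id"].isin(known_reports)
        | ~drugs["drug_id"].isin(known_drugs)
        | ~drugs["role"].isin(DRUG_ROLES)
    )
    for i in drugs.index[bad]:
        log.append(f"report_drugs line {i + 2}: unresolved key or bad role, skipped")
    drugs = drugs[~bad]

    for col in ("onset_year", "onset_month", "onset_day"):
        events[col] = pd.to_numeric(events[col], errors="coerce")
    bad = ~events["report_id"].isin(known_reports) | ~events["pt_code"].isin(known_pts)
    for i in events.index[bad]:
        log.append(f"report_events line {i + 2}: unresolved key, skipped")
    events = events[~bad]

    # reports must carry >=1 drug and >=1 event
    has_drug = reports["report_id"].isin(set(drugs["report_id"]))
    has_event = reports["report_id"].isin(set(events["report_id"]))
    orphan = ~(has_drug & has_event)
    for rid in reports.loc[orphan, "report_id"]:
        log.append(f"report {rid}: no valid drug or event rows, dropped")
    reports = reports[~orphan]
    keep = set(reports["report_id"])
    drugs = drugs[drugs["report_id"].isin(keep)]
    events = events[events["report_id"].isin(keep)]

    if log:
        logger.warning("read_database: %d rows skipped or amended during validation", len(log))
    if len(reports) == 0:
        raise ValueError("zero valid reports after validation")

    return IcsrDatabase(
        reports=reports.reset_index(drop=True),
        report_drugs=drugs.reset_index(drop=True),
        report_events=events.reset_index(drop=True),
        drug_dictionary=drug_dict.reset_index(drop=True),
        event_dictionary=event_dict.reset_index(drop=True),
        load_log=log,
    )


def read_database_dir(directory) -> IcsrDatabase:
    d = Path(directory)
    return read_database(
        d / "reports.tsv",
        d / "report_drugs.tsv",
        d / "report_events.tsv",
        d / "drug_dictionary.tsv",
        d / "event_dictionary.tsv",
    )


def _fmt_int(series: pd.Series) -> pd.Series:
    return series.map(lambda v: "" if pd.isna(v) else str(int(v)))


def write_database(db: IcsrDatabase, directory) -> dict:
    """Write the five TSVs; numeric formatting is fixed so identical
    databases serialise to identical bytes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    reports = db.reports.copy()
    reports["report_year"] = _fmt_int(reports["report_year"])
    reports["serious"] = reports["serious"].astype(int)
    reports["age_years"] = reports["age_years"].map(
        lambda v: "" if pd.isna(v) else f"{v:.1f}"
    )
    paths = {}
    specs = [
        ("reports.tsv", reports, REPORT_COLUMNS, []),
        ("report_drugs.tsv", db.report_drugs, DRUG_LINK_COLUMNS,
         ["start_year", "start_month", "start_day"]),
        ("report_events.tsv", db.report_events, EVENT_LINK_COLUMNS,
         ["onset_year", "onset_month", "onset_day"]),
        ("drug_dictionary.tsv", db.drug_dictionary, DRUG_DICT_COLUMNS, []),
        ("event_dictionary.tsv", db.event_dictionary, EVENT_DICT_COLUMNS, []),
    ]
    for name, frame, cols, int_cols in specs:
        out = frame.copy()
        for c in int_cols:
            out[c] = _fmt_int(out[c])
        path = d / name
        out[cols].to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# case selection and exclusion

def select_cases(db: IcsrDatabase, pt_set) -> set:
    """Report ids carrying >=1 event whose PT is in ``pt_set``.

    Unknown PT codes are fatal: a typo must not silently produce an empty
    case series.
    """
    pt_set = set(pt_set)
    if not pt_set:
        raise ValueError("pt_set is empty")
    unknown = pt_set - set(db.event_dictionary["pt_code"])
    if unknown:
        raise KeyError(f"unknown PT codes in case definition: {sorted(unknown)}")
    mask = db.report_events["pt_code"].isin(pt_set)
    return set(db.report_events.loc[mask, "report_id"])


def rp_treatment_drug_ids(db: IcsrDatabase, atc_prefixes=None) -> set:
    """Drugs matching the treatment-exclusion rule.

    With ``atc_prefixes=None`` the dictionary's ``rp_treatment`` flag is
    used; otherwise drugs with any ATC code starting with any given prefix
    match.  An empty prefix list matches nothing.
    """
    dd = db.drug_dictionary
    if atc_prefixes is None:
        return set(dd.loc[dd["rp_treatment"] == 1, "drug_id"])
    prefixes = tuple(atc_prefixes)
    if not prefixes:
        return set()

    def matches(codes: str) -> bool:
        return any(c.startswith(prefixes) for c in str(codes).split(";") if c)

    return set(dd.loc[dd["atc_codes"].map(matches), "drug_id"])


def apply_exclusion(db: IcsrDatabase, case_ids, atc_prefixes=None) -> set:
    """Drop every case report carrying >=1 treatment-class drug in any role.

    The rule applies regardless of the drug's role: a concomitant
    treatment drug signals pre-existing disease just as a suspect one does.
    Counts matching the selection flow (selected / excluded / included) are
    logged.
    """
    case_ids = set(case_ids)
    bad_drugs = rp_treatment_drug_ids(db, atc_prefixes)
    links = db.report_drugs
    hit = links["drug_id"].isin(bad_drugs) & links["report_id"].isin(case_ids)
    excluded = set(links.loc[hit, "report_id"])
    retained = case_ids - excluded
    logger.info(
        "case flow: selected=%d excluded=%d included=%d",
        len(case_ids), len(excluded), len(retained),
    )
    return retained


# ---------------------------------------------------------------------------
# indicator matrices (shared by disproportionality and network stages)

def drug_indicator(db: IcsrDatabase, roles=ANALYSIS_ROLES):
    """Sparse boolean reports x drugs matrix plus its axis labels.

    Only link rows with a role in ``roles`` count; by default suspect and
    interacting entries, the roles that enter drug marginals.
    """
    links = db.report_drugs
    if roles is not None:
        links = links[links["role"].isin(roles)]
    rid_index = pd.Index(db.reports["report_id"])
    did_index = pd.Index(db.drug_dictionary["drug_id"])
    rows = rid_index.get_indexer(links["report_id"])
    cols = did_index.get_indexer(links["drug_id"])
    data = np.ones(len(links), dtype=np.int8)
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(rid_index), len(did_index))
    )
    mat.data[:] = 1  # collapse duplicate links to binary
    mat.sum_duplicates()
    mat.data = np.minimum(mat.data, 1).astype(np.int8)
    return mat, rid_index, did_index


def event_indicator(db: IcsrDatabase):
    """Sparse boolean reports x PTs matrix plus its axis labels."""
    links = db.report_events
    rid_index = pd.Index(db.reports["report_id"])
    pt_index = pd.Index(db.event_dictionary["pt_code"])
    rows = rid_index.get_indexer(links["report_id"])
    cols = pt_index.get_indexer(links["pt_code"])
    mat = sparse.csr_matrix(
        (np.ones(len(links), dtype=np.int8), (rows, cols)),
        shape=(len(rid_index), len(pt_index)),
    )
    mat.sum_duplicates()
    mat.data = np.minimum(mat.data, 1).astype(np.int8)
    return mat, rid_index, pt_index


def age_band(age_years, edges=DEFAULT_AGE_BAND_EDGES) -> pd.Series:
    """Map ages in years to band labels; missing age -> ``"unknown"``."""
    age = pd.to_numeric(pd.Series(age_years), errors="coerce")
    bins = [-np.inf, *edges, np.inf]
    bands = pd.cut(age, bins=bins, right=False, labels=AGE_BAND_LABELS[:-1])
    out = bands.astype(object)
    out[age.isna()] = "unknown"
    return out


# ---------------------------------------------------------------------------
# case summaries

@dataclass
class CaseSummary:
    """Descriptive features of the case series supporting one drug."""

    drug_id: str
    n: int
    age_mean: float | None = None
    age_sd: float | None = None
    pct_female: float | None = None
    tto_n: int = 0
    tto_median: float | None = None
    tto_q1: float | None = None
    tto_q3: float | None = None
    pct_serious: float | None = None
    pct_hcp: float | None = None
    top_coreported: list = field(default_factory=list)


def _partial_date_from_row(y, m, d) -> PartialDate | None:
    if pd.isna(y):
        return None
    return PartialDate(
        int(y),
        None if pd.isna(m) else int(m),
        None if pd.isna(d) else int(d),
    )


def summarize_cases(
    db: IcsrDatabase,
    case_ids,
    drug_id: str,
    pt_set=None,
    top_k: int = 5,
) -> CaseSummary:
    """Summarise the cases in which ``drug_id`` appears as suspect or
    interacting: demographics, seriousness, reporter mix, time to onset
    (drug start to case-event onset, after date completion), and the most
    frequently co-reported drugs.

    ``pt_set`` restricts which event onsets anchor the TTO; with ``None``
    the earliest event onset in the report is used.
    """
    case_ids = set(case_ids)
    links = db.report_drugs
    drug_rows = links[
        (links["drug_id"] == drug_id)
        & links["role"].isin(ANALYSIS_ROLES)
        & links["report_id"].isin(case_ids)
    ]
    hit_ids = set(drug_rows["report_id"])
    if not hit_ids:
        return CaseSummary(drug_id=drug_id, n=0)

    rep = db.reports[db.reports["report_id"].isin(hit_ids)]
    age = rep["age_years"].dropna()
    summary = CaseSummary(
        drug_id=drug_id,
        n=len(rep),
        age_mean=float(age.mean()) if len(age) else None,
        age_sd=float(age.std(ddof=1)) if len(age) > 1 else None,
        pct_female=float(100.0 * (rep["sex"] == "F").mean()),
        pct_serious=float(100.0 * (rep["serious"] == 1).mean()),
        pct_hcp=float(100.0 * (rep["reporter_type"] == "health_professional").mean()),
    )

    # time to onset: this drug's start vs the case-defining event onset
    ev = db.report_events[db.report_events["report_id"].isin(hit_ids)]
    if pt_set is not None:
        ev = ev[ev["pt_code"].isin(set(pt_set))]
    onset_dt = impute_ymd_arrays(ev["onset_year"], ev["onset_month"], ev["onset_day"])
    ev = ev.assign(_onset=onset_dt.values)
    first_onset = ev.dropna(subset=["_onset"]).groupby("report_id")["_onset"].min()

    ttos = []
    start_rows = drug_rows.drop_duplicates("report_id").set_index("report_id")
    for rid, row in start_rows.iterrows():
        if rid not in first_onset.index:
            continue
        start = _partial_date_from_row(row["start_year"], row["start_month"], row["start_day"])
        onset_ts = first_onset.loc[rid]
        onset = PartialDate(onset_ts.year, onset_ts.month, onset_ts.day)
        tto = compute_tto(start, onset)
        if tto is not None:
            ttos.append(tto)
    if ttos:
        arr = np.asarray(ttos, dtype=float)
        summary.tto_n = len(arr)
        summary.tto_median = float(np.median(arr))
        summary.tto_q1 = float(np.percentile(arr, 25))
        summary.tto_q3 = float(np.percentile(arr, 75))

    co = links[links["report_id"].isin(hit_ids) & (links["drug_id"] != drug_id)]
    counts = co.drop_duplicates(["report_id", "drug_id"])["drug_id"].value_counts()
    summary.top_coreported = [(d, int(c)) for d, c in counts.head(top_k).items()]
    return summary
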