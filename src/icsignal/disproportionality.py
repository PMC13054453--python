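"""Bayesian information-component (IC) disproportionality.

The IC compares the observed number of reports ``O`` mentioning both a drug
and an event against the count ``E = n_drug * n_event / N`` expected under
independent reporting, on a log2 scale with shrinkage::

    IC = log2((O + 0.5) / (E + 0.5))

A drug-event pair is a signal of disproportionate reporting (SDR) when the
lower bound of the 95% credibility interval of the IC exceeds 0.  The
credibility interval comes from the gamma posterior of the shrunk
observed-to-expected ratio (shape ``O + 0.5``, rate ``E + 0.5``), whose
mean reproduces the IC point value; a closed-form approximation
``IC - 3.3 (O+0.5)^-1/2 - 2 (O+0.5)^-3/2`` is kept as a cross-check.

Five analyses are provided: the primary whole-database comparison and four
sensitivity variants — health-professional-reported cases only, an
ATC-level-3 restricted background (drugs sharing a pharmacological
subgroup), Mantel-Haenszel stratification by sex and age band, and a
broadened case definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import store
from .store import IcsrDatabase, apply_exclusion, select_cases
from .vocab import BROAD_PT_SET, DEFAULT_AGE_BAND_EDGES, NARROW_PT_SET

logger = logging.getLogger(__name__)

__all__ = [
    "ANALYSES",
    "ContingencyTable",
    "SignalResult",
    "AnalysisOptions",
    "ic_point",
    "ic_lower_bound",
    "mh_expected",
    "build_table",
    "run_analysis",
    "screen_all_pairs",
]

ANALYSES = ("primary", "hcp_only", "atc3_background", "mh_stratified", "broad_definition")
SENSITIVITY_ANALYSES = ANALYSES[1:]


@dataclass(frozen=True)
class ContingencyTable:
    """Observed count and marginals of one drug-event 2x2 table."""

    O: int
    n_drug: int
    n_event: int
    N: int
    stratum_label: str | None = None

    def __post_init__(self):
        if not (0 <= self.O <= min(self.n_drug, self.n_event) <= self.N):
            raise ValueError(f"inconsistent contingency counts: {self}")

    @property
    def expected(self) -> float:
        return self.n_drug * self.n_event / self.N


@dataclass(frozen=True)
class SignalResult:
    drug_id: str
    analysis_id: str
    O: int
    E: float
    IC: float
    IC_LB: float
    significant: bool
    evaluable: bool = True


@dataclass
class AnalysisOptions:
    """Configuration shared by all five analyses."""

    rp_pt_codes: tuple = NARROW_PT_SET
    broad_pt_codes: tuple = BROAD_PT_SET
    exclusion_atc_prefixes: tuple | None = None  # None -> dictionary flag
    age_band_edges: tuple = DEFAULT_AGE_BAND_EDGES
    min_obs: int = 0
    level: float = 0.95
    lb_method: str = "exact_gamma"


# ---------------------------------------------------------------------------
# the statistic

def ic_point(O, E):
    """IC point estimate in bits; accepts scalars or arrays."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    out = np.log2((O + 0.5) / (E + 0.5))
    return float(out) if out.ndim == 0 else out


def ic_lower_bound(O, E, level: float = 0.95, method: str = "exact_gamma"):
    """Lower bound of the central ``level`` credibility interval of the IC.

    ``exact_gamma`` takes the (1-level)/2 quantile of the gamma posterior
    of the observed-to-expected ratio (shape ``O+0.5``, rate ``E+0.5``).
    ``approximate`` uses the closed-form series in ``O`` around the point
    estimate; the two agree within 0.1 bits for O >= 10.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if method == "exact_gamma":
        alpha = (1.0 - level) / 2.0
        q = stats.gamma.ppf(alpha, a=O + 0.5, scale=1.0 / (E + 0.5))
        out = np.log2(q)
    elif method == "approximate":
        shrunk = O + 0.5
        out = ic_point(O, E) - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(out) if np.ndim(out) == 0 else out


def mh_expected(tables) -> tuple:
    """Mantel-Haenszel pooled observed and expected counts over strata.

    ``E_mh = sum_s n_drug,s * n_event,s / N_s`` with empty strata dropped
    (warned).  With a single stratum this reduces exactly to the crude
    expected count.
    """
    tables = list(tables)
    kept = [t for t in tables if t.N > 0]
    if len(kept) < len(tables):
        logger.warning("mh_expected: dropped %d empty strata", len(tables) - len(kept))
    if not kept:
        raise ValueError("no non-empty strata")
    o_total = int(sum(t.O for t in kept))
    e_mh = float(sum(t.n_drug * t.n_event / t.N for t in kept))
    return o_total, e_mh


def build_table(db: IcsrDatabase, drug_id: str, case_ids, background_ids) -> ContingencyTable:
    """Counts for one drug against one case series within a background.

    Drug marginals count suspect/interacting entries only.
    """
    case_ids = set(case_ids)
    background_ids = set(background_ids)
    if not background_ids:
        raise ValueError("empty background")
    if not case_ids <= background_ids:
        raise ValueError("case_ids must be a subset of background_ids")
    links = db.report_drugs
    drug_reports = set(
        links.loc[
            (links["drug_id"] == drug_id) & links["role"].isin(store.ANALYSIS_ROLES),
            "report_id",
        ]
    ) & background_ids
    return ContingencyTable(
        O=len(drug_reports & case_ids),
        n_drug=len(drug_reports),
        n_event=len(case_ids),
        N=len(background_ids),
    )


# ---------------------------------------------------------------------------
# vectorised whole-database analyses

def _results_frame(drug_index, analysis_id, O, E, evaluable, opts) -> pd.DataFrame:
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    ic = ic_point(O, E)
    lb = ic_lower_bound(O, E, level=opts.level, method=opts.lb_method)
    out = pd.DataFrame({
        "drug_id": np.asarray(drug_index),
        "analysis_id": analysis_id,
        "O": O.astype(int),
        "E": E,
        "IC": ic,
        "IC_LB": lb,
        "evaluable": np.asarray(evaluable, dtype=bool),
    })
    out["significant"] = (out["IC_LB"] > 0) & out["evaluable"] & (out["O"] >= opts.min_obs)
    return out


def _included_universe(db, pt_codes, opts):
    """Case series after exclusion, and the analysis universe.

    Reports excluded for carrying a treatment-class drug leave the
    analysis entirely; the comparator is every remaining report.
    """
    selected = select_cases(db, pt_codes)
    included = apply_exclusion(db, selected, opts.exclusion_atc_prefixes)
    dropped = selected - included
    universe = set(db.report_ids) - dropped
    return included, universe


def run_analysis(db: IcsrDatabase, analysis_id: str, options: AnalysisOptions | None = None) -> pd.DataFrame:
    """One row per drug appearing as suspect/interacting in >=1 included
    case: O, E, IC, IC_LB, significance, evaluability.

    Drugs that cannot be evaluated under an analysis (for example no ATC
    code, or no case in the restricted background) are flagged
    ``evaluable=False`` rather than dropped.
    """
    opts = options or AnalysisOptions()
    if analysis_id not in ANALYSES:
        raise ValueError(f"unknown analysis: {analysis_id!r}")

    pt_codes = opts.broad_pt_codes if analysis_id == "broad_definition" else opts.rp_pt_codes
    included, universe = _included_universe(db, pt_codes, opts)

    X, rid_index, did_index = store.drug_indicator(db)
    in_universe = rid_index.isin(universe)
    is_case = rid_index.isin(included) & in_universe

    if analysis_id == "hcp_only":
        hcp = (db.reports["reporter_type"] == "health_professional").to_numpy()
        in_universe = in_universe & hcp
        is_case = is_case & hcp

    case_drug_counts = np.asarray(X[is_case].sum(axis=0)).ravel()
    drug_mask = case_drug_counts > 0
    drugs = did_index[drug_mask]

    if analysis_id in ("primary", "hcp_only", "broad_definition"):
        O = case_drug_counts[drug_mask]
        n_drug = np.asarray(X[in_universe].sum(axis=0)).ravel()[drug_mask]
        N = int(in_universe.sum())
        n_event = int(is_case.sum())
        E = n_drug * n_event / N
        return _results_frame(drugs, analysis_id, O, E, np.ones(len(drugs), bool), opts)

    if analysis_id == "atc3_background":
        return _run_atc3(db, X, rid_index, did_index, in_universe, is_case, drug_mask, opts)

    # mh_stratified
    sex = db.reports["sex"].to_numpy()
    bands = store.age_band(db.reports["age_years"], opts.age_band_edges).to_numpy()
    strata = pd.Series(sex).astype(str) + "|" + pd.Series(bands).astype(str)
    O = case_drug_counts[drug_mask]
    E = np.zeros(drug_mask.sum())
    for _, idx in strata.groupby(strata).groups.items():
        s_mask = np.zeros(len(rid_index), dtype=bool)
        s_mask[idx] = True
        s_mask &= in_universe
        n_s = int(s_mask.sum())
        if n_s == 0:
            continue
        n_event_s = int((is_case & s_mask).sum())
        n_drug_s = np.asarray(X[s_mask].sum(axis=0)).ravel()[drug_mask]
        E += n_drug_s * n_event_s / n_s
    return _results_frame(drugs, analysis_id, O, E, np.ones(len(drugs), bool), opts)


def _atc3_codes(atc_codes: str) -> set:
    return {c[:4] for c in str(atc_codes).split(";") if len(c) >= 4}


def _run_atc3(db, X, rid_index, did_index, in_universe, is_case, drug_mask, opts):
    """Background restricted, per drug, to reports containing >=1 drug
    sharing any ATC level-3 subgroup with it (the index drug's own reports
    included)."""
    dd = db.drug_dictionary.set_index("drug_id")
    drug_atc3 = {d: _atc3_codes(dd.loc[d, "atc_codes"]) for d in did_index}

    # reports x atc3 membership via the drug indicator
    all_atc3 = sorted(set().union(*drug_atc3.values()) - set())
    atc3_pos = {a: i for i, a in enumerate(all_atc3)}
    A = np.zeros((len(did_index), len(all_atc3)), dtype=np.int8)
    for j, d in enumerate(did_index):
        for a in drug_atc3[d]:
            A[j, atc3_pos[a]] = 1
    report_atc3 = (X @ A) > 0  # dense n_reports x n_atc3

    rows = []
    for j in np.flatnonzero(drug_mask):
        d = did_index[j]
        codes = drug_atc3[d]
        if not codes:
            rows.append((d, 0, np.nan, False))
            continue
        cols = [atc3_pos[a] for a in codes]
        bg = np.asarray(report_atc3[:, cols].any(axis=1)).ravel() & in_universe
        case_bg = is_case & bg
        n_event = int(case_bg.sum())
        N = int(bg.sum())
        drug_col = np.asarray(X[:, j].todense()).ravel() > 0
        O = int((drug_col & case_bg).sum())
        n_drug = int((drug_col & bg).sum())
        if N == 0 or n_event == 0:
            rows.append((d, O, np.nan, False))
            continue
        rows.append((d, O, n_drug * n_event / N, True))

    drugs = [r[0] for r in rows]
    O = np.array([r[1] for r in rows], dtype=float)
    E = np.array([r[2] for r in rows], dtype=float)
    evaluable = np.array([r[3] for r in rows], dtype=bool)
    E_safe = np.where(np.isnan(E), 0.0, E)
    out = _results_frame(drugs, "atc3_background", O, E_safe, evaluable, opts)
    out.loc[~evaluable, ["E", "IC", "IC_LB"]] = np.nan
    out.loc[~evaluable, "significant"] = False
    return out


def screen_all_pairs(db: IcsrDatabase, min_obs: int = 0, options: AnalysisOptions | None = None) -> pd.DataFrame:
    """Whole-database drug x event disproportionality screen.

    Every PT is treated in turn as the case definition over the full
    database (no exclusion rule); used for calibration checks and for
    exploratory screening.
    """
    opts = options or AnalysisOptions()
    X, rid_index, did_index = store.drug_indicator(db)
    Y, _, pt_index = store.event_indicator(db)
    N = len(rid_index)
    O = np.asarray((X.T.astype(np.int64) @ Y.astype(np.int64)).todense(), dtype=float)
    n_drug = np.asarray(X.sum(axis=0)).ravel()
    n_event = np.asarray(Y.sum(axis=0)).ravel()
    E = np.outer(n_drug, n_event) / N

    mask = O >= min_obs
    di, pi = np.nonzero(mask)
    o = O[di, pi]
    e = E[di, pi]
    out = pd.DataFrame({
        "drug_id": did_index.to_numpy()[di],
        "pt_code": pt_index.to_numpy()[pi],
        "O": o.astype(int),
        "n_drug": n_drug[di].astype(int),
        "n_event": n_event[pi].astype(int),
        "N": N,
        "E": e,
        "IC": ic_point(o, e),
        "IC_LB": ic_lower_bound(o, e, level=opts.level, method=opts.lb_method),
    })
    out["significant"] = out["IC_LB"] > 0
    return out
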