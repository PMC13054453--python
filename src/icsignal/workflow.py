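"""Orchestration of primary and sensitivity analyses.

Joins the five per-drug analyses into one consistency record per drug,
attaches the descriptive case summary, and orders the table for expert
review.  A drug is *consistent* when it is significant in the primary
analysis and in every sensitivity analysis in which it is evaluable;
non-evaluable analyses (for example, no health-professional report for the
drug) are excluded from the requirement and flagged.  Plausibility
adjudication itself is expert work and is not automated here — at most a
user-supplied prior-awareness lookup is carried through.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .disproportionality import (
    ANALYSES,
    SENSITIVITY_ANALYSES,
    AnalysisOptions,
    run_analysis,
)
from .store import IcsrDatabase, apply_exclusion, select_cases, summarize_cases

logger = logging.getLogger(__name__)

__all__ = ["run_all", "rank_signals", "dotplot_table"]

_SUMMARY_FIELDS = (
    "n", "age_mean", "age_sd", "pct_female", "tto_n", "tto_median",
    "tto_q1", "tto_q3", "pct_serious", "pct_hcp",
)


def run_all(
    db: IcsrDatabase,
    options: AnalysisOptions | None = None,
    analyses=ANALYSES,
    with_summaries: bool = True,
) -> pd.DataFrame:
    """One consistency record per drug evaluated in the primary analysis.

    Columns: primary O/E/IC/IC_LB, per-analysis significance and
    evaluability, ``significant_in`` (semicolon-joined analysis ids),
    ``consistent_all``, and the case-summary fields.  Deterministic given
    the database.
    """
    opts = options or AnalysisOptions()
    analyses = list(analyses)
    if "primary" not in analyses:
        raise ValueError("the primary analysis is required")

    frames = {a: run_analysis(db, a, opts) for a in analyses}
    primary = frames["primary"].set_index("drug_id")
    records = pd.DataFrame({
        "drug_id": primary.index,
        "O": primary["O"].to_numpy(),
        "E": primary["E"].to_numpy(),
        "IC": primary["IC"].to_numpy(),
        "IC_LB": primary["IC_LB"].to_numpy(),
        "significant_primary": primary["significant"].to_numpy(),
    }).set_index("drug_id")

    sens = [a for a in analyses if a != "primary"]
    for a in sens:
        f = frames[a].set_index("drug_id")
        sig = f["significant"].to_dict()
        can = f["evaluable"].to_dict()
        records[f"sig_{a}"] = [bool(sig.get(d, False)) for d in records.index]
        # absent from an analysis -> not evaluable there
        records[f"eval_{a}"] = [bool(can.get(d, False)) for d in records.index]

    sig_in = []
    consistent = []
    for drug, row in records.iterrows():
        hits = ["primary"] if row["significant_primary"] else []
        ok = bool(row["significant_primary"])
        for a in sens:
            if row[f"sig_{a}"]:
                hits.append(a)
            if row[f"eval_{a}"] and not row[f"sig_{a}"]:
                ok = False
        sig_in.append(";".join(hits))
        consistent.append(ok)
    records["significant_in"] = sig_in
    records["consistent_all"] = consistent

    if with_summaries:
        included = apply_exclusion(
            db, select_cases(db, opts.rp_pt_codes), opts.exclusion_atc_prefixes
        )
        summaries = {
            drug: summarize_cases(db, included, drug, pt_set=opts.rp_pt_codes)
            for drug in records.index
        }
        for fld in _SUMMARY_FIELDS:
            records[f"case_{fld}"] = [getattr(summaries[d], fld) for d in records.index]
        records["case_top_coreported"] = [
            ";".join(f"{d}:{c}" for d, c in summaries[drug].top_coreported)
            for drug in records.index
        ]
    return records.reset_index()


def rank_signals(
    records: pd.DataFrame,
    awareness_table: pd.DataFrame | None = None,
    drug_dictionary: pd.DataFrame | None = None,
    exclude_combinations: bool = True,
) -> pd.DataFrame:
    """Order records for review: consistent signals first, then by primary
    IC_LB descending (drug id breaks ties).

    ``awareness_table`` (columns ``drug_id``, ``already_described``)
    annotates prior awareness verbatim; unknown drug ids in it only warn.
    Fixed-dose combination products (dictionary ``class_tags`` containing
    ``combination``) are dropped from the ranking when a dictionary is
    supplied, since their signals are not attributable to one substance.
    """
    out = records.copy()
    if exclude_combinations and drug_dictionary is not None:
        tags = drug_dictionary.set_index("drug_id")["class_tags"].fillna("")
        combos = set(tags[tags.str.split(";").apply(lambda t: "combination" in t)].index)
        out = out[~out["drug_id"].isin(combos)]

    out["prior_awareness"] = "unknown"
    if awareness_table is not None and len(awareness_table):
        known = awareness_table.set_index("drug_id")["already_described"]
        stray = set(known.index) - set(out["drug_id"])
        if stray:
            logger.warning("awareness table names unknown drugs: %s", sorted(stray))
        flagged = known[known.astype(int) == 1].index
        out.loc[out["drug_id"].isin(flagged), "prior_awareness"] = "already_described"

    out = out.sort_values(
        ["consistent_all", "IC_LB", "drug_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out


def dotplot_table(db_frames: dict | None = None, *, records: pd.DataFrame | None = None,
                  db: IcsrDatabase | None = None,
                  options: AnalysisOptions | None = None) -> pd.DataFrame:
    """Drug x analysis IC_LB table for external plotting (the circular
    dot-plot layout): one row per drug, one column per analysis."""
    if db_frames is None:
        if db is None:
            raise ValueError("provide db_frames or db")
        opts = options or AnalysisOptions()
        db_frames = {a: run_analysis(db, a, opts) for a in ANALYSES}
    long = pd.concat(db_frames.values(), ignore_index=True)
    return long.pivot_table(index="drug_id", columns="analysis_id", values="IC_LB").reset_index()
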