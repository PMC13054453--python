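"""Aggregation of pharmacological targets across signal drugs.

Given a drug-to-target map (target id, name, and action such as agonist or
inhibitor), targets are ranked by the number of case reports supporting
the drugs that hit them.  A drug with several targets contributes its case
count to each — the multiplicity is deliberate and visible in the schema,
since the ranking asks "which mechanism is touched by the most reports",
not "how many distinct reports exist".
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_target_map", "aggregate_targets"]

TARGET_MAP_COLUMNS = ["drug_id", "target_id", "target_name", "action"]
ACTIONS = ("agonist", "antagonist", "inhibitor", "substrate", "other")


def read_target_map(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in TARGET_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"target map missing columns: {missing}")
    df = df[TARGET_MAP_COLUMNS].copy()
    df["action"] = df["action"].where(df["action"].isin(ACTIONS), "other")
    dup = df.duplicated(["drug_id", "target_id", "action"])
    if dup.any():
        logger.warning("target map: %d duplicate (drug, target, action) rows dropped", dup.sum())
    return df[~dup].reset_index(drop=True)


def aggregate_targets(signal_records: pd.DataFrame, target_map: pd.DataFrame) -> pd.DataFrame:
    """Rank (target, action) pairs by supporting case counts.

    ``signal_records`` needs ``drug_id`` and ``O`` (primary-analysis case
    count) columns; typically the caller passes the subset of records it
    considers signal-worthy.  Output columns: target_id, target_name,
    action, n_drugs (distinct contributing drugs), n_icsrs (sum of O over
    them), ordered by n_icsrs desc, n_drugs desc, target_id.  Drugs absent
    from the map are reported in ``result.attrs["unmapped_drugs"]``.
    """
    required = {"drug_id", "O"}
    if not required <= set(signal_records.columns):
        raise ValueError(f"signal_records must have columns {sorted(required)}")

    merged = signal_records[["drug_id", "O"]].merge(target_map, on="drug_id", how="left")
    unmapped = sorted(merged.loc[merged["target_id"].isna(), "drug_id"].unique())
    if unmapped:
        logger.warning("%d signal drugs have no target mapping: %s", len(unmapped), unmapped)
    mapped = merged.dropna(subset=["target_id"])

    if len(mapped) == 0:
        out = pd.DataFrame(columns=["target_id", "target_name", "action", "n_drugs", "n_icsrs"])
    else:
        out = (
            mapped.groupby(["target_id", "target_name", "action"], as_index=False)
            .agg(n_drugs=("drug_id", "nunique"), n_icsrs=("O", "sum"))
        )
        out["n_icsrs"] = out["n_icsrs"].astype(int)
        out = out.sort_values(
            ["n_icsrs", "n_drugs", "target_id"], ascending=[False, False, True]
        ).reset_index(drop=True)
    out.attrs["unmapped_drugs"] = unmapped
    return out
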