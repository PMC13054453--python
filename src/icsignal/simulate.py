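"""Synthetic spontaneous-report database generator with known ground truth.

The generator emulates the structure of a large pharmacovigilance database:
multi-drug multi-event reports with drug roles, partial dates, demographic
and reporter fields, a power-law drug/event frequency spectrum, and three
kinds of planted structure that the analysis stages must recover:

* **planted signals** — a drug multiplies the reporting probability of one
  event by a configured rate ratio (the disproportionality target);
* **confounders** — a drug and an event are both enriched in one stratum
  (for example, in women) while remaining conditionally independent within
  every stratum: the canonical scenario in which a crude analysis flags the
  pair and a stratified analysis must not;
* **symptom clusters** — a latent per-report switch makes a set of PTs
  co-occur in reports carrying a tagged drug class, giving the event
  networks something to find.

Event occurrence is per-PT Bernoulli given the report's drugs and stratum,
so planted rate ratios are exact in expectation and pairs without planted
structure are independent given the stratum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .store import IcsrDatabase

__all__ = [
    "PlantedSignal",
    "Confounder",
    "SymptomCluster",
    "GeneratorConfig",
    "GroundTruth",
    "generate_database",
    "plant_confounded_scenario",
    "demo_config",
    "generate_target_map",
]


@dataclass(frozen=True)
class PlantedSignal:
    """Multiply ``pt_code``'s reporting probability by ``rate_ratio`` in
    reports carrying ``drug_id`` as suspect or interacting.

    When ``presence_prob`` is set the drug is included in reports by an
    independent Bernoulli channel (with that exact probability) instead of
    the weighted pool, so the pair's expected observed count is
    ``n_reports * presence_prob * base_rate * rate_ratio`` in closed form.
    """

    drug_id: str
    pt_code: str
    rate_ratio: float
    presence_prob: float | None = None

    def __post_init__(self):
        if self.rate_ratio < 1:
            raise ValueError("rate_ratio must be >= 1")


@dataclass(frozen=True)
class Confounder:
    """Joint stratum-level enrichment of a drug and an event.

    Within every stratum the drug and event are independent; across strata
    both are ``*_multiplier`` times more frequent when the stratum variable
    equals ``stratum_value``.  The drug is included by an independent
    Bernoulli channel with base probability ``drug_base_prob``.
    """

    stratum_var: str  # "sex" or "age_band"
    stratum_value: str
    drug_id: str
    pt_code: str
    drug_multiplier: float = 3.0
    event_multiplier: float = 3.0
    drug_base_prob: float = 0.12
    event_base_rate: float = 0.05


@dataclass(frozen=True)
class SymptomCluster:
    """Latent co-occurrence cluster among ``pt_codes`` in reports carrying
    a drug tagged ``class_tag``: with probability ``prob_on`` the cluster
    switches on and each member PT additionally occurs with probability
    ``p_within`` (OR-combined with its baseline)."""

    class_tag: str
    pt_codes: tuple
    prob_on: float = 0.3
    p_within: float = 0.35


_FILLER_ATC3 = ("J01C", "A02B", "M01A", "R03A", "N05A", "A10B", "R06A", "L04A", "D07A", "S01E")
_CLASS_ATC3 = (
    ("beta_blocker", "C07A"),
    ("antimigraine", "N02C"),
    ("amphetamine_like", "N06B"),
    ("tki", "L01E"),
)
_RP_TREATMENT_ATCS = ("C08CA05", "G04BE03", "C09AA02", "C02CA04", "C09CA01", "C02KX01", "B01AC09")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic database.

    Demographic defaults follow the reported profile of Raynaud case
    series (mean age ~47, ~19 SD, ~70% female among cases is induced by
    the confounding scenarios when requested; the base population is ~60%
    female, ~59% health-professional reported).
    """

    n_reports: int = 20_000
    n_drugs: int = 80
    n_events: int = 60
    seed: int = 0

    # frequency spectra
    drug_weight_exponent: float = 0.8
    event_rate_max: float = 0.10
    event_rate_exponent: float = 0.5
    event_rate_min: float = 0.004
    event_rate_overrides: dict = field(default_factory=lambda: {
        vocab.RAYNAUDS_PT: 0.010,
        vocab.PERIPHERAL_ISCHAEMIA_PT: 0.004,
        vocab.CHILBLAINS_PT: 0.003,
    })

    # per-report sizes
    max_drugs: int = 5
    n_drugs_probs: tuple = (0.45, 0.25, 0.15, 0.10, 0.05)
    max_events: int = 10

    # drug roles for non-anchor pool drugs
    role_probs: tuple = (0.65, 0.10, 0.25)  # suspect, interacting, concomitant

    # demographics / report fields
    sex_probs: dict = field(default_factory=lambda: {"F": 0.60, "M": 0.37, "unknown": 0.03})
    age_mean: float = 47.4
    age_sd: float = 19.0
    p_age_missing: float = 0.08
    reporter_probs: dict = field(default_factory=lambda: {
        "health_professional": 0.59, "consumer": 0.35, "other": 0.03, "unknown": 0.03,
    })
    country_probs: dict = field(default_factory=lambda: {
        "US": 0.45, "FR": 0.11, "GB": 0.10, "DE": 0.08, "JP": 0.06, "other": 0.20,
    })
    year_range: tuple = (2005, 2024)
    p_serious: float = 0.35

    # partial-date behaviour
    p_date_missing: float = 0.15
    p_month_missing: float = 0.08  # given date present; implies day missing
    p_day_missing: float = 0.20    # given month present
    tto_scale_days: float = 45.0

    # planted structure
    planted_signals: tuple = ()
    confounders: tuple = ()
    clusters: tuple = ()

    n_rp_treatment_drugs: int = 5


@dataclass
class GroundTruth:
    """Ledger of everything planted plus realised bookkeeping counts."""

    seed: int
    n_reports: int
    planted_signals: list
    confounders: list
    clusters: list
    event_base_rates: dict
    stratum_counts: dict
    reporter_counts: dict
    sex_counts: dict
    drug_class_tags: dict

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_signals"] = [dataclasses.asdict(p) if dataclasses.is_dataclass(p) else p
                                for p in self.planted_signals]
        d["confounders"] = [dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c
                            for c in self.confounders]
        d["clusters"] = [dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c
                         for c in self.clusters]
        return d

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# dictionaries

def _build_drug_dictionary(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    n_regular = cfg.n_drugs - cfg.n_rp_treatment_drugs
    n_class = len(_CLASS_ATC3)
    per_class = max(1, min(6, n_regular // (2 * n_class)))
    for i in range(n_regular):
        drug_id = f"D{i + 1:04d}"
        if i < per_class * n_class:
            tag, atc3 = _CLASS_ATC3[i // per_class]
            atc = f"{atc3}A{(i % per_class) + 1:02d}"
        else:
            j = i - per_class * n_class
            atc3 = _FILLER_ATC3[j % len(_FILLER_ATC3)]
            tag = ""
            atc = f"{atc3}A{j // len(_FILLER_ATC3) + 1:02d}"
        rows.append((drug_id, f"drug_{i + 1:04d}", atc, 0, tag))
    for k in range(cfg.n_rp_treatment_drugs):
        i = n_regular + k
        atc = _RP_TREATMENT_ATCS[k % len(_RP_TREATMENT_ATCS)]
        rows.append((f"D{i + 1:04d}", f"drug_{i + 1:04d}", atc, 1, "rp_treatment"))
    return pd.DataFrame(rows, columns=["drug_id", "name", "atc_codes", "rp_treatment", "class_tags"])


def _build_event_dictionary(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = list(vocab.NAMED_PTS[: cfg.n_events])
    socs = ("SOC_GI", "SOC_NERVOUS", "SOC_SKIN", "SOC_CARDIAC", "SOC_GENERAL", "SOC_MUSC")
    for j in range(len(rows), cfg.n_events):
        k = j - len(vocab.NAMED_PTS)
        rows.append((
            f"PT{2_000_000 + k + 1}",
            f"pt_generic_{k + 1:03d}",
            f"HLT_G{k % 12:02d}",
            socs[k % len(socs)],
        ))
    return pd.DataFrame(rows, columns=["pt_code", "pt_name", "hlt", "soc"])


def _event_base_rates(cfg: GeneratorConfig, pt_codes: pd.Series) -> np.ndarray:
    ranks = np.arange(1, len(pt_codes) + 1, dtype=float)
    rates = np.clip(
        cfg.event_rate_max * ranks ** -cfg.event_rate_exponent,
        cfg.event_rate_min,
        cfg.event_rate_max,
    )
    # named PTs sit at the front; generic rates keep the power-law shape
    rate_map = dict(zip(pt_codes, rates))
    for pt, r in cfg.event_rate_overrides.items():
        if pt in rate_map:
            rate_map[pt] = r
    for conf in cfg.confounders:
        if conf.pt_code in rate_map:
            rate_map[conf.pt_code] = conf.event_base_rate
    return np.array([rate_map[pt] for pt in pt_codes])


# ---------------------------------------------------------------------------
# generation

def _choice(rng, n, probs: dict):
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return np.asarray(keys, dtype=object)[idx]


def generate_database(cfg: GeneratorConfig):
    """Generate one database and its ground-truth ledger.

    Deterministic given ``cfg.seed``: the same config serialises to
    byte-identical TSVs.  Raises ``ValueError`` naming the offending
    (drug, PT) or (stratum, PT) pair if multipliers push any per-report
    event probability above 1.
    """
    rng = np.random.default_rng(cfg.seed)
    drug_dict = _build_drug_dictionary(cfg)
    event_dict = _build_event_dictionary(cfg)
    n = cfg.n_reports
    drug_ids = drug_dict["drug_id"].to_numpy()
    pt_codes = event_dict["pt_code"].to_numpy()
    did_pos = {d: i for i, d in enumerate(drug_ids)}
    pt_pos = {p: i for i, p in enumerate(pt_codes)}

    for planted in cfg.planted_signals:
        if planted.drug_id not in did_pos or planted.pt_code not in pt_pos:
            raise ValueError(f"planted pair not in dictionaries: {planted}")
    for conf in cfg.confounders:
        if conf.drug_id not in did_pos or conf.pt_code not in pt_pos:
            raise ValueError(f"confounder pair not in dictionaries: {conf}")

    # --- report-level fields --------------------------------------------
    sex = _choice(rng, n, cfg.sex_probs)
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    age = np.clip(age, 0.0, 120.0).round(1)
    age_missing = rng.random(n) < cfg.p_age_missing
    reporter = _choice(rng, n, cfg.reporter_probs)
    country = _choice(rng, n, cfg.country_probs)
    year = rng.integers(cfg.year_range[0], cfg.year_range[1] + 1, size=n)
    serious = (rng.random(n) < cfg.p_serious).astype(int)

    from .store import age_band  # local import to avoid cycle at module load
    bands = age_band(pd.Series(np.where(age_missing, np.nan, age))).to_numpy()

    # --- drug membership -------------------------------------------------
    channel_drugs = {p.drug_id for p in cfg.planted_signals if p.presence_prob is not None}
    channel_drugs |= {c.drug_id for c in cfg.confounders}
    weights = (np.arange(1, len(drug_ids) + 1, dtype=float)) ** -cfg.drug_weight_exponent
    for d in channel_drugs:
        weights[did_pos[d]] = 0.0

    n_per_report = rng.choice(
        np.arange(1, cfg.max_drugs + 1), size=n, p=np.asarray(cfg.n_drugs_probs)
    )
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    scores = logw[None, :] + rng.gumbel(size=(n, len(drug_ids)))
    order = np.argsort(-scores, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(len(drug_ids))[None, :]
    member = ranks < n_per_report[:, None]

    # independent-channel drugs (planted with fixed prevalence, confounders)
    channel_presence = {}
    for planted in cfg.planted_signals:
        if planted.presence_prob is not None:
            channel_presence[planted.drug_id] = np.full(n, planted.presence_prob)
    for conf in cfg.confounders:
        stratum = sex if conf.stratum_var == "sex" else bands
        p = np.where(
            stratum == conf.stratum_value,
            conf.drug_base_prob * conf.drug_multiplier,
            conf.drug_base_prob,
        )
        if np.any(p > 1):
            raise ValueError(
                f"infeasible drug probability for ({conf.drug_id}, "
                f"{conf.stratum_var}={conf.stratum_value}): max {p.max():.3f} > 1"
            )
        channel_presence[conf.drug_id] = p
    for d, p in channel_presence.items():
        member[:, did_pos[d]] = rng.random(n) < p

    # roles: the best-scoring pool drug is the suspect anchor; channel
    # drugs are suspects; remaining pool drugs draw a role
    pool_scores = np.where(member, scores, -np.inf)
    for d in channel_drugs:
        pool_scores[:, did_pos[d]] = -np.inf
    anchor = np.argmax(pool_scores, axis=1)
    role_draw = rng.choice(3, size=member.shape, p=np.asarray(cfg.role_probs))
    roles = np.select(
        [role_draw == 0, role_draw == 1], ["suspect", "interacting"], "concomitant"
    ).astype(object)
    roles[rows[:, 0], anchor] = "suspect"
    for d in channel_drugs:
        roles[:, did_pos[d]] = "suspect"
    si_member = member & (roles != "concomitant")

    # --- event probabilities ---------------------------------------------
    base = _event_base_rates(cfg, event_dict["pt_code"])
    prob = np.broadcast_to(base, (n, len(pt_codes))).copy()

    for conf in cfg.confounders:
        stratum = sex if conf.stratum_var == "sex" else bands
        in_stratum = stratum == conf.stratum_value
        j = pt_pos[conf.pt_code]
        prob[in_stratum, j] *= conf.event_multiplier
        if prob[:, j].max() > 1:
            raise ValueError(
                f"infeasible event probability for ({conf.stratum_var}="
                f"{conf.stratum_value}, {conf.pt_code})"
            )
    for planted in cfg.planted_signals:
        i, j = did_pos[planted.drug_id], pt_pos[planted.pt_code]
        carrier = si_member[:, i]
        prob[carrier, j] *= planted.rate_ratio
        if prob[:, j].max() > 1:
            raise ValueError(
                f"infeasible event probability for planted pair "
                f"({planted.drug_id}, {planted.pt_code})"
            )

    cluster_draws = []
    for clus in cfg.clusters:
        tagged = drug_dict["class_tags"].fillna("").str.split(";").apply(
            lambda t, tag=clus.class_tag: tag in t
        ).to_numpy()
        carrier = si_member[:, tagged].any(axis=1)
        z = carrier & (rng.random(n) < clus.prob_on)
        cluster_draws.append(z)
        cols = [pt_pos[p] for p in clus.pt_codes if p in pt_pos]
        # OR-combination: baseline occurrence or latent-cluster occurrence
        prob[np.ix_(z, cols)] = 1.0 - (1.0 - prob[np.ix_(z, cols)]) * (1.0 - clus.p_within)

    # --- draw events; every report needs >=1, at most max_events ---------
    events = rng.random(prob.shape) < prob
    for _ in range(50):
        empty = ~events.any(axis=1)
        if not empty.any():
            break
        events[empty] = rng.random((empty.sum(), prob.shape[1])) < prob[empty]
    still_empty = ~events.any(axis=1)
    if still_empty.any():
        events[still_empty, np.argmax(prob[still_empty], axis=1)] = True
    counts = events.sum(axis=1)
    over = np.flatnonzero(counts > cfg.max_events)
    for i in over:
        on = np.flatnonzero(events[i])
        keep = rng.choice(on, size=cfg.max_events, replace=False)
        events[i] = False
        events[i, keep] = True

    # --- dates ------------------------------------------------------------
    year_start = np.asarray(
        [np.datetime64(f"{y}-01-01") for y in range(cfg.year_range[0], cfg.year_range[1] + 2)]
    )
    anchor_date = year_start[year - cfg.year_range[0]] + rng.integers(0, 365, size=n)

    r_idx, d_idx = np.nonzero(member)
    start_offset = rng.integers(-365, 1, size=len(r_idx))
    is_anchor = d_idx == anchor[r_idx]
    start_offset[is_anchor] = 0
    start_date = anchor_date[r_idx] + start_offset

    e_r, e_c = np.nonzero(events)
    onset_date = anchor_date[e_r] + rng.exponential(cfg.tto_scale_days, size=len(e_r)).astype(int)

    def partialize(dates: np.ndarray, n_rows: int):
        ts = pd.DatetimeIndex(dates)
        y = ts.year.to_numpy().astype(float)
        m = ts.month.to_numpy().astype(float)
        d = ts.day.to_numpy().astype(float)
        gone = rng.random(n_rows) < cfg.p_date_missing
        no_month = ~gone & (rng.random(n_rows) < cfg.p_month_missing)
        no_day = no_month | (~gone & (rng.random(n_rows) < cfg.p_day_missing))
        y[gone] = np.nan
        m[gone | no_month] = np.nan
        d[gone | no_day] = np.nan
        return y, m, d

    sy, sm, sd = partialize(start_date, len(r_idx))
    oy, om, od = partialize(onset_date, len(e_r))

    # --- assemble tables --------------------------------------------------
    report_ids = np.array([f"R{i + 1:07d}" for i in range(n)], dtype=object)
    reports = pd.DataFrame({
        "report_id": report_ids,
        "country": country,
        "report_year": year,
        "reporter_type": reporter,
        "serious": serious,
        "age_years": np.where(age_missing, np.nan, age),
        "sex": sex,
    })
    report_drugs = pd.DataFrame({
        "report_id": report_ids[r_idx],
        "drug_id": drug_ids[d_idx],
        "role": roles[r_idx, d_idx],
        "start_year": sy,
        "start_month": sm,
        "start_day": sd,
    })
    report_events = pd.DataFrame({
        "report_id": report_ids[e_r],
        "pt_code": pt_codes[e_c],
        "onset_year": oy,
        "onset_month": om,
        "onset_day": od,
    })

    db = IcsrDatabase(
        reports=reports,
        report_drugs=report_drugs,
        report_events=report_events,
        drug_dictionary=drug_dict,
        event_dictionary=event_dict,
    )

    strat_labels = pd.Series(sex).astype(str) + "|" + pd.Series(bands).astype(str)
    truth = GroundTruth(
        seed=cfg.seed,
        n_reports=n,
        planted_signals=list(cfg.planted_signals),
        confounders=list(cfg.confounders),
        clusters=list(cfg.clusters),
        event_base_rates={pt: float(r) for pt, r in zip(pt_codes, base)},
        stratum_counts=strat_labels.value_counts().to_dict(),
        reporter_counts=pd.Series(reporter).value_counts().to_dict(),
        sex_counts=pd.Series(sex).value_counts().to_dict(),
        drug_class_tags=dict(zip(drug_dict["drug_id"], drug_dict["class_tags"])),
    )
    return db, truth


def plant_confounded_scenario(
    cfg: GeneratorConfig,
    drug_id: str = "D0070",
    pt_code: str = "PT2000001",
    multiplier: float = 3.0,
) -> GeneratorConfig:
    """Add the canonical confounding scenario to a config: the drug and the
    event are each ``multiplier`` times more frequent in female reports but
    independent within every stratum, so the crude observed/expected ratio
    is inflated while the stratified one is null."""
    conf = Confounder(
        stratum_var="sex",
        stratum_value="F",
        drug_id=drug_id,
        pt_code=pt_code,
        drug_multiplier=multiplier,
        event_multiplier=multiplier,
    )
    return dataclasses.replace(cfg, confounders=(*cfg.confounders, conf))


def demo_config(seed: int = 0, n_reports: int = 20_000) -> GeneratorConfig:
    """A richer scenario for pipeline demonstrations: planted Raynaud
    signals of graded strength plus symptom clusters for two drug classes."""
    return GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        planted_signals=(
            PlantedSignal("D0013", vocab.RAYNAUDS_PT, 8.0),   # amphetamine-like
            PlantedSignal("D0001", vocab.RAYNAUDS_PT, 4.0),   # beta blocker
            PlantedSignal("D0007", vocab.RAYNAUDS_PT, 2.0),   # antimigraine
        ),
        # the index PT is itself a cluster member: the latent switch then
        # ties the other members to it, so they are disproportionately
        # co-reported with the index condition within the class
        clusters=(
            SymptomCluster("beta_blocker",
                           (vocab.RAYNAUDS_PT, "PT1000004", "PT1000005", "PT1000011"),
                           0.30, 0.35),
            SymptomCluster("amphetamine_like",
                           (vocab.RAYNAUDS_PT, "PT1000004", "PT1000006", "PT1000008"),
                           0.30, 0.35),
        ),
    )


_CLASS_TARGETS = {
    "beta_blocker": [
        ("T0001", "Beta-1 adrenergic receptor", "antagonist"),
        ("T0002", "Beta-2 adrenergic receptor", "antagonist"),
    ],
    "amphetamine_like": [
        ("T0003", "Sodium-dependent noradrenaline transporter", "inhibitor"),
        ("T0004", "Sodium-dependent dopamine transporter", "inhibitor"),
    ],
    "antimigraine": [
        ("T0005", "5-hydroxytryptamine receptor 1B", "agonist"),
        ("T0006", "5-hydroxytryptamine receptor 1D", "agonist"),
    ],
    "tki": [
        ("T0007", "Tyrosine-protein kinase ABL1", "inhibitor"),
    ],
}


def generate_target_map(drug_dictionary: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Synthetic drug-to-target map: class-tagged drugs share their class
    targets; other drugs draw one or two generic targets."""
    rng = np.random.default_rng(seed)
    generic = [(f"T{100 + k}", f"target_generic_{k:02d}", "other") for k in range(12)]
    rows = []
    for _, drug in drug_dictionary.iterrows():
        tags = [t for t in str(drug["class_tags"]).split(";") if t]
        emitted = False
        for tag in tags:
            for tid, tname, action in _CLASS_TARGETS.get(tag, []):
                rows.append((drug["drug_id"], tid, tname, action))
                emitted = True
        if not emitted and drug["rp_treatment"] != 1:
            for k in rng.choice(len(generic), size=rng.integers(1, 3), replace=False):
                tid, tname, action = generic[k]
                rows.append((drug["drug_id"], tid, tname, action))
    return pd.DataFrame(rows, columns=["drug_id", "target_id", "target_name", "action"])
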