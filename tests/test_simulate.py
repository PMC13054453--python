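import dataclasses

import numpy as np
import pandas as pd
import pytest

from icsignal import vocab
from icsignal.disproportionality import screen_all_pairs
from icsignal.simulate import (
    Confounder,
    GeneratorConfig,
    PlantedSignal,
    generate_database,
    generate_target_map,
    plant_confounded_scenario,
)
from icsignal.store import write_database


def _pair_oe(db, drug_id, pt_code):
    sc = screen_all_pairs(db)
    row = sc[(sc.drug_id == drug_id) & (sc.pt_code == pt_code)].iloc[0]
    return row.O, row.E


class TestDeterminism:
    def test_same_seed_gives_identical_tsv_bytes(self, tmp_path):
        cfg = GeneratorConfig(n_reports=2000, seed=42)
        for sub in ("a", "b"):
            db, _ = generate_database(cfg)
            write_database(db, tmp_path / sub)
        for name in ("reports.tsv", "report_drugs.tsv", "report_events.tsv",
                     "drug_dictionary.tsv", "event_dictionary.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        db1, _ = generate_database(GeneratorConfig(n_reports=500, seed=1))
        db2, _ = generate_database(GeneratorConfig(n_reports=500, seed=2))
        assert not db1.report_events.equals(db2.report_events)


class TestLedger:
    def test_ledger_counts_match_generated_data_exactly(self, null_db):
        db, truth = null_db
        assert sum(truth.reporter_counts.values()) == db.n_reports
        assert truth.reporter_counts == db.reports["reporter_type"].value_counts().to_dict()
        assert truth.sex_counts == db.reports["sex"].value_counts().to_dict()
        assert sum(truth.stratum_counts.values()) == db.n_reports

    def test_report_structure_bounds(self, null_db):
        db, _ = null_db
        per_report_drugs = db.report_drugs.groupby("report_id").size()
        per_report_events = db.report_events.groupby("report_id").size()
        assert per_report_drugs.between(1, 6).all()  # pool drugs + <=1 channel
        assert per_report_events.between(1, 10).all()
        assert set(per_report_drugs.index) == set(db.reports["report_id"])
        assert set(per_report_events.index) == set(db.reports["report_id"])


class TestNullIndependence:
    def test_no_planted_structure_gives_unit_rate_ratios(self, null_db):
        db, _ = null_db
        sc = screen_all_pairs(db)
        # condition on the expected count, not the observed one: selecting
        # on O would pick out upward fluctuations by construction
        sc = sc[sc.E >= 10]
        ratios = (sc.O / sc.E).to_numpy()
        assert len(ratios) > 200
        assert abs(np.mean(ratios) - 1.0) < 0.03
        assert np.median(ratios) == pytest.approx(1.0, abs=0.05)


class TestPlantedSignals:
    def test_planted_rate_ratio_recovered(self):
        cfg = GeneratorConfig(
            n_reports=50_000, seed=7,
            planted_signals=(PlantedSignal("D0013", vocab.RAYNAUDS_PT, 8.0),),
        )
        db, _ = generate_database(cfg)
        O, E = _pair_oe(db, "D0013", vocab.RAYNAUDS_PT)
        assert O / E >= 4.0

    def test_recovery_improves_with_sample_size(self):
        """Consistency: empirical O/E approaches the planted ratio."""
        errs = []
        for n in (5_000, 50_000):
            cfg = GeneratorConfig(
                n_reports=n, seed=13,
                planted_signals=(PlantedSignal(
                    "D0020", vocab.RAYNAUDS_PT, 4.0, presence_prob=0.05),),
            )
            db, _ = generate_database(cfg)
            O, E = _pair_oe(db, "D0020", vocab.RAYNAUDS_PT)
            errs.append(abs(O / E - 4.0))
        assert errs[1] < errs[0]

    def test_infeasible_probability_names_the_pair(self):
        cfg = GeneratorConfig(
            n_reports=100, seed=0,
            planted_signals=(PlantedSignal("D0001", "PT1000004", 500.0),),
        )
        with pytest.raises(ValueError, match="D0001"):
            generate_database(cfg)

    def test_planted_pair_must_resolve_in_dictionaries(self):
        cfg = GeneratorConfig(
            n_reports=100, seed=0,
            planted_signals=(PlantedSignal("D9999", vocab.RAYNAUDS_PT, 2.0),),
        )
        with pytest.raises(ValueError, match="D9999"):
            generate_database(cfg)


class TestConfoundedScenario:
    def test_crude_inflated_but_strata_null(self):
        cfg = plant_confounded_scenario(GeneratorConfig(n_reports=20_000, seed=3))
        db, truth = generate_database(cfg)
        conf = truth.confounders[0]
        O, E = _pair_oe(db, conf.drug_id, conf.pt_code)
        assert O / E > 1.1  # mixture expectation ~1.2 for x3 enrichment

        # within each sex stratum the pair is independent by construction
        for sex in ("F", "M"):
            ids = set(db.reports.loc[db.reports.sex == sex, "report_id"])
            drugs = db.report_drugs
            events = db.report_events
            with_drug = set(drugs.loc[drugs.drug_id == conf.drug_id, "report_id"]) & ids
            with_event = set(events.loc[events.pt_code == conf.pt_code, "report_id"]) & ids
            o_s = len(with_drug & with_event)
            e_s = len(with_drug) * len(with_event) / len(ids)
            assert o_s / e_s == pytest.approx(1.0, abs=0.15)

    def test_unit_multiplier_changes_nothing_in_expectation(self):
        base = GeneratorConfig(n_reports=20_000, seed=9)
        cfg = dataclasses.replace(base, confounders=(
            Confounder("sex", "F", "D0070", "PT2000001",
                       drug_multiplier=1.0, event_multiplier=1.0),
        ))
        db, truth = generate_database(cfg)
        conf = truth.confounders[0]
        O, E = _pair_oe(db, conf.drug_id, conf.pt_code)
        assert O / E == pytest.approx(1.0, abs=0.15)


def test_target_map_is_deterministic_and_class_faithful(null_db):
    db, _ = null_db
    tm1 = generate_target_map(db.drug_dictionary, seed=4)
    tm2 = generate_target_map(db.drug_dictionary, seed=4)
    pd.testing.assert_frame_equal(tm1, tm2)
    beta = db.drug_classes("beta_blocker")
    hits = tm1[tm1.drug_id.isin(beta)]
    assert set(hits.target_id) == {"T0001", "T0002"}
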