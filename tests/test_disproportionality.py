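import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icsignal.disproportionality import (
    AnalysisOptions,
    ContingencyTable,
    build_table,
    ic_lower_bound,
    ic_point,
    mh_expected,
    run_analysis,
)

OPTS = AnalysisOptions(rp_pt_codes=("RP",), broad_pt_codes=("RP", "PI", "CH"))


class TestIcPoint:
    @pytest.mark.parametrize(
        "O, E, expected",
        [
            (0, 0.0, 0.0),                       # log2(0.5/0.5)
            (20, 5.0, np.log2(20.5 / 5.5)),      # ~1.898
            (7, 7.0, 0.0),                       # O == E
        ],
    )
    def test_known_values(self, O, E, expected):
        assert ic_point(O, E) == pytest.approx(expected, abs=1e-12)

    def test_vectorised(self):
        out = ic_point([0, 20], [0.0, 5.0])
        assert out.shape == (2,)
        assert out[1] == pytest.approx(np.log2(20.5 / 5.5))

    @given(
        st.integers(0, 500), st.integers(0, 500),
        st.floats(0.0, 200.0), st.floats(0.001, 50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_O_and_E(self, o1, do, e, de):
        assert ic_point(o1 + do + 1, e) > ic_point(o1, e)
        assert ic_point(o1, e + de) < ic_point(o1, e)


class TestLowerBound:
    def test_approximate_closed_form_value(self):
        # IC - 3.3(O+.5)^-1/2 - 2(O+.5)^-3/2 = 1.898 - 0.729 - 0.022
        lb = ic_lower_bound(20, 5.0, method="approximate")
        assert lb == pytest.approx(1.1476, abs=5e-4)

    def test_lower_bound_below_point_estimate(self):
        rng = np.random.default_rng(0)
        O = rng.integers(0, 300, 200)
        E = rng.uniform(0.01, 100, 200)
        for method in ("exact_gamma", "approximate"):
            assert np.all(ic_lower_bound(O, E, method=method) < ic_point(O, E))

    def test_methods_agree_for_moderate_counts(self):
        O, E = np.meshgrid(np.arange(10, 201), np.geomspace(0.1, 100, 20))
        diff = np.abs(
            ic_lower_bound(O, E, method="exact_gamma")
            - ic_lower_bound(O, E, method="approximate")
        )
        assert diff.max() < 0.1

    def test_zero_observed_never_significant(self):
        assert ic_lower_bound(0, 0.0) < -5
        assert ic_lower_bound(0, 10.0) < -5

    def test_level_and_method_validated(self):
        with pytest.raises(ValueError):
            ic_lower_bound(5, 1.0, level=1.5)
        with pytest.raises(ValueError):
            ic_lower_bound(5, 1.0, method="bogus")


class TestMantelHaenszel:
    def test_single_stratum_reduces_to_crude(self):
        t = ContingencyTable(O=4, n_drug=10, n_event=8, N=100)
        o, e = mh_expected([t])
        assert o == 4 and e == pytest.approx(t.expected)

    def test_two_strata_hand_computation(self):
        tables = [
            ContingencyTable(O=2, n_drug=10, n_event=10, N=1000),
            ContingencyTable(O=1, n_drug=20, n_event=5, N=500),
        ]
        o, e = mh_expected(tables)
        assert o == 3 and e == pytest.approx(0.1 + 0.2)

    def test_empty_strata_dropped(self):
        tables = [
            ContingencyTable(O=2, n_drug=10, n_event=10, N=1000),
            ContingencyTable(O=0, n_drug=0, n_event=0, N=0),
        ]
        o, e = mh_expected(tables)
        assert o == 2 and e == pytest.approx(0.1)

    def test_all_empty_fatal(self):
        with pytest.raises(ValueError):
            mh_expected([ContingencyTable(O=0, n_drug=0, n_event=0, N=0)])


class TestBuildTable:
    def test_direct_counts(self, tiny_db):
        # cases {R1,R3}; DA suspect/interacting in R1,R5,R8 within universe
        t = build_table(tiny_db, "DA", {"R1", "R3"}, set(tiny_db.report_ids) - {"R2"})
        assert (t.O, t.n_drug, t.n_event, t.N) == (1, 3, 2, 9)

    def test_concomitant_entries_do_not_count(self, tiny_db):
        # DB concomitant in R6 -> marginal counts R3, R4, R9 only
        t = build_table(tiny_db, "DB", {"R1", "R3"}, set(tiny_db.report_ids))
        assert t.n_drug == 3

    def test_stale_case_ids_rejected(self, tiny_db):
        with pytest.raises(ValueError):
            build_table(tiny_db, "DA", {"R1", "R99"}, set(tiny_db.report_ids))

    def test_empty_background_fatal(self, tiny_db):
        with pytest.raises(ValueError):
            build_table(tiny_db, "DA", set(), set())

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(O=5, n_drug=3, n_event=10, N=100)


class TestRunAnalysis:
    def test_primary_counts_on_fixture(self, tiny_db):
        res = run_analysis(tiny_db, "primary", OPTS).set_index("drug_id")
        # R2 excluded -> universe of 9; cases {R1, R3}
        assert res.loc["DA", "O"] == 1
        assert res.loc["DA", "E"] == pytest.approx(3 * 2 / 9)
        assert res.loc["DB", "O"] == 1
        assert "DD" not in res.index  # no included case carries DD

    def test_hcp_restriction_recomputes_within_subset(self, tiny_db):
        res = run_analysis(tiny_db, "hcp_only", OPTS).set_index("drug_id")
        # HCP universe: R1,R3,R5,R7,R9 (R2 already excluded)
        assert res.loc["DA", "O"] == 1
        assert res.loc["DA", "E"] == pytest.approx(2 * 2 / 5)

    def test_broad_definition_adds_cases(self, tiny_db):
        res = run_analysis(tiny_db, "broad_definition", OPTS).set_index("drug_id")
        # broad cases after exclusion: R1,R3,R4,R7 -> DD now evaluated
        assert "DD" in res.index
        assert res.loc["DB", "O"] == 2

    def test_mh_single_covered_stratum_matches_crude_shape(self, tiny_db):
        crude = run_analysis(tiny_db, "primary", OPTS).set_index("drug_id")
        mh = run_analysis(tiny_db, "mh_stratified", OPTS).set_index("drug_id")
        assert set(mh.index) == set(crude.index)
        assert (mh["O"] == crude["O"]).all()

    def test_atc3_background_restricts_comparator(self, tiny_db):
        res = run_analysis(tiny_db, "atc3_background", OPTS).set_index("drug_id")
        # DA (C07A): only DA-carrying reports share the subgroup ->
        # background {R1,R5,R8}, cases within it {R1}
        assert res.loc["DA", "O"] == 1
        assert res.loc["DA", "E"] == pytest.approx(3 * 1 / 3)

    def test_drug_without_atc_flagged_not_evaluable(self, tiny_db):
        db = tiny_db
        db.drug_dictionary.loc[db.drug_dictionary.drug_id == "DA", "atc_codes"] = ""
        res = run_analysis(db, "atc3_background", OPTS).set_index("drug_id")
        assert not res.loc["DA", "evaluable"]
        assert not res.loc["DA", "significant"]
        assert "DA" in res.index  # not silently dropped

    def test_unknown_analysis_rejected(self, tiny_db):
        with pytest.raises(ValueError):
            run_analysis(tiny_db, "bogus", OPTS)


class TestPlantedRecovery:
    def test_strong_planted_signal_significant_everywhere(self, demo_db):
        db, truth = demo_db
        strong = max(truth.planted_signals, key=lambda p: p.rate_ratio)
        for analysis in ("primary", "hcp_only", "atc3_background",
                         "mh_stratified", "broad_definition"):
            res = run_analysis(db, analysis).set_index("drug_id")
            assert bool(res.loc[strong.drug_id, "significant"]), analysis
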