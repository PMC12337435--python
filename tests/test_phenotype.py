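import itertools

import numpy as np
import pandas as pd
import pytest

from famcoag.phenotype import (
    CASE,
    CONTROL,
    MISSING,
    AssessmentRecord,
    PhenotypeError,
    PhenotypePanel,
    aggregate_lifetime,
    assign_analysis_age,
    composite_phenotype,
    summarize,
)

from conftest import make_records


def rec(status, wave="1A", age=40.0, iid="x", ph="D"):
    return AssessmentRecord(iid, ph, wave, status, None if status == MISSING else age)


class TestLifetimeAggregation:
    @pytest.mark.parametrize(
        "statuses,expected",
        [
            ([CASE, CONTROL, MISSING], CASE),
            ([CONTROL, MISSING, CONTROL], CONTROL),
            ([MISSING, MISSING], MISSING),
            ([], MISSING),
        ],
    )
    def test_rules(self, statuses, expected):
        waves = ["1A", "2A", "3A"]
        records = [rec(s, w) for s, w in zip(statuses, waves)]
        assert aggregate_lifetime(records) == expected

    def test_order_invariance(self):
        waves = ["1A", "2A", "3A"]
        for statuses in itertools.product([CASE, CONTROL, MISSING], repeat=3):
            results = {
                aggregate_lifetime([rec(s, w) for s, w in zip(perm, waves)])
                for perm in itertools.permutations(statuses)
            }
            assert len(results) == 1

    @pytest.mark.parametrize(
        "components,expected",
        [
            ([CONTROL, MISSING, CASE], CASE),
            ([CONTROL, MISSING], CONTROL),
            ([MISSING, MISSING], MISSING),
        ],
    )
    def test_composite_rules(self, components, expected):
        assert composite_phenotype(components) == expected

    def test_composite_idempotent_commutative(self):
        for comps in itertools.product([CASE, CONTROL, MISSING], repeat=2):
            r = composite_phenotype(list(comps))
            assert composite_phenotype([r, r]) == r
            assert composite_phenotype(list(comps[::-1])) == r

    def test_composite_empty_raises(self):
        with pytest.raises(PhenotypeError):
            composite_phenotype([])


class TestAnalysisAge:
    def test_case_age_is_first_case_wave(self, wave_order):
        records = [rec(CONTROL, "1A", 40), rec(CASE, "2A", 44), rec(CASE, "3A", 48)]
        assert assign_analysis_age(records, CASE, wave_order) == 44

    def test_control_age_is_last_observed(self, wave_order):
        records = [rec(CONTROL, "1A", 40), rec(CONTROL, "2A", 44)]
        assert assign_analysis_age(records, CONTROL, wave_order) == 44

    def test_all_missing_is_none(self, wave_order):
        assert assign_analysis_age([rec(MISSING, "1A")], MISSING, wave_order) is None

    def test_mismatch_raises(self, wave_order):
        with pytest.raises(PhenotypeError, match="no wave-level case"):
            assign_analysis_age([rec(CONTROL, "1A", 40)], CASE, wave_order)


class TestPanelFromRecords:
    def test_statuses_and_ages(self, wave_order):
        df = make_records(
            [
                ("a", "D", "1A", 0, 40.0),
                ("a", "D", "2A", 1, 44.0),
                ("a", "D", "3A", 1, 48.0),
                ("b", "D", "1A", 0, 30.0),
                ("b", "D", "2A", None, None),
                ("c", "D", "1A", None, None),
            ]
        )
        panel = PhenotypePanel.from_records(df, wave_order)
        assert panel.lifetime_status("a", "D") == CASE
        assert panel.analysis_age("a", "D") == 44.0
        assert panel.lifetime_status("b", "D") == CONTROL
        assert panel.analysis_age("b", "D") == 30.0
        assert panel.lifetime_status("c", "D") == MISSING
        assert np.isnan(panel.analysis_age("c", "D"))

    def test_wave_order_not_lexical(self):
        # wave labels sort lexically as B < Z, but assessment order is Z then B
        df = make_records([("a", "D", "Z", 0, 40.0), ("a", "D", "B", 0, 50.0)])
        panel = PhenotypePanel.from_records(df, ["Z", "B"])
        assert panel.analysis_age("a", "D") == 50.0

    def test_duplicate_rows_raise(self, wave_order):
        df = make_records([("a", "D", "1A", 0, 40.0), ("a", "D", "1A", 1, 40.0)])
        with pytest.raises(PhenotypeError, match="duplicate"):
            PhenotypePanel.from_records(df, wave_order)

    def test_age_required_when_observed(self, wave_order):
        df = make_records([("a", "D", "1A", 0, None)])
        with pytest.raises(PhenotypeError, match="age required"):
            PhenotypePanel.from_records(df, wave_order)

    def test_records_and_cube_paths_agree(self, wave_order):
        rng = np.random.default_rng(3)
        n, P, W = 40, 3, 3
        status = rng.choice([1, 0, -1], size=(n, P, W), p=[0.2, 0.5, 0.3]).astype(np.int8)
        base_age = rng.uniform(20, 70, n)
        age = np.broadcast_to((base_age[:, None] + np.array([0.0, 4.0, 10.5]))[:, None, :], (n, P, W)).copy()
        age[status == -1] = np.nan
        iids = [f"i{k}" for k in range(n)]
        phenos = [f"P{k}" for k in range(P)]
        from_cube = PhenotypePanel.from_cube(iids, phenos, status, age)
        rows = []
        for i in range(n):
            for p in range(P):
                for w in range(W):
                    s = status[i, p, w]
                    rows.append(
                        (iids[i], phenos[p], wave_order[w], None if s < 0 else int(s),
                         None if s < 0 else age[i, p, w])
                    )
        from_rec = PhenotypePanel.from_records(make_records(rows), wave_order)
        from_rec_status = from_rec.status.loc[from_cube.status.index, from_cube.status.columns]
        pd.testing.assert_frame_equal(from_cube.status, from_rec_status, check_dtype=False)
        pd.testing.assert_frame_equal(
            from_cube.age, from_rec.age.loc[from_cube.age.index, from_cube.age.columns]
        )

    def test_analysis_age_within_observed_range(self, wave_order):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(30):
            for w, wave in enumerate(wave_order):
                s = rng.choice([1, 0, None], p=[0.3, 0.4, 0.3])
                rows.append((f"i{i}", "D", wave, s, None if s is None else 30.0 + i + 4 * w))
        panel = PhenotypePanel.from_records(make_records(rows), wave_order)
        df = make_records(rows).dropna(subset=["status"])
        for iid, grp in df.groupby("iid"):
            a = panel.analysis_age(iid, "D")
            assert grp["age"].min() <= a <= grp["age"].max()


class TestCompositeAndExclusions:
    def test_add_composite(self, wave_order):
        df = make_records(
            [
                ("a", "X", "1A", 0, 40.0),
                ("a", "Y", "2A", 1, 44.0),
                ("b", "X", "1A", 0, 30.0),
                ("c", "Y", "1A", None, None),
            ]
        )
        panel = PhenotypePanel.from_records(df, wave_order).add_composite("XY", ["X", "Y"])
        assert panel.lifetime_status("a", "XY") == CASE
        assert panel.analysis_age("a", "XY") == 44.0
        assert panel.lifetime_status("b", "XY") == CONTROL  # partial data still a control
        assert panel.lifetime_status("c", "XY") == MISSING

    def test_exclusion_sets_target_missing(self, wave_order):
        df = make_records(
            [
                ("a", "FM", "1A", 1, 40.0),
                ("a", "RA", "1A", 1, 40.0),
                ("b", "FM", "1A", 1, 35.0),
                ("b", "RA", "1A", 0, 35.0),
            ]
        )
        panel = PhenotypePanel.from_records(df, wave_order)
        out = panel.apply_exclusions({"FM": ["RA"]})
        assert out.lifetime_status("a", "FM") == MISSING
        assert out.lifetime_status("a", "RA") == CASE  # other phenotype untouched
        assert out.lifetime_status("b", "FM") == CASE

    def test_empty_map_is_identity(self, wave_order):
        df = make_records([("a", "D", "1A", 1, 40.0)])
        panel = PhenotypePanel.from_records(df, wave_order)
        out = panel.apply_exclusions({})
        pd.testing.assert_frame_equal(out.status, panel.status)

    def test_case_count_drops_by_overlap(self, wave_order):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(200):
            rows.append((f"i{i}", "T", "1A", int(rng.random() < 0.3), 40.0))
            rows.append((f"i{i}", "E", "1A", int(rng.random() < 0.2), 40.0))
        panel = PhenotypePanel.from_records(make_records(rows), wave_order)
        before = int((panel.status["T"] == 1).sum())
        overlap = int(((panel.status["T"] == 1) & (panel.status["E"] == 1)).sum())
        after_panel = panel.apply_exclusions({"T": ["E"]})
        assert int((after_panel.status["T"] == 1).sum()) == before - overlap

    def test_unknown_phenotype_in_map_raises(self, wave_order):
        df = make_records([("a", "D", "1A", 1, 40.0)])
        panel = PhenotypePanel.from_records(df, wave_order)
        with pytest.raises(PhenotypeError, match="unknown"):
            panel.apply_exclusions({"D": ["nope"]})


class TestSummary:
    def test_matches_manual_recomputation(self, wave_order, three_gen_ped):
        rng = np.random.default_rng(2)
        rows = []
        for iid in three_gen_ped.iids:
            s = rng.choice([1, 0, None], p=[0.4, 0.4, 0.2])
            rows.append((iid, "D", "1A", s, None if s is None else float(rng.integers(20, 80))))
        panel = PhenotypePanel.from_records(make_records(rows), wave_order)
        table = summarize(panel, three_gen_ped).set_index("statistic")["value"]
        codes = panel.status["D"]
        assert table["N"] == len(panel.status)
        assert table["D_cases"] == (codes == 1).sum()
        n_data = int((codes >= 0).sum())
        if n_data:
            assert table["D_prevalence_pct"] == pytest.approx(100 * (codes == 1).sum() / n_data)

    def test_tsv_round_trip(self, wave_order, tmp_path):
        df = make_records([("a", "D", "1A", 1, 40.0), ("b", "D", "1A", 0, 30.0)])
        panel = PhenotypePanel.from_records(df, wave_order)
        panel.to_tsv(tmp_path / "panel.tsv")
        back = pd.read_csv(tmp_path / "panel.tsv", sep="\t")
        assert set(back["lifetime_status"]) == {"case", "control"}
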