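import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsurv import tables_io as tio
from conftest import toy_table


class TestFeatureTableIO:
    def test_tsv_round_trip_preserves_counts_and_lineages(self, tmp_path):
        table = toy_table()
        path = tmp_path / "t.tsv"
        tio.write_feature_table(table, path)
        back = tio.read_feature_table(path)
        pd.testing.assert_frame_equal(back.counts, table.counts)
        assert back.taxonomy == table.taxonomy

    def test_tsv_dimensions(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("feature_id\tS1\tS2\nF1\t1\t2\nF2\t0\t4\nF3\t5\t6\n")
        t = tio.read_feature_table(path)
        assert t.counts.shape == (2, 3)
        assert t.taxonomy is None

    def test_duplicate_sample_column_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("feature_id\tS1\tS1\nF1\t1\t2\n")
        with pytest.raises(tio.TableError):
            tio.read_feature_table(path)

    @pytest.mark.parametrize("bad", [
        pd.DataFrame([[1, -2]], index=["S1"], columns=["F1", "F2"]),
        pd.DataFrame([[1.5, 2]], index=["S1"], columns=["F1", "F2"]),
    ])
    def test_negative_or_fractional_counts_rejected(self, bad):
        with pytest.raises(tio.TableError):
            tio.FeatureTable(bad)

    def test_biom_json_round_trip(self, tmp_path):
        import json
        biom = {"matrix_type": "sparse",
                "rows": [{"id": "F1", "metadata":
                          {"taxonomy": ["k__Bacteria", "p__Firmicutes"]}},
                         {"id": "F2", "metadata": None}],
                "columns": [{"id": "S1"}, {"id": "S2"}],
                "data": [[0, 0, 3], [1, 1, 7]]}
        path = tmp_path / "t.biom"
        path.write_text(json.dumps(biom))
        t = tio.read_feature_table(path, format="biom-json")
        assert t.counts.loc["S1", "F1"] == 3
        assert t.counts.loc["S2", "F2"] == 7
        assert t.taxonomy["F1"][1] == "Firmicutes"


class TestParseLineage:
    def test_partial_lineage(self):
        r = tio.parse_lineage(
            "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales")
        assert r["class"] == "Clostridia"
        assert r["order"] == "Clostridiales"
        assert r["genus"] == tio.UNCLASSIFIED

    def test_empty_string_all_unclassified(self):
        assert all(v == tio.UNCLASSIFIED
                   for v in tio.parse_lineage("").values())

    def test_no_space_dialect_with_empty_ranks(self):
        r = tio.parse_lineage("k__Bacteria;p__;c__")
        assert r["kingdom"] == "Bacteria"
        assert r["phylum"] == tio.UNCLASSIFIED
        assert r["class"] == tio.UNCLASSIFIED


class TestDepthFilter:
    def test_boundary_is_inclusive(self):
        counts = pd.DataFrame({"F1": [7000, 5999, 6000]},
                              index=["A", "B", "C"])
        kept = tio.filter_low_depth(tio.FeatureTable(counts), 6000)
        assert kept.sample_ids == ["A", "C"]

    def test_zero_threshold_is_identity(self, cohort):
        out = tio.filter_low_depth(cohort.table, 0)
        pd.testing.assert_frame_equal(out.counts, cohort.table.counts)

    def test_all_removed_raises_with_threshold(self):
        counts = pd.DataFrame({"F1": [100, 100]}, index=["A", "B"])
        with pytest.raises(tio.TableError, match="6000"):
            tio.filter_low_depth(tio.FeatureTable(counts), 6000)


class TestEndpoints:
    def test_recurrence_then_death(self):
        rec = tio.SurvivalRecord("p", recurrence_time=10, death_time=20,
                                 last_followup_time=20, died=True)
        assert (tio.derive_endpoint(rec, "RFS").time,
                tio.derive_endpoint(rec, "RFS").event) == (10, 1)
        assert (tio.derive_endpoint(rec, "DFS").time,
                tio.derive_endpoint(rec, "DFS").event) == (10, 1)
        assert (tio.derive_endpoint(rec, "OS").time,
                tio.derive_endpoint(rec, "OS").event) == (20, 1)

    def test_new_primary_counts_only_for_dfs(self):
        rec = tio.SurvivalRecord("p", new_primary_time=12,
                                 last_followup_time=50, died=False)
        assert (tio.derive_endpoint(rec, "DFS").time,
                tio.derive_endpoint(rec, "DFS").event) == (12, 1)
        assert (tio.derive_endpoint(rec, "RFS").time,
                tio.derive_endpoint(rec, "RFS").event) == (50, 0)
        assert (tio.derive_endpoint(rec, "OS").time,
                tio.derive_endpoint(rec, "OS").event) == (50, 0)

    def test_no_events_censored_at_last_followup(self):
        rec = tio.SurvivalRecord("p", last_followup_time=60)
        for ep in tio.ENDPOINTS:
            e = tio.derive_endpoint(rec, ep)
            assert (e.time, e.event) == (60, 0)

    def test_death_imputed_from_recurrence(self):
        rec = tio.SurvivalRecord("p", recurrence_time=8,
                                 last_followup_time=8, died=True)
        out = tio.impute_missing_death(rec)
        assert out.death_time == 8 and out.death_imputed

    def test_present_death_unchanged(self):
        rec = tio.SurvivalRecord("p", death_time=5, last_followup_time=5,
                                 died=True)
        assert tio.impute_missing_death(rec) is rec

    def test_death_unimputable_raises(self):
        rec = tio.SurvivalRecord("p", last_followup_time=9, died=True)
        with pytest.raises(tio.TableError):
            tio.impute_missing_death(rec)

    @given(rec_t=st.one_of(st.none(), st.floats(0, 100)),
           np_t=st.one_of(st.none(), st.floats(0, 100)),
           death_t=st.one_of(st.none(), st.floats(0, 100)),
           fu=st.floats(0.1, 200))
    @settings(max_examples=200, deadline=None)
    def test_endpoint_time_ordering(self, rec_t, np_t, death_t, fu):
        """DFS time <= RFS time <= OS time for every consistent event
        history (events cannot occur after the end of follow-up)."""
        from hypothesis import assume
        assume(all(t is None or t <= fu for t in (rec_t, np_t, death_t)))
        rec = tio.SurvivalRecord("p", recurrence_time=rec_t,
                                 new_primary_time=np_t, death_time=death_t,
                                 last_followup_time=fu,
                                 died=death_t is not None)
        dfs = tio.derive_endpoint(rec, "DFS")
        rfs = tio.derive_endpoint(rec, "RFS")
        os_ = tio.derive_endpoint(rec, "OS")
        assert dfs.time <= rfs.time <= os_.time

    def test_earlier_event_never_increases_time(self):
        base = tio.SurvivalRecord("p", death_time=30, last_followup_time=30,
                                  died=True)
        earlier = tio.SurvivalRecord("p", recurrence_time=5, death_time=30,
                                     last_followup_time=30, died=True)
        assert (tio.derive_endpoint(earlier, "RFS").time
                <= tio.derive_endpoint(base, "RFS").time)

    def test_survival_record_round_trip(self, tmp_path, cohort):
        path = tmp_path / "surv.tsv"
        tio.write_survival_records(cohort.records, path)
        back = tio.read_survival_records(path)
        for a, b in zip(cohort.records, back):
            assert a.patient_id == b.patient_id
            assert a.died == b.died
            assert a.last_followup_time == pytest.approx(b.last_followup_time)


class TestCovariates:
    def test_dummy_coding_reference_is_lexicographic_first(self):
        cs = tio.CovariateSet(pd.DataFrame(
            {"smoking": ["never", "former", "current"], "age": [60, 70, 80.0]},
            index=["a", "b", "c"]))
        d = cs.design_matrix()
        assert set(d.columns) == {"age", "smoking_former", "smoking_never"}

    def test_unknown_level_rejected(self):
        with pytest.raises(tio.TableError):
            tio.CovariateSet(pd.DataFrame({"sex": ["robot"]}, index=["a"]))

    def test_screen_threshold_one_retains_all(self, cohort):
        kept = tio.screen_covariates(cohort.covariates, cohort.records,
                                     p_threshold=1.0)
        assert kept == list(cohort.covariates.table.columns)
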