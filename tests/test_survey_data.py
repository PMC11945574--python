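"""Survey descriptive statistics: detection, variability, trend, similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrethro import survey_data as sv
from pyrethro.errors import DomainError, ValidationError
from pyrethro.survey_data import SurveyTable, UrineRecord


def make_table(values, lods=None, cycle="1999-2000", age="6-11", metabolite="3PBA"):
    lods = lods if lods is not None else [0.1] * len(values)
    rows = []
    for i, (v, l) in enumerate(zip(values, lods)):
        cens = v is None
        rows.append(
            {
                "subject_id": f"s{i}",
                "cycle": cycle,
                "age_group": age,
                "body_weight": 30.0,
                "metabolite": metabolite,
                "value": np.nan if cens else v,
                "lod": l,
                "below_lod": cens,
                "creatinine": 1.0,
            }
        )
    return SurveyTable(pd.DataFrame(rows))


class TestRecordsAndTable:
    def test_censored_record_cannot_carry_a_value(self):
        with pytest.raises(ValidationError):
            UrineRecord("s", "1999-2000", "6-11", 30.0, "3PBA", 0.2, 0.1, True)

    def test_detected_value_below_lod_rejected(self):
        with pytest.raises(ValidationError):
            UrineRecord("s", "1999-2000", "6-11", 30.0, "3PBA", 0.05, 0.1, False)

    def test_round_trip_through_csv(self, tmp_path):
        t = make_table([0.5, None, 1.2, None, 0.3])
        path = tmp_path / "survey.csv"
        t.to_csv(path)
        back = SurveyTable.read_csv(path)
        pd.testing.assert_frame_equal(
            back.frame, t.frame, check_dtype=False, check_like=True
        )

    def test_coverage_counts_records(self):
        t = make_table([0.5, None, 1.2])
        cov = t.coverage
        assert cov.loc[0, "n"] == 3


class TestDetectionRate:
    def test_all_detected_gives_one(self):
        assert sv.detection_rate(make_table([1.0, 2.0, 3.0]), "3PBA") == 1.0

    def test_four_of_five_censored_gives_point_two(self):
        t = make_table([1.0, None, None, None, None])
        assert sv.detection_rate(t, "3PBA") == pytest.approx(0.2)

    def test_empty_selection_raises(self):
        with pytest.raises(DomainError):
            sv.detection_rate(make_table([1.0]), "FPBA")

    def test_invariant_under_record_order(self, rng):
        vals = [float(v) if v > 0.5 else None for v in rng.uniform(0, 1, 50)]
        t1 = make_table(vals)
        t2 = make_table(vals[::-1])
        assert sv.detection_rate(t1, "3PBA") == sv.detection_rate(t2, "3PBA")


class TestPercentileRatio:
    def test_constant_sample_gives_one(self):
        assert sv.percentile_ratio(np.full(50, 3.3)) == pytest.approx(1.0)

    def test_lognormal_closed_form(self, rng):
        x = np.exp(rng.standard_normal(100_000) * np.log(2.0))
        assert sv.percentile_ratio(x) == pytest.approx(2**1.6449, rel=0.02)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(DomainError):
            sv.percentile_ratio(np.ones(5))

    def test_zero_median_rejected(self):
        x = np.zeros(30)
        with pytest.raises(DomainError):
            sv.percentile_ratio(x)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.01, 1e4))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 0.5, 200)
        assert sv.percentile_ratio(scale * x) == pytest.approx(sv.percentile_ratio(x), rel=1e-9)


class TestGeometricMeanTrend:
    def _two_cycle_table(self, factor):
        rows = []
        for cyc, mult in (("1999-2000", 1.0), ("2015-2016", factor)):
            t = make_table(list(np.full(40, 0.5 * mult)), cycle=cyc)
            rows.append(t.frame)
        return SurveyTable(pd.concat(rows, ignore_index=True))

    def test_flat_trend_ratio_one(self):
        trend = sv.geometric_mean_trend(self._two_cycle_table(1.0), "3PBA")
        assert trend.gm.iloc[-1] / trend.gm.iloc[0] == pytest.approx(1.0)

    def test_doubling_recovered(self):
        trend = sv.geometric_mean_trend(self._two_cycle_table(2.0), "3PBA")
        assert trend.gm.iloc[-1] / trend.gm.iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_single_cycle_raises(self):
        with pytest.raises(DomainError):
            sv.geometric_mean_trend(make_table([1.0, 2.0]), "3PBA")

    def test_all_censored_cycle_flagged(self):
        rows = [
            make_table([0.5] * 30, cycle="1999-2000").frame,
            make_table([None] * 30, cycle="2001-2002").frame,
        ]
        trend = sv.geometric_mean_trend(SurveyTable(pd.concat(rows, ignore_index=True)), "3PBA")
        assert bool(trend.set_index("cycle").loc["2001-2002", "all_censored"])


class TestAgeGroupSimilarity:
    def test_identical_rows_merge_at_distance_zero(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]], index=["A", "B", "C"], columns=["c1", "c2"]
        )
        res = sv.age_group_similarity(m)
        assert res["linkage"][0, 2] == pytest.approx(0.0)
        assert res["labels"]["A"] == res["labels"]["B"] != res["labels"]["C"]

    def test_constructed_separation_splits_offset_groups(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 1.5, 4)
        m = pd.DataFrame(
            [base, base * 1.1, base * 100, base * 110, base * 95],
            index=["A", "B", "C", "D", "E"],
        )
        res = sv.age_group_similarity(m, n_clusters=2)
        labels = res["labels"]
        assert labels["A"] == labels["B"]
        assert labels["C"] == labels["D"] == labels["E"]
        assert labels["A"] != labels["C"]

    def test_column_permutation_leaves_topology_unchanged(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.lognormal(0, 1, (5, 6)), index=list("ABCDE"))
        res1 = sv.age_group_similarity(m)
        res2 = sv.age_group_similarity(m[[3, 0, 5, 1, 4, 2]])
        assert np.allclose(res1["linkage"][:, 2], res2["linkage"][:, 2])
        assert res1["labels"] == res2["labels"]

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(DomainError):
            sv.age_group_similarity(pd.DataFrame([[1.0, 2.0]], index=["A"]))


def test_xpt_ingestion_maps_comment_codes_to_censoring(monkeypatch):
    """Coded missingness (comment code 1) becomes a below-LOD flag."""
    raw = pd.DataFrame(
        {
            "SEQN": [1001, 1002, 1003, 1004],
            "URX3PB": [0.5, np.nan, 1.2, np.nan],
            "URD3PBLC": [0, 1, 0, np.nan],
        }
    )
    monkeypatch.setattr(pd, "read_sas", lambda path, format: raw)
    table = sv.read_xpt_survey(
        "fake.xpt", {"3PBA": ("URX3PB", "URD3PBLC", 0.1)}, cycle="1999-2000"
    )
    # the all-missing row (no value, no code) is dropped
    assert len(table) == 3
    assert sv.detection_rate(table, "3PBA") == pytest.approx(2 / 3)
    assert (table.frame.lod == 0.1).all()


def test_imputation_policies(rng):
    t = make_table([None, None, 1.0], lods=[0.2, 0.2, 0.1])
    assert sv.SurveyTable.imputed_values(t, "3PBA", policy="sqrt2")[0] == pytest.approx(0.2 / np.sqrt(2))
    assert sv.SurveyTable.imputed_values(t, "3PBA", policy="half")[0] == pytest.approx(0.1)
    assert sv.SurveyTable.imputed_values(t, "3PBA", policy="zero")[0] == 0.0
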