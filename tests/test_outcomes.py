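"""DAS28 arithmetic, EULAR classification and visit selection."""

import numpy as np
import pandas as pd
import pytest

from tnfigrs.outcomes import (
    compute_deltas,
    das28,
    derive_outcomes,
    eular_response,
    select_visits,
)


def eular_grid_oracle(baseline: float, eval_: float) -> str:
    """Independently coded 3x3 published response grid."""
    imp = baseline - eval_
    row = 0 if imp > 1.2 else (1 if imp > 0.6 else 2)
    col = 0 if eval_ <= 3.2 else (1 if eval_ <= 5.1 else 2)
    table = [
        ["good", "moderate", "moderate"],
        ["moderate", "moderate", "none"],
        ["none", "none", "none"],
    ]
    return table[row][col]


class TestDas28:
    def test_all_zero_limit(self):
        assert das28(0, 0, 1, 0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "args,expected",
        [((8, 8, 28, 54), 5.465), ((28, 28, 100, 100), 9.068)],
    )
    def test_hand_arithmetic(self, args, expected):
        assert das28(*args) == pytest.approx(expected, abs=1e-3)

    def test_invalid_inputs_refused(self):
        with pytest.raises(ValueError, match="ESR"):
            das28(1, 1, 0, 10)
        with pytest.raises(ValueError, match="counts"):
            das28(29, 1, 10, 10)
        with pytest.raises(ValueError, match="VAS"):
            das28(1, 1, 10, 101)

    def test_nan_propagates(self):
        out = das28(np.array([np.nan]), np.array([1.0]), np.array([10.0]), np.array([10.0]))
        assert np.isnan(out[0])


class TestEular:
    @pytest.mark.parametrize(
        "b,e,expected",
        [
            (5.0, 3.0, "good"),
            (5.0, 4.5, "none"),
            (6.0, 4.6, "moderate"),
            (5.0, 3.2, "good"),       # boundary: eval exactly 3.2 still good
            (5.0, 3.8, "moderate"),   # improvement exactly 1.2 is not "good"
            (6.25, 5.15, "none"),     # improvement 1.1 <= 1.2 with eval > 5.1
        ],
    )
    def test_examples(self, b, e, expected):
        assert eular_response(b, e) == expected

    def test_agrees_with_grid_oracle_on_coarse_grid(self):
        grid = np.arange(0, 10.0001, 0.25)
        b, e = np.meshgrid(grid, grid, indexing="ij")
        got = eular_response(b.ravel(), e.ravel())
        expect = [eular_grid_oracle(x, y) for x, y in zip(b.ravel(), e.ravel())]
        assert list(got) == expect

    def test_monotone_in_attained_das28(self):
        """For a fixed baseline, decreasing the attained DAS28 never worsens
        the response class."""
        order = {"none": 0, "moderate": 1, "good": 2}
        evals = np.arange(10, -0.001, -0.05)
        for baseline in np.arange(0, 10.001, 0.5):
            classes = [order[eular_response(baseline, e)] for e in evals]
            assert all(np.diff(classes) >= 0)

    def test_nan_refused(self):
        with pytest.raises(ValueError):
            eular_response(np.nan, 3.0)


def _visits(rows):
    cols = ["subject_id", "days_since_treatment_start", "tjc28", "sjc28", "esr", "crp",
            "vas_global", "vas_pain", "haq"]
    df = pd.DataFrame(rows, columns=["subject_id", "days_since_treatment_start"])
    for c in cols[2:]:
        df[c] = 10.0
    df["drug"] = "infliximab"
    return df


class TestSelectVisits:
    def test_nearest_to_target_day(self):
        v = _visits([("s1", 0), ("s1", 70), ("s1", 140), ("s1", 200)])
        sel = select_visits(v, (60, 240), 150)
        assert sel.evaluation["days_since_treatment_start"].tolist() == [140]

    def test_equidistant_tie_goes_to_earlier_visit(self):
        v = _visits([("s1", 0), ("s1", 140), ("s1", 160)])
        sel = select_visits(v, (60, 240), 150)
        assert sel.evaluation["days_since_treatment_start"].tolist() == [140]

    def test_outside_window_excludes_subject(self):
        v = _visits([("s1", 0), ("s1", 250)])
        sel = select_visits(v, (60, 240), 150)
        assert sel.evaluation.empty
        assert sel.excluded["subject_id"].tolist() == ["s1"]
        assert "window" in sel.excluded["reason"][0]

    def test_missing_baseline_excludes_subject(self):
        v = _visits([("s1", 30), ("s1", 140)])
        sel = select_visits(v, (60, 240), 150)
        assert sel.excluded["subject_id"].tolist() == ["s1"]
        assert "baseline" in sel.excluded["reason"][0]

    def test_row_order_independence_and_idempotence(self, rng):
        rows = [("s1", 0), ("s1", 100), ("s1", 180), ("s2", -3), ("s2", 160), ("s2", 90)]
        v = _visits(rows)
        ref = select_visits(v)
        for _ in range(5):
            shuffled = v.sample(frac=1, random_state=int(rng.integers(1e6))).reset_index(drop=True)
            got = select_visits(shuffled)
            pd.testing.assert_frame_equal(got.evaluation, ref.evaluation)
            pd.testing.assert_frame_equal(got.baseline, ref.baseline)
        again = select_visits(pd.concat([ref.baseline, ref.evaluation], ignore_index=True))
        pd.testing.assert_frame_equal(again.evaluation, ref.evaluation)

    def test_visit_with_missing_das28_component_skipped(self):
        v = _visits([("s1", 0), ("s1", 150), ("s1", 100)])
        v.loc[v["days_since_treatment_start"] == 150, "esr"] = np.nan
        sel = select_visits(v)
        assert sel.evaluation["days_since_treatment_start"].tolist() == [100]

    def test_malformed_day_value_refused(self):
        v = _visits([("s1", 0)])
        v.loc[0, "days_since_treatment_start"] = "soon"
        with pytest.raises((ValueError, TypeError)):
            select_visits(v)


class TestDeltas:
    def _row(self, **kw):
        base = dict(subject_id="s1", tjc28=8, sjc28=8, esr=28, crp=20.0,
                    vas_global=54, vas_pain=50, haq=1.0)
        base.update(kw)
        return pd.Series(base)

    def test_identical_rows_give_zero(self):
        d = compute_deltas(self._row(), self._row())
        assert all(v == 0 for v in d.values())

    def test_improvement_is_negative(self):
        b = self._row()
        e = self._row(tjc28=2, sjc28=2, esr=10, vas_global=20, haq=0.7)
        d = compute_deltas(b, e)
        assert d["DAS28"] == pytest.approx(das28(2, 2, 10, 20) - das28(8, 8, 28, 54))
        assert d["DAS28"] < 0
        assert d["HAQ"] == pytest.approx(-0.3)

    def test_missing_measure_yields_missing_delta(self):
        e = self._row()
        e["haq"] = np.nan
        d = compute_deltas(self._row(), e)
        assert np.isnan(d["HAQ"])
        assert d["TJC"] == 0

    def test_subject_mismatch_refused(self):
        with pytest.raises(ValueError):
            compute_deltas(self._row(), self._row(subject_id="s2"))


def test_derive_outcomes_end_to_end():
    v = _visits([("s1", 0), ("s1", 150), ("s2", 2), ("s2", 90), ("s3", 0)])
    v.loc[(v.subject_id == "s1") & (v.days_since_treatment_start == 150),
          ["tjc28", "sjc28", "esr", "vas_global"]] = [2, 2, 5, 10]
    out = derive_outcomes(v)
    assert set(out["subject_id"]) == {"s1", "s2"}  # s3 has no follow-up
    s1 = out.set_index("subject_id").loc["s1"]
    assert s1["eular"] == "good"
    assert s1["response"] == 1
    assert s1["d_DAS28"] == pytest.approx(das28(2, 2, 5, 10) - das28(10, 10, 10, 10))
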