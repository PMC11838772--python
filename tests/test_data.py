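"""Trajectory IO, scaling, and edit-window enumeration."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trajedit as te
from trajedit.data import EditWindow


def long_df(n_entities=2, n_vars=3, n_times=4):
    rows = []
    for e in range(n_entities):
        for v in range(n_vars):
            for t in range(n_times):
                rows.append(
                    {"entity_id": f"e{e}", "time": t, "variable": f"v{v}",
                     "value": float(e * 100 + v * 10 + t)}
                )
    return pd.DataFrame(rows)


def test_read_fully_observed_long_format(tmp_path):
    path = tmp_path / "x.csv"
    long_df().to_csv(path, index=False)
    trs = te.read_trajectories(path)
    assert len(trs) == 2
    for tr in trs:
        assert tr.values.shape == (3, 4)
        assert tr.mask.all()
    assert trs[0].values[1, 2] == 12.0  # e0, v1, t2


def test_read_missing_cell_masks_exactly_that_cell(tmp_path):
    df = long_df()
    df = df[~((df.entity_id == "e0") & (df.variable == "v1") & (df.time == 2))]
    path = tmp_path / "x.csv"
    df.to_csv(path, index=False)
    trs = te.read_trajectories(path)
    tr = next(t for t in trs if t.entity_id == "e0")
    expected = np.ones((3, 4), dtype=bool)
    expected[1, 2] = False
    assert np.array_equal(tr.mask, expected)


def test_read_duplicate_row_raises_with_location(tmp_path):
    df = pd.concat([long_df(), long_df().iloc[[5]]])
    path = tmp_path / "x.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="duplicate"):
        te.read_trajectories(path)


def test_read_non_numeric_value_raises_with_row(tmp_path):
    df = long_df().astype({"value": object})
    df.loc[3, "value"] = "oops"
    path = tmp_path / "x.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="non-numeric"):
        te.read_trajectories(path)


def test_read_skips_single_timepoint_entity(tmp_path, caplog):
    df = long_df()
    extra = pd.DataFrame(
        [{"entity_id": "solo", "time": 0, "variable": "v0", "value": 1.0}]
    )
    path = tmp_path / "x.csv"
    pd.concat([df, extra]).to_csv(path, index=False)
    with caplog.at_level(logging.WARNING):
        trs = te.read_trajectories(path)
    assert {t.entity_id for t in trs} == {"e0", "e1"}
    assert any("solo" in r.message for r in caplog.records)


def test_read_write_read_roundtrip_is_idempotent(tmp_path, tiny_dataset):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    te.write_trajectories(tiny_dataset.trajectories, p1)
    once = te.read_trajectories(p1)
    te.write_trajectories(once, p2)
    twice = te.read_trajectories(p2)
    for a, b in zip(once, twice):
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.times, b.times)


def test_scaling_maps_range_endpoints():
    tr = te.Trajectory(
        "e", ["a"], np.arange(4), np.array([[10.0, 12.0, 15.0, 20.0]]),
        np.ones((1, 4), dtype=bool),
    )
    spec = te.fit_scaling([tr], eps_pos=0.01)
    scaled = spec.apply(tr.values)
    assert scaled[0, 0] == pytest.approx(0.01)
    assert scaled[0, -1] == pytest.approx(1.0)


def test_scaling_constant_variable_maps_to_midpoint():
    tr = te.Trajectory(
        "e", ["a"], np.arange(3), np.full((1, 3), 5.0), np.ones((1, 3), dtype=bool)
    )
    spec = te.fit_scaling([tr])
    assert np.allclose(spec.apply(tr.values), 0.5)
    assert np.allclose(spec.invert(spec.apply(tr.values)), 5.0)


def test_scaling_unobserved_variable_raises():
    tr = te.Trajectory(
        "e", ["a", "b"], np.arange(3), np.ones((2, 3)),
        np.array([[True] * 3, [False] * 3]),
    )
    with pytest.raises(ValueError, match="b"):
        te.fit_scaling([tr])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    vals=st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=4, max_size=12
    )
)
def test_scaling_roundtrip_property(vals):
    arr = np.array(vals)[None, :]
    tr = te.Trajectory("e", ["a"], np.arange(arr.shape[1]), arr,
                       np.ones_like(arr, dtype=bool))
    spec = te.fit_scaling([tr])
    back = spec.invert(spec.apply(arr))
    denom = np.maximum(np.abs(arr), 1.0)
    assert np.max(np.abs(back - arr) / denom) <= 1e-9


def test_scaling_spec_json_roundtrip(tiny_dataset):
    spec = te.fit_scaling(tiny_dataset.trajectories)
    spec2 = te.ScalingSpec.from_json(spec.to_json())
    x = tiny_dataset.trajectories[0].values
    assert np.array_equal(spec.apply(x), spec2.apply(x))


def test_edit_windows_immediate_enumeration():
    tr = te.Trajectory("e", ["a"], np.arange(5), np.ones((1, 5)),
                       np.ones((1, 5), dtype=bool))
    wins = te.make_edit_windows(tr, min_history=2, horizon_set={1})
    assert [(w.history_end, w.target_index) for w in wins] == [(1, 2), (2, 3), (3, 4)]


def test_edit_windows_delayed_protocol_targets():
    """History of nine steps, horizons 1..14 -> targets at indices 9..22."""
    tr = te.Trajectory("e", ["a"], np.arange(23), np.ones((1, 23)),
                       np.ones((1, 23), dtype=bool))
    wins = [w for w in te.make_edit_windows(tr, 9, set(range(1, 15))) if w.history_end == 8]
    assert sorted(w.target_index for w in wins) == list(range(9, 23))


def test_edit_windows_too_short_is_empty():
    tr = te.Trajectory("e", ["a"], np.arange(3), np.ones((1, 3)),
                       np.ones((1, 3), dtype=bool))
    assert te.make_edit_windows(tr, min_history=5, horizon_set={1}) == []


@pytest.mark.parametrize("T,min_hist,horizons", [(8, 2, {1, 3}), (12, 4, {1, 2, 5, 11}),
                                                 (5, 1, {1}), (6, 6, {2})])
def test_edit_window_count_matches_bruteforce(T, min_hist, horizons):
    tr = te.Trajectory("e", ["a"], np.arange(T), np.ones((1, T)),
                       np.ones((1, T), dtype=bool))
    wins = te.make_edit_windows(tr, min_hist, horizons)
    brute = [
        EditWindow(t_i, t_i + g, g)
        for t_i in range(T)
        for g in sorted(horizons)
        if t_i + 1 >= min_hist and t_i + g < T
    ]
    assert set(wins) == set(brute)
    expected = sum(max(0, T - g - min_hist + 1) for g in horizons)
    assert len(wins) == expected


def test_wide_export_shape(tmp_path, tiny_dataset):
    path = tmp_path / "wide.csv"
    te.write_wide(tiny_dataset.trajectories[:2], path)
    df = pd.read_csv(path)
    tr = tiny_dataset.trajectories[0]
    assert list(df.columns) == ["entity_id", "time"] + tr.variables
    assert len(df) == 2 * tr.n_times
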