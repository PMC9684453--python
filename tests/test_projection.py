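import numpy as np
import pytest

from phenoescape import (
    ClimateGrid,
    ParameterSummary,
    continental_summary,
    delta_window,
    light_window,
    mask_forest,
    predict_surface,
    scenario_delta_summary,
)
from phenoescape.projection import WindowMap


def _ps(name, mean):
    return ParameterSummary(name, mean, mean, 0.1, mean - 0.2, mean + 0.2)


def _grid(values, variable="spring_temp", scenario="current", nodata=-9999.0):
    return ClimateGrid(
        values=np.asarray(values, dtype=np.float64),
        transform=(-89.5, 51.5, 1.0, -1.0),
        variable=variable, scenario=scenario, nodata=nodata,
    )


def _summaries(b0, b1, b2):
    return {
        "community_intercept": _ps("community_intercept", b0),
        "beta1": _ps("beta1", b1),
        "beta2": _ps("beta2", b2),
    }


def test_predict_surface_arithmetic():
    temp = _grid(np.full((2, 2), 5.0))
    elev = _grid(np.zeros((2, 2)), variable="elevation")
    surf = predict_surface(_summaries(150.0, -3.0, 0.0), temp, elev)
    assert np.allclose(surf.grid.values, 135.0)


def test_predict_surface_linearity_in_temperature():
    rng = np.random.default_rng(2)
    t = _grid(rng.normal(8, 2, (5, 4)))
    e = _grid(rng.uniform(0, 1000, (5, 4)), variable="elevation")
    s = _summaries(140.0, -3.5, 0.01)
    base = predict_surface(s, t, e)
    warmed = predict_surface(s, t.with_values(t.values + 1.0), e)
    assert np.allclose(warmed.grid.values - base.grid.values, -3.5, atol=1e-12)


def test_predict_surface_matches_cellwise_oracle():
    """Vectorised surface equals an independently coded per-cell loop."""
    rng = np.random.default_rng(5)
    t = _grid(rng.normal(8, 2, (6, 7)))
    e = _grid(rng.uniform(0, 1500, (6, 7)), variable="elevation")
    b0, b1, b2 = 147.2, -3.31, 0.018
    surf = predict_surface(_summaries(b0, b1, b2), t, e)
    for i in range(6):
        for j in range(7):
            expected = b0 + b1 * t.values[i, j] + b2 * e.values[i, j]
            assert abs(surf.grid.values[i, j] - expected) < 1e-9


def test_predict_surface_requires_alignment_and_params():
    t = _grid(np.zeros((2, 2)))
    e_bad = ClimateGrid(np.zeros((3, 3)), transform=(-89.5, 51.5, 1.0, -1.0),
                        variable="elevation")
    with pytest.raises(Exception):
        predict_surface(_summaries(1, 1, 1), t, e_bad)
    with pytest.raises(KeyError):
        predict_surface({"beta1": _ps("beta1", -3)}, t, t.with_values(t.values))


def _surface(vals, scenario="current", stratum="wildflower"):
    from phenoescape.projection import PhenologySurface

    return PhenologySurface(_grid(vals, scenario=scenario), stratum,
                            "NorthAmerica", scenario)


@pytest.mark.parametrize("ffd,lod,expected", [(100.0, 112.0, 12.0),
                                              (110.0, 110.0, 0.0),
                                              (115.0, 110.0, -5.0)])
def test_light_window_is_lod_minus_ffd(ffd, lod, expected):
    w = light_window(_surface(np.full((2, 2), ffd)),
                     _surface(np.full((2, 2), lod)))
    assert np.allclose(w.grid.values, expected)


def test_light_window_scenario_mismatch_raises():
    with pytest.raises(ValueError, match="scenario"):
        light_window(_surface(np.zeros((2, 2)), "current"),
                     _surface(np.zeros((2, 2)), "future"))


def test_delta_window_sign_and_antisymmetry():
    cur = WindowMap(_grid(np.full((2, 2), 10.0)), "current")
    fut = WindowMap(_grid(np.full((2, 2), 14.0)), "future")
    d = delta_window(cur, fut)
    assert np.allclose(d.grid.values, 4.0)  # positive = window lengthens
    assert np.allclose(delta_window(fut, cur).grid.values,
                       -d.grid.values)
    same = delta_window(cur, cur)
    assert np.allclose(same.grid.values, 0.0)
    flipped = delta_window(cur, fut, future_minus_current=False)
    assert np.allclose(flipped.grid.values, -4.0)


def _forest(vals):
    return _grid(vals, variable="forest_fraction")


def test_mask_forest_threshold_rule():
    w = WindowMap(_grid(np.array([[5.0, 6.0, 7.0]])), "current")
    forest = _forest(np.array([[0.005, 0.015, 0.5]]))
    masked = mask_forest(w, forest)
    assert masked.grid.values[0, 0] == masked.grid.nodata  # <1% cover masked
    assert masked.grid.values[0, 1] == 6.0                 # >=1% retained
    assert masked.masked


def test_mask_forest_idempotent():
    rng = np.random.default_rng(7)
    w = WindowMap(_grid(rng.normal(10, 3, (4, 4))), "current")
    forest = _forest(rng.uniform(0, 0.05, (4, 4)))
    once = mask_forest(w, forest)
    twice = mask_forest(once, forest)
    assert np.array_equal(once.grid.values, twice.grid.values)


def test_mask_forest_invalid_threshold():
    w = WindowMap(_grid(np.zeros((2, 2))), "current")
    with pytest.raises(ValueError, match="threshold"):
        mask_forest(w, _forest(np.full((2, 2), 0.5)), threshold=1.5)


def test_continental_summary_hand_computed():
    w = WindowMap(_grid(np.array([[2.0, 4.0, 6.0]])), "current")
    mean, sd = continental_summary(w)
    assert mean == pytest.approx(4.0)
    assert sd == pytest.approx(np.sqrt(8.0 / 3.0), abs=1e-12)  # 1.633 pop. sd


def test_continental_summary_single_cell_and_mask_contract():
    single = WindowMap(_grid(np.array([[3.5]])), "current")
    assert continental_summary(single) == (3.5, 0.0)
    vals = np.array([[1.0, -9999.0], [3.0, -9999.0]])
    a = continental_summary(WindowMap(_grid(vals), "current"))
    vals2 = vals.copy()
    vals2[vals2 == -9999.0] = -9999.0  # masked cell payloads are irrelevant
    b = continental_summary(WindowMap(_grid(vals2), "current"))
    assert a == b == (2.0, 1.0)
    fully = WindowMap(_grid(np.full((2, 2), -9999.0)), "current")
    with pytest.raises(ValueError, match="fully masked"):
        continental_summary(fully)


def test_scenario_delta_summary_uniform_and_composition():
    cur = _grid(np.random.default_rng(1).normal(8, 2, (4, 4)))
    fut = cur.with_values(cur.values + 5.0, scenario="future")
    mean, sd = scenario_delta_summary(cur, fut)
    assert mean == pytest.approx(5.0, abs=1e-12)
    assert sd == pytest.approx(0.0, abs=1e-12)
    # antisymmetry
    m2, _ = scenario_delta_summary(fut, cur)
    assert m2 == pytest.approx(-5.0, abs=1e-12)
    # composition identity with continental_summary of the difference grid
    diff = cur.with_values(fut.values - cur.values)
    m3, s3 = continental_summary(WindowMap(diff, "delta"))
    assert (m3, s3) == (pytest.approx(mean), pytest.approx(sd))


def test_mask_before_vs_after_differencing(fixture_grids):
    """Masking commutes with scenario differencing on the unmasked set."""
    temp_c = fixture_grids["spring_temp_current"]
    temp_f = fixture_grids["spring_temp_future"]
    elev = fixture_grids["elevation"]
    forest = fixture_grids["forest_fraction"]
    wf = _summaries(145.0, -3.1, 0.02)
    tr = _summaries(150.0, -3.6, 0.02)
    maps = {}
    for scen, t in (("current", temp_c), ("future", temp_f)):
        ffd = predict_surface(wf, t, elev, "wildflower", "NA")
        lod = predict_surface(tr, t, elev, "tree", "NA")
        maps[scen] = light_window(ffd, lod)
    d_then_mask = mask_forest(delta_window(maps["current"], maps["future"]),
                              forest)
    mask_then_d = delta_window(mask_forest(maps["current"], forest),
                               mask_forest(maps["future"], forest))
    keep = d_then_mask.grid.mask_valid & mask_then_d.grid.mask_valid
    assert np.array_equal(d_then_mask.grid.mask_valid, mask_then_d.grid.mask_valid)
    assert np.allclose(d_then_mask.grid.values[keep],
                       mask_then_d.grid.values[keep], atol=1e-9)
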