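import numpy as np
import pandas as pd
import pytest

from coreniche.niche import (NicheLadder, clean_response, locate_optimum,
                             univariate_response, vif_screen)


# --------------------------------------------------------- clean_response

def test_clean_response_constant_removes_nothing():
    df = pd.DataFrame({"y": [0.2] * 40})
    out = clean_response(df, "y")
    assert len(out) == 40


def test_clean_response_drops_transformed_outlier():
    df = pd.DataFrame({"y": [0.1] * 34 + [0.9]})
    out = clean_response(df, "y")
    assert len(out) == 34
    assert (out["y"] == 0.1).all()


def test_clean_response_zero_maps_to_minus_four():
    df = pd.DataFrame({"y": [0.0] + [10 ** (-4 + i / 10) for i in range(40)]})
    out = clean_response(df, "y", min_samples=10)
    assert out["log_response"].iloc[0] == pytest.approx(np.log10(1e-4), abs=1e-6)


def test_clean_response_minimum_sample_guard():
    df = pd.DataFrame({"y": [0.1] * 10})
    with pytest.raises(ValueError, match="remain"):
        clean_response(df, "y")
    with pytest.raises(ValueError, match="non-negative"):
        clean_response(pd.DataFrame({"y": [-1.0] * 40}), "y")


# --------------------------------------------------------------- VIF

def test_vif_orthogonal_predictors():
    n = 64
    x = pd.DataFrame({"a": np.tile([1, -1], n // 2),
                      "b": np.repeat([1, -1], n // 2)}, dtype=float)
    vifs = vif_screen(x)
    assert vifs["a"] == pytest.approx(1.0)
    assert vifs["b"] == pytest.approx(1.0)


def test_vif_correlated_pair_closed_form():
    rng = np.random.default_rng(0)
    a = rng.normal(size=500)
    resid = rng.normal(size=500)
    resid -= np.polyval(np.polyfit(a, resid, 1), a)  # exactly orthogonal
    r = 0.9
    b = r * (a - a.mean()) / a.std() + np.sqrt(1 - r**2) * resid / resid.std()
    with pytest.warns(UserWarning, match="collinearity"):
        vifs = vif_screen(pd.DataFrame({"a": a, "b": b}))
    assert vifs["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)


def test_vif_duplicate_column_is_infinite():
    rng = np.random.default_rng(1)
    a = rng.normal(size=50)
    with pytest.warns(UserWarning):
        vifs = vif_screen(pd.DataFrame({"a": a, "b": a}))
    assert np.isinf(vifs["a"])


# ------------------------------------------------------ univariate fits

def test_univariate_exact_linear():
    x = np.linspace(0, 10, 30)
    fit = univariate_response(x, 3 * x + 1)
    assert fit.model == "linear"
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.coefficients[0] == pytest.approx(3.0)


def test_univariate_noiseless_parabola_vertex():
    x = np.linspace(-1, 5, 40)
    fit = univariate_response(x, (x - 2) ** 2)
    assert fit.model == "quadratic"
    assert fit.r_squared == pytest.approx(1.0)
    a, b, _ = fit.coefficients
    assert -b / (2 * a) == pytest.approx(2.0, abs=1e-8)


def test_univariate_slope_recovery():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 5, 100)
    y = 2 * x + rng.normal(0, 0.1, 100)
    fit = univariate_response(x, y)
    slope = fit.coefficients[-2]
    assert 1.9 <= slope <= 2.1


def test_univariate_guards():
    with pytest.raises(ValueError, match="10 points"):
        univariate_response([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError, match="constant"):
        univariate_response(np.ones(20), np.arange(20.0))


# ------------------------------------------------------------ the ladder

def _bowl_data(seed=0, n=200, interaction=0.0, noise=0.1):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "temperature": rng.uniform(10, 28, n),
        "DO": rng.uniform(2, 10, n),
        "NO3-N": rng.uniform(0.1, 2.0, n),
        "station": rng.choice([f"st{i}" for i in range(8)], n),
    })
    y = (-((df["temperature"] - 18) / 10) ** 2
         - ((df["DO"] - 3.5) / 6) ** 2
         - ((df["NO3-N"] - 0.64) / 1.0) ** 2
         + interaction * (df["temperature"] - 18) * (df["DO"] - 6) / 20
         + rng.normal(0, noise, n))
    df["log_response"] = y
    return df


def test_ladder_selection_has_minimum_aic_and_nesting():
    fit = NicheLadder(data=_bowl_data(seed=1)).fit()
    table = fit.aic_table()
    assert set(table.index) == {"M1", "M2", "M3", "M4"}
    converged = table[table["converged"]]
    assert fit.best.aic == pytest.approx(converged["aic"].min())
    assert table.loc[fit.selected, "selected"]


def test_ladder_optimum_recovery_noiseless_bowl():
    fit = NicheLadder(data=_bowl_data(seed=2, n=400, noise=0.0)).fit()
    opt, value, boundary = fit.locate_optimum(resolution=50)
    box = fit.evaluation_box()
    step = {v: (hi - lo) / 49 for v, (lo, hi) in box.items()}
    assert abs(opt["temperature"] - 18.0) <= step["temperature"] + 1e-9
    assert abs(opt["DO"] - 3.5) <= step["DO"] + 1e-9
    assert abs(opt["NO3-N"] - 0.64) <= step["NO3-N"] + 1e-9
    assert not any(boundary.values())


def test_locate_optimum_deterministic_and_refinement_consistent():
    fit = NicheLadder(data=_bowl_data(seed=3)).fit()
    opt1, _, _ = fit.locate_optimum(resolution=30)
    opt2, _, _ = fit.locate_optimum(resolution=30)
    assert opt1 == opt2
    opt_fine, _, _ = fit.locate_optimum(resolution=60)
    box = fit.evaluation_box()
    for v, (lo, hi) in box.items():
        coarse_step = (hi - lo) / 29
        assert abs(opt_fine[v] - opt1[v]) <= coarse_step + 1e-9


def test_monotone_response_hits_boundary_with_warning():
    df = _bowl_data(seed=4)
    df["log_response"] = 0.1 * df["temperature"] + 0.01 * np.random.default_rng(0).normal(size=len(df))
    fit = NicheLadder(data=df).fit()
    with pytest.warns(UserWarning, match="boundary"):
        opt, _, boundary = fit.locate_optimum(resolution=25)
    assert boundary["temperature"]
    box = fit.evaluation_box()
    assert opt["temperature"] == pytest.approx(box["temperature"][1])


def test_pairwise_surfaces_shapes():
    fit = NicheLadder(data=_bowl_data(seed=5)).fit()
    surfaces = fit.pairwise_surfaces(resolution=10)
    assert len(surfaces) == 3
    for (v1, v2), grid in surfaces.items():
        assert len(grid) == 100
        assert {"predicted", v1, v2} <= set(grid.columns)
    assert "selected" in fit.summary()
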