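import subprocess

import numpy as np
import pandas as pd
import pytest

from coreniche.drivers import (MantelResult, env_distance, geographic_distance,
                               hellinger, partial_mantel, rf_importance,
                               spearman_matrix, vpa)


def _categories():
    return {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1"]}


def _predictors(rng, n):
    return pd.DataFrame(rng.normal(size=(n, 5)),
                        columns=["a1", "a2", "b1", "b2", "c1"])


def _community_from(signal: np.ndarray, rng, n_taxa=12, noise=0.1):
    """Counts whose composition is driven by the given signal columns."""
    n = signal.shape[0]
    loadings = rng.normal(size=(signal.shape[1], n_taxa))
    eta = signal @ loadings + noise * rng.normal(size=(n, n_taxa))
    weights = np.exp(eta - eta.max(axis=1, keepdims=True))
    weights /= weights.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(2000, w) for w in weights])
    return pd.DataFrame(counts, columns=[f"T{j}" for j in range(n_taxa)])


# ----------------------------------------------------------------- VPA

def test_vpa_fractions_sum_to_one():
    rng = np.random.default_rng(0)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        x = _predictors(rng, 40)
        counts = _community_from(rng.normal(size=(40, 2)), rng)
        res = vpa(counts, x, _categories())
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in res.clamped.values())


def test_vpa_planted_single_category_signal():
    rng = np.random.default_rng(1)
    x = _predictors(rng, 60)
    counts = _community_from(x[["a1", "a2"]].to_numpy(), rng, noise=0.05)
    res = vpa(counts, x, _categories())
    total = res.marginal_adjusted_r2["ABC"]
    assert res.fractions["unique[A]"] == pytest.approx(total, abs=0.05)
    assert abs(res.fractions["unique[B]"]) < 0.05
    assert abs(res.fractions["unique[C]"]) < 0.05


def test_vpa_duplicated_category_forces_sharing():
    rng = np.random.default_rng(2)
    x = _predictors(rng, 60)
    x["b1"] = x["a1"] + 1e-6 * rng.normal(size=60)
    x["b2"] = x["a2"] + 1e-6 * rng.normal(size=60)
    counts = _community_from(x[["a1", "a2"]].to_numpy(), rng, noise=0.05)
    res = vpa(counts, x, _categories())
    assert abs(res.fractions["unique[A]"]) < 0.05
    assert abs(res.fractions["unique[B]"]) < 0.05
    assert res.fractions["shared[A&B]"] > 0.3


def test_vpa_all_noise_unique_fractions_center_on_zero():
    uniques = []
    for seed in range(300):
        rng = np.random.default_rng(seed)
        x = _predictors(rng, 30)
        counts = _community_from(rng.normal(size=(30, 2)), rng)
        res = vpa(counts, x, _categories())
        uniques.append([res.fractions["unique[A]"], res.fractions["unique[B]"],
                        res.fractions["unique[C]"]])
    means = np.mean(uniques, axis=0)
    assert np.all(np.abs(means) < 0.01)


def test_vpa_rank_deficient_block_named():
    rng = np.random.default_rng(3)
    x = _predictors(rng, 40)
    x["a2"] = 2 * x["a1"]
    counts = _community_from(rng.normal(size=(40, 2)), rng)
    with pytest.raises(ValueError, match="rank-deficient.*'A'"):
        vpa(counts, x, _categories())


def test_vpa_matches_vegan_varpart(tmp_path):
    """Independent oracle: vegan::varpart on the same Hellinger matrix."""
    rng = np.random.default_rng(7)
    x = _predictors(rng, 35)
    counts = _community_from(x[["a1", "b1"]].to_numpy(), rng)
    res = vpa(counts, x, _categories())

    y = pd.DataFrame(hellinger(counts))
    y.to_csv(tmp_path / "y.csv", index=False)
    x.to_csv(tmp_path / "x.csv", index=False)
    rscript = f"""
    y <- as.matrix(read.csv("{tmp_path}/y.csv"))
    x <- read.csv("{tmp_path}/x.csv")
    v <- vegan::varpart(y, x[,c("a1","a2")], x[,c("b1","b2")], x[,"c1",drop=FALSE])
    f <- v$part$indfract$Adj.R.square
    cat(paste(f, collapse=","))
    """
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, check=True)
    f = [float(v) for v in out.stdout.strip().split(",")]
    # vegan order: [a]=unique X1, [b]=unique X2, [c]=unique X3,
    # [d]=X1&X2, [e]=X2&X3, [f]=X1&X3, [g]=all, [h]=residual
    got = res.fractions
    keys = ["unique[A]", "unique[B]", "unique[C]", "shared[A&B]",
            "shared[B&C]", "shared[A&C]", "shared[all]", "residual"]
    np.testing.assert_allclose([got[k] for k in keys], f, atol=1e-6)


# ------------------------------------------------------------ Mantel

def test_partial_mantel_perfect_correlation():
    x = np.arange(10.0)
    d = env_distance(x)
    control = np.zeros_like(d)
    res = partial_mantel(d, d, control, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value <= 0.05


def test_partial_mantel_anticorrelation():
    x = np.arange(10.0)
    d = env_distance(x)
    reversed_d = d.max() - d
    np.fill_diagonal(reversed_d, 0.0)
    res = partial_mantel(reversed_d, d, None, n_perm=99, seed=0)
    assert res.r == pytest.approx(-1.0)


def test_simple_mantel_matches_skbio():
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel as skbio_mantel

    rng = np.random.default_rng(5)
    a = env_distance(rng.normal(size=12))
    b = env_distance(rng.normal(size=12))
    ours = partial_mantel(a, b, None, n_perm=99, seed=0)
    r_ref, _, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                               permutations=0)
    assert ours.r == pytest.approx(r_ref, abs=1e-10)


def test_mantel_p_floor_and_size_check():
    x = np.arange(8.0)
    d = env_distance(x)
    res = partial_mantel(d, d, None, n_perm=99, seed=1)
    assert res.p_value >= 1 / 100
    with pytest.raises(ValueError, match="size"):
        partial_mantel(d, env_distance(np.arange(5.0)), None)


def test_geographic_distance_sanity():
    d = geographic_distance([114.0, 115.0], [22.0, 22.0])
    assert d[0, 1] == pytest.approx(103.0, rel=0.02)  # ~1 deg lon at 22N


# ----------------------------------------------------- random forest

def test_rf_planted_signal_ranks_first():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.normal(size=(80, 8)),
                     columns=[f"v{j}" for j in range(7)] + ["temperature"])
    y = x["temperature"].to_numpy() + 0.1 * rng.normal(size=80)
    res = rf_importance(x, y, n_trees=150, n_null=60, seed=3)
    assert res.index[0] == "temperature"
    assert res.loc["temperature", "p_value"] <= 0.05
    assert sorted(res["rank"]) == list(range(1, 9))


def test_rf_reproducible_with_seed():
    rng = np.random.default_rng(1)
    x = pd.DataFrame(rng.normal(size=(40, 5)))
    x.columns = [f"v{j}" for j in range(5)]
    y = rng.normal(size=40)
    a = rf_importance(x, y, n_trees=60, n_null=20, seed=9)
    b = rf_importance(x, y, n_trees=60, n_null=20, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_rf_duplicated_predictor_keeps_signal_on_top():
    rng = np.random.default_rng(4)
    x = pd.DataFrame(rng.normal(size=(80, 6)),
                     columns=[f"v{j}" for j in range(5)] + ["temperature"])
    y = x["temperature"].to_numpy() + 0.1 * rng.normal(size=80)
    x2 = x.copy()
    x2["temperature_dup"] = x["temperature"]
    res = rf_importance(x2, y, n_trees=150, n_null=30, seed=5)
    assert res.index[0] in ("temperature", "temperature_dup")


def test_rf_input_validation():
    rng = np.random.default_rng(2)
    x = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match="degenerate"):
        rf_importance(x, np.ones(40), n_trees=10, n_null=5)
    with pytest.raises(ValueError, match="30 samples"):
        rf_importance(x.iloc[:10], rng.normal(size=10), n_trees=10, n_null=5)


# ------------------------------------------------------------ Spearman

def test_spearman_examples():
    x = np.linspace(0.1, 3.0, 20)
    env = pd.DataFrame({"x": x, "expx": np.exp(x), "negx": -x})
    rho, padj = spearman_matrix(env)
    assert rho.loc["x", "expx"] == pytest.approx(1.0)
    assert rho.loc["x", "negx"] == pytest.approx(-1.0)


def test_spearman_hand_rank_example():
    env = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
    rho, _ = spearman_matrix(env)
    assert rho.loc["x", "y"] == pytest.approx(0.8)


def test_spearman_constant_column_is_nan():
    env = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
    rho, padj = spearman_matrix(env)
    assert np.isnan(rho.loc["x", "c"])
    with pytest.raises(ValueError, match="3 samples"):
        spearman_matrix(env.iloc[:2])
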