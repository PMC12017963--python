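import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from coreniche.diversity import (alpha_diversity, bray_curtis, pcoa_lingoes,
                                 pcoa_permanova, seasonal_test, stars)
from coreniche.io import CommunityMatrix


def _cm(counts, seasons=None, stations=None):
    n = len(counts)
    df = pd.DataFrame(counts, index=[f"S{i}" for i in range(n)])
    df.columns = [f"T{j}" for j in range(df.shape[1])]
    meta = pd.DataFrame({
        "station": stations or [f"st{i}" for i in range(n)],
        "month": [(i % 12) + 1 for i in range(n)],
    }, index=df.index)
    if seasons is not None:
        meta["season"] = seasons
    return CommunityMatrix(df, meta)


# ------------------------------------------------------------ alpha

@pytest.mark.parametrize("row,h,rich", [
    ([10, 10, 10, 10], np.log(4), 4),
    ([20], 0.0, 1),
    ([1, 1, 2], 1.0397, 3),
])
def test_shannon_examples(row, h, rich):
    m = _cm([row, row])
    div = alpha_diversity(m)
    assert div["shannon"].iloc[0] == pytest.approx(h, abs=1e-4)
    assert div["richness"].iloc[0] == rich


def test_shannon_bounded_by_log_richness(small_survey):
    div = alpha_diversity(small_survey[0])
    ok = div["richness"] >= 1
    assert (div.loc[ok, "shannon"] <= np.log(div.loc[ok, "richness"]) + 1e-9).all()


def test_all_zero_sample_flagged():
    m = _cm([[0, 0, 0], [1, 2, 3]])
    div = alpha_diversity(m)
    assert div["flagged"].iloc[0]
    assert np.isnan(div["shannon"].iloc[0])


def test_star_encoding():
    assert stars(0.0005) == "***"
    assert stars(0.005) == "**"
    assert stars(0.04) == "*"
    assert stars(0.2) == ""


# ---------------------------------------------------------- seasonal test

def test_identical_groups_no_stars():
    vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    seasons = pd.Series(["winter"] * 3 + ["summer"] * 3)
    out = seasonal_test(vals, seasons)
    assert out["omnibus_p"] > 0.5
    assert (out["pairwise"]["stars"] == "").all()


def test_small_groups_cannot_reach_significance():
    vals = pd.Series([1, 2, 3, 101, 102, 103], dtype=float)
    seasons = pd.Series(["w"] * 3 + ["s"] * 3)
    out = seasonal_test(vals, seasons)
    # smallest attainable two-sided rank-sum p for n=3,3 is 0.1
    assert out["pairwise"]["p_raw"].iloc[0] == pytest.approx(0.1, abs=0.01)
    assert (out["pairwise"]["stars"] == "").all()


def test_omnibus_p_uniform_under_null():
    rng = np.random.default_rng(17)
    pvals = []
    for _ in range(1000):
        vals = pd.Series(rng.normal(size=15))
        seasons = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        pvals.append(seasonal_test(vals, seasons)["omnibus_p"])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_sparse_season_excluded():
    vals = pd.Series([1.0, 2.0, 3.0, 4.0, 9.0])
    seasons = pd.Series(["w", "w", "s", "s", "lonely"])
    out = seasonal_test(vals, seasons)
    groups = set(out["pairwise"][["group_a", "group_b"]].to_numpy().ravel())
    assert "lonely" not in groups


# ------------------------------------------------------- PCoA / PERMANOVA

def test_pcoa_reproduces_euclidean_configuration():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(10, 2))
    d = squareform(pdist(pts))
    coords, eigval, explained, c = pcoa_lingoes(d, n_axes=2)
    assert c == 0.0  # Euclidean input needs no correction
    np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-8)
    # agrees with scikit-bio's PCoA on the same matrix
    from skbio.stats.ordination import pcoa as skbio_pcoa
    ref = skbio_pcoa(d, dimensions=2)
    np.testing.assert_allclose(
        np.abs(coords), np.abs(ref.samples.to_numpy()[:, :2]), atol=1e-6)


def test_lingoes_correction_applied_for_noneuclidean():
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 20, size=(8, 12))
    counts[:, 0] += 1
    d = bray_curtis(pd.DataFrame(counts))
    _, eigval_unc, _, _ = pcoa_lingoes(d)  # first call may or may not correct
    # uncorrected eigenvalues
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    raw = np.linalg.eigvalsh(j @ (-0.5 * d**2) @ j)
    if raw.min() < -1e-10:
        coords, eigval, _, c = pcoa_lingoes(d)
        assert c > 0
        assert eigval.sum() >= raw[raw > 0].sum() - 1e-8
        assert eigval.min() >= -1e-8


def test_permanova_no_structure_gives_f_near_zero():
    # the same two profiles duplicated into both groups: no between-group
    # structure, exact enumeration fallback engaged
    a, b = [10, 0, 5], [0, 10, 5]
    m = _cm([a, b, a, b, a, b, a, b],
            seasons=["w", "w", "w", "w", "s", "s", "s", "s"])
    out = pcoa_permanova(m, n_perm=999, seed=0)
    assert out["pseudo_F"] == pytest.approx(0.0, abs=1e-9)
    assert out["p_value"] > 0.9


def test_permanova_separated_clusters_hits_floor():
    rng = np.random.default_rng(8)
    g1 = rng.poisson(20, size=(10, 15))
    g2 = rng.poisson(20, size=(10, 15))
    g2[:, :7] += 60  # clear compositional shift
    m = _cm(np.vstack([g1, g2]), seasons=["w"] * 10 + ["s"] * 10)
    out = pcoa_permanova(m, n_perm=999, seed=1)
    assert out["p_value"] == pytest.approx(0.001)


def test_permanova_seed_invariant_to_sample_order():
    rng = np.random.default_rng(9)
    counts = rng.poisson(15, size=(12, 10))
    seasons = ["w"] * 6 + ["s"] * 6
    m = _cm(counts, seasons=seasons)
    out1 = pcoa_permanova(m, n_perm=99, seed=5)
    perm = rng.permutation(12)
    m2 = CommunityMatrix(m.counts.iloc[perm], m.metadata.iloc[perm])
    out2 = pcoa_permanova(m2, n_perm=99, seed=5)
    assert out1["pseudo_F"] == pytest.approx(out2["pseudo_F"])


def test_permanova_needs_two_groups():
    m = _cm([[1, 2], [2, 1]], seasons=["w", "w"])
    with pytest.raises(ValueError, match="2 groups"):
        pcoa_permanova(m)
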