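import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreniche.core import (ContributionCurve, compute_occupancy, contribution_curve,
                            core_fraction, select_core)
from coreniche.io import CommunityMatrix


def _cm(counts: np.ndarray) -> CommunityMatrix:
    n, t = counts.shape
    df = pd.DataFrame(counts, index=[f"S{i}" for i in range(n)],
                      columns=[f"T{j}" for j in range(t)])
    meta = pd.DataFrame({"station": [f"st{i % 4}" for i in range(n)],
                         "month": [(i % 12) + 1 for i in range(n)]},
                        index=df.index)
    return CommunityMatrix(df, meta)


def brute_force_curve(counts: np.ndarray, ranking_idx: list[int]) -> np.ndarray:
    """Independent oracle: direct pairwise loops over sample pairs."""
    n, t = counts.shape
    def sim_sum(cols):
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                num = sum(min(counts[i, c], counts[j, c]) for c in cols)
                total += 2.0 * num / (counts[i].sum() + counts[j].sum())
        return total
    full = sim_sum(range(t))
    return np.array([sim_sum(ranking_idx[:k]) / full for k in range(1, t + 1)])


# ----------------------------------------------------------- occupancy

def test_occupancy_full_presence(tiny_community):
    occ = compute_occupancy(tiny_community)
    # taxa A, B, D occur in every sample
    for taxon in ("A", "B", "D"):
        assert occ.loc[taxon, "overall_occupancy"] == 1.0
        assert occ.loc[taxon, "temporal_occupancy"] == 1.0


def test_temporal_occupancy_half():
    counts = np.zeros((12, 2), dtype=int)
    counts[:, 1] = 1
    counts[:6, 0] = 3  # taxon 0 present in all stations of 6 of 12 months
    df = pd.DataFrame(counts, index=[f"S{i}" for i in range(12)],
                      columns=["X", "Y"])
    meta = pd.DataFrame({"station": ["st1"] * 12, "month": list(range(1, 13))},
                        index=df.index)
    occ = compute_occupancy(CommunityMatrix(df, meta))
    assert occ.loc["X", "temporal_occupancy"] == 0.5


def test_tie_break_by_abundance():
    counts = pd.DataFrame({"lo": [1, 1], "hi": [2, 2]}, index=["S1", "S2"])
    meta = pd.DataFrame({"station": ["a", "b"], "month": [1, 1]},
                        index=counts.index)
    occ = compute_occupancy(CommunityMatrix(counts, meta))
    assert occ.index[0] == "hi"  # identical occupancies; 2/3 > 1/3 abundance


def test_ranks_are_permutation(small_survey):
    m = small_survey[0]
    occ = compute_occupancy(m)
    assert sorted(occ["rank"]) == list(range(1, m.n_taxa + 1))
    assert occ["overall_occupancy"].between(0, 1).all()


# ---------------------------------------------------- contribution curve

def test_curve_hand_example():
    m = _cm(np.array([[8, 2], [6, 4]]))
    curve = contribution_curve(m, ["T0", "T1"])
    # full sim = 2*(6+2)/20 = 0.8; top-1 sim = 2*6/20 = 0.6
    assert curve.contribution == pytest.approx([0.75, 1.0], abs=1e-12)


def test_curve_single_taxon():
    m = _cm(np.array([[5], [3]]))
    curve = contribution_curve(m, ["T0"])
    assert curve.contribution == pytest.approx([1.0])


def test_curve_matches_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = rng.integers(0, 20, size=(6, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        m = _cm(counts)
        ranking = list(rng.permutation(m.taxon_ids))
        got = contribution_curve(m, ranking).contribution
        idx = [m.taxon_ids.index(t) for t in ranking]
        expected = brute_force_curve(counts.astype(float), idx)
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_curve_invariant_to_taxon_column_order():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 15, size=(5, 6))
    counts[:, 0] += 1
    m = _cm(counts)
    ranking = list(rng.permutation(m.taxon_ids))
    c1 = contribution_curve(m, ranking).contribution
    perm = rng.permutation(m.n_taxa)
    m2 = CommunityMatrix(m.counts.iloc[:, perm], m.metadata)
    c2 = contribution_curve(m2, ranking).contribution
    np.testing.assert_allclose(c1, c2, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_curve_nondecreasing_and_ends_at_one(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 30, size=(4, 7))
    counts[counts.sum(axis=1) == 0, 0] = 1
    m = _cm(counts)
    curve = contribution_curve(m, m.taxon_ids)
    assert np.all(np.diff(curve.contribution) >= -1e-12)
    assert curve.contribution[-1] == pytest.approx(1.0, abs=1e-9)


def test_curve_needs_two_samples():
    m = _cm(np.array([[1, 2]]))
    with pytest.raises(ValueError, match="2 samples"):
        contribution_curve(m, m.taxon_ids)


# ----------------------------------------------------------- select_core

def _curve_from(c):
    c = np.asarray(c, float)
    gains = np.concatenate([[np.nan], np.diff(c) / c[:-1]])
    return ContributionCurve([f"T{i}" for i in range(len(c))], c, gains)


def test_select_core_hand_gains():
    curve = _curve_from([0.60, 0.75, 0.90, 0.905, 0.906])
    assert select_core(curve, 0.01) == ["T0", "T1", "T2"]
    assert select_core(curve, 0.20) == ["T0", "T1"]


def test_select_core_flat_curve_falls_back_to_top1():
    curve = _curve_from([0.7, 0.7, 0.7])
    with pytest.warns(UserWarning, match="top-1"):
        assert select_core(curve, 0.01) == ["T0"]


def test_select_core_rejects_nonpositive_gain():
    with pytest.raises(ValueError):
        select_core(_curve_from([0.5, 1.0]), 0.0)


# ---------------------------------------------------------- core_fraction

@pytest.mark.parametrize("core,total,expected", [
    (912, 5416, 16.8),
    (1, 1, 100.0),
    (1, 3, 33.3),
    (1, 8, 12.5),
])
def test_core_fraction(core, total, expected):
    assert core_fraction(core, total) == expected


def test_core_fraction_rejects_bad_inputs():
    with pytest.raises(ValueError):
        core_fraction(1, 0)
    with pytest.raises(ValueError):
        core_fraction(5, 3)
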