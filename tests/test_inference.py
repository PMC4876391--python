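import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elevbeta import (
    PlotMetadata,
    SimilarityMatrix,
    ValidationError,
    dissimilarity_from,
    distance_decay_fit,
    pairwise_permanova,
    permanova,
)


def _block_distance(n_per_group, n_groups, within, between):
    n = n_per_group * n_groups
    d = np.full((n, n), between, dtype=float)
    for g in range(n_groups):
        sl = slice(g * n_per_group, (g + 1) * n_per_group)
        d[sl, sl] = within
    np.fill_diagonal(d, 0.0)
    labels = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    return d, labels


def test_pseudo_f_hand_example():
    d, labels = _block_distance(2, 2, within=0.2, between=1.0)
    res = permanova(d, labels, n_permutations=99, seed=0)
    assert res.pseudo_F == pytest.approx(49.0)
    assert res.ss_total == pytest.approx(1.02)
    assert res.ss_among == pytest.approx(0.98)
    assert res.ss_within == pytest.approx(0.04)
    assert (res.df_among, res.df_within) == (1, 2)


def test_equal_distances_give_unit_pseudo_f():
    d = 1.0 - np.eye(4)
    res = permanova(d, ["a", "a", "b", "b"], n_permutations=99, seed=0)
    assert res.pseudo_F == pytest.approx(1.0)
    assert res.ss_among == pytest.approx(0.5)


def test_ss_decomposition_identity_and_relabel_invariance():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    labels = np.repeat(["a", "b", "c"], 4)
    res = permanova(d, labels, n_permutations=49, seed=1)
    assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)
    # relabelling plots (rows/cols + labels together) leaves pseudo-F unchanged
    perm = rng.permutation(12)
    res2 = permanova(d[np.ix_(perm, perm)], labels[perm], n_permutations=49, seed=1)
    assert res2.pseudo_F == pytest.approx(res.pseudo_F)


def test_permutation_p_value_floor():
    d, labels = _block_distance(4, 3, within=0.1, between=1.0)
    res = permanova(d, labels, n_permutations=199, seed=3)
    assert res.p_value >= 1.0 / (res.n_permutations + 1)


def test_permanova_matches_independent_implementation():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(7)
    pts = rng.normal(size=(15, 4))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    labels = np.repeat(["a", "b", "c"], 5)
    ours = permanova(d, labels, n_permutations=99, seed=0)
    theirs = skbio_permanova(DistanceMatrix(d), grouping=list(labels), permutations=99)
    assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_null_p_values_are_uniform():
    """With random group labels on structureless distances the permutation p
    is uniform on its grid (Kolmogorov-Smirnov over repeated draws)."""
    rng = np.random.default_rng(11)
    pvals = []
    for _ in range(150):
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = rng.permutation(np.repeat(["a", "b", "c"], 4))
        pvals.append(
            permanova(d, labels, n_permutations=99, seed=rng.integers(2**31)).p_value
        )
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_permanova_input_validation():
    d, labels = _block_distance(2, 2, 0.2, 1.0)
    with pytest.raises(ValidationError, match="fewer than 2"):
        permanova(d, ["a", "a", "a", "b"], n_permutations=9)
    bad = d.copy()
    bad[0, 1] = 0.5
    with pytest.raises(ValidationError, match="symmetric"):
        permanova(bad, labels, n_permutations=9)


def test_pairwise_permanova_structure():
    d, labels = _block_distance(5, 4, within=0.2, between=1.0)
    table = pairwise_permanova(d, labels, n_permutations=999, seed=5)
    assert len(table) == 6
    assert (table["t"] > 0).all()
    assert (table["p_bonferroni"] >= table["p_value"]).all()


def test_pairwise_permanova_identical_groups_not_significant():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(5, 3))
    pts = np.vstack([pts, pts])  # second band duplicates the first
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    labels = np.repeat(["low", "high"], 5)
    table = pairwise_permanova(d, labels, n_permutations=999, seed=0)
    assert table["p_value"].iloc[0] > 0.5


def _sim_from(values: np.ndarray, ids, index_name="sorensen") -> SimilarityMatrix:
    return SimilarityMatrix(
        values=pd.DataFrame(values, index=ids, columns=ids),
        index_name=index_name,
        species_scope="common",
    )


def _meta(ids, elevations):
    return PlotMetadata(
        pd.DataFrame(
            {
                "plot_id": ids,
                "transect": "T1",
                "band": [str(int(e // 100) * 100) for e in elevations],
                "elevation_m": elevations,
            }
        )
    )


def test_decay_fit_recovers_exact_linear_relationship():
    ids = [f"p{i}" for i in range(5)]
    elev = [800.0, 950.0, 1100.0, 1250.0, 1400.0]
    values = np.ones((5, 5))
    for i, j in itertools.combinations(range(5), 2):
        values[i, j] = values[j, i] = 0.9 - 0.0005 * abs(elev[i] - elev[j])
    fit = distance_decay_fit(_sim_from(values, ids), _meta(ids, elev))
    assert fit.slope == pytest.approx(-0.0005)
    assert fit.intercept == pytest.approx(0.9)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.n_pairs == 10


def test_decay_fit_constant_similarity_convention():
    ids = [f"p{i}" for i in range(4)]
    elev = [800.0, 900.0, 1000.0, 1200.0]
    values = np.full((4, 4), 0.4)
    np.fill_diagonal(values, 1.0)
    fit = distance_decay_fit(_sim_from(values, ids), _meta(ids, elev))
    assert fit.slope == 0.0
    assert fit.r_squared == 0.0


def test_decay_fit_matches_two_pass_ols_formula():
    rng = np.random.default_rng(9)
    ids = [f"p{i}" for i in range(8)]
    elev = rng.uniform(800, 1400, size=8).tolist()
    values = np.ones((8, 8))
    for i, j in itertools.combinations(range(8), 2):
        values[i, j] = values[j, i] = rng.uniform(0, 1)
    fit = distance_decay_fit(_sim_from(values, ids), _meta(ids, elev))
    x = np.array([abs(elev[i] - elev[j]) for i, j in itertools.combinations(range(8), 2)])
    y = np.array([values[i, j] for i, j in itertools.combinations(range(8), 2)])
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert fit.slope == pytest.approx(slope)
    assert fit.intercept == pytest.approx(y.mean() - slope * x.mean())


def test_decay_fit_needs_elevation_spread():
    ids = ["p1", "p2", "p3"]
    values = np.full((3, 3), 0.5)
    np.fill_diagonal(values, 1.0)
    with pytest.raises(ValidationError, match="distinct"):
        distance_decay_fit(_sim_from(values, ids), _meta(ids, [800.0, 800.0, 800.0]))


def test_decay_fit_refuses_raup_crick_unless_forced():
    ids = [f"p{i}" for i in range(4)]
    elev = [800.0, 900.0, 1100.0, 1400.0]
    values = np.full((4, 4), 0.5)
    np.fill_diagonal(values, 1.0)
    sim = _sim_from(values, ids, index_name="raup_crick")
    with pytest.raises(ValidationError, match="non-metric"):
        distance_decay_fit(sim, _meta(ids, elev))
    fit = distance_decay_fit(sim, _meta(ids, elev), force=True)
    assert fit.slope == 0.0


def test_raup_crick_dissimilarity_conversion_warns():
    ids = ["p1", "p2"]
    values = np.array([[np.nan, 0.3], [0.3, np.nan]])
    sim = _sim_from(values, ids, index_name="raup_crick")
    with pytest.warns(UserWarning, match="non-metric"):
        d = dissimilarity_from(sim)
    assert d.loc["p1", "p2"] == pytest.approx(0.7)
    assert d.loc["p1", "p1"] == 0.0
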