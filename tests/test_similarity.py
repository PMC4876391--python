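import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from elevbeta import (
    CommunityMatrix,
    PlotMetadata,
    ValidationError,
    bray_curtis,
    chao_sorensen_estimated,
    pairwise_matrix,
    raup_crick,
    sorensen,
)
from elevbeta.similarity import INDEX_SCOPES


# -- Sørensen ---------------------------------------------------------------


def test_sorensen_examples():
    assert sorensen({"X", "Y"}, {"X", "Y"}) == 1.0
    assert sorensen({"X", "Y"}, {"X"}) == pytest.approx(2 / 3)
    assert sorensen({"X"}, {"Y"}) == 0.0


def test_sorensen_empty_sets_warn_and_return_zero():
    with pytest.warns(UserWarning):
        assert sorensen(set(), set()) == 0.0


# -- Bray–Curtis ------------------------------------------------------------


def test_bray_curtis_examples():
    assert bray_curtis([0.3, 0.1], [0.3, 0.1]) == pytest.approx(1.0)
    assert bray_curtis([0.5, 0.0], [0.0, 0.5]) == 0.0
    assert bray_curtis([0.4, 0.2], [0.2, 0.2]) == pytest.approx(0.8)


def test_bray_curtis_rejects_negative_proportions():
    with pytest.raises(ValidationError):
        bray_curtis([0.2, -0.1], [0.1, 0.1])


# -- Chao–Sørensen ----------------------------------------------------------


def test_chao_sorensen_examples():
    assert chao_sorensen_estimated([4, 0], 4, [0, 3], 3) == 0.0
    assert chao_sorensen_estimated([4, 1], 5, [4, 1], 5) == pytest.approx(1.0)
    # shared species is neither singleton nor doubleton: no correction terms
    assert chao_sorensen_estimated([4, 1, 0], 5, [3, 0, 2], 5) == pytest.approx(
        2 * 0.8 * 0.6 / 1.4
    )


@pytest.mark.parametrize("seed", range(5))
def test_chao_sorensen_reduces_to_classic_estimator_without_rare_shared(seed):
    """When no shared species is a singleton or doubleton in the other plot,
    the correction vanishes and the index equals 2UV/(U+V) with U, V the
    observed shared proportions."""
    rng = np.random.default_rng(seed)
    x = rng.integers(3, 9, size=6)
    y = rng.integers(3, 9, size=6)
    x[rng.integers(0, 6)] = 0  # some unshared structure
    n, m = int(x.sum()) + 5, int(y.sum()) + 5
    shared = (x > 0) & (y > 0)
    u = x[shared].sum() / n
    v = y[shared].sum() / m
    expected = 0.0 if u + v == 0 else 2 * u * v / (u + v)
    assert chao_sorensen_estimated(x, n, y, m) == pytest.approx(expected)


# -- Raup–Crick -------------------------------------------------------------


def test_raup_crick_examples():
    assert raup_crick(set(), {"X"}, 4) == 0.0
    assert raup_crick({"X"}, {"X"}, 2) == pytest.approx(0.5)
    with pytest.warns(UserWarning, match="degenerate"):
        assert raup_crick({"X", "Y"}, {"X", "Y"}, 2) == 0.0


@pytest.mark.parametrize("seed", range(6))
def test_raup_crick_matches_full_enumeration(seed):
    """For pools of ≤ 8 species the hypergeometric closed form must equal the
    exhaustive average over all equally likely draw pairs."""
    rng = np.random.default_rng(seed)
    pool = list(range(int(rng.integers(3, 9))))
    na, nb = rng.integers(1, len(pool) + 1, size=2)
    a = set(rng.choice(pool, size=na, replace=False).tolist())
    b = set(rng.choice(pool, size=nb, replace=False).tolist())
    j_obs = len(a & b)
    draws_a = list(itertools.combinations(pool, len(a)))
    draws_b = list(itertools.combinations(pool, len(b)))
    less = sum(
        len(set(da) & set(db)) < j_obs for da in draws_a for db in draws_b
    )
    expected = less / (len(draws_a) * len(draws_b))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate full-pool draws may warn
        assert raup_crick(a, b, len(pool)) == pytest.approx(expected)


# -- symmetry (all four) ----------------------------------------------------

vectors = st.lists(st.integers(min_value=0, max_value=6), min_size=3, max_size=6)


@given(x=vectors, y=vectors)
def test_indices_are_symmetric(x, y):
    k = min(len(x), len(y))
    x, y = np.array(x[:k]), np.array(y[:k])
    a = {i for i in range(k) if x[i] > 0}
    b = {i for i in range(k) if y[i] > 0}
    if a or b:
        assert sorensen(a, b) == pytest.approx(sorensen(b, a))
    n = int(x.sum()) + 1
    m = int(y.sum()) + 1
    assert chao_sorensen_estimated(x, n, y, m) == pytest.approx(
        chao_sorensen_estimated(y, m, x, n)
    )
    assert raup_crick(a, b, k) == pytest.approx(raup_crick(b, a, k))
    if x.sum() + y.sum() > 0:
        assert bray_curtis(x / n, y / m) == pytest.approx(bray_curtis(y / m, x / n))


# -- matrix assembly --------------------------------------------------------


def test_pairwise_matrix_covers_all_unordered_pairs():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(0, 20, size=(20, 8)),
        index=[f"p{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(8)],
    )
    m = CommunityMatrix(counts)
    sim = pairwise_matrix(m, "sorensen", common_species=m.species_ids)
    assert len(sim.condensed_pairs()) == 190
    off = sim.values.to_numpy()[~np.eye(20, dtype=bool)]
    assert ((off >= 0) & (off <= 1)).all()


def test_identical_plots_have_similarity_one():
    counts = pd.DataFrame({"A": [3, 3], "B": [1, 1]}, index=["p1", "p2"])
    m = CommunityMatrix(counts)
    sim = pairwise_matrix(m, "sorensen", common_species=m.species_ids)
    assert sim.values.loc["p1", "p2"] == 1.0


@pytest.mark.parametrize("index_name", sorted(INDEX_SCOPES))
def test_pairwise_matrix_equals_per_pair_recomputation(index_name):
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(
        rng.integers(0, 12, size=(4, 6)),
        index=[f"p{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    m = CommunityMatrix(counts)
    common = [s for s in m.species_ids if m.species_totals[s] >= 5]
    sim = pairwise_matrix(m, index_name, common_species=common)
    totals = m.plot_totals
    recorded = [s for s in m.species_ids if m.species_totals[s] > 0]
    for i, j in itertools.combinations(range(4), 2):
        pi, pj = f"p{i}", f"p{j}"
        if index_name == "sorensen":
            a = {s for s in common if counts.loc[pi, s] > 0}
            b = {s for s in common if counts.loc[pj, s] > 0}
            expected = sorensen(a, b) if (a or b) else 0.0
        elif index_name == "bray_curtis":
            p = counts.loc[pi, common].to_numpy() / totals[pi]
            q = counts.loc[pj, common].to_numpy() / totals[pj]
            expected = bray_curtis(p, q)
        elif index_name == "chao_sorensen":
            expected = chao_sorensen_estimated(
                counts.loc[pi], int(totals[pi]), counts.loc[pj], int(totals[pj])
            )
        else:
            a = {s for s in recorded if counts.loc[pi, s] > 0}
            b = {s for s in recorded if counts.loc[pj, s] > 0}
            expected = raup_crick(a, b, len(recorded))
        assert sim.values.loc[pi, pj] == pytest.approx(expected)


def test_pairwise_matrix_refuses_mixed_transects():
    counts = pd.DataFrame({"A": [1, 2]}, index=["p1", "p2"])
    meta = PlotMetadata(
        pd.DataFrame(
            {
                "plot_id": ["p1", "p2"],
                "transect": ["T1", "T2"],
                "band": "800",
                "elevation_m": 800.0,
            }
        )
    )
    with pytest.raises(ValidationError, match="transect"):
        pairwise_matrix(
            CommunityMatrix(counts), "sorensen", metadata=meta, common_species=["A"]
        )


def test_raup_crick_diagonal_flagged_invalid():
    counts = pd.DataFrame({"A": [1, 2], "B": [0, 1]}, index=["p1", "p2"])
    m = CommunityMatrix(counts)
    sim = pairwise_matrix(m, "raup_crick")
    assert not sim.diagonal_valid
    assert np.isnan(sim.values.loc["p1", "p1"])
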