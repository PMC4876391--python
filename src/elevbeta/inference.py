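"""Elevational stratification tests and distance-decay regression.

PERMANOVA (permutational multivariate analysis of variance) tests whether
assemblage composition differs among elevational bands.  From a plots ×
plots dissimilarity matrix ``d`` with ``N`` plots in ``a`` groups,

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²_ij
    pseudo-F  = (SS_among / (a − 1)) / (SS_within / (N − a)),

with SS_among = SS_total − SS_within.  The p-value comes from unrestricted
permutation of plot-to-group labels, counting the observed statistic once:
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations).  For a one-way design
this Type-III decomposition coincides with the sequential one.

The distance-decay regression quantifies elevational sensitivity as the OLS
slope of pairwise similarity on pairwise elevation difference (metres):
steeper negative slopes mean faster compositional turnover with elevation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import PlotMetadata, ValidationError
from .similarity import SimilarityMatrix

__all__ = [
    "PermanovaResult",
    "DecayFit",
    "permanova",
    "pairwise_permanova",
    "distance_decay_fit",
    "dissimilarity_from",
]


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_among: int
    df_within: int
    p_value: float
    n_permutations: int
    ss_total: float
    ss_among: float
    ss_within: float

    def to_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_F,
            "df_among": self.df_among,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "ss_total": self.ss_total,
            "ss_among": self.ss_among,
            "ss_within": self.ss_within,
        }


@dataclass
class DecayFit:
    """OLS fit of similarity on Δelevation over all within-transect pairs."""

    slope: float  # similarity units per metre
    intercept: float
    r_squared: float
    n_pairs: int
    index_name: str = ""
    mantel_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_pairs": self.n_pairs,
            "index_name": self.index_name,
        }
        if self.mantel_p is not None:
            d["mantel_p"] = self.mantel_p
        return d


def dissimilarity_from(sim: SimilarityMatrix) -> pd.DataFrame:
    """Convert a similarity matrix to d = 1 − s for PERMANOVA/ordination.

    Raup–Crick values are probabilities, not a metric; they are accepted with
    a warning since stratification tests on them are still interpretable as
    tests of exchangeability.
    """
    if sim.index_name == "raup_crick":
        warnings.warn(
            "Raup–Crick is a non-metric probabilistic measure; PERMANOVA on "
            "1 − RC is a pragmatic convention",
            stacklevel=2,
        )
    return sim.to_dissimilarity()


def _validate_square(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be symmetric")
    return d


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        block = d2[np.ix_(idx, idx)]
        ss += block.sum() / (2.0 * len(idx))  # full block double-counts i<j
    return ss


def _n_arrangements(sizes: np.ndarray) -> float:
    """Number of distinct assignments of labelled plots to groups of these sizes."""
    from math import comb

    total, n = 1.0, int(sizes.sum())
    for s in sizes:
        total *= comb(n, int(s))
        n -= int(s)
    return total


def _iter_arrangements(sizes: np.ndarray):
    """Yield every distinct group-code vector with the given group sizes."""
    from itertools import combinations

    n = int(sizes.sum())

    def rec(remaining: tuple[int, ...], g: int, codes: np.ndarray):
        if g == len(sizes) - 1:
            codes[list(remaining)] = g
            yield codes
            return
        for chosen in combinations(remaining, int(sizes[g])):
            codes[list(chosen)] = g
            rest = tuple(i for i in remaining if i not in set(chosen))
            yield from rec(rest, g + 1, codes)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 4999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    ``groups`` is a sequence of group labels aligned with the matrix rows.
    Every group needs at least two plots.  The permutation p-value counts the
    observed labelling once, so p ≥ 1 / (n_permutations + 1).

    When the number of distinct plot-to-group assignments does not exceed
    ``n_permutations`` the test is exact: all assignments are enumerated and
    p = #{F ≥ F_obs} / #assignments (the observed assignment is in the
    enumeration).  This mirrors how permutation software handles small
    designs, where random sampling would merely resample a handful of unique
    permutations.
    """
    d = _validate_square(dist)
    labels = np.asarray(list(groups))
    if len(labels) != d.shape[0]:
        raise ValidationError("groups length must match the matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = uniq[sizes < 2].tolist()
        raise ValidationError(f"group(s) with fewer than 2 plots: {small}")
    n = d.shape[0]
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, a)
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, n - a
    denom = ss_within / df_within
    f_obs = np.inf if denom == 0 else (ss_among / df_among) / denom

    def f_of(codes_perm: np.ndarray) -> float:
        ssw = _ss_within(d2, codes_perm, a)
        ssw_ms = ssw / df_within
        return np.inf if ssw_ms == 0 else ((ss_total - ssw) / df_among) / ssw_ms

    n_arr = _n_arrangements(sizes)
    if n_arr <= n_permutations:
        # exact test over every distinct assignment (observed one included)
        count_ge = sum(1 for c in _iter_arrangements(sizes) if f_of(c) >= f_obs - 1e-12)
        p = count_ge / n_arr
        n_effective = int(n_arr)
    else:
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if f_of(codes[perm]) >= f_obs - 1e-12:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_permutations)
        n_effective = n_permutations
    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_among=df_among,
        df_within=df_within,
        p_value=p,
        n_permutations=n_effective,
        ss_total=float(ss_total),
        ss_among=float(ss_among),
        ss_within=float(ss_within),
    )


def pairwise_permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 4999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Post hoc band-pair comparisons: t = √pseudo-F on each two-band submatrix.

    Each pair gets its own permutation p; raw p-values are reported alongside
    a Bonferroni-adjusted column.
    """
    d = _validate_square(dist)
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("pairwise comparisons need at least two groups")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(uniq) * (len(uniq) - 1) // 2)
    rows = []
    for k, (g1, g2) in enumerate(itertools.combinations(uniq, 2)):
        idx = np.flatnonzero((labels == g1) | (labels == g2))
        sub = d[np.ix_(idx, idx)]
        res = permanova(
            sub, labels[idx], n_permutations=n_permutations, seed=child_seeds[k]
        )
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                # non-metric dissimilarities can push F slightly negative
                "t": float(np.sqrt(max(res.pseudo_F, 0.0))),
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * len(out))
    return out


def distance_decay_fit(
    sim: SimilarityMatrix,
    metadata: PlotMetadata,
    force: bool = False,
    mantel_permutations: int = 0,
    seed: int | None = None,
) -> DecayFit:
    """OLS of pairwise similarity on pairwise elevation difference.

    Plot pairs are treated as independent observations, as is conventional
    for descriptive decay regressions; set ``mantel_permutations`` > 0 for an
    additional Mantel-style permutation p on the slope.  Raup–Crick input is
    refused unless ``force=True`` — it is a non-metric probabilistic measure
    for which a linear decay fit is not meaningful.
    """
    if sim.index_name == "raup_crick" and not force:
        raise ValidationError(
            "distance-decay regression on Raup–Crick values is refused "
            "(non-metric probabilistic index); pass force=True to override"
        )
    elev = metadata.elevations()
    ids = sim.plot_ids
    missing = [p for p in ids if p not in elev.index]
    if missing:
        raise ValidationError(f"plots without elevation metadata: {missing}")
    e = elev.loc[ids].to_numpy(dtype=float)
    pairs = list(itertools.combinations(range(len(ids)), 2))
    x = np.array([abs(e[i] - e[j]) for i, j in pairs])
    y = np.array([sim.values.iat[i, j] for i, j in pairs])
    if len(np.unique(x)) < 3:
        raise ValidationError(
            "need at least 3 distinct elevation differences for a decay fit"
        )
    if np.allclose(y, y[0]):
        fit = DecayFit(0.0, float(y[0]), 0.0, len(pairs), sim.index_name)
    else:
        res = stats.linregress(x, y)
        fit = DecayFit(
            float(res.slope),
            float(res.intercept),
            float(res.rvalue**2),
            len(pairs),
            sim.index_name,
        )
    if mantel_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = abs(fit.slope)
        count = 0
        n = len(ids)
        for _ in range(mantel_permutations):
            perm = rng.permutation(n)
            xp = np.array([abs(e[perm[i]] - e[perm[j]]) for i, j in pairs])
            if np.allclose(y, y[0]):
                sp = 0.0
            else:
                sp = abs(stats.linregress(xp, y).slope)
            if sp >= obs - 1e-15:
                count += 1
        fit.mantel_p = (1 + count) / (1 + mantel_permutations)
    return fit
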