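"""Pairwise assemblage similarity indices.

Four complementary views of compositional similarity between two plots:

* ``sorensen`` — presence/absence: 2a / (2a + b + c), computed on common
  species only.
* ``bray_curtis`` — quantitative: 2·Σ min(p_k, q_k) / Σ (p_k + q_k) on
  proportional abundances of common species (proportions are taken relative
  to the plot's total catch over *all* species, so vectors need not sum to 1).
* ``chao_sorensen`` — the abundance-based Sørensen estimator that corrects
  for unseen shared species using shared species that are singletons or
  doubletons in the other sample; robust to undersampling of rare species.
* ``raup_crick`` — probabilistic: the chance that two random plots with the
  same richnesses drawn from the transect species pool would share fewer
  species than observed; insensitive to richness differences.

All four are symmetric and bounded in [0, 1].  Downstream analyses use the
dissimilarity d = 1 − s.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .community import CommunityMatrix, PlotMetadata, ValidationError

__all__ = [
    "SimilarityMatrix",
    "sorensen",
    "bray_curtis",
    "chao_sorensen_estimated",
    "raup_crick",
    "raup_crick_simulated",
    "pairwise_matrix",
    "INDEX_SCOPES",
]

#: Paper-protocol species scope for each index.
INDEX_SCOPES = {
    "sorensen": "common",
    "bray_curtis": "common",
    "chao_sorensen": "all",
    "raup_crick": "all",
}


@dataclass
class SimilarityMatrix:
    """Labelled symmetric pairwise plot-similarity values for one index.

    The diagonal is 1 for sorensen/bray_curtis/chao_sorensen; for raup_crick
    a self-comparison is not meaningful and the diagonal is NaN
    (``diagonal_valid`` is False).
    """

    values: pd.DataFrame
    index_name: str
    species_scope: str

    @property
    def plot_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def diagonal_valid(self) -> bool:
        return self.index_name != "raup_crick"

    def condensed_pairs(self) -> pd.DataFrame:
        """All unordered plot pairs as rows (plot_a, plot_b, similarity)."""
        rows = []
        ids = self.plot_ids
        for i, j in itertools.combinations(range(len(ids)), 2):
            rows.append((ids[i], ids[j], self.values.iat[i, j]))
        return pd.DataFrame(rows, columns=["plot_a", "plot_b", "similarity"])

    def to_dissimilarity(self) -> pd.DataFrame:
        """d = 1 − s with a zero diagonal (also for raup_crick)."""
        d = 1.0 - self.values
        np.fill_diagonal(d.to_numpy(), 0.0)
        return d

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="plot_id")


# -- the four indices ------------------------------------------------------


def sorensen(a: Iterable, b: Iterable) -> float:
    """Presence/absence Sørensen similarity 2|a∩b| / (|a| + |b|)."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        warnings.warn("Sørensen of two empty assemblages defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def bray_curtis(p: Sequence[float], q: Sequence[float]) -> float:
    """Quantitative Bray–Curtis similarity 2·Σ min / Σ (p + q) on proportions."""
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise ValidationError("proportion vectors must have equal length")
    if (pa < 0).any() or (qa < 0).any():
        raise ValidationError("proportional abundances must be non-negative")
    denom = pa.sum() + qa.sum()
    if denom == 0:
        warnings.warn("Bray–Curtis of two all-zero vectors defined as 0", stacklevel=2)
        return 0.0
    return float(2.0 * np.minimum(pa, qa).sum() / denom)


def chao_sorensen_estimated(
    x: Sequence[float], n: int, y: Sequence[float], m: int
) -> float:
    """Chao's abundance-based Sørensen estimator 2UV / (U + V).

    ``x`` and ``y`` are abundance vectors over the same species list; ``n``
    and ``m`` are the plots' total catches over all species.  U estimates the
    total proportion of individuals in sample 1 belonging to shared species,
    augmented by a correction from shared species observed once or twice in
    sample 2 (and symmetrically for V); both are capped at 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("abundance vectors must have equal length")
    shared = (xa > 0) & (ya > 0)
    if not shared.any():
        return 0.0

    def one_side(u: np.ndarray, nu: int, v: np.ndarray, nv: int) -> float:
        f1 = int(np.sum(shared & (v == 1)))  # shared, singleton in the other sample
        f2 = int(np.sum(shared & (v == 2)))  # shared, doubleton in the other sample
        base = u[shared].sum() / nu
        corr = ((nv - 1) / nv) * (f1 / (2.0 * max(f2, 1))) * u[shared & (v == 1)].sum() / nu
        return min(1.0, base + corr)

    U = one_side(xa, n, ya, m)
    V = one_side(ya, m, xa, n)
    if U + V == 0:
        return 0.0
    return float(2.0 * U * V / (U + V))


def raup_crick(a: Iterable, b: Iterable, pool_size: int) -> float:
    """Closed-form Raup–Crick similarity.

    With J ~ Hypergeometric(pool_size, |a|, |b|) the number of species two
    random plots of the observed richnesses would share, returns
    P(J < j_obs) — large values mean the plots share more species than
    chance predicts.
    """
    sa, sb = set(a), set(b)
    j_obs = len(sa & sb)
    if len(sa) > pool_size or len(sb) > pool_size:
        raise ValidationError("plot richness exceeds the species pool size")
    if j_obs > min(len(sa), len(sb)):  # pragma: no cover - set algebra forbids this
        raise ValidationError("shared count exceeds the smaller richness")
    if len(sa) == pool_size and len(sb) == pool_size:
        warnings.warn(
            "both plots contain the entire species pool; Raup–Crick is "
            "degenerate (0) here",
            stacklevel=2,
        )
    if j_obs == 0:
        return 0.0
    return float(hypergeom.cdf(j_obs - 1, pool_size, len(sa), len(sb)))


def raup_crick_simulated(
    a: Iterable,
    b: Iterable,
    occurrence_freq: pd.Series,
    n_reps: int = 999,
    seed: int | None = None,
) -> float:
    """Monte-Carlo Raup–Crick with occurrence-frequency weighted draws.

    Sensitivity-analysis variant: null plots draw species without replacement
    with probability proportional to how many plots each species occupies,
    instead of equally likely draws.
    """
    rng = np.random.default_rng(seed)
    pool = occurrence_freq.index.to_numpy()
    w = occurrence_freq.to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValidationError("occurrence frequencies must be positive")
    p = w / w.sum()
    sa, sb = set(a), set(b)
    j_obs = len(sa & sb)
    less = 0
    for _ in range(n_reps):
        da = rng.choice(pool, size=len(sa), replace=False, p=p)
        db = rng.choice(pool, size=len(sb), replace=False, p=p)
        if len(set(da) & set(db)) < j_obs:
            less += 1
    return less / n_reps


# -- matrix assembly -------------------------------------------------------


def _presence(matrix: CommunityMatrix, species: Sequence[str]) -> dict[str, set]:
    sub = matrix.counts[list(species)]
    return {p: set(sub.columns[sub.loc[p] > 0]) for p in matrix.plot_ids}


def pairwise_matrix(
    matrix: CommunityMatrix,
    index_name: str,
    metadata: PlotMetadata | None = None,
    species_scope: str | None = None,
    common_species: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """All unordered within-transect plot pairs for one similarity index.

    ``species_scope`` defaults to the protocol pairing (Sørensen and
    Bray–Curtis on common species; Chao–Sørensen and Raup–Crick on all
    species).  For the ``common`` scope, pass the common species list from
    :func:`elevbeta.richness.filter_common_species`.  Plots from more than
    one transect may not be mixed: between-transect similarities are near
    zero by construction of the study design and are analysed separately.
    """
    if index_name not in INDEX_SCOPES:
        raise ValidationError(
            f"unknown index {index_name!r}; choose from {sorted(INDEX_SCOPES)}"
        )
    if metadata is not None:
        transects = metadata.match(matrix).transects()
        if len(transects) > 1:
            raise ValidationError(
                f"plots from multiple transects mixed in one similarity "
                f"matrix: {transects}"
            )
    scope = species_scope or INDEX_SCOPES[index_name]
    if scope not in ("common", "all"):
        raise ValidationError("species_scope must be 'common' or 'all'")
    if scope == "common":
        if common_species is None:
            raise ValidationError(
                "species_scope='common' requires the common_species list"
            )
        species = [s for s in common_species if s in matrix.counts.columns]
    else:
        species = matrix.species_ids

    ids = matrix.plot_ids
    n = len(ids)
    out = np.ones((n, n))

    if index_name == "sorensen":
        pres = _presence(matrix, species)
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = sorensen(pres[ids[i]], pres[ids[j]])
    elif index_name == "bray_curtis":
        totals = matrix.plot_totals.to_numpy(dtype=float)  # all-species totals
        sub = matrix.counts[species].to_numpy(dtype=float)
        props = sub / totals[:, None]
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = bray_curtis(props[i], props[j])
    elif index_name == "chao_sorensen":
        totals = matrix.plot_totals
        sub = matrix.counts[species]
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = chao_sorensen_estimated(
                sub.iloc[i], int(totals.iloc[i]), sub.iloc[j], int(totals.iloc[j])
            )
    else:  # raup_crick
        recorded = [s for s in species if matrix.species_totals[s] > 0]
        pool_size = len(recorded)
        pres = _presence(matrix, recorded)
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = raup_crick(pres[ids[i]], pres[ids[j]], pool_size)
        np.fill_diagonal(out, np.nan)

    values = pd.DataFrame(out, index=ids, columns=ids)
    return SimilarityMatrix(values=values, index_name=index_name, species_scope=scope)
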