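"""Abundance-standardized richness and the common-species detection rule.

Plots along a light-trapping transect differ widely in the number of
individuals caught, and observed richness scales with catch size.  Richness
is therefore standardized by individual-based (Hurlbert) rarefaction: the
expected number of species in a random draw of ``n`` individuals from a plot,

    E[S_n] = Σ_i [ 1 − C(N − N_i, n) / C(N, n) ],

with ``N`` the plot total and ``N_i`` the abundance of species ``i``.  The
analytic form is the exact mean of the enumeration over all C(N, n) subsets;
no resampling noise is introduced.

"Common" species are defined through the detection model
``P = 1 − (1 − 1/n)^N``: the probability that a species with ``N`` individuals
spread at random over ``n`` equally likely plots is caught in any one plot.
The commonness threshold is the smallest ``N`` reaching a target detection
probability, and only common species enter the presence/absence and
proportional-abundance similarity indices downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .community import CommunityMatrix, PlotMetadata, ValidationError

__all__ = [
    "CommonSpeciesRule",
    "rarefied_richness",
    "common_species_threshold",
    "filter_common_species",
]


@dataclass(frozen=True)
class CommonSpeciesRule:
    """Minimum total abundance for a species to count as 'common'.

    ``threshold`` is the smallest integer N with 1 − (1 − 1/n)^N ≥ P for
    ``n_plots`` plots and target detection probability P; comparison is
    inclusive (a species with exactly ``threshold`` individuals is common).
    """

    n_plots: int
    target_probability: float
    threshold: int


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n, dtype=float) + 1) - gammaln(k + 1) - gammaln(
        np.asarray(n, dtype=float) - k + 1
    )


def _hurlbert(abundances: np.ndarray, n: int) -> float:
    """E[S] in a draw of n individuals, exact in log space."""
    ab = abundances[abundances > 0]
    total = int(ab.sum())
    if n == total:
        return float(len(ab))
    rest = total - ab  # N - N_i
    prob_absent = np.zeros(len(ab))
    feasible = rest >= n  # else species i is certainly drawn
    if feasible.any():
        prob_absent[feasible] = np.exp(_log_comb(rest[feasible], n) - _log_comb(total, n))
    return float(np.sum(1.0 - prob_absent))


def rarefied_richness(
    matrix: CommunityMatrix, n_standard: int, on_small: str = "error"
) -> pd.DataFrame:
    """Expected species richness per plot at a common abundance ``n_standard``.

    Parameters
    ----------
    matrix
        Plots × species counts.
    n_standard
        Rarefaction depth (number of individuals drawn without replacement).
    on_small
        ``"error"`` (default) raises listing plots whose total is below
        ``n_standard``; ``"skip"`` reports NaN for those plots instead.

    Returns
    -------
    DataFrame with columns ``plot_id``, ``n_standard``, ``expected_species``.
    """
    if n_standard < 1:
        raise ValidationError("n_standard must be ≥ 1")
    if on_small not in ("error", "skip"):
        raise ValueError("on_small must be 'error' or 'skip'")
    totals = matrix.plot_totals
    small = totals.index[totals < n_standard].tolist()
    if small and on_small == "error":
        raise ValidationError(
            f"plot total below rarefaction depth {n_standard} for plots: {small}"
        )
    values = []
    for plot in matrix.plot_ids:
        if plot in small:
            values.append(np.nan)
        else:
            values.append(_hurlbert(matrix.counts.loc[plot].to_numpy(), n_standard))
    return pd.DataFrame(
        {
            "plot_id": matrix.plot_ids,
            "n_standard": n_standard,
            "expected_species": values,
        }
    )


def common_species_threshold(n_plots: int, target_probability: float) -> CommonSpeciesRule:
    """Smallest total abundance N with detection probability ≥ target.

    Solves 1 − (1 − 1/n)^N ≥ P for integer N; with a single plot any species
    present is detected, so the threshold is 1.
    """
    if n_plots < 1:
        raise ValidationError("n_plots must be ≥ 1")
    if not 0 < target_probability < 1:
        raise ValidationError("target_probability must lie strictly in (0, 1)")
    if n_plots == 1:
        return CommonSpeciesRule(1, target_probability, 1)
    miss = 1.0 - 1.0 / n_plots
    # N ≥ log(1-P)/log(1-1/n); guard the ceiling against float edge cases
    n = max(1, math.ceil(math.log1p(-target_probability) / math.log(miss)))
    while 1.0 - miss**n < target_probability:
        n += 1
    while n > 1 and 1.0 - miss ** (n - 1) >= target_probability:
        n -= 1
    return CommonSpeciesRule(n_plots, target_probability, n)


def filter_common_species(
    matrix: CommunityMatrix, rule: CommonSpeciesRule
) -> CommunityMatrix:
    """Retain species whose total abundance in the matrix meets the rule.

    The matrix is expected to hold a single transect (commonness is assessed
    within the habitat where the detection model applies); plot rows are
    preserved.  An empty result is returned with a warning if no species
    qualifies.
    """
    totals = matrix.species_totals
    keep = totals.index[totals >= rule.threshold].tolist()
    if not keep:
        warnings.warn(
            f"no species reaches the commonness threshold {rule.threshold}",
            stacklevel=2,
        )
    return matrix.subset(species=keep)
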