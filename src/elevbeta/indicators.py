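"""Indicator-species analysis over elevational band ranges.

The Dufrêne–Legendre indicator value measures how strongly a species marks a
group of plots.  For a candidate group (here: a single elevational band or a
contiguous run of bands, never the whole transect), treating the transect as
the binary partition {inside, outside}:

    A (specificity) = mean abundance inside / (mean abundance inside + mean abundance outside)
    B (fidelity)    = fraction of inside plots occupied
    IndVal          = A · B · 100   (percent)

IndVal reaches 100 exactly when the species occurs in every inside plot and
nowhere outside.  Each species is assigned to the candidate group where its
IndVal is largest; significance of that maximum is assessed by permuting the
plot-to-band assignment (band sizes preserved).

Because transects differ enormously in species richness, raw counts of
significant indicators are not comparable across transects.  The comparison
statistic is instead a null-model standardized effect size: the full
significance procedure is re-run on shuffled datasets and

    effect size = (observed count − mean null count) / sd(null counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .community import CommunityMatrix, PlotMetadata, ValidationError

__all__ = [
    "GroupingScheme",
    "EffectSizeResult",
    "candidate_groupings",
    "indval",
    "best_indicator",
    "indval_significance",
    "count_significant",
    "effect_size_null_model",
]


@dataclass(frozen=True)
class GroupingScheme:
    """Candidate band groupings: every contiguous run except the full gradient.

    For B bands there are B(B+1)/2 − 1 groupings (B = 4 gives nine).  Groups
    are ordered by span, then by starting elevation — the deterministic
    tie-break order used when several groupings share the maximal IndVal.
    """

    bands_ordered: tuple[str, ...]
    groups: tuple[tuple[str, ...], ...]

    @staticmethod
    def label(group: Sequence[str]) -> str:
        return group[0] if len(group) == 1 else f"{group[0]}-{group[-1]}"

    @property
    def labels(self) -> list[str]:
        return [self.label(g) for g in self.groups]


def candidate_groupings(bands_ordered: Sequence[str]) -> GroupingScheme:
    """All contiguous band ranges of 1..B−1 bands, smallest span first."""
    bands = tuple(str(b) for b in bands_ordered)
    b = len(bands)
    if b < 2:
        raise ValidationError("candidate groupings need at least two bands")
    groups = []
    for span in range(1, b):  # the full run (span == b) is excluded
        for start in range(0, b - span + 1):
            groups.append(bands[start : start + span])
    return GroupingScheme(bands_ordered=bands, groups=tuple(groups))


# -- vectorised IndVal machinery -------------------------------------------


def _codes_and_masks(
    matrix: CommunityMatrix, metadata: PlotMetadata, scheme: GroupingScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Plot band codes and the (groups × plots) membership mask."""
    band_of = metadata.match(matrix).band_of()
    band_index = {b: i for i, b in enumerate(scheme.bands_ordered)}
    unknown = sorted(set(band_of) - set(band_index))
    if unknown:
        raise ValidationError(f"plots in bands outside the scheme: {unknown}")
    codes = np.array([band_index[band_of[p]] for p in matrix.plot_ids])
    masks = np.zeros((len(scheme.groups), len(codes)))
    for gi, group in enumerate(scheme.groups):
        member = np.isin(codes, [band_index[b] for b in group])
        if not member.any():
            raise ValidationError(f"grouping {scheme.label(group)} contains no plots")
        masks[gi] = member
    return codes, masks


def _indval_table(x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """IndVal (%) for every grouping × species; ``x`` is plots × species counts.

    ``masks`` may carry a leading batch axis for permuted assignments.
    """
    single = masks.ndim == 2
    m = masks[None, ...] if single else masks
    n_plots = m.shape[-1]
    n_in = m.sum(axis=-1)  # (batch, G)
    n_out = n_plots - n_in
    sums_in = np.einsum("qgp,ps->qgs", m, x)
    occ_in = np.einsum("qgp,ps->qgs", m, (x > 0).astype(float))
    tot = x.sum(axis=0)  # (S,)
    mean_in = sums_in / n_in[..., None]
    mean_out = (tot[None, None, :] - sums_in) / n_out[..., None]
    denom = mean_in + mean_out
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, mean_in / np.where(denom > 0, denom, 1.0), 0.0)
    b = occ_in / n_in[..., None]
    iv = 100.0 * a * b
    return iv[0] if single else iv


def indval(
    matrix: CommunityMatrix, metadata: PlotMetadata, grouping: Sequence[str]
) -> pd.Series:
    """IndVal (%) of every species for one candidate grouping."""
    bands = metadata.match(matrix).df["band"]
    scheme_bands = pd.unique(bands)
    band_set = set(scheme_bands)
    group = tuple(str(b) for b in grouping)
    if not set(group) <= band_set:
        raise ValidationError(f"grouping {group} references unknown bands")
    member = bands.isin(group).to_numpy()
    if not member.any():
        raise ValidationError("grouping contains no plots")
    mask = member.astype(float)[None, :]
    iv = _indval_table(matrix.values().astype(float), mask)[0]
    return pd.Series(iv, index=matrix.species_ids, name="indval")


def best_indicator(
    matrix: CommunityMatrix, metadata: PlotMetadata, scheme: GroupingScheme
) -> pd.DataFrame:
    """Best grouping and maximal IndVal per species.

    Ties are broken toward the grouping spanning fewer bands, then the lower
    elevation — the order the scheme enumerates its groups in.
    """
    _, masks = _codes_and_masks(matrix, metadata, scheme)
    iv = _indval_table(matrix.values().astype(float), masks)  # (G, S)
    best_idx = np.argmax(iv, axis=0)  # first maximum = tie-break order
    return pd.DataFrame(
        {
            "species_id": matrix.species_ids,
            "best_group": [scheme.labels[i] for i in best_idx],
            "indval": iv[best_idx, np.arange(iv.shape[1])],
        }
    )


def _max_indval_permuted(
    x: np.ndarray, masks: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Max-over-groupings IndVal per species for a batch of plot permutations.

    ``perms`` has shape (Q, P); row q permutes the plot-to-band assignment.
    """
    batch = masks[:, perms].transpose(1, 0, 2)  # (Q, G, P)
    iv = _indval_table(x, batch)
    return iv.max(axis=1)  # (Q, S)


def indval_significance(
    matrix: CommunityMatrix,
    metadata: PlotMetadata,
    scheme: GroupingScheme,
    n_permutations: int = 999,
    seed=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test of each species' maximal IndVal.

    The null permutes the plot-to-band assignment (band sizes preserved);
    p = (1 + #{null max ≥ observed max}) / (1 + n_permutations).  Significance
    is assessed at ``alpha`` on raw p-values (the protocol applies no
    multiplicity correction); a Benjamini–Hochberg ``q_value`` column is
    emitted for reference.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be ≥ 1")
    x = matrix.values().astype(float)
    _, masks = _codes_and_masks(matrix, metadata, scheme)
    iv = _indval_table(x, masks)
    best_idx = np.argmax(iv, axis=0)
    obs_max = iv[best_idx, np.arange(iv.shape[1])]

    rng = np.random.default_rng(seed)
    n_plots = x.shape[0]
    perms = np.stack([rng.permutation(n_plots) for _ in range(n_permutations)])
    null_max = _max_indval_permuted(x, masks, perms)  # (Q, S)
    count_ge = (null_max >= obs_max[None, :] - 1e-9).sum(axis=0)
    p = (1 + count_ge) / (1 + n_permutations)

    out = pd.DataFrame(
        {
            "species_id": matrix.species_ids,
            "best_group": [scheme.labels[i] for i in best_idx],
            "indval": obs_max,
            "p_value": p,
        }
    )
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_value"] <= alpha
    return out


def count_significant(results: pd.DataFrame) -> tuple[int, pd.Series]:
    """Total significant indicators and their proportions per best grouping."""
    if len(results) == 0:
        return 0, pd.Series(dtype=float)
    sig = results[results["significant"]]
    total = int(len(sig))
    if total == 0:
        return 0, pd.Series(dtype=float)
    props = sig["best_group"].value_counts(normalize=True).sort_index()
    return total, props


@dataclass
class EffectSizeResult:
    """Observed significant-indicator count against its shuffled-data null."""

    observed_count: int
    null_counts: np.ndarray
    effect_size: float
    n_null: int
    alpha: float
    n_permutations: int
    inner_permutations: int
    undefined: bool = False

    def to_dict(self) -> dict:
        nc = np.asarray(self.null_counts, dtype=float)
        return {
            "observed_count": self.observed_count,
            "effect_size": None if self.undefined else self.effect_size,
            "undefined": self.undefined,
            "n_null": self.n_null,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "inner_permutations": self.inner_permutations,
            "null_mean": float(nc.mean()),
            "null_sd": float(nc.std(ddof=1)),
            "null_min": float(nc.min()),
            "null_q1": float(np.percentile(nc, 25)),
            "null_median": float(np.percentile(nc, 50)),
            "null_q3": float(np.percentile(nc, 75)),
            "null_max": float(nc.max()),
        }


def _significant_count(
    x: np.ndarray,
    masks: np.ndarray,
    codes_perm: np.ndarray | None,
    n_permutations: int,
    rng: np.random.Generator,
    alpha: float,
) -> int:
    """Significant-indicator count for one (possibly shuffled) assignment."""
    n_plots = x.shape[0]
    base = masks if codes_perm is None else masks[:, codes_perm]
    iv = _indval_table(x, base)
    obs_max = iv.max(axis=0)
    perms = np.stack([rng.permutation(n_plots) for _ in range(n_permutations)])
    # permutations compose with the shuffled assignment
    eff = perms if codes_perm is None else codes_perm[perms]
    null_max = _max_indval_permuted(x, masks, eff)
    count_ge = (null_max >= obs_max[None, :] - 1e-9).sum(axis=0)
    p = (1 + count_ge) / (1 + n_permutations)
    return int((p <= alpha).sum())


def effect_size_null_model(
    matrix: CommunityMatrix,
    metadata: PlotMetadata,
    scheme: GroupingScheme,
    n_null: int = 999,
    n_permutations: int = 999,
    inner_permutations: int = 199,
    seed=None,
    alpha: float = 0.05,
) -> EffectSizeResult:
    """Standardized effect size of the significant-indicator count.

    The observed count uses ``n_permutations`` for per-species significance.
    Each of the ``n_null`` null datasets shuffles the plot-to-band assignment
    and re-runs the full significance procedure with ``inner_permutations``
    (cheaper by default; the effect size is robust to the inner count).  All
    permutation streams are spawned independently from ``seed``, so results
    are reproducible and order-independent.
    """
    if n_null < 2:
        raise ValidationError("n_null must be ≥ 2")
    if n_permutations < 1 or inner_permutations < 1:
        raise ValidationError("permutation counts must be ≥ 1")
    x = matrix.values().astype(float)
    _, masks = _codes_and_masks(matrix, metadata, scheme)
    n_plots = x.shape[0]

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_null + 1)
    observed = _significant_count(
        x, masks, None, n_permutations, np.random.default_rng(streams[0]), alpha
    )
    null_counts = np.empty(n_null, dtype=int)
    for r in range(n_null):
        rng = np.random.default_rng(streams[r + 1])
        shuffle = rng.permutation(n_plots)
        null_counts[r] = _significant_count(
            x, masks, shuffle, inner_permutations, rng, alpha
        )
    sd = null_counts.std(ddof=1)
    if sd == 0:
        return EffectSizeResult(
            observed, null_counts, float("nan"), n_null, alpha,
            n_permutations, inner_permutations, undefined=True,
        )
    es = (observed - null_counts.mean()) / sd
    return EffectSizeResult(
        observed, null_counts, float(es), n_null, alpha,
        n_permutations, inner_permutations,
    )
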