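"""Lightweight figures: decay scatter, effect-size box, NMDS hook."""

from __future__ import annotations

import numpy as np

from .community import PlotMetadata
from .indicators import EffectSizeResult
from .inference import DecayFit
from .similarity import SimilarityMatrix


def decay_scatter(
    sim: SimilarityMatrix, metadata: PlotMetadata, fit: DecayFit | None, path
) -> None:
    """Similarity vs Δelevation scatter with the fitted trend line (SVG/PNG)."""
    import matplotlib.pyplot as plt

    pairs = sim.condensed_pairs()
    elev = metadata.elevations()
    dx = np.abs(elev.loc[pairs["plot_a"]].to_numpy() - elev.loc[pairs["plot_b"]].to_numpy())
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(dx, pairs["similarity"], s=12, alpha=0.6)
    if fit is not None:
        xs = np.linspace(dx.min(), dx.max(), 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, color="black")
        ax.set_title(
            f"{sim.index_name}: slope={fit.slope:.2e}, $R^2$={fit.r_squared:.2f}",
            fontsize=9,
        )
    ax.set_xlabel("Δ elevation (m)")
    ax.set_ylabel(f"{sim.index_name} similarity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def effect_size_box(results: dict[str, EffectSizeResult], path) -> None:
    """Observed indicator counts (dots) against null distributions (boxes)."""
    import matplotlib.pyplot as plt

    labels = list(results)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot([results[t].null_counts for t in labels], tick_labels=labels, whis=(0, 100))
    for i, t in enumerate(labels, start=1):
        r = results[t]
        ax.plot(i, r.observed_count, "ko")
        if not r.undefined:
            ax.annotate(f"ES={r.effect_size:.1f}", (i, r.observed_count),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_ylabel("significant indicator species")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def nmds_plot(sim: SimilarityMatrix, metadata: PlotMetadata, path, seed: int = 0) -> None:
    """Non-metric MDS ordination of plots, colour-coded by band.

    Visualization only — stress minimization is delegated to
    :class:`sklearn.manifold.MDS`.
    """
    import matplotlib.pyplot as plt
    from sklearn.manifold import MDS

    d = sim.to_dissimilarity().to_numpy()
    coords = MDS(
        n_components=2, metric=False, dissimilarity="precomputed",
        random_state=seed, normalized_stress="auto",
    ).fit_transform(d)
    bands = metadata.band_of().loc[sim.plot_ids]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    for band in bands.unique():
        sel = (bands == band).to_numpy()
        ax.scatter(coords[sel, 0], coords[sel, 1], label=str(band), s=24)
    ax.legend(title="band", fontsize=8)
    ax.set_title(f"NMDS ({sim.index_name})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
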