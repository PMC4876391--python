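"""End-to-end orchestration of the elevational sensitivity analysis.

One call runs, per transect: stratum pooling → rarefied richness → common
species filtering → the four similarity matrices → PERMANOVA (+ pairwise
post hoc) → distance-decay regression → indicator-species analysis → the
null-model effect size.  Every stage writes a CSV or JSON artefact and all
randomness derives from a single seed, so a config reproduces its outputs
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indicators, inference, richness, similarity
from .community import (
    CommunityMatrix,
    PlotMetadata,
    ValidationError,
    pool_strata,
    read_community_csv,
    read_metadata_csv,
    split_by_transect,
)
from .synthetic import SyntheticConfig, generate_multi_transect

log = logging.getLogger("elevbeta")

__all__ = ["PipelineConfig", "run_all"]

DEFAULT_INDICES = ("sorensen", "bray_curtis", "chao_sorensen", "raup_crick")


@dataclass
class PipelineConfig:
    """Flat, JSON-serializable configuration of a full run."""

    community_csv: str | None = None
    metadata_csv: str | None = None
    synthetic: list[dict] | None = None  # SyntheticConfig kwargs, one per transect
    n_standard: int = 364
    common_p: float = 0.95
    indices: tuple[str, ...] = DEFAULT_INDICES
    permutations: int = 4999
    indicator_permutations: int = 999
    null_reps: int = 999
    inner_permutations: int = 199
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "elevbeta_out"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "indices" in raw:
            raw["indices"] = tuple(raw["indices"])
        return cls(**raw)


def _load(config: PipelineConfig) -> tuple[CommunityMatrix, PlotMetadata]:
    if config.synthetic:
        cfgs = []
        for i, kw in enumerate(config.synthetic):
            kw = dict(kw)
            kw.setdefault("transect", f"T{i + 1}")
            kw.setdefault("seed", config.seed + i)
            cfgs.append(SyntheticConfig(**kw))
        if len(cfgs) == 1:
            from .synthetic import generate_assemblage

            m, md, _ = generate_assemblage(cfgs[0])
            return m, md
        m, md, _ = generate_multi_transect(cfgs)
        return m, md
    if not (config.community_csv and config.metadata_csv):
        raise ValidationError(
            "config needs either 'synthetic' or both community_csv and metadata_csv"
        )
    return read_community_csv(config.community_csv), read_metadata_csv(config.metadata_csv)


def _stage(name: str, transect: str):
    log.info("stage=%s transect=%s", name, transect)
    return time.perf_counter()


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    matrix, metadata = _load(config)
    matrix, metadata = pool_strata(matrix, metadata)
    per_transect = split_by_transect(matrix, metadata)
    master = np.random.SeedSequence(config.seed)
    transect_seeds = {tr: s for tr, s in zip(sorted(per_transect), master.spawn(len(per_transect)))}

    summary: dict = {"transects": {}, "parameters": dataclasses.asdict(config)}
    for tr, (m, md) in per_transect.items():
        tdir = out / tr
        tdir.mkdir(exist_ok=True)
        seeds = transect_seeds[tr].spawn(4)
        entry: dict = {"n_plots": m.n_plots, "n_species": m.n_species}
        try:
            t0 = _stage("richness", tr)
            rich = richness.rarefied_richness(m, config.n_standard, on_small="skip")
            rich.to_csv(tdir / "richness.csv", index=False)

            _stage("common_species", tr)
            bands = md.bands_ordered(tr)
            n_per_band = int((md.df["transect"] == tr).sum() / len(bands))
            rule = richness.common_species_threshold(n_per_band, config.common_p)
            common = richness.filter_common_species(m, rule)
            entry["common_threshold"] = rule.threshold
            entry["n_common_species"] = common.n_species

            _stage("similarity", tr)
            sims = {}
            for index in config.indices:
                sims[index] = similarity.pairwise_matrix(
                    m, index, metadata=md, common_species=common.species_ids
                )
                sims[index].to_csv(tdir / f"similarity_{index}.csv")

            _stage("permanova", tr)
            groups = md.band_of().loc[m.plot_ids]
            perm_out, pair_rows = {}, []
            pseeds = seeds[0].spawn(2 * len(sims))
            for k, (index, sim) in enumerate(sims.items()):
                d = inference.dissimilarity_from(sim)
                res = inference.permanova(
                    d, groups, n_permutations=config.permutations, seed=pseeds[2 * k]
                )
                perm_out[index] = res.to_dict()
                pw = inference.pairwise_permanova(
                    d.to_numpy(), groups, n_permutations=config.permutations,
                    seed=pseeds[2 * k + 1],
                )
                pw.insert(0, "index", index)
                pair_rows.append(pw)
            (tdir / "permanova.json").write_text(json.dumps(perm_out, indent=2, sort_keys=True))
            pd.concat(pair_rows).to_csv(tdir / "pairwise_permanova.csv", index=False)
            entry["permanova"] = perm_out

            _stage("decay", tr)
            decay_out = {}
            for index, sim in sims.items():
                if index == "raup_crick":
                    continue  # non-metric probabilistic index: no decay regression
                decay_out[index] = inference.distance_decay_fit(sim, md).to_dict()
            (tdir / "decay.json").write_text(json.dumps(decay_out, indent=2, sort_keys=True))
            entry["decay"] = decay_out

            _stage("indicators", tr)
            scheme = indicators.candidate_groupings(bands)
            ind = indicators.indval_significance(
                common, md, scheme,
                n_permutations=config.indicator_permutations,
                seed=seeds[1], alpha=config.alpha,
            )
            ind.to_csv(tdir / "indicators.csv", index=False)
            n_sig, props = indicators.count_significant(ind)
            entry["significant_indicators"] = n_sig
            entry["indicator_proportions"] = props.round(6).to_dict()

            _stage("effect_size", tr)
            es = indicators.effect_size_null_model(
                common, md, scheme,
                n_null=config.null_reps,
                n_permutations=config.indicator_permutations,
                inner_permutations=config.inner_permutations,
                seed=seeds[2], alpha=config.alpha,
            )
            (tdir / "effect_size.json").write_text(
                json.dumps(es.to_dict(), indent=2, sort_keys=True)
            )
            entry["effect_size"] = es.to_dict()
        except ValidationError as err:
            raise ValidationError(f"transect {tr}: {err}") from err
        summary["transects"][tr] = entry

    # rank transects by elevational sensitivity (steeper decay / larger effect size)
    trs = list(summary["transects"])
    slope_of = {
        t: abs(summary["transects"][t].get("decay", {}).get("sorensen", {}).get("slope", 0.0))
        for t in trs
    }
    es_of = {
        t: (summary["transects"][t].get("effect_size", {}).get("effect_size") or 0.0)
        for t in trs
    }
    summary["ranking_by_decay_slope"] = sorted(trs, key=lambda t: -slope_of[t])
    summary["ranking_by_effect_size"] = sorted(trs, key=lambda t: -es_of[t])
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
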