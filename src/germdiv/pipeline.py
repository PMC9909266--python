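"""Config-driven end-to-end diversity analysis.

One :func:`run` call reproduces the full workflow shape on any panel:
per-primer marker statistics -> diversity indices -> distance matrices
per data layer -> UPGMA dendrograms with cophenetic validation ->
tanglegram comparisons between configured layer pairs -> PCA of the
trait layer, writing every intermediate as a text artifact (CSV, Newick,
JSON) so each stage can also be rerun standalone. Identical config and
seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import cophenetic_correlation, cut_tree, upgma
from .colorimetry import color_feature_matrix
from .distances import binary_distance, euclidean_distance, gower_distance
from .diversity import diversity_table, minmax_profile
from .errors import AlignmentError, ConfigError, FormatError
from .io_formats import (
    read_band_matrix,
    read_color_table,
    read_trait_table,
    write_band_matrix,
    write_color_table,
    write_newick,
    write_trait_table,
)
from .marker_stats import band_stats, panel_summary
from .pca import pca, select_components
from .synthetic import PanelConfig, config_to_dict, simulate_panel
from .tables import BandMatrix
from .tanglegram import untangle

__all__ = ["RunConfig", "run", "combine_marker_layers"]

_LAYER_METRICS = {
    "marker": ("simple-matching", "jaccard", "euclidean"),
    "trait": ("gower", "euclidean"),
    "color": ("euclidean",),
}


@dataclass
class RunConfig:
    """Inputs, per-layer metric choices, and comparison plan for one run."""

    band_matrix: str | None = None
    trait_table: str | None = None
    color_table: str | None = None
    #: generate a synthetic panel instead of reading files
    synthetic: PanelConfig | None = None
    marker_metric: str = "simple-matching"
    trait_metric: str = "gower"
    color_metric: str = "euclidean"
    k: int = 4
    L: float = 1.5
    untangle_method: str = "step2side"
    #: pairs of layer names to compare as tanglegrams
    tanglegram_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("marker", "trait"), ("marker", "color"),
                                 ("trait", "color")]
    )
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and not (
            self.band_matrix or self.trait_table or self.color_table
        ):
            raise ConfigError("no data layer configured")
        for layer, metric in (
            ("marker", self.marker_metric),
            ("trait", self.trait_metric),
            ("color", self.color_metric),
        ):
            if metric not in _LAYER_METRICS[layer]:
                raise ConfigError(
                    f"metric {metric!r} not valid for {layer} layer "
                    f"(choose from {_LAYER_METRICS[layer]})"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "tanglegram_pairs"})
        if "tanglegram_pairs" in raw:
            cfg.tanglegram_pairs = [tuple(p) for p in raw["tanglegram_pairs"]]
        if syn is not None:
            if "primers" in syn:
                syn["primers"] = [tuple(p) for p in syn["primers"]]
            if "color_organs" in syn:
                syn["color_organs"] = tuple(syn["color_organs"])
            cfg.synthetic = PanelConfig(**syn)
        return cfg


def combine_marker_layers(*matrices: BandMatrix) -> BandMatrix:
    """Column-concatenate band matrices over one genotype set.

    All matrices must list identical genotypes in identical order and
    carry disjoint band ids; primer annotations are preserved.
    """
    if not matrices:
        raise ConfigError("no matrices to combine")
    first = matrices[0]
    for m in matrices[1:]:
        if m.genotype_ids != first.genotype_ids:
            only_a = set(first.genotype_ids) - set(m.genotype_ids)
            only_b = set(m.genotype_ids) - set(first.genotype_ids)
            raise AlignmentError(
                f"genotype sets differ (only first: {sorted(only_a)}, "
                f"only other: {sorted(only_b)}) or order differs"
            )
    band_ids: list[str] = []
    primer_of_band: dict[str, str] = {}
    for m in matrices:
        for b in m.band_ids:
            if b in primer_of_band:
                raise FormatError(f"duplicate band id across layers: {b!r}")
            primer_of_band[b] = m.primer_of_band[b]
        band_ids.extend(m.band_ids)
    calls = np.concatenate([m.calls for m in matrices], axis=1)
    return BandMatrix(list(first.genotype_ids), band_ids, primer_of_band, calls)


def _layer_distance(layer: str, obj, metric: str):
    if layer == "marker":
        if metric == "euclidean":
            return euclidean_distance(obj.to_dataframe(), standardize=False)
        return binary_distance(obj, method=metric)
    if layer == "trait":
        if metric == "gower":
            return gower_distance(obj)
        return euclidean_distance(obj.ordinal_encoded(), standardize=True)
    if layer == "color":
        feats = color_feature_matrix(obj)
        # hue may be missing at achromatic points; those columns are imputed
        # with the column mean before Euclidean distance (documented policy)
        filled = feats.apply(lambda c: c.fillna(c.mean()))
        return euclidean_distance(filled, standardize=True)
    raise ConfigError(f"unknown layer {layer!r}")


def run(config: RunConfig, outdir) -> dict:
    """Execute the configured workflow; returns the run report dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "germdiv_version": __version__,
        "seed": config.seed,
        "conventions": {
            "upgma_tie_break": "lexicographically smallest label pair",
            "merge_height": "raw merge distance (hclust convention)",
            "entanglement": "0 = perfect alignment, 1 = full reversal",
            "entanglement_L": config.L,
            "zscore_sd": "population (divisor N)",
        },
        "layers": {},
    }

    layers: dict[str, object] = {}
    if config.synthetic is not None:
        panel = simulate_panel(config.synthetic)
        layers["marker"] = panel.band_matrix
        layers["trait"] = panel.trait_table
        layers["color"] = panel.color_table
        report["true_groups"] = panel.true_groups
        report["synthetic_config"] = config_to_dict(config.synthetic)
        write_band_matrix(panel.band_matrix, out / "band_matrix.csv")
        write_trait_table(panel.trait_table, out / "trait_table.csv")
        write_color_table(panel.color_table, out / "color_table.csv")
    else:
        if config.band_matrix:
            layers["marker"] = read_band_matrix(config.band_matrix)
        if config.trait_table:
            layers["trait"] = read_trait_table(config.trait_table)
        if config.color_table:
            layers["color"] = read_color_table(config.color_table)

    metrics = {
        "marker": config.marker_metric,
        "trait": config.trait_metric,
        "color": config.color_metric,
    }

    if "marker" in layers:
        bm = layers["marker"]
        band_stats(bm).to_csv(out / "band_stats.csv")
        summ = panel_summary(bm)
        summ.per_primer.to_csv(out / "primer_stats.csv")
        report["marker_summary"] = {
            "total_bands": summ.total_bands,
            "total_polymorphic": summ.total_polymorphic,
            "mean_polymorphic_per_primer": summ.mean_polymorphic_per_primer,
            "pooled_percent_polymorphic": summ.pooled_percent_polymorphic,
            "mean_percent_polymorphic": float(
                summ.averages["percent_polymorphic"]
            ),
        }
        per, overall = diversity_table(bm.to_dataframe())
        per.to_csv(out / "diversity_marker.csv")
        overall.to_csv(out / "diversity_marker_summary.csv")

    trees = {}
    for layer, obj in layers.items():
        d = _layer_distance(layer, obj, metrics[layer])
        d.to_dataframe().to_csv(out / f"distance_{layer}.csv")
        t = upgma(d)
        trees[layer] = t
        write_newick(t, out / f"tree_{layer}.nwk")
        r = cophenetic_correlation(d, t)
        clusters = cut_tree(t, min(config.k, t.n_leaves))
        report["layers"][layer] = {
            "metric": d.metric,
            "n_units": d.n,
            "cophenetic_r": r,
            "clusters_at_k": clusters,
        }

    if "trait" in layers:
        encoded = layers["trait"].ordinal_encoded()
        if not encoded.isna().any().any():
            res = pca(encoded, standardize=True)
            res.loadings.to_csv(out / "pca_loadings.csv")
            res.scores.to_csv(out / "pca_scores.csv")
            res.contributions.to_csv(out / "pca_contributions.csv")
            report["pca"] = {
                "eigenvalues": res.eigenvalues.tolist(),
                "explained_percent": res.explained.tolist(),
                "n_kaiser": select_components(res, "kaiser"),
            }
            per, overall = diversity_table(minmax_profile(encoded))
            per.to_csv(out / "diversity_trait.csv")
            overall.to_csv(out / "diversity_trait_summary.csv")

    report["tanglegrams"] = {}
    for a, b in config.tanglegram_pairs:
        if a in trees and b in trees:
            res = untangle(
                trees[a], trees[b], method=config.untangle_method,
                L=config.L, seed=config.seed, k=min(config.k, trees[a].n_leaves),
            )
            key = f"{a}-{b}"
            report["tanglegrams"][key] = res.to_dict()
            with open(out / f"tanglegram_{key}.json", "w", encoding="utf-8") as fh:
                json.dump(res.to_dict(), fh, indent=2, sort_keys=True)

    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
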