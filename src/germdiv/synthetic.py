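"""Synthetic germplasm panels with known latent group structure.

The generator emulates the data shapes of a typical ornamental-germplasm
diversity study: ~32 genotypes falling into K latent groups (species
clusters, cultivar families), fingerprinted with dominant markers
(SRAP-like primer combinations, SCoT-like single primers), phenotyped
for mixed quantitative/qualitative traits, and color-measured per organ
region in CIELab. Because all three layers are driven by the same latent
group labels, marker- and trait-based dendrograms built from one panel
are *coupled* — the property tanglegram comparisons are meant to detect.

Groups are not just shared labels: each group g carries a latent
coordinate u_g ~ N(0, I_r) (r = ``latent_dim``), drawn once per panel
and shared by all layers. Every layer derives its group effects by
projecting u_g on its own random directions, so between-group
relatedness is consistent across markers, traits and colors — two
groups close in latent space are similar in every layer, which is what
couples the layers' dendrograms. Marginally each layer still follows
the simple model below.

Model per layer, given equal-sized groups g(i):

* bands — each band draws a baseline presence frequency from
  Beta(alpha, beta); a fraction of bands is "group-informative", each
  group receiving a +delta/2 or -delta/2 offset so that two groups
  differ in presence frequency by delta when their signs differ. A
  ``coupled_fraction`` of these bands take their signs from median
  splits of the latent coordinates along random directions (markers
  tracking relatedness); the rest use i.i.d. signs (homoplasious
  markers, keeping every group pair distinguishable). Frequencies are
  clamped to [0.02, 0.98] and calls are Bernoulli. Operating on
  band-presence frequencies directly (not diploid dosage) matches what
  dominant-marker scoring observes.
* quantitative traits — genotype value ~ Normal(m_g, sigma^2) with
  group means m_g = Delta * sigma / sqrt(2) * (v . u_g) for a unit
  random direction v, hence m_g ~ Normal(0, (Delta * sigma)^2 / 2) and
  RMS between-group mean separation Delta standard deviations.
* qualitative traits — each group prefers one level (groups ranked
  along a random latent direction and binned into levels); a genotype
  shows the preferred level with probability ``qual_bias``, otherwise a
  uniform level.
* colors — per organ and channel, group means are
  center + between_sd * (w . u_g) around realistic CIELab centers;
  genotype values add within-group noise; L* clipped to [0, 100].

All randomness flows from one integer seed through a single
``numpy.random.default_rng`` stream, so a config + seed pair is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables import (
    DEFAULT_ORGANS,
    QUALITATIVE,
    QUANTITATIVE,
    BandMatrix,
    ColorTable,
    TraitTable,
)

__all__ = [
    "PanelConfig",
    "SyntheticPanel",
    "simulate_panel",
    "simulate_band_matrix",
    "scot_like_primers",
    "srap_like_primers",
]


def scot_like_primers() -> list[tuple[str, int]]:
    """12 single-primer markers, 204 bands total (mean 17 per primer)."""
    counts = [14, 18, 15, 19, 16, 17, 17, 18, 16, 17, 18, 19]
    return [(f"SC{i + 1:02d}", c) for i, c in enumerate(counts)]


def srap_like_primers() -> list[tuple[str, int]]:
    """26 primer combinations, 349 bands total (mean ~13.4)."""
    counts = [12, 14, 13, 15, 12, 14, 13, 15, 12, 14, 13, 15, 12,
              14, 13, 15, 12, 14, 13, 15, 12, 14, 13, 15, 13, 12]
    return [(f"SR{i + 1:02d}", c) for i, c in enumerate(counts)]


@dataclass
class PanelConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror a 32-genotype collection in four latent groups with a
    SCoT-like 12-primer panel, 19 quantitative and 17 qualitative traits,
    and six measured organ regions.
    """

    n_genotypes: int = 32
    n_groups: int = 4
    primers: list[tuple[str, int]] = field(default_factory=scot_like_primers)
    freq_alpha: float = 2.0
    freq_beta: float = 2.0
    #: between-group band-frequency shift delta
    group_shift: float = 0.6
    #: fraction of bands that are group-informative
    shifted_fraction: float = 0.5
    #: fraction of group-informative bands whose splits follow the latent geometry
    coupled_fraction: float = 0.5
    n_quant_traits: int = 19
    #: RMS between-group mean separation, in units of the noise SD
    group_separation: float = 3.0
    trait_noise_sd: float = 1.0
    n_qual_traits: int = 17
    qual_levels: int = 3
    #: probability a genotype shows its group's preferred level
    qual_bias: float = 0.7
    color_organs: tuple[str, ...] = DEFAULT_ORGANS
    color_between_sd: float = 10.0
    color_within_sd: float = 3.0
    #: dimension of the latent group coordinates shared across layers
    latent_dim: int = 3
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ConfigError("n_groups must be >= 1")
        if self.n_groups > self.n_genotypes:
            raise ConfigError("more groups than genotypes")
        if self.n_genotypes < 2:
            raise ConfigError("need >= 2 genotypes")
        if not self.primers:
            raise ConfigError("need >= 1 primer")
        if self.group_shift < 0 or self.group_separation < 0:
            raise ConfigError("group shift and separation must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0 <= self.shifted_fraction <= 1:
            raise ConfigError("shifted_fraction must be in [0, 1]")
        if not 0 <= self.coupled_fraction <= 1:
            raise ConfigError("coupled_fraction must be in [0, 1]")
        if self.qual_levels < 2:
            raise ConfigError("qualitative traits need >= 2 levels")
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")


@dataclass
class SyntheticPanel:
    band_matrix: BandMatrix
    trait_table: TraitTable
    color_table: ColorTable
    true_groups: dict[str, str]
    config: PanelConfig

    def __post_init__(self) -> None:
        g = self.band_matrix.genotype_ids
        assert self.trait_table.genotype_ids == g
        assert self.color_table.genotype_ids == g


def _group_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Equal-sized (as near as possible) groups in random genotype order."""
    blocks = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    return rng.permutation(blocks)


def simulate_band_matrix(
    groups: np.ndarray,
    primers: list[tuple[str, int]],
    rng: np.random.Generator,
    freq_alpha: float = 2.0,
    freq_beta: float = 2.0,
    group_shift: float = 0.6,
    shifted_fraction: float = 0.5,
    missing_rate: float = 0.0,
    genotype_ids: list[str] | None = None,
    group_coords: np.ndarray | None = None,
    coupled_fraction: float = 0.5,
) -> BandMatrix:
    """Bernoulli band calls from group-structured presence frequencies.

    When ``group_coords`` (groups x latent dims) is given, a
    ``coupled_fraction`` of the shifted bands take their +-delta/2 offset
    signs from median splits of the latent group coordinates along random
    directions (markers tracking group relatedness); the remaining bands
    use i.i.d. signs per group (markers segregating independently of the
    latent geometry, ensuring every group pair stays distinguishable).
    """
    groups = np.asarray(groups)
    n = len(groups)
    k = int(groups.max()) + 1
    if genotype_ids is None:
        genotype_ids = [f"G{i + 1:02d}" for i in range(n)]
    band_ids: list[str] = []
    primer_of_band: dict[str, str] = {}
    freq_cols = []
    for name, n_bands in primers:
        for b in range(n_bands):
            band = f"{name}.b{b + 1}"
            band_ids.append(band)
            primer_of_band[band] = name
            base = rng.beta(freq_alpha, freq_beta)
            if rng.random() < shifted_fraction:
                if group_coords is not None and rng.random() < coupled_fraction:
                    w = rng.normal(size=group_coords.shape[1])
                    proj = group_coords @ w
                    signs = np.where(proj >= np.median(proj), 1.0, -1.0)
                else:
                    signs = rng.choice([-1.0, 1.0], size=k)
                f = base + group_shift / 2.0 * signs
            else:
                f = np.full(k, base)
            freq_cols.append(np.clip(f, 0.02, 0.98))
    freqs = np.stack(freq_cols, axis=1)  # groups x bands
    calls = (rng.random((n, len(band_ids))) < freqs[groups]).astype(float)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    return BandMatrix(genotype_ids, band_ids, primer_of_band, calls)


def _simulate_traits(
    groups: np.ndarray, cfg: PanelConfig, rng: np.random.Generator,
    genotype_ids: list[str], group_coords: np.ndarray,
) -> TraitTable:
    k = int(groups.max()) + 1
    n = len(groups)
    cols: dict[str, list] = {}
    var_types: dict[str, str] = {}
    levels: dict[str, list[str]] = {}
    sigma = cfg.trait_noise_sd
    for t in range(cfg.n_quant_traits):
        var = f"Q{t + 1:02d}"
        v = rng.normal(size=group_coords.shape[1])
        v /= np.linalg.norm(v)
        means = cfg.group_separation * sigma / np.sqrt(2.0) * (group_coords @ v)
        cols[var] = list(means[groups] + rng.normal(0.0, sigma, size=n))
        var_types[var] = QUANTITATIVE
    level_names = [f"L{j + 1}" for j in range(cfg.qual_levels)]
    for t in range(cfg.n_qual_traits):
        var = f"C{t + 1:02d}"
        # groups ranked along a random latent direction, binned into levels
        w = rng.normal(size=group_coords.shape[1])
        ranks = np.argsort(np.argsort(group_coords @ w))
        preferred = (ranks * cfg.qual_levels // k).astype(int)
        vals = []
        for g in groups:
            if rng.random() < cfg.qual_bias:
                vals.append(level_names[preferred[g]])
            else:
                vals.append(level_names[rng.integers(0, cfg.qual_levels)])
        cols[var] = vals
        var_types[var] = QUALITATIVE
        levels[var] = list(level_names)
    values = pd.DataFrame(cols, index=genotype_ids)
    return TraitTable(values, var_types, levels)


#: plausible CIELab centers per channel
_COLOR_CENTERS = {"L": 55.0, "a": 10.0, "b": 15.0}


def _simulate_colors(
    groups: np.ndarray, cfg: PanelConfig, rng: np.random.Generator,
    genotype_ids: list[str], group_coords: np.ndarray,
) -> ColorTable:
    k = int(groups.max()) + 1
    rows = []
    for organ in cfg.color_organs:
        means = {}
        for ch, center in _COLOR_CENTERS.items():
            w = rng.normal(size=group_coords.shape[1])
            w /= np.linalg.norm(w)
            means[ch] = center + cfg.color_between_sd * (group_coords @ w)
        for i, g in enumerate(genotype_ids):
            grp = groups[i]
            L = float(np.clip(
                means["L"][grp] + rng.normal(0.0, cfg.color_within_sd), 0.0, 100.0
            ))
            a = float(means["a"][grp] + rng.normal(0.0, cfg.color_within_sd))
            b = float(means["b"][grp] + rng.normal(0.0, cfg.color_within_sd))
            rows.append({"genotype": g, "organ": organ, "L": L, "a": a, "b": b})
    df = pd.DataFrame(rows)
    # reorder genotype-major so genotype_ids order is preserved
    df["__g"] = pd.Categorical(df["genotype"], categories=genotype_ids, ordered=True)
    df = df.sort_values(["__g"], kind="stable").drop(columns="__g")
    return ColorTable(df.reset_index(drop=True))


def simulate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate a full coupled panel (bands + traits + colors) from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_genotypes, config.n_groups
    genotype_ids = [f"G{i + 1:02d}" for i in range(n)]
    groups = _group_assignment(n, k, rng)
    group_coords = rng.normal(size=(k, config.latent_dim))
    bm = simulate_band_matrix(
        groups,
        config.primers,
        rng,
        freq_alpha=config.freq_alpha,
        freq_beta=config.freq_beta,
        group_shift=config.group_shift,
        shifted_fraction=config.shifted_fraction,
        missing_rate=config.missing_rate,
        genotype_ids=genotype_ids,
        group_coords=group_coords,
        coupled_fraction=config.coupled_fraction,
    )
    traits = _simulate_traits(groups, config, rng, genotype_ids, group_coords)
    colors = _simulate_colors(groups, config, rng, genotype_ids, group_coords)
    true_groups = {g: f"grp{groups[i] + 1}" for i, g in enumerate(genotype_ids)}
    return SyntheticPanel(bm, traits, colors, true_groups, config)


def config_to_dict(config: PanelConfig) -> dict:
    d = asdict(config)
    d["primers"] = [list(p) for p in config.primers]
    d["color_organs"] = list(config.color_organs)
    return d
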