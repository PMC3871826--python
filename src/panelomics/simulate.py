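"""Synthetic diversity-panel generator with planted ground truth.

The generator emulates the statistical design the analysis assumes: a panel
of inbred parent lines paired into crosses with F1 hybrids, two ordered
developmental stages, a few biological replicates, and traits on four
expression levels.  Per (trait, cross, stage) an inheritance mode is planted
by placing the hybrid mean at midparent + (D/A) * A for a D/A ratio drawn
uniformly inside the mode's band.  Genotype-by-stage interactions are
planted per trait at a configurable per-level frequency, and groups of
traits share a latent genotype factor so that their genotype means correlate
at a planted level, providing recoverable cross-level network edges.

Every stochastic choice flows from a single seed, so regeneration is
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inheritance import MODES, classify_mode
from .panel import (DEFAULT_STAGES, LEVELS, CrossDesign, PanelError,
                    TraitTable, make_trait_meta)

#: D/A bands the planted ratios are drawn from (uniform within band).
#: Open-ended bands are capped at |D/A| = 2 to keep effects realistic.
MODE_BANDS = {
    "over_recessive": (-2.0, -1.2),
    "recessive": (-1.2, -0.8),
    "additive": (-0.8, 0.8),
    "dominant": (0.8, 1.2),
    "overdominant": (1.2, 2.0),
}

_DEFAULT_TRAIT_COUNTS = {"phenotype": 3, "metabolite": 26, "enzyme": 26, "protein_spot": 60}
# per-level frequency of a planted genotype-by-stage interaction; the
# metabolite/phenotype and protein-spot frequencies match the reported
# 93% and 57%, the enzyme frequency the sparse interaction stars of the
# enzyme variation table (~5/26)
_DEFAULT_INTERACTIONS = {"phenotype": 0.93, "metabolite": 0.93, "enzyme": 0.19, "protein_spot": 0.57}
# ~60% additive inheritance with no bias between dominance and recessivity
_DEFAULT_MODES = {"over_recessive": 0.1, "recessive": 0.1, "additive": 0.6,
                  "dominant": 0.1, "overdominant": 0.1}

_LEVEL_PREFIX = {"phenotype": "phe", "metabolite": "met", "enzyme": "enz", "protein_spot": "spot"}


@dataclass
class PanelConfig:
    """Study-design and effect-size parameters of the synthetic panel.

    ``effect_scale`` is the between-genotype standard deviation in units of
    the residual (replicate) standard deviation ``noise_sd``; stage effects
    and planted interactions are drawn on the same scale.  ``baseline``
    shifts every trait to a positive concentration-like scale; it cancels in
    every downstream statistic except the max/min fold-change ratios.
    """

    n_parent_pairs: int = 4
    extra_parents: int = 0
    stages: tuple = DEFAULT_STAGES
    n_replicates: int = 3
    n_traits_per_level: dict = field(default_factory=lambda: dict(_DEFAULT_TRAIT_COUNTS))
    interaction_fraction: dict = field(default_factory=lambda: dict(_DEFAULT_INTERACTIONS))
    mode_distribution: dict = field(default_factory=lambda: dict(_DEFAULT_MODES))
    effect_scale: float = 4.0
    noise_sd: float = 1.0
    baseline: float = 50.0
    n_correlation_blocks: int = 3
    block_size: int = 5
    block_rho: float = 0.9
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if self.n_parent_pairs < 1 or self.n_replicates < 1:
            raise PanelError("n_parent_pairs and n_replicates must be positive")
        if self.extra_parents < 0:
            raise PanelError("extra_parents must be >= 0")
        bad = set(self.n_traits_per_level) - set(LEVELS)
        if bad:
            raise PanelError(f"unknown trait level(s) {sorted(bad)}")
        if any(n < 0 for n in self.n_traits_per_level.values()):
            raise PanelError("trait counts must be non-negative")
        probs = np.array([self.mode_distribution.get(m, 0.0) for m in MODES], dtype=float)
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise PanelError("mode_distribution must be non-negative and sum to 1")
        if not (0.0 <= self.block_rho < 1.0):
            raise PanelError("block_rho must lie in [0, 1)")
        if self.noise_sd < 0 or self.effect_scale < 0:
            raise PanelError("noise_sd and effect_scale must be >= 0")

    @property
    def parent_ids(self) -> list:
        n = 2 * self.n_parent_pairs + self.extra_parents
        return [f"P{i:02d}" for i in range(1, n + 1)]

    @property
    def hybrid_ids(self) -> list:
        return [f"H{i}" for i in range(1, self.n_parent_pairs + 1)]

    def cross_design(self) -> CrossDesign:
        # parent1 of cross i is P_i (the "cultivated" side), parent2 P_{i+k}
        k = self.n_parent_pairs
        return CrossDesign([
            (f"H{i}", f"P{i:02d}", f"P{i + k:02d}") for i in range(1, k + 1)
        ])

    def trait_ids_by_level(self) -> dict:
        out = {}
        for level in LEVELS:
            n = int(self.n_traits_per_level.get(level, 0))
            width = 3 if level == "protein_spot" else 2
            out[level] = [f"{_LEVEL_PREFIX[level]}_{i:0{width}d}" for i in range(1, n + 1)]
        return out


@dataclass
class PanelGroundTruth:
    """Planted parameters of a generated panel, for recovery tests.

    ``modes`` has one row per (trait, cross, stage) with the planted mode,
    D/A ratio and the exact pre-noise parent/hybrid means.  ``traits``
    records per-trait interaction flags and correlation-block membership.
    ``planted_edges`` lists within-block trait pairs (the correlations the
    generator plants on genotype means), flagged by whether the pair spans
    two expression levels.
    """

    modes: pd.DataFrame
    traits: pd.DataFrame
    planted_edges: pd.DataFrame
    config: PanelConfig


def plant_hybrid_mean(p1_mean: float, p2_mean: float, target_da_ratio: float) -> float:
    """Hybrid mean realizing a target D/A ratio for given parent means.

    Returns midparent + target * (p1 - p2)/2.  Undefined (error) for a
    non-zero target with equal parents, where A = 0.
    """
    if target_da_ratio != 0.0 and p1_mean == p2_mean:
        raise PanelError("non-additive D/A requested with equal parent means (A = 0)")
    mid = (p1_mean + p2_mean) / 2.0
    return mid + target_da_ratio * (p1_mean - p2_mean) / 2.0


def generate_panel(config: PanelConfig):
    """Generate (TraitTable, CrossDesign, PanelGroundTruth) from a config."""
    rng = np.random.default_rng(config.seed)
    stages = list(config.stages)
    parents = config.parent_ids
    design = config.cross_design()
    ids_by_level = config.trait_ids_by_level()
    trait_ids = [t for level in LEVELS for t in ids_by_level[level]]
    trait_levels = [level for level in LEVELS for _ in ids_by_level[level]]
    n_traits, n_parents, n_stages = len(trait_ids), len(parents), len(stages)
    sigma_g = config.effect_scale * config.noise_sd if config.noise_sd > 0 else config.effect_scale

    # 1. interaction flags per trait (per-level frequency)
    u = rng.random(n_traits)
    has_interaction = np.array([
        u[i] < config.interaction_fraction.get(trait_levels[i], 0.0)
        for i in range(n_traits)
    ])

    # 2. correlation-block membership, drawn from interaction-free traits so
    # block correlations on genotype means are not diluted by stage-specific
    # effects
    block_of = np.full(n_traits, -1)
    n_block_traits = config.n_correlation_blocks * config.block_size
    eligible = np.flatnonzero(~has_interaction)
    if n_block_traits > 0:
        if len(eligible) < n_block_traits:
            raise PanelError(
                f"need {n_block_traits} interaction-free traits for the planted "
                f"correlation blocks, only {len(eligible)} available"
            )
        chosen = rng.permutation(eligible)[:n_block_traits]
        for b in range(config.n_correlation_blocks):
            block_of[chosen[b * config.block_size:(b + 1) * config.block_size]] = b

    # 3. trait baselines/stage effects and genotype main effects
    stage_eff = rng.normal(0.0, sigma_g, size=(n_traits, n_stages))
    z_block = rng.normal(0.0, 1.0, size=(max(config.n_correlation_blocks, 1), n_parents))
    eps = rng.normal(0.0, 1.0, size=(n_traits, n_parents))
    g_main = np.empty((n_traits, n_parents))
    r = config.block_rho
    for i in range(n_traits):
        b = block_of[i]
        if b >= 0:
            g_main[i] = sigma_g * (math.sqrt(r) * z_block[b] + math.sqrt(1.0 - r) * eps[i])
        else:
            g_main[i] = sigma_g * eps[i]

    # 4. interaction terms (zeroed where the flag is off)
    inter = rng.normal(0.0, sigma_g, size=(n_traits, n_parents, n_stages))
    inter[~has_interaction] = 0.0

    # parent means: trait x parent x stage; the baseline keeps values on a
    # positive concentration-like scale without touching any test statistic
    parent_mean = (
        config.baseline + stage_eff[:, None, :] + g_main[:, :, None] + inter
    )

    # 5. planted modes and hybrid means
    mode_names = list(MODES)
    probs = np.array([config.mode_distribution[m] for m in mode_names])
    n_crosses = len(design)
    mode_idx = rng.choice(len(mode_names), size=(n_traits, n_crosses, n_stages), p=probs)
    u_band = rng.random(size=(n_traits, n_crosses, n_stages))
    # traits without a planted interaction keep one (mode, D/A) per cross:
    # their parental profiles are stage-parallel, and a stage-varying hybrid
    # deviation would itself be a genotype-by-stage interaction
    for s in range(1, n_stages):
        mode_idx[~has_interaction, :, s] = mode_idx[~has_interaction, :, 0]
        u_band[~has_interaction, :, s] = u_band[~has_interaction, :, 0]
    parent_pos = {g: i for i, g in enumerate(parents)}
    hybrid_mean = np.empty((n_traits, n_crosses, n_stages))
    gt_rows = []
    for c, (hybrid, p1, p2) in enumerate(design):
        i1, i2 = parent_pos[p1], parent_pos[p2]
        for i in range(n_traits):
            for s in range(n_stages):
                mode = mode_names[mode_idx[i, c, s]]
                lo, hi = MODE_BANDS[mode]
                da = lo + u_band[i, c, s] * (hi - lo)
                m1, m2 = parent_mean[i, i1, s], parent_mean[i, i2, s]
                hm = plant_hybrid_mean(m1, m2, da)
                hybrid_mean[i, c, s] = hm
                gt_rows.append({
                    "trait_id": trait_ids[i], "cross_id": hybrid, "stage": stages[s],
                    "mode": mode, "da_ratio": da,
                    "A": (m1 - m2) / 2.0, "D": hm - (m1 + m2) / 2.0,
                    "p1_mean": m1, "p2_mean": m2, "hybrid_mean": hm,
                })

    # 6. assemble replicate-level values with iid Gaussian noise
    genotypes = parents + config.hybrid_ids
    index = pd.MultiIndex.from_product(
        [genotypes, stages, range(1, config.n_replicates + 1)],
        names=("genotype", "stage", "replicate"),
    )
    mean_matrix = np.empty((len(genotypes), n_stages, n_traits))
    for gi, g in enumerate(genotypes):
        for s in range(n_stages):
            if g in parent_pos:
                mean_matrix[gi, s] = parent_mean[:, parent_pos[g], s]
            else:
                c = design.hybrids.index(g)
                mean_matrix[gi, s] = hybrid_mean[:, c, s]
    noise = rng.normal(0.0, config.noise_sd,
                       size=(len(genotypes), n_stages, config.n_replicates, n_traits))
    values = (mean_matrix[:, :, None, :] + noise).reshape(len(index), n_traits)
    if config.lognormal:
        # optional positivity transform; planted modes then hold on log scale
        values = np.exp(values / max(sigma_g, 1.0))
    frame = pd.DataFrame(values, index=index, columns=trait_ids)
    meta = make_trait_meta(trait_ids, trait_levels)
    table = TraitTable(frame, meta, tuple(stages))

    traits_gt = pd.DataFrame({
        "trait_id": trait_ids,
        "level": trait_levels,
        "has_interaction": has_interaction,
        "block": block_of,
    }).set_index("trait_id")

    edge_rows = []
    for b in range(config.n_correlation_blocks):
        members = [trait_ids[i] for i in np.flatnonzero(block_of == b)]
        for i, a in enumerate(members):
            for bb in members[i + 1:]:
                edge_rows.append({
                    "block": b, "trait_a": a, "trait_b": bb,
                    "level_a": traits_gt.at[a, "level"], "level_b": traits_gt.at[bb, "level"],
                    "cross_level": traits_gt.at[a, "level"] != traits_gt.at[bb, "level"],
                })
    planted_edges = pd.DataFrame(
        edge_rows, columns=["block", "trait_a", "trait_b", "level_a", "level_b", "cross_level"])

    truth = PanelGroundTruth(
        modes=pd.DataFrame(gt_rows),
        traits=traits_gt,
        planted_edges=planted_edges,
        config=config,
    )
    return table, design, truth
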