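"""End-to-end orchestration: simulate/load -> screen -> networks -> manifest.

A run is driven by a :class:`RunConfig` (constructible from a YAML/JSON
file).  Every artifact is written as delimited text under the output
directory, and a ``manifest.json`` records each file with its SHA-256
checksum: identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .corrnet import all_pairs_correlations, cross_level_summary, significant_edges
from .inheritance import inheritance_scan, mode_distribution
from .multivariate import autoscale, pca
from .panel import DEFAULT_STAGES, PanelError
from .simulate import PanelConfig, generate_panel
from .spls import lagged_network, spls_network
from .variation import gated_traits, variation_table

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    outdir: str = "panelomics_run"
    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    panel: PanelConfig | None = None          # synthetic input
    trait_table: str | None = None            # or paths to real input
    trait_metadata: str | None = None
    cross_design: str | None = None
    layout: str = "long"
    alpha_variation: float = 0.05
    alpha_inheritance: float = 0.05
    alpha_corr: float = 0.01
    r_min: float = 0.7
    spls: dict = field(default_factory=dict)  # n_components, keep_x, keep_y, threshold
    lagged_spls: bool = True

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        for name in ("alpha_variation", "alpha_inheritance", "alpha_corr"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise PanelError(f"{name} must lie in (0, 1); got {v}")
        if not (0.0 < self.r_min <= 1.0):
            raise PanelError(f"r_min must lie in (0, 1]; got {self.r_min}")
        thr = self.spls.get("threshold", 0.7)
        if thr < 0:
            raise PanelError("spls threshold must be >= 0")
        if self.panel is None and self.trait_table is None:
            self.panel = PanelConfig(seed=self.seed)
        if self.panel is not None:
            self.panel.seed = int(self.seed)
            unknown = set(self.stages) - set(self.panel.stages)
            if unknown:
                raise PanelError(f"unknown stage label(s) {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        panel = raw.pop("panel", None)
        cfg = cls(**raw)
        if panel is not None:
            cfg.panel = PanelConfig(**panel)
            cfg.panel.seed = int(cfg.seed)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the artifact manifest.

    Stages run in order: panel (simulate or load) -> variation screen ->
    inheritance scan -> PCA -> correlation networks -> sPLS networks.
    Any failure aborts with an error naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts.append(path)
        return path

    stage_name = "panel"
    try:
        if config.panel is not None:
            table, design, truth = generate_panel(config.panel)
            emit("ground_truth_modes.tsv", lambda p: _write_tsv(truth.modes, p))
            emit("ground_truth_traits.tsv", lambda p: _write_tsv(truth.traits, p, index=True))
        else:
            table = pio.read_trait_table(config.trait_table, config.layout,
                                         metadata=config.trait_metadata,
                                         stage_order=config.stages)
            design = pio.read_cross_design(config.cross_design)
        emit("trait_table.tsv", lambda p: pio.write_trait_table(table, p, layout="long"))
        emit("trait_metadata.tsv", lambda p: pio.write_trait_metadata(table.traits, p))
        emit("cross_design.tsv", lambda p: pio.write_cross_design(design, p))

        stages = [s for s in config.stages if s in table.stages]

        stage_name = "variation"
        var = variation_table(table, stages=stages)
        emit("variation.tsv", lambda p: _write_tsv(var, p))

        stage_name = "inheritance"
        inh = inheritance_scan(table, design, alpha=config.alpha_inheritance, stages=stages)
        emit("inheritance.tsv", lambda p: _write_tsv(inh, p))
        emit("inheritance_modes.tsv", lambda p: _write_tsv(mode_distribution(inh), p))

        stage_name = "pca"
        combined = autoscale(table.genotype_means())
        res = pca(combined)
        emit("pca_combined_scores.tsv", lambda p: _write_tsv(res.scores, p, index=True))
        emit("pca_combined_variance.tsv", lambda p: _write_tsv(
            pd.DataFrame({"component": res.scores.columns,
                          "variance_pct": res.variance_explained}), p))
        for stage in stages:
            scaled = autoscale(table.genotype_means(stage=stage))
            r = pca(scaled)
            emit(f"pca_{stage}_scores.tsv", lambda p, r=r: _write_tsv(r.scores, p, index=True))
            emit(f"pca_{stage}_loadings.tsv", lambda p, r=r: _write_tsv(r.loadings, p, index=True))

        stage_name = "corrnet"
        levels = table.traits["level"].to_dict()
        for stage in stages:
            gate = gated_traits(var, stage, alpha=config.alpha_variation)
            means = table.genotype_means(stage=stage, trait_ids=gate)
            pairs = all_pairs_correlations(means)
            emit(f"correlations_{stage}.tsv", lambda p, d=pairs: _write_tsv(d, p))
            net = significant_edges(means, levels, gated=gate,
                                    r_min=config.r_min, alpha=config.alpha_corr)
            emit(f"corr_network_{stage}.tsv",
                 lambda p, n=net: pio.write_network(n, p, "edge_list"))
            emit(f"corr_network_{stage}.graphml",
                 lambda p, n=net: pio.write_network(n, p, "graphml"))
            summ = cross_level_summary(pairs, levels, r_min=config.r_min,
                                       alpha=config.alpha_corr)
            emit(f"corr_level_summary_{stage}.tsv", lambda p, d=summ: _write_tsv(d, p))

        stage_name = "spls"
        sp = dict(config.spls)
        threshold = sp.pop("threshold", 0.7)
        for stage in stages:
            model, M, net = spls_network(table, stage, threshold=threshold, **sp)
            emit(f"spls_similarity_{stage}.tsv", lambda p, d=M: _write_tsv(d, p, index=True))
            emit(f"spls_network_{stage}.tsv",
                 lambda p, n=net: pio.write_network(n, p, "edge_list"))
        if config.lagged_spls and len(stages) >= 2:
            model, M, net = lagged_network(table, stages[0], stages[1],
                                           threshold=threshold, **sp)
            emit(f"spls_network_{stages[0]}_to_{stages[1]}.tsv",
                 lambda p, n=net: pio.write_network(n, p, "edge_list"))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {err}") from err

    manifest = {p.name: _sha256(p) for p in sorted(artifacts)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
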