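"""Core containers for a diversity-panel trait study.

A panel is a set of genotypes (inbred parent lines plus F1 hybrids) measured
for quantitative traits at one or more fruit developmental stages, with
biological replicates.  Traits live on one of four expression levels:
phenotype, metabolite, enzyme (maximal activity, Vmax) or protein_spot
(2-DE spot volume).  All values are assumed to be on a dry-weight basis so
the levels are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: the four expression levels a trait may belong to
LEVELS = ("phenotype", "metabolite", "enzyme", "protein_spot")

#: default ordered stage set: cell expansion, then orange-red ripening
DEFAULT_STAGES = ("CE", "OR")

SAMPLE_INDEX_NAMES = ("genotype", "stage", "replicate")


class PanelError(ValueError):
    """Raised when a table, design or config violates a structural invariant."""


@dataclass
class TraitTable:
    """Samples x traits matrix with per-trait level metadata.

    Parameters
    ----------
    values
        DataFrame indexed by a (genotype, stage, replicate) MultiIndex with
        one column per trait.  Missing measurements are NaN.
    traits
        DataFrame indexed by ``trait_id`` with columns ``level`` (one of
        :data:`LEVELS`) and optional ``annotation`` / ``process`` free text.
    stage_order
        Declared ordered stage set; every stage appearing in ``values`` must
        be drawn from it.
    """

    values: pd.DataFrame
    traits: pd.DataFrame
    stage_order: tuple = DEFAULT_STAGES

    def __post_init__(self) -> None:
        self.stage_order = tuple(self.stage_order)
        v = self.values
        if not isinstance(v.index, pd.MultiIndex) or v.index.nlevels != 3:
            raise PanelError("values must be indexed by (genotype, stage, replicate)")
        v.index = v.index.set_names(SAMPLE_INDEX_NAMES)
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise PanelError(f"duplicate sample key {dup!r}")
        reps = v.index.get_level_values("replicate")
        if (np.asarray(reps, dtype=float) < 1).any():
            raise PanelError("replicate numbers must be >= 1")
        unknown = set(v.index.get_level_values("stage")) - set(self.stage_order)
        if unknown:
            raise PanelError(f"stage labels {sorted(unknown)} not in declared stage set {self.stage_order}")
        t = self.traits
        if t.index.name != "trait_id":
            t = t.copy()
            t.index = t.index.set_names("trait_id")
            self.traits = t
        if t.index.duplicated().any():
            raise PanelError("duplicate trait_id in trait metadata")
        if "level" not in t.columns:
            raise PanelError("trait metadata must have a 'level' column")
        bad = set(t["level"]) - set(LEVELS)
        if bad:
            raise PanelError(f"unknown trait level(s) {sorted(bad)}; expected one of {LEVELS}")
        missing_meta = [c for c in v.columns if c not in t.index]
        if missing_meta:
            raise PanelError(f"traits without metadata: {missing_meta[:5]}")
        # keep metadata aligned to the value columns
        self.traits = t.loc[list(v.columns)]

    # -- convenience views -------------------------------------------------

    @property
    def genotypes(self) -> list:
        return list(dict.fromkeys(self.values.index.get_level_values("genotype")))

    @property
    def stages(self) -> list:
        present = set(self.values.index.get_level_values("stage"))
        return [s for s in self.stage_order if s in present]

    @property
    def trait_ids(self) -> list:
        return list(self.values.columns)

    def levels_of(self, trait_ids: Iterable[str] | None = None) -> pd.Series:
        ids = list(trait_ids) if trait_ids is not None else self.trait_ids
        return self.traits.loc[ids, "level"]

    def traits_at_level(self, level: str | Sequence[str]) -> list:
        wanted = {level} if isinstance(level, str) else set(level)
        return [t for t in self.trait_ids if self.traits.at[t, "level"] in wanted]

    def subset(self, trait_ids: Sequence[str]) -> "TraitTable":
        ids = list(trait_ids)
        return TraitTable(self.values[ids].copy(), self.traits.loc[ids].copy(), self.stage_order)

    def genotype_means(self, stage: str | None = None,
                       trait_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-genotype replicate means.

        With ``stage`` given, returns genotypes x traits for that stage.
        Without it, returns a (genotype, stage) x traits matrix, i.e. one row
        per genotype-stage cell — the input for combined-stage multivariate
        analysis.
        """
        v = self.values if trait_ids is None else self.values[list(trait_ids)]
        if stage is not None:
            if stage not in self.stage_order:
                raise PanelError(f"unknown stage {stage!r}")
            sub = v.xs(stage, level="stage")
            return sub.groupby(level="genotype", sort=True).mean()
        return v.groupby(level=["genotype", "stage"], sort=True).mean()


@dataclass
class CrossDesign:
    """Hybrid -> (parent1, parent2) mapping.

    By convention parent1 is the large-fruited *S. lycopersicum* parent of
    the cross; the sign of the additive component follows this order.
    """

    crosses: list = field(default_factory=list)  # (hybrid, parent1, parent2)

    def __post_init__(self) -> None:
        seen = set()
        for hybrid, p1, p2 in self.crosses:
            if len({hybrid, p1, p2}) != 3:
                raise PanelError(f"cross ({hybrid}, {p1}, {p2}) must have three distinct genotypes")
            if hybrid in seen:
                raise PanelError(f"hybrid {hybrid!r} listed twice")
            seen.add(hybrid)

    def __len__(self) -> int:
        return len(self.crosses)

    def __iter__(self):
        return iter(self.crosses)

    @property
    def hybrids(self) -> list:
        return [h for h, _, _ in self.crosses]

    def parents_of(self, hybrid: str) -> tuple:
        for h, p1, p2 in self.crosses:
            if h == hybrid:
                return (p1, p2)
        raise KeyError(hybrid)


def make_trait_meta(trait_ids: Sequence[str], levels: Sequence[str] | str,
                    annotation: Sequence[str] | None = None,
                    process: Sequence[str] | None = None) -> pd.DataFrame:
    """Build a trait-metadata frame from parallel sequences."""
    ids = list(trait_ids)
    if isinstance(levels, str):
        levels = [levels] * len(ids)
    df = pd.DataFrame(
        {
            "level": list(levels),
            "annotation": list(annotation) if annotation is not None else [""] * len(ids),
            "process": list(process) if process is not None else [""] * len(ids),
        },
        index=pd.Index(ids, name="trait_id"),
    )
    return df


def table_from_long(records: pd.DataFrame, traits: pd.DataFrame,
                    stage_order: Sequence[str] = DEFAULT_STAGES) -> TraitTable:
    """Assemble a TraitTable from long-format records.

    ``records`` needs columns genotype, stage, replicate, trait_id, value.
    Duplicate (sample, trait) entries are a hard error.
    """
    needed = {"genotype", "stage", "replicate", "trait_id", "value"}
    missing = needed - set(records.columns)
    if missing:
        raise PanelError(f"long records missing columns {sorted(missing)}")
    dup = records.duplicated(subset=["genotype", "stage", "replicate", "trait_id"])
    if dup.any():
        row = records.loc[dup.idxmax()]
        raise PanelError(
            "duplicate entry for sample "
            f"({row['genotype']}, {row['stage']}, {row['replicate']}) trait {row['trait_id']}"
        )
    wide = records.pivot(index=["genotype", "stage", "replicate"],
                         columns="trait_id", values="value")
    wide.columns.name = None
    # preserve metadata trait order where possible
    ordered = [t for t in traits.index if t in wide.columns]
    ordered += [t for t in wide.columns if t not in traits.index]
    return TraitTable(wide[ordered], traits, tuple(stage_order))


def coerce_numeric(frame: pd.DataFrame, context: str = "trait table") -> pd.DataFrame:
    """Coerce cells to float; non-numeric cells become NaN with a warning."""
    out = frame.apply(pd.to_numeric, errors="coerce")
    n_bad = int((out.isna() & frame.notna()).to_numpy().sum())
    if n_bad:
        warnings.warn(f"{context}: {n_bad} non-numeric cell(s) set to missing", stacklevel=2)
    return out.astype(float)
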