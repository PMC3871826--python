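"""Delimited-text I/O for trait tables, cross designs and networks.

Trait tables travel as TSV/CSV in either long layout (columns genotype,
stage, replicate, trait_id, value) or wide layout (one trait per column
after the three key columns).  Trait metadata is a separate table
(trait_id, level, annotation, process).  The delimiter is auto-detected
between tab and comma; the decimal separator is always a point.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .network import Edge, TraitNetwork
from .panel import (DEFAULT_STAGES, CrossDesign, PanelError, TraitTable,
                    coerce_numeric, make_trait_meta, table_from_long)

KEY_COLUMNS = ["genotype", "stage", "replicate"]


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_trait_metadata(path) -> pd.DataFrame:
    """Read a trait-metadata table (trait_id, level[, annotation, process])."""
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if "trait_id" not in df.columns or "level" not in df.columns:
        raise PanelError(f"{path}: trait metadata needs trait_id and level columns")
    for col in ("annotation", "process"):
        if col not in df.columns:
            df[col] = ""
    df = df.fillna({"annotation": "", "process": ""})
    return df.set_index("trait_id")[["level", "annotation", "process"]]


def write_trait_metadata(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t")


def read_trait_table(path, layout: str = "long", metadata=None,
                     stage_order: Sequence[str] = DEFAULT_STAGES) -> TraitTable:
    """Read a trait table from a delimited file.

    Parameters
    ----------
    path
        Data file.
    layout
        ``"long"`` (genotype, stage, replicate, trait_id, value rows) or
        ``"wide"`` (key columns then one column per trait).
    metadata
        Trait-metadata DataFrame, or a path to one.  For a long file that
        carries its own ``level`` column it may be omitted.
    """
    if layout not in ("long", "wide"):
        raise PanelError(f"unknown layout {layout!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing key column(s) {missing}")
    if isinstance(metadata, (str, Path)):
        metadata = read_trait_metadata(metadata)

    if layout == "long":
        if "trait_id" not in df.columns or "value" not in df.columns:
            raise PanelError(f"{path}: long layout needs trait_id and value columns")
        if metadata is None:
            if "level" not in df.columns:
                raise PanelError(f"{path}: no metadata given and no 'level' column present")
            meta_src = df.drop_duplicates("trait_id")
            metadata = make_trait_meta(
                meta_src["trait_id"],
                meta_src["level"],
                meta_src.get("annotation"),
                meta_src.get("process"),
            )
        rec = df[["genotype", "stage", "trait_id"]].copy()
        rec["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
        rec["value"] = pd.to_numeric(df["value"], errors="coerce")
        n_bad = int((rec["value"].isna() & df["value"].notna()).sum())
        if n_bad:
            warnings.warn(f"{path}: {n_bad} non-numeric value(s) set to missing")
        return table_from_long(rec, metadata, stage_order)

    # wide layout
    trait_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    if metadata is None:
        raise PanelError(f"{path}: wide layout requires a trait-metadata table")
    keys = pd.MultiIndex.from_arrays(
        [df["genotype"], df["stage"], pd.to_numeric(df["replicate"]).astype(int)],
        names=("genotype", "stage", "replicate"),
    )
    if keys.duplicated().any():
        raise PanelError(f"{path}: duplicate sample key {keys[keys.duplicated()][0]!r}")
    values = coerce_numeric(df[trait_cols].set_axis(keys, axis=0), context=str(path))
    return TraitTable(values, metadata, tuple(stage_order))


def write_trait_table(table: TraitTable, path, layout: str = "long") -> None:
    """Write a trait table as TSV in long or wide layout."""
    if layout == "wide":
        table.values.to_csv(path, sep="\t")
        return
    if layout != "long":
        raise PanelError(f"unknown layout {layout!r}")
    long = (
        table.values.stack(future_stack=True)
        .rename("value")
        .reset_index()
        .rename(columns={"level_3": "trait_id"})
    )
    long.to_csv(path, sep="\t", index=False)


def read_cross_design(path) -> CrossDesign:
    """Read a three-column (hybrid, parent1, parent2) table."""
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    needed = ["hybrid", "parent1", "parent2"]
    if list(df.columns[:3]) != needed:
        # accept any header naming as long as there are three columns
        if df.shape[1] < 3:
            raise PanelError(f"{path}: cross design needs three columns (hybrid, parent1, parent2)")
        df = df.iloc[:, :3].set_axis(needed, axis=1)
    crosses = [tuple(row) for row in df.itertuples(index=False)]
    return CrossDesign(crosses)


def write_cross_design(design: CrossDesign, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["hybrid", "parent1", "parent2"])
        writer.writerows(design.crosses)


# -- networks ---------------------------------------------------------------

NETWORK_FORMATS = ("edge_list", "graphml")


def write_network(net: TraitNetwork, path, format: str = "edge_list") -> None:
    """Serialize a network as a plain edge list or GraphML.

    The edge list keeps one row per edge (node_a, node_b, weight, source);
    GraphML additionally preserves isolated nodes and node levels.
    """
    if format == "edge_list":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["node_a", "node_b", "weight", "source"])
            for e in net.edges:
                writer.writerow([e.node_a, e.node_b, f"{e.weight:.10g}", e.source])
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise PanelError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_list", levels=None) -> TraitNetwork:
    """Read a network written by :func:`write_network`.

    ``levels`` (mapping trait_id -> level) may re-attach level annotation to
    an edge list, which does not store it.
    """
    if format == "edge_list":
        df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
        edges = [
            Edge(r.node_a, r.node_b, float(r.weight), str(r.source))
            for r in df.itertuples(index=False)
        ]
        net = TraitNetwork(edges=edges)
        if levels:
            net.nodes = {n: levels.get(n, "unknown") for n in net.nodes}
        return net
    if format == "graphml":
        return TraitNetwork.from_networkx(nx.read_graphml(path))
    raise PanelError(f"unknown network format {format!r}")
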