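"""Readers and writers for the tab-delimited interchange formats.

Expression: genes x samples TSV, first column gene ids, header row sample
ids.  Traits: samples x traits TSV.  Survival: (sample, time, event) TSV.
Networks are written both as weighted edge lists and GML.  Every table
written here carries a comment header documenting its columns, and a run
manifest (JSON) records the configuration, seeds and package versions
needed to reproduce an output directory.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "read_traits",
    "read_survival",
    "read_pair_list",
    "write_pair_list",
    "write_network",
    "read_network",
    "write_table",
    "write_manifest",
]


def read_expression(path) -> pd.DataFrame:
    """Parse and validate a genes x samples expression TSV.

    Raises with the offending identifiers on duplicate gene ids and with
    (gene, sample) coordinates on non-numeric or missing cells.  Constant
    (zero-variance) rows are legal but reported via ``attrs``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene identifiers in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        locs = [
            (str(numeric.index[i]), str(numeric.columns[j]))
            for i, j in zip(*np.where(bad.to_numpy()))
        ][:10]
        raise ValueError(f"non-numeric or missing cells in {path} at {locs}")
    numeric.index = numeric.index.map(str)
    numeric.columns = numeric.columns.map(str)
    constant = numeric.index[numeric.std(axis=1) == 0].tolist()
    numeric.attrs["constant_rows"] = constant
    return numeric


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    return df


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table lacks required columns: {sorted(missing)}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return df[["time", "event"]]


_PAIR_HEADER = "# ranked candidate pairs: node1, node2, similarity, nominal p, FDR\n"


def write_pair_list(pairs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_PAIR_HEADER)
        pairs.to_csv(fh, sep="\t", index=False)


def read_pair_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_network(network: nx.Graph, path_prefix) -> None:
    """Write a weighted edge list TSV and a GML file for a network."""
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("# weighted edge list: node1, node2, weight (co-expression similarity)\n")
        for u, v, w in sorted(
            ((str(u), str(v), w) for u, v, w in network.edges(data="weight", default=1.0))
        ):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")
    g = nx.relabel_nodes(network, {u: str(u) for u in network.nodes})
    nx.write_gml(g, prefix.with_suffix(".gml"))


def read_network(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=float(w))
    return g


def write_table(df: pd.DataFrame, path, header_comment: str = "", index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_manifest(path, config: dict, seed: int, stage_log: list | None = None) -> None:
    import pfnet

    manifest = {
        "package": "pfnet",
        "version": getattr(pfnet, "__version__", "unknown"),
        "python": sys.version.split()[0],
        "seed": seed,
        "config": _jsonable(config),
        "stages": stage_log or [],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
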