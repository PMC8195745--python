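"""File formats: count-table/metadata TSV, edge-list TSV, GraphML,
distance-matrix TSV, JSON reports, and flat design configs.

The count-table dialect: first column ``otu_id``, header row of sample
ids, integer cells. Metadata TSV is joined on ``sample_id`` and must
carry ``experiment`` and ``condition`` columns. Every writer's output
is re-readable by the matching reader.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable, SignedNetwork

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_network_tsv",
    "write_network_tsv",
    "write_network_graphml",
    "write_distance_matrix",
    "read_distance_matrix",
    "read_taxonomy",
    "write_json",
    "read_design_config",
    "write_design_config",
]


def read_count_table(path, metadata_path) -> CountTable:
    """Read a counts TSV plus a metadata TSV into a validated CountTable."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    if df.empty and not otu_ids:
        counts = np.zeros((0, len(sample_ids)), dtype=np.int64)
    else:
        counts = np.zeros(df.shape, dtype=np.int64)
        for j, col in enumerate(df.columns):
            for i, raw in enumerate(df[col]):
                try:
                    val = int(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-integer cell at OTU {otu_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}: {raw!r}") from None
                if val < 0:
                    raise ValueError(
                        f"negative count at OTU {otu_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}: {val}")
                counts[i, j] = val
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    unknown = sorted(set(meta.index) - set(sample_ids))
    if unknown:
        raise ValueError(f"metadata lists unknown samples: {unknown}")
    return CountTable(counts, otu_ids, sample_ids, meta)


def write_count_table(table: CountTable, path, metadata_path) -> None:
    table.to_frame().rename_axis("otu_id").to_csv(path, sep="\t")
    table.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


# ----------------------------------------------------------------------
NETWORK_COLUMNS = ["otu_a", "otu_b", "partial_r", "sign", "stability_frequency"]


def write_network_tsv(net: SignedNetwork, path) -> None:
    rows = []
    for (a, b), w in sorted(net.edges.items()):
        rows.append({
            "otu_a": a, "otu_b": b, "partial_r": w,
            "sign": "+" if w > 0 else "-",
            "stability_frequency": net.stability.get((a, b), ""),
        })
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_network_tsv(path, name: str | None = None) -> SignedNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"otu_a": str, "otu_b": str})
    edges = {}
    stability = {}
    for _, row in df.iterrows():
        pair = (row["otu_a"], row["otu_b"])
        edges[pair] = float(row["partial_r"])
        f = row.get("stability_frequency")
        if f is not None and not (isinstance(f, float) and math.isnan(f)) and f != "":
            stability[pair] = float(f)
    return SignedNetwork(name=name or Path(path).stem, edges=edges,
                         stability=stability)


def write_network_graphml(net: SignedNetwork, path) -> None:
    import networkx as nx

    g = net.to_networkx()
    for (a, b), f in net.stability.items():
        if g.has_edge(a, b):
            g[a][b]["stability_frequency"] = f
    nx.write_graphml(g, path)


# ----------------------------------------------------------------------
def write_distance_matrix(dist, path) -> None:
    """Square TSV with a header row/column of sample ids."""
    data = dist.data if hasattr(dist, "data") else np.asarray(dist)
    ids = list(dist.ids) if hasattr(dist, "ids") else [str(i) for i in range(len(data))]
    pd.DataFrame(data, index=ids, columns=ids).rename_axis("sample_id") \
        .to_csv(path, sep="\t")


def read_distance_matrix(path):
    from skbio import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def read_taxonomy(path) -> dict[str, str]:
    """Taxonomy TSV: columns ``otu_id`` and ``phylum`` (extra ranks kept aside)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "otu_id" not in df.columns or "phylum" not in df.columns:
        raise ValueError("taxonomy TSV needs 'otu_id' and 'phylum' columns")
    return dict(zip(df["otu_id"], df["phylum"]))


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


# ----------------------------------------------------------------------
def write_design_config(design, path) -> None:
    """Flat ``key = value`` serialization of a StudyDesign (edge sets as JSON)."""
    lines = []
    for key, val in design.__dict__.items():
        if isinstance(val, dict):
            enc = {}
            for k, v in val.items():
                if isinstance(v, dict):  # per-species edge sets
                    enc[k] = {f"{i},{j}": s for (i, j), s in v.items()}
                else:
                    enc[f"{k[0]},{k[1]}"] = v
            lines.append(f"{key} = {json.dumps(enc)}")
        elif isinstance(val, tuple):
            lines.append(f"{key} = {json.dumps(list(val))}")
        else:
            lines.append(f"{key} = {json.dumps(val)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_design_config(path):
    from .simulate import StudyDesign

    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        val = json.loads(raw.strip())
        if key in ("backbone_edges", "common_ic_edges"):
            val = {tuple(map(int, k.split(","))): s for k, s in val.items()}
        elif key in ("sc_edges", "ic_specific_edges"):
            val = {sp: {tuple(map(int, k.split(","))): s for k, s in d.items()}
                   for sp, d in val.items()}
        elif key == "conditions":
            val = tuple(val)
        kwargs[key] = val
    return StudyDesign(**kwargs)
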