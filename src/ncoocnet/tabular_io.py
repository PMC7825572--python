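"""Readers and writers for the tabular and graph formats the pipeline touches.

Formats
-------
* OTU table: tab-delimited, OTUs as rows, samples as columns, first
  column the OTU id, final column ``taxonomy`` (a ``;``-separated
  lineage; ``g__``-style rank prefixes accepted but not required).
* Soil metadata: tab-delimited, samples as rows, numeric variables as
  columns, missing values encoded ``NA``.
* Networks: GraphML (round-trippable) or a flat edge-list TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "SoilMetadata",
    "extract_genus",
    "read_abundance_table",
    "write_abundance_table",
    "read_soil_metadata",
    "write_soil_metadata",
    "read_network",
    "write_network",
    "write_reports",
]

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "d__")


def extract_genus(lineage: str) -> str:
    """Genus = last non-empty rank of a ``;``-separated lineage.

    Rank prefixes (``g__`` etc.) are stripped.  An empty or
    all-unclassified lineage yields ``"unclassified"``.
    """
    ranks = [r.strip() for r in str(lineage).split(";")]
    for rank in reversed(ranks):
        name = rank
        for pre in _RANK_PREFIXES:
            if name.lower().startswith(pre):
                name = name[len(pre):]
                break
        if name and name.lower() not in ("", "unclassified", "nan"):
            return name
    return "unclassified"


@dataclass
class AbundanceTable:
    """OTU x sample count matrix with per-OTU taxonomy and per-sample group.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = OTU ids, columns = sample ids.
    taxonomy : pandas.Series
        Lineage string per OTU, aligned to ``counts.index``.
    group : pandas.Series
        Treatment label per sample, aligned to ``counts.columns``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts contain non-finite values")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        if self.taxonomy.isna().any():
            missing = self.taxonomy.index[self.taxonomy.isna()].tolist()
            raise ValueError(f"missing taxonomy for OTUs: {missing}")
        self.group = self.group.reindex(self.counts.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise ValueError(f"missing group label for samples: {missing}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genus(self) -> pd.Series:
        return self.taxonomy.map(extract_genus)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group:
            if g not in seen:
                seen.append(g)
        return seen

    def subset(self, otus=None, samples=None) -> "AbundanceTable":
        counts = self.counts
        if otus is not None:
            counts = counts.loc[list(otus)]
        if samples is not None:
            counts = counts[list(samples)]
        return AbundanceTable(
            counts=counts,
            taxonomy=self.taxonomy.reindex(counts.index),
            group=self.group.reindex(counts.columns),
        )


@dataclass
class SoilMetadata:
    """Per-sample numeric soil variables (pH, AP, AK, AN, ... extensible).

    ``data`` has samples as rows and variables as columns; missing values
    are NaN and are excluded pairwise from downstream correlations.
    """

    data: pd.DataFrame
    constant_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


def _infer_groups(sample_ids) -> pd.Series:
    """Group = text before the final underscore when every id has one."""
    ids = list(sample_ids)
    if all("_" in s for s in ids):
        return pd.Series([s.rsplit("_", 1)[0] for s in ids], index=ids)
    return pd.Series(["all"] * len(ids), index=ids)


def read_abundance_table(path, group_map=None) -> AbundanceTable:
    """Read a tab-delimited OTU table (rows = OTUs, final column taxonomy).

    ``group_map`` optionally maps sample id -> treatment label; when
    absent, groups are inferred from the ``<group>_<replicate>`` sample
    naming convention, falling back to a single group ``"all"``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    if "taxonomy" not in df.columns:
        raise ValueError(f"{path}: missing required final 'taxonomy' column")
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(cols)) != len(cols):
        dups = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"{path}: duplicated sample headers: {dups}")
    taxonomy = df["taxonomy"].fillna("unclassified")
    counts_raw = df.drop(columns=["taxonomy"])
    try:
        counts = counts_raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count value: {exc}") from exc
    bad = ~np.isfinite(counts.to_numpy())
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-finite count at OTU {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    if (counts.to_numpy() < 0).any():
        r, c = np.argwhere(counts.to_numpy() < 0)[0]
        raise ValueError(
            f"{path}: negative count at OTU {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    if group_map is not None:
        group = pd.Series({s: group_map[s] for s in counts.columns})
    else:
        group = _infer_groups(counts.columns)
    return AbundanceTable(counts=counts, taxonomy=taxonomy, group=group)


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.counts.copy()
    df["taxonomy"] = table.taxonomy
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_soil_metadata(path, table: AbundanceTable | None = None) -> SoilMetadata:
    """Read sample x variable metadata; reorder to ``table``'s samples.

    Samples absent from the table are dropped with a logged warning;
    zero overlap is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = None
    meta = SoilMetadata(data=df)
    if table is not None:
        meta = match_samples(meta, table)
    return meta


def match_samples(metadata: SoilMetadata, table: AbundanceTable) -> SoilMetadata:
    """Reorder metadata rows to the table's sample order, dropping extras."""
    wanted = table.sample_ids
    present = [s for s in wanted if s in metadata.data.index]
    if not present:
        raise ValueError("no overlapping samples between metadata and table")
    extra = [s for s in metadata.data.index if s not in wanted]
    if extra:
        logger.warning("dropping %d unmatched metadata samples: %s", len(extra), extra)
    missing = [s for s in wanted if s not in metadata.data.index]
    if missing:
        logger.warning("table samples missing from metadata: %s", missing)
    return SoilMetadata(data=metadata.data.loc[present])


def write_soil_metadata(metadata: SoilMetadata, path) -> None:
    df = metadata.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def write_network(network, path, format: str = "graphml") -> None:
    """Write a network as GraphML or an edge-list TSV.

    GraphML nodes carry id, genus, node_class and mean relative
    abundance; edges carry sign, observed score and BH q-value.  The TSV
    mirrors the edge attributes one edge per row.
    """
    g = _as_graph(network)
    fmt = format.lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt in ("tsv", "edgelist", "edge-list"):
        rows = []
        for u, v, attrs in g.edges(data=True):
            row = {"source": u, "target": v}
            row.update(attrs)
            rows.append(row)
        cols = ["source", "target", "sign", "score", "q"]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = pd.Series(dtype=object)
        extra = [c for c in df.columns if c not in cols]
        df[cols + extra].to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path) -> nx.Graph:
    """Read a GraphML file written by :func:`write_network`."""
    return nx.read_graphml(path)


def write_reports(topology_reports, keystones, stats, out_dir) -> dict[str, Path]:
    """Write the per-network topology table, keystone lists and extra stats.

    ``topology_reports`` maps network label -> TopologyReport-like object
    (anything with the seven metric attributes); ``keystones`` maps label
    -> list of (node id, degree, closeness, betweenness) records;
    ``stats`` maps file stem -> DataFrame and is written verbatim.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    metric_cols = [
        "nodes", "edges", "clustering_coefficient", "network_diameter",
        "shortest_paths", "avg_neighbors", "graph_density",
    ]
    rows = []
    for label, rep in topology_reports.items():
        row = {"network": label}
        row.update({c: getattr(rep, c) for c in metric_cols})
        rows.append(row)
    topo_path = out_dir / "topology_report.tsv"
    pd.DataFrame(rows, columns=["network"] + metric_cols).to_csv(
        topo_path, sep="\t", index=False
    )
    written["topology"] = topo_path

    key_rows = []
    for label, nodes in keystones.items():
        for rec in nodes:
            key_rows.append({
                "network": label,
                "node": rec["node"],
                "degree": rec["degree"],
                "closeness": rec["closeness"],
                "betweenness": rec["betweenness"],
            })
    key_path = out_dir / "keystone_taxa.tsv"
    pd.DataFrame(
        key_rows,
        columns=["network", "node", "degree", "closeness", "betweenness"],
    ).to_csv(key_path, sep="\t", index=False)
    written["keystones"] = key_path

    for stem, df in (stats or {}).items():
        p = out_dir / f"{stem}.tsv"
        df.to_csv(p, sep="\t")
        written[stem] = p
    return written
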