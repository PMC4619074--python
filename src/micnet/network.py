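"""Cross-platform correlation networks: edge filtering, single-linkage
grouping (connected components of the thresholded graph) and hub discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .blocks import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    threshold: float = 0.75
    min_hub_degree: int = 4
    use_absolute_pearson: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValidationError("threshold must lie in (0, 1]")
        if self.min_hub_degree < 1:
            raise ValidationError("min_hub_degree must be >= 1")


def filter_edges(pairs: pd.DataFrame, config: NetworkConfig | None = None
                 ) -> pd.DataFrame:
    """Keep cross-platform pairs whose Pearson (|r| by default) or MIC meets
    the threshold; each edge carries the larger qualifying magnitude as its
    weight. Missing statistics never qualify."""
    config = config or NetworkConfig()
    cross = pairs["platform_a"] != pairs["platform_b"]
    r = pairs["pearson_r"].to_numpy(dtype=float)
    r_mag = np.abs(r) if config.use_absolute_pearson else r
    r_ok = ~np.isnan(r) & (r_mag >= config.threshold)
    mic = pairs["mic"].to_numpy(dtype=float)
    mic_ok = ~np.isnan(mic) & (mic >= config.threshold)
    keep = cross.to_numpy() & (r_ok | mic_ok)
    out = pairs.loc[keep].copy()
    qual_r = np.where(r_ok[keep], np.abs(r[keep]), -np.inf)
    qual_m = np.where(mic_ok[keep], mic[keep], -np.inf)
    out["weight"] = np.maximum(qual_r, qual_m)
    return out.reset_index(drop=True)


def build_network(edges: pd.DataFrame,
                  node_platforms: dict[str, str] | None = None) -> nx.Graph:
    """Graph whose components are the single-linkage groups at the applied
    threshold; component ids are deterministic (smallest member first)."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.feature_a, platform=row.platform_a)
        g.add_node(row.feature_b, platform=row.platform_b)
        g.add_edge(row.feature_a, row.feature_b, weight=float(row.weight),
                   pearson_r=float(row.pearson_r), mic=float(row.mic))
    if node_platforms:
        for node, platform in node_platforms.items():
            if node in g:
                g.nodes[node]["platform"] = platform
    components = sorted((sorted(c) for c in nx.connected_components(g)),
                        key=lambda c: c[0])
    for cid, members in enumerate(components):
        for node in members:
            g.nodes[node]["component"] = cid
    for node in g:
        g.nodes[node]["degree"] = g.degree[node]
    return g


@dataclass
class HubReport:
    hubs: list[str]
    neighbors: dict[str, list[str]]
    degrees: dict[str, int]

    def __len__(self) -> int:
        return len(self.hubs)


def find_hubs(network: nx.Graph, config: NetworkConfig | None = None) -> HubReport:
    """Nodes with at least ``min_hub_degree`` neighbors, with neighbor lists."""
    config = config or NetworkConfig()
    hubs = sorted(n for n in network if network.degree[n] >= config.min_hub_degree)
    for node in network:
        network.nodes[node]["is_hub"] = node in set(hubs)
    return HubReport(
        hubs=hubs,
        neighbors={h: sorted(network.neighbors(h)) for h in hubs},
        degrees={h: network.degree[h] for h in hubs},
    )


def hub_gene_list(report: HubReport, gene_symbols: pd.Series) -> list[str]:
    """Unique gene symbols of hubs and their neighbors, in first-seen order;
    features without a symbol (phenotypes, unannotated probes) are dropped."""
    out: list[str] = []
    seen: set[str] = set()
    for hub in report.hubs:
        for feat in [hub, *report.neighbors[hub]]:
            symbol = gene_symbols.get(feat, "")
            if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)):
                symbol = ""
            symbol = str(symbol)
            if not symbol:
                log.info("feature %s has no gene symbol; dropped from hub list", feat)
                continue
            if symbol not in seen:
                seen.add(symbol)
                out.append(symbol)
    return out


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def write_edge_tsv(network: nx.Graph, path: str | Path) -> None:
    rows = [
        {"feature_a": a, "feature_b": b, **{k: d[k] for k in ("weight", "pearson_r", "mic")}}
        for a, b, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "weight",
                                "pearson_r", "mic"]).to_csv(path, sep="\t", index=False)
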