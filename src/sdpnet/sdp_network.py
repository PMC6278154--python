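"""Specificity-determining networks over cluster-determining positions.

CDP columns become graph nodes; an edge joins two CDPs whose covariation
z-score reaches the threshold (default 6.5, the conventional cut-off for
alignments of roughly 400 identity clusters).  Nodes with two or more
direct connections are promoted to SDP (specificity determining position),
nodes with exactly one connection are putative SDPs (pSDP), isolated nodes
stay unsupported.  Connected components of the graph are the specificity
determining networks (SDNs).  Positions classified SDP in the networks of
two independently analysed clades are "key SDPs".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .alignment_io import ColumnMap
from .cdp import CdpResult
from .covariation import CovariationResult

SDP = "SDP"
PSDP = "pSDP"
UNSUPPORTED = "unsupported"

CLUSTER_COUNT_ADVISORY = 400  # above this the z threshold should be raised


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class SdpNetwork:
    """CDP graph with SDP/pSDP classification and SDN components."""

    nodes: tuple[int, ...]  # 1-based columns, sorted
    edges: frozenset[tuple[int, int]]  # i < j
    threshold: float
    node_class: dict[int, str]
    components: tuple[frozenset[int], ...]  # SDNs, size-descending
    degree: dict[int, int]

    def sdp_columns(self) -> frozenset[int]:
        return frozenset(n for n, c in self.node_class.items() if c == SDP)

    def psdp_columns(self) -> frozenset[int]:
        return frozenset(n for n, c in self.node_class.items() if c == PSDP)

    def component_of(self, node: int) -> int | None:
        """0-based SDN index of a node, or None if isolated."""
        for k, comp in enumerate(self.components):
            if node in comp:
                return k
        return None

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        for n in self.nodes:
            g.nodes[n]["class"] = self.node_class[n]
        return g


def empty_network(z_threshold: float = 6.5) -> SdpNetwork:
    """The network over zero CDPs (e.g. a scan with no significant columns)."""
    return SdpNetwork(
        nodes=(),
        edges=frozenset(),
        threshold=z_threshold,
        node_class={},
        components=(),
        degree={},
    )


def build_network(
    cdps: list[CdpResult],
    cov: CovariationResult,
    z_threshold: float = 6.5,
    n_clusters: int | None = None,
) -> SdpNetwork:
    """Threshold the covariation z-scores over CDP columns.

    Only edges between two CDP columns enter the graph ("direct
    connections"); other alignment columns never mediate.  A coverage error
    is raised when a CDP column is missing from the covariation result.
    Passing ``n_clusters`` enables an advisory warning when the dataset
    exceeds the cluster count the default threshold was calibrated for.
    """
    cdp_cols = sorted({c.column for c in cdps if c.is_cdp})
    if not cdp_cols:
        raise NetworkError("no CDP columns to build a network from")
    covered = set(cov.columns_used)
    missing = [c for c in cdp_cols if c not in covered]
    if missing:
        raise NetworkError(
            f"CDP columns absent from covariation result: {missing}"
        )
    if n_clusters is not None and n_clusters > CLUSTER_COUNT_ADVISORY:
        warnings.warn(
            f"dataset has {n_clusters} identity clusters (> "
            f"{CLUSTER_COUNT_ADVISORY}); z threshold {z_threshold} may be "
            "too permissive and should likely be raised",
            stacklevel=2,
        )
    edges = set()
    for a_idx, a in enumerate(cdp_cols):
        for b in cdp_cols[a_idx + 1 :]:
            score = cov.pairs.get((a, b))
            if score is not None and score.z >= z_threshold:
                edges.add((a, b))
    g = nx.Graph()
    g.add_nodes_from(cdp_cols)
    g.add_edges_from(edges)
    degree = {n: int(d) for n, d in g.degree()}
    node_class = {
        n: SDP if d >= 2 else (PSDP if d == 1 else UNSUPPORTED)
        for n, d in degree.items()
    }
    comps = [frozenset(c) for c in nx.connected_components(g) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return SdpNetwork(
        nodes=tuple(cdp_cols),
        edges=frozenset(edges),
        threshold=z_threshold,
        node_class=node_class,
        components=tuple(comps),
        degree=degree,
    )


@dataclass(frozen=True)
class KeySdpResult:
    positions: frozenset[int]  # reference numbering
    unmapped_columns: frozenset[int]  # SDP columns the reference gaps over


def key_sdps(
    net_a: SdpNetwork,
    net_b: SdpNetwork,
    map_a: ColumnMap,
    map_b: ColumnMap,
    include_psdp: bool = False,
) -> KeySdpResult:
    """Reference positions classified SDP in both networks.

    pSDPs are excluded by default (they need corroborating evidence before
    promotion); ``include_psdp`` admits them for exploration.  SDP columns
    the reference sequence gaps over cannot be compared across datasets and
    are returned in a side list.
    """
    if map_a.reference_id != map_b.reference_id:
        raise NetworkError(
            "key-SDP intersection requires both networks mapped to the same "
            f"reference ({map_a.reference_id!r} vs {map_b.reference_id!r})"
        )

    def ref_set(net: SdpNetwork, cmap: ColumnMap) -> tuple[set[int], set[int]]:
        cols = set(net.sdp_columns())
        if include_psdp:
            cols |= net.psdp_columns()
        mapped, unmapped = set(), set()
        for c in cols:
            r = cmap.ref_position(c)
            (mapped.add(r) if r is not None else unmapped.add(c))
        return mapped, unmapped

    ref_a, un_a = ref_set(net_a, map_a)
    ref_b, un_b = ref_set(net_b, map_b)
    return KeySdpResult(
        positions=frozenset(ref_a & ref_b),
        unmapped_columns=frozenset(un_a | un_b),
    )


def connectivity_table(
    nets: list[SdpNetwork], maps: list[ColumnMap], names: list[str] | None = None
) -> pd.DataFrame:
    """Per reference position: class, degree and SDN id in every network."""
    if not nets:
        raise NetworkError("at least one network required")
    if names is None:
        names = [f"net{k + 1}" for k in range(len(nets))]
    rows: dict[int | str, dict] = {}
    for name, net, cmap in zip(names, nets, maps):
        for col in net.nodes:
            ref = cmap.ref_position(col)
            key = ref if ref is not None else f"col{col}"
            row = rows.setdefault(key, {"ref_position": key})
            comp = net.component_of(col)
            row[f"{name}_class"] = net.node_class[col]
            row[f"{name}_degree"] = net.degree[col]
            row[f"{name}_sdn"] = f"SDN{comp + 1}" if comp is not None else None
    table = pd.DataFrame(sorted(rows.values(), key=lambda r: str(r["ref_position"])))
    return table


def threshold_sweep_table(
    cdps: list[CdpResult], cov: CovariationResult, z_values: list[float]
) -> pd.DataFrame:
    """Edge/SDP/pSDP/SDN counts as the z threshold is swept."""
    if not z_values:
        raise ValueError("empty threshold list")
    rows = []
    for z in z_values:
        net = build_network(cdps, cov, z_threshold=z)
        classes = list(net.node_class.values())
        rows.append(
            {
                "z_threshold": z,
                "n_edges": len(net.edges),
                "n_sdp": classes.count(SDP),
                "n_psdp": classes.count(PSDP),
                "n_sdn": len(net.components),
                "sdn_sizes": ",".join(str(len(c)) for c in net.components),
            }
        )
    return pd.DataFrame(rows)


def export_edge_list(net: SdpNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("col_i\tcol_j\n")
        for i, j in sorted(net.edges):
            fh.write(f"{i}\t{j}\n")


def export_graphml(net: SdpNetwork, path) -> None:
    nx.write_graphml(net.to_graph(), path)


def network_summary(net: SdpNetwork) -> dict:
    classes = list(net.node_class.values())
    return {
        "threshold": net.threshold,
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_sdp": classes.count(SDP),
        "n_psdp": classes.count(PSDP),
        "n_unsupported": classes.count(UNSUPPORTED),
        "sdn_sizes": [len(c) for c in net.components],
    }
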