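"""End-to-end two-clade specificity analysis.

The canonical workflow: trim the alignment, weight sequences by identity
clustering, scan for cluster-determining positions between two focal
clades, run covariation analysis three times (each clade alone and both
combined), build an SDP network from each covariation result, intersect
the two single-clade networks for key SDPs, and call clade-specific
inserts on the untrimmed alignment (inserts live exactly in the gap-rich
regions trimming removes).

Key-SDP determination deliberately uses only the two single-clade
networks: the combined dataset has many more identity clusters, where a
fixed covariation z threshold grows too permissive; the combined network
is still computed and reported for comparison.

Every stochastic stage requires a seed; a run is a pure function of
(inputs, config, seed), and the config is archived next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import alignment_io, cdp, covariation, csi, grouping, sdp_network
from .alignment_io import Alignment, ColumnMap
from .grouping import GroupAssignment, SequenceWeights

logger = logging.getLogger("sdpnet.pipeline")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Serializable parameters of a full run; see module docstring."""

    msa: str | None = None
    tree: str | None = None
    group_table: str | None = None
    pdb: str | None = None
    reference_id: str | None = None
    first_residue_number: int = 1
    trim_g: float = 0.3
    trim_h: float = 0.8
    identity_threshold: float = 0.62
    n_perm: int = 999
    alpha: float = 0.05
    adjust: str = "bh"
    pseudocount: float = 0.05
    n_shuffles: int = 100
    z_threshold: float = 6.5
    csi_theta_in: float = 0.5
    csi_theta_out: float = 0.1
    csi_min_len: int = 5
    csi_max_gap_run: int = 2
    seed: int | None = None
    out_dir: str | None = None

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError(
                "no seed configured: stochastic stages refuse to run without one"
            )
        return self.seed

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class TwoCladeResult:
    """Artifacts of a two-clade run; attribute names follow the stages."""

    kept_columns: list[int]
    weights_combined: SequenceWeights
    weights_a: SequenceWeights
    weights_b: SequenceWeights
    cdps: list[cdp.CdpResult]
    cov_a: covariation.CovariationResult
    cov_b: covariation.CovariationResult
    cov_combined: covariation.CovariationResult
    net_a: sdp_network.SdpNetwork
    net_b: sdp_network.SdpNetwork
    net_combined: sdp_network.SdpNetwork
    key: sdp_network.KeySdpResult
    connectivity: "object"  # pandas DataFrame
    csi_calls: list[csi.InsertCall]
    column_map: ColumnMap
    clade_a: str
    clade_b: str

    def summary(self) -> dict:
        return {
            "clades": [self.clade_a, self.clade_b],
            "n_kept_columns": len(self.kept_columns),
            "n_clusters": {
                "combined": self.weights_combined.n_clusters,
                self.clade_a: self.weights_a.n_clusters,
                self.clade_b: self.weights_b.n_clusters,
            },
            "n_cdps": sum(1 for r in self.cdps if r.is_cdp),
            "networks": {
                self.clade_a: sdp_network.network_summary(self.net_a),
                self.clade_b: sdp_network.network_summary(self.net_b),
                "combined": sdp_network.network_summary(self.net_combined),
            },
            "key_sdps": sorted(self.key.positions),
            "n_csi_calls": len(self.csi_calls),
        }


def _identity_map(aln: Alignment) -> ColumnMap:
    cols = {c: c for c in range(1, aln.n_cols + 1)}
    return ColumnMap(reference_id="<columns>", col_to_ref=dict(cols))


def analyze_two_clades(
    aln: Alignment,
    groups: GroupAssignment,
    clade_a: str,
    clade_b: str,
    cfg: RunConfig | None = None,
) -> TwoCladeResult:
    """Run the full two-clade analysis on in-memory objects."""
    cfg = cfg or RunConfig(seed=0)
    seed = cfg.require_seed()
    t0 = time.time()

    if cfg.reference_id is not None:
        cmap = alignment_io.build_column_map(
            aln, cfg.reference_id, cfg.first_residue_number
        )
    else:
        cmap = _identity_map(aln)

    _, kept = alignment_io.trim_alignment(aln, g=cfg.trim_g, h=cfg.trim_h)
    logger.info("trimming kept %d/%d columns", len(kept), aln.n_cols)

    members_a = groups.members(clade_a)
    members_b = groups.members(clade_b)
    both = members_a | members_b
    aln_both = aln.subset_rows(both)
    aln_a = aln.subset_rows(members_a)
    aln_b = aln.subset_rows(members_b)

    w_both = grouping.cluster_weights(aln_both, cfg.identity_threshold)
    w_a = grouping.cluster_weights(aln_a, cfg.identity_threshold)
    w_b = grouping.cluster_weights(aln_b, cfg.identity_threshold)
    logger.info(
        "identity clusters: combined=%d %s=%d %s=%d",
        w_both.n_clusters, clade_a, w_a.n_clusters, clade_b, w_b.n_clusters,
    )

    cdps = cdp.cdp_scan(
        aln_both,
        groups,
        w_both,
        group_a=clade_a,
        group_b=clade_b,
        n_perm=cfg.n_perm,
        alpha=cfg.alpha,
        adjust=cfg.adjust,
        seed=seed,
        column_map=cmap,
        columns=kept,
    )
    n_cdps = sum(1 for r in cdps if r.is_cdp)
    logger.info("CDP scan: %d significant columns", n_cdps)

    mi_kwargs = dict(
        n_shuffles=cfg.n_shuffles,
        pseudocount=cfg.pseudocount,
        columns=kept,
    )
    cov_a = covariation.mi_zscores(aln_a, w_a, seed=seed + 1, **mi_kwargs)
    cov_b = covariation.mi_zscores(aln_b, w_b, seed=seed + 2, **mi_kwargs)
    cov_c = covariation.mi_zscores(aln_both, w_both, seed=seed + 3, **mi_kwargs)

    if n_cdps == 0:
        net_a = net_b = net_c = sdp_network.empty_network(cfg.z_threshold)
    else:
        net_a = sdp_network.build_network(
            cdps, cov_a, cfg.z_threshold, n_clusters=w_a.n_clusters
        )
        net_b = sdp_network.build_network(
            cdps, cov_b, cfg.z_threshold, n_clusters=w_b.n_clusters
        )
        net_c = sdp_network.build_network(
            cdps, cov_c, cfg.z_threshold, n_clusters=w_both.n_clusters
        )

    key = sdp_network.key_sdps(net_a, net_b, cmap, cmap)
    conn = sdp_network.connectivity_table(
        [net_a, net_b, net_c], [cmap, cmap, cmap],
        names=[clade_a, clade_b, "combined"],
    )
    calls = csi.call_csis(
        aln,
        groups,
        theta_in=cfg.csi_theta_in,
        theta_out=cfg.csi_theta_out,
        min_len=cfg.csi_min_len,
        max_gap_run=cfg.csi_max_gap_run,
        weights=grouping.cluster_weights(aln, cfg.identity_threshold),
    )
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return TwoCladeResult(
        kept_columns=kept,
        weights_combined=w_both,
        weights_a=w_a,
        weights_b=w_b,
        cdps=cdps,
        cov_a=cov_a,
        cov_b=cov_b,
        cov_combined=cov_c,
        net_a=net_a,
        net_b=net_b,
        net_combined=net_c,
        key=key,
        connectivity=conn,
        csi_calls=calls,
        column_map=cmap,
        clade_a=clade_a,
        clade_b=clade_b,
    )


def run_two_clade_analysis(
    cfg: RunConfig, clade_a: str, clade_b: str
) -> TwoCladeResult:
    """Config-driven entry point: load inputs from paths, run, write artifacts."""
    if cfg.msa is None:
        raise ConfigError("config must set 'msa'")
    aln = alignment_io.read_alignment(cfg.msa)
    if cfg.group_table is not None:
        groups = grouping.groups_from_table(cfg.group_table)
    else:
        raise ConfigError(
            "config must set 'group_table' (tree-derived grouping needs "
            "exemplars; derive the table with grouping.groups_from_tree first)"
        )
    result = analyze_two_clades(aln, groups, clade_a, clade_b, cfg)
    if cfg.out_dir is not None:
        write_artifacts(result, cfg)
    return result


def write_artifacts(result: TwoCladeResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    cdp.cdp_report(result.cdps).to_csv(out / "cdp.tsv", sep="\t", index=False)
    for name, cov in (
        (result.clade_a, result.cov_a),
        (result.clade_b, result.cov_b),
        ("combined", result.cov_combined),
    ):
        covariation.edge_table(cov, result.column_map).to_csv(
            out / f"mi_{name}.tsv", sep="\t", index=False
        )
    for name, net in (
        (result.clade_a, result.net_a),
        (result.clade_b, result.net_b),
        ("combined", result.net_combined),
    ):
        sdp_network.export_edge_list(net, out / f"network_{name}.tsv")
        sdp_network.export_graphml(net, out / f"network_{name}.graphml")
    result.connectivity.to_csv(out / "connectivity.tsv", sep="\t", index=False)
    csi.csi_report(result.csi_calls).to_csv(
        out / "csi.tsv", sep="\t", index=False
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)


def threshold_sweep(
    result: TwoCladeResult, z_values: list[float], which: str = "a"
) -> "object":
    """Edge/class/SDN counts of an existing covariation result under a
    descending (or any) list of z thresholds."""
    cov = {"a": result.cov_a, "b": result.cov_b, "combined": result.cov_combined}[
        which
    ]
    return sdp_network.threshold_sweep_table(result.cdps, cov, z_values)
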