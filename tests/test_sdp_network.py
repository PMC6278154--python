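import itertools

import numpy as np
import pytest

from sdpnet.alignment_io import ColumnMap
from sdpnet.cdp import CdpResult
from sdpnet.covariation import CovariationResult, PairScore
from sdpnet.sdp_network import (
    NetworkError,
    PSDP,
    SDP,
    UNSUPPORTED,
    build_network,
    connectivity_table,
    key_sdps,
    threshold_sweep_table,
)


def make_cdps(columns):
    return [
        CdpResult(
            column=c, ref_position=None, statistic=1.0, p_value=0.001,
            p_adjusted=0.001, z=10.0, is_cdp=True,
        )
        for c in columns
    ]


def make_cov(columns, z_edges):
    """z_edges: {(i, j): z}; unlisted pairs get z=0."""
    pairs = {}
    for i, j in itertools.combinations(sorted(columns), 2):
        pairs[(i, j)] = PairScore(
            mi_raw=0.1, mi_apc=0.05, z=float(z_edges.get((i, j), 0.0))
        )
    return CovariationResult(
        pairs=pairs, columns_used=tuple(sorted(columns)), n_shuffles=100, seed=0
    )


def identity_map(columns, reference_id="ref"):
    return ColumnMap(reference_id=reference_id, col_to_ref={c: c for c in columns})


class TestPromotionRule:
    def test_hub_is_sdp_leaves_are_psdp(self):
        cdps = make_cdps([1, 2, 3])
        cov = make_cov([1, 2, 3], {(1, 2): 7.0, (1, 3): 7.0})
        net = build_network(cdps, cov)
        assert net.node_class == {1: SDP, 2: PSDP, 3: PSDP}
        assert net.components == (frozenset({1, 2, 3}),)

    def test_connected_pair_is_two_psdps(self):
        net = build_network(make_cdps([1, 2]), make_cov([1, 2], {(1, 2): 7.0}))
        assert net.node_class == {1: PSDP, 2: PSDP}

    def test_no_edges_all_unsupported(self):
        net = build_network(make_cdps([1, 2, 3]), make_cov([1, 2, 3], {}))
        assert set(net.node_class.values()) == {UNSUPPORTED}
        assert net.components == ()

    def test_coverage_error_names_column(self):
        cdps = make_cdps([1, 2, 9])
        cov = make_cov([1, 2], {})
        with pytest.raises(NetworkError, match="9"):
            build_network(cdps, cov)

    def test_cluster_count_advisory_warning(self):
        cdps = make_cdps([1, 2])
        cov = make_cov([1, 2], {(1, 2): 7.0})
        with pytest.warns(UserWarning, match="threshold"):
            build_network(cdps, cov, n_clusters=533)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        """Degree rule and components vs an enumeration/union-find oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        cols = list(range(1, n + 1))
        z_edges = {
            (i, j): 7.0
            for i, j in itertools.combinations(cols, 2)
            if rng.random() < 0.08
        }
        net = build_network(make_cdps(cols), make_cov(cols, z_edges))
        # brute-force degree
        degree = {c: 0 for c in cols}
        for i, j in z_edges:
            degree[i] += 1
            degree[j] += 1
        for c in cols:
            expect = SDP if degree[c] >= 2 else (PSDP if degree[c] == 1 else UNSUPPORTED)
            assert net.node_class[c] == expect
        # union-find oracle for components
        parent = {c: c for c in cols}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in z_edges:
            parent[find(i)] = find(j)
        comps = {}
        for c in cols:
            comps.setdefault(find(c), set()).add(c)
        expect_comps = sorted(
            (frozenset(s) for s in comps.values() if len(s) > 1),
            key=lambda s: (-len(s), min(s)),
        )
        assert list(net.components) == expect_comps

    def test_lowering_threshold_only_adds_edges(self):
        rng = np.random.default_rng(7)
        cols = list(range(1, 20))
        z_edges = {
            p: float(rng.normal(3, 3))
            for p in itertools.combinations(cols, 2)
        }
        cov = make_cov(cols, z_edges)
        cdps = make_cdps(cols)
        prev = None
        rank = {UNSUPPORTED: 0, PSDP: 1, SDP: 2}
        for z in (9.0, 6.5, 4.0, 1.0):
            net = build_network(cdps, cov, z_threshold=z)
            if prev is not None:
                assert prev.edges <= net.edges
                for c in cols:
                    assert rank[net.node_class[c]] >= rank[prev.node_class[c]]
            prev = net


class TestKeySdps:
    def _net(self, sdp_cols, psdp_cols=()):
        cols = list(sdp_cols) + list(psdp_cols)
        z = {}
        # wire each SDP to two partners, each pSDP to one
        for c in sdp_cols:
            others = [x for x in cols if x != c][:2]
            for o in others:
                z[(min(c, o), max(c, o))] = 7.0
        net = build_network(make_cdps(cols), make_cov(cols, z))
        return net

    def test_intersection_of_independent_networks(self):
        """Positions SDP in both single-clade networks — and only those —
        come out as key SDPs."""
        shared = [89, 307, 343, 346, 349]
        net_a = self._net(shared + [340])
        net_b = self._net(shared + [228, 455])
        assert frozenset(shared) <= net_a.sdp_columns()
        assert frozenset(shared) <= net_b.sdp_columns()
        cmap = identity_map(range(1, 500))
        res = key_sdps(net_a, net_b, cmap, cmap)
        assert res.positions == net_a.sdp_columns() & net_b.sdp_columns()
        assert frozenset(shared) <= res.positions
        assert 340 not in res.positions and 228 not in res.positions

    def test_disjoint_sdp_sets_give_empty(self):
        net_a = self._net([1, 2, 3])
        net_b = self._net([10, 11, 12])
        cmap = identity_map(range(1, 20))
        assert key_sdps(net_a, net_b, cmap, cmap).positions == frozenset()

    def test_identical_networks_idempotent(self):
        net = self._net([5, 6, 7])
        cmap = identity_map(range(1, 10))
        res = key_sdps(net, net, cmap, cmap)
        assert res.positions == frozenset(
            c for c in net.sdp_columns()
        )

    def test_symmetric_in_arguments(self):
        net_a = self._net([1, 2, 3, 4])
        net_b = self._net([3, 4, 5, 6])
        cmap = identity_map(range(1, 10))
        assert (
            key_sdps(net_a, net_b, cmap, cmap).positions
            == key_sdps(net_b, net_a, cmap, cmap).positions
        )

    def test_psdps_excluded_by_default(self):
        # a two-node pair: both pSDP, never key
        pair = build_network(make_cdps([1, 2]), make_cov([1, 2], {(1, 2): 7.0}))
        cmap = identity_map(range(1, 10))
        assert key_sdps(pair, pair, cmap, cmap).positions == frozenset()
        assert key_sdps(pair, pair, cmap, cmap, include_psdp=True).positions == {
            1,
            2,
        }

    def test_unmapped_sdp_reported_not_dropped(self):
        net = self._net([1, 2, 3])
        full = identity_map(range(1, 10))
        partial = ColumnMap(reference_id="ref", col_to_ref={1: 1, 2: 2})
        res = key_sdps(net, net, partial, full)
        assert 3 in res.unmapped_columns

    def test_different_references_rejected(self):
        net = self._net([1, 2, 3])
        a = identity_map(range(1, 10), "refA")
        b = identity_map(range(1, 10), "refB")
        with pytest.raises(NetworkError, match="reference"):
            key_sdps(net, net, a, b)


class TestTables:
    def test_chain_degrees(self):
        net = build_network(
            make_cdps([1, 2, 3]), make_cov([1, 2, 3], {(1, 2): 7.0, (2, 3): 7.0})
        )
        cmap = identity_map([1, 2, 3])
        table = connectivity_table([net], [cmap], names=["n"])
        got = dict(zip(table.ref_position, table.n_degree))
        assert got == {1: 1, 2: 2, 3: 1}

    def test_position_absent_from_second_network(self):
        net1 = build_network(
            make_cdps([1, 2, 3]), make_cov([1, 2, 3], {(1, 2): 7.0, (1, 3): 7.0})
        )
        net2 = build_network(make_cdps([2, 3]), make_cov([2, 3], {(2, 3): 7.0}))
        cmap = identity_map([1, 2, 3])
        table = connectivity_table([net1, net2], [cmap, cmap], names=["a", "b"])
        import pandas as pd

        row1 = table[table.ref_position == 1].iloc[0]
        assert row1.a_class == SDP and pd.isna(row1.b_class)

    def test_separate_components_get_distinct_sdn_ids(self):
        net = build_network(
            make_cdps([1, 2, 3, 4]),
            make_cov([1, 2, 3, 4], {(1, 2): 7.0, (3, 4): 7.0}),
        )
        cmap = identity_map([1, 2, 3, 4])
        table = connectivity_table([net], [cmap], names=["n"])
        ids = dict(zip(table.ref_position, table.n_sdn))
        assert ids[1] == ids[2] != ids[3] == ids[4]

    def test_threshold_sweep_monotone(self):
        rng = np.random.default_rng(3)
        cols = list(range(1, 15))
        z_edges = {
            p: float(rng.normal(4, 3)) for p in itertools.combinations(cols, 2)
        }
        cov = make_cov(cols, z_edges)
        sweep = threshold_sweep_table(
            make_cdps(cols), cov, z_values=[10.0, 6.5, 3.0, 0.0]
        )
        edges = sweep.n_edges.tolist()
        assert edges == sorted(edges)
        zmax = max(z_edges.values())
        above = threshold_sweep_table(make_cdps(cols), cov, [zmax + 1])
        assert above.n_edges.iloc[0] == 0

    def test_empty_sweep_rejected(self):
        cov = make_cov([1, 2, 3], {})
        with pytest.raises(ValueError):
            threshold_sweep_table(make_cdps([1, 2, 3]), cov, [])
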