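import itertools
import math

import numpy as np
import pytest

from sdpnet.alignment_io import AMINO_ACIDS, alignment_from_records
from sdpnet.covariation import (
    CovariationError,
    apc_correct,
    mi_zscores,
    pairwise_mi,
)
from sdpnet.grouping import SequenceWeights, cluster_weights
from sdpnet.synthetic_data import PairSpec, SyntheticTruth, generate


def unit_weights(aln):
    return SequenceWeights(
        weight={i: 1.0 for i in aln.ids},
        clusters={i: k for k, i in enumerate(aln.ids)},
        n_clusters=aln.n_seqs,
        identity_threshold=1.0,
    )


def mi_oracle(aln, weights, pseudocount):
    """Brute-force double-loop joint-frequency MI, independent of the
    vectorised implementation."""
    pc_mass = pseudocount * weights.n_clusters
    out = {}
    for i, j in itertools.combinations(range(1, aln.n_cols + 1), 2):
        joint = {
            (a, b): pc_mass / 400.0 for a in AMINO_ACIDS for b in AMINO_ACIDS
        }
        for sid, row in zip(aln.ids, aln.rows):
            ci, cj = row[i - 1], row[j - 1]
            if ci in AMINO_ACIDS and cj in AMINO_ACIDS:
                joint[(ci, cj)] += weights.weight[sid]
        tot = sum(joint.values())
        if tot == 0:
            out[(i, j)] = 0.0
            continue
        pa = {a: sum(joint[(a, b)] for b in AMINO_ACIDS) / tot for a in AMINO_ACIDS}
        pb = {b: sum(joint[(a, b)] for a in AMINO_ACIDS) / tot for b in AMINO_ACIDS}
        mi = 0.0
        for (a, b), c in joint.items():
            p = c / tot
            if p > 0 and pa[a] > 0 and pb[b] > 0:
                mi += p * math.log(p / (pa[a] * pb[b]))
        out[(i, j)] = max(mi, 0.0)
    return out


def random_alignment(rng, n_seqs, n_cols, gap_prob=0.15):
    letters = AMINO_ACIDS + "-"
    probs = [(1 - gap_prob) / 20] * 20 + [gap_prob]
    rows = [
        "".join(rng.choice(list(letters), size=n_cols, p=probs))
        for _ in range(n_seqs)
    ]
    return alignment_from_records((f"s{k}", r) for k, r in enumerate(rows))


class TestPairwiseMi:
    def test_deterministic_pair_is_ln2(self):
        aln = alignment_from_records(
            [("s1", "AL"), ("s2", "AL"), ("s3", "RV"), ("s4", "RV")]
        )
        mi = pairwise_mi(aln, unit_weights(aln), pseudocount=0.0)
        assert math.isclose(mi[(1, 2)], math.log(2), rel_tol=1e-12)

    def test_product_form_joint_is_zero(self):
        aln = alignment_from_records(
            [("s1", "AL"), ("s2", "AV"), ("s3", "RL"), ("s4", "RV")]
        )
        mi = pairwise_mi(aln, unit_weights(aln), pseudocount=0.0)
        assert abs(mi[(1, 2)]) <= 1e-12

    def test_conserved_column_mi_vanishes_with_pseudocount(self):
        """A conserved column carries no information: mi_raw -> 0 as the
        pseudocount -> 0, and the flat-pseudocount inflation is monotone."""
        rows = [(f"s{k}", "AL" if k % 2 else "AV") for k in range(100)]
        aln = alignment_from_records(rows)
        w = unit_weights(aln)
        assert pairwise_mi(aln, w, pseudocount=0.0)[(1, 2)] <= 1e-12
        assert pairwise_mi(aln, w, pseudocount=0.001)[(1, 2)] <= 0.01
        assert (
            pairwise_mi(aln, w, pseudocount=0.001)[(1, 2)]
            < pairwise_mi(aln, w, pseudocount=0.05)[(1, 2)]
        )

    def test_fewer_than_two_usable_columns(self):
        aln = alignment_from_records([("s1", "A-"), ("s2", "A-")])
        with pytest.raises(CovariationError):
            pairwise_mi(aln, unit_weights(aln))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("pseudocount", [0.0, 0.05])
    def test_matches_bruteforce_oracle(self, seed, pseudocount):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n_seqs=8, n_cols=6)
        w = cluster_weights(aln, 0.62)
        fast = pairwise_mi(aln, w, pseudocount=pseudocount, min_occupancy=0.0)
        slow = mi_oracle(aln, w, pseudocount)
        for pair, v in fast.items():
            assert abs(v - slow[pair]) <= 1e-12

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, 10, 8)
        mi = pairwise_mi(aln, unit_weights(aln), min_occupancy=0.0)
        assert all(v >= 0 for v in mi.values())
        assert all(i < j for i, j in mi)


class TestApc:
    def test_equal_mi_gives_zero_everywhere(self):
        mi = {p: 0.37 for p in [(1, 2), (1, 3), (2, 3), (1, 4), (2, 4), (3, 4)]}
        apc = apc_correct(mi)
        assert all(abs(v) <= 1e-12 for v in apc.values())

    def test_all_zero_stays_zero(self):
        mi = {(1, 2): 0.0, (1, 3): 0.0, (2, 3): 0.0}
        assert all(v == 0.0 for v in apc_correct(mi).values())

    def test_uncoupled_pair_goes_negative(self):
        mi = {(1, 2): 0.5, (1, 3): 0.5, (2, 3): 0.0}
        apc = apc_correct(mi)
        assert apc[(2, 3)] < 0

    def test_preserves_pair_set_and_product_identity(self):
        rng = np.random.default_rng(4)
        cols = range(1, 7)
        mi = {p: float(rng.random()) for p in itertools.combinations(cols, 2)}
        apc = apc_correct(mi)
        assert set(apc) == set(mi)
        # sum of corrections equals sum of product terms
        k = 6
        m_i = {
            c: np.mean([mi[p] for p in mi if c in p]) for c in cols
        }
        m_bar = np.mean(list(mi.values()))
        expect = sum(m_i[i] * m_i[j] / m_bar for i, j in mi)
        assert math.isclose(
            sum(mi[p] - apc[p] for p in mi), expect, rel_tol=1e-10
        )

    def test_needs_three_columns(self):
        with pytest.raises(CovariationError):
            apc_correct({(1, 2): 0.5})


class TestZScores:
    def test_seed_required_and_minimum_shuffles(self):
        rng = np.random.default_rng(0)
        aln = random_alignment(rng, 10, 5)
        w = unit_weights(aln)
        with pytest.raises(CovariationError, match="seed"):
            mi_zscores(aln, w, n_shuffles=50)
        with pytest.raises(CovariationError, match="50"):
            mi_zscores(aln, w, n_shuffles=10, seed=1)

    def test_no_self_pairs(self, background_dataset):
        aln = background_dataset.alignment.subset_columns(range(1, 11))
        cov = mi_zscores(aln, cluster_weights(aln), n_shuffles=50, seed=2)
        assert all(i != j for i, j in cov.pairs)

    def test_planted_deterministic_pair_attains_max_z(self):
        truth = SyntheticTruth(
            seed=31, planted_pairs=(PairSpec(col_i=10, col_j=20, rho=1.0),)
        )
        data = generate({"A": 100, "B": 100}, 50, truth)
        aln = data.alignment.subset_rows(data.groups.members("A"))
        w = cluster_weights(aln, 0.62)
        cov = mi_zscores(aln, w, n_shuffles=50, seed=8)
        best = max(cov.pairs, key=lambda p: cov.pairs[p].z)
        assert best == (10, 20)
        assert cov.pairs[best].z >= 6.5

    def test_z_invariant_under_sequence_reordering(self):
        rng = np.random.default_rng(12)
        aln = random_alignment(rng, 12, 6, gap_prob=0.0)
        w = unit_weights(aln)
        cov1 = mi_zscores(aln, w, n_shuffles=50, seed=3, min_occupancy=0.0)
        order = list(rng.permutation(aln.n_seqs))
        reordered = alignment_from_records(
            (aln.ids[i], aln.rows[i]) for i in order
        )
        cov2 = mi_zscores(
            reordered, unit_weights(reordered), n_shuffles=50, seed=3,
            min_occupancy=0.0,
        )
        # same null distribution family; observed mi_apc identical
        for p in cov1.pairs:
            assert math.isclose(
                cov1.pairs[p].mi_apc, cov2.pairs[p].mi_apc, abs_tol=1e-12
            )

    def test_degenerate_pairs_flagged_not_infinite(self):
        rows = [(f"s{k}", "AAL" if k % 2 else "AAV") for k in range(20)]
        aln = alignment_from_records(rows)
        cov = mi_zscores(
            aln, unit_weights(aln), n_shuffles=50, seed=4, pseudocount=0.0
        )
        s = cov.pairs[(1, 2)]
        assert s.degenerate and s.z == 0.0
        assert all(np.isfinite(v.z) for v in cov.pairs.values())
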