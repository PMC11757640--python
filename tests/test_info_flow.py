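"""Binarization and plug-in set transfer entropy, held against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acpflow.acp_task import generate_dataset
from acpflow.elman_rnn import StateTrace, init_network, record_traces
from acpflow.info_flow import (
    BinaryTrace,
    SourceTargetPair,
    binarize,
    joint_distribution,
    sample_pairs,
    te_from_bits,
    te_profile,
    transfer_entropy,
)


# ---------------------------------------------------------------------------
# independent oracle: termwise evaluation of the TE sum over all states


def te_oracle(table: np.ndarray) -> float:
    """Brute-force TE: enumerate every (x', x_j, x_S) cell and sum
    p * log2[ p(x'|x_j,x_S) / p(x'|x_j) ] from explicitly built marginals."""
    te = 0.0
    n_src = table.shape[2]
    for xn, xj, xs in itertools.product(range(2), range(2), range(n_src)):
        p = table[xn, xj, xs]
        if p == 0:
            continue
        p_js = table[:, xj, xs].sum()
        p_j = table[:, xj, :].sum()
        p_nj = table[xn, xj, :].sum()
        te += p * np.log2((p / p_js) / (p_nj / p_j))
    return te


def bits_trace(bits: np.ndarray) -> BinaryTrace:
    """Wrap a raw [episodes x T x 16] bit tensor as a BinaryTrace."""
    return BinaryTrace(
        bits=bits.astype(np.uint8),
        medians=np.zeros(16),
        degenerate=np.zeros(16, dtype=bool),
    )


@pytest.fixture(scope="module")
def data():
    return generate_dataset()


@pytest.fixture(scope="module")
def network_bt(data):
    # nonzero biases keep every state distinct from the median tie at 0
    # that a freshly initialised (zero-bias) network produces at blank inputs
    net = init_network(42)
    rng = np.random.default_rng(7)
    net.b_h = rng.normal(0, 0.5, net.b_h.shape)
    net.b_o = rng.normal(0, 0.5, net.b_o.shape)
    return binarize(record_traces(net, data))


class TestBinarize:
    def test_stated_tie_rule(self):
        # node series [0.1, 0.5, 0.9] with median 0.5 -> bits [0, 0, 1]
        states = np.zeros((1, 3, 16))
        states[0, :, 0] = [0.1, 0.5, 0.9]
        bt = binarize(StateTrace(states=states))
        np.testing.assert_array_equal(bt.bits[0, :, 0], [0, 0, 1])

    def test_constant_node_all_zero_and_flagged(self):
        states = np.full((2, 4, 16), 0.3)
        bt = binarize(StateTrace(states=states))
        assert not bt.bits.any()
        assert bt.degenerate.all()

    def test_ones_count_on_distinct_continuous_values(self):
        # strict-median thresholding on an even count of distinct values
        # leaves 47 or 48 ones out of 96 per node (maximal-entropy split)
        rng = np.random.default_rng(11)
        bt = binarize(StateTrace(states=rng.normal(0, 0.4, (24, 4, 16))))
        ones = bt.bits.reshape(-1, 16).sum(axis=0)
        assert np.all((ones == 47) | (ones == 48))
        frac = bt.bits.reshape(-1, 16).mean(axis=0)
        assert np.all(np.abs(frac - 0.5) <= 1 / 96 + 1e-12)

    def test_ones_never_exceed_half_on_network_traces(self, network_bt):
        # episodes sharing a config differ only in timing, so pre-onset
        # states repeat exactly across episodes; ties at the median then
        # push the ones count below half, never above
        ones = network_bt.bits.reshape(-1, 16).sum(axis=0)
        assert np.all(ones <= 48)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            binarize(StateTrace(states=np.zeros((1, 1, 16))))


class TestJointDistribution:
    def test_normalised(self, network_bt):
        pair = SourceTargetPair(sources=(0, 3), target=7)
        table = joint_distribution(network_bt, pair)
        assert table.shape == (2, 2, 4)
        assert table.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_source_eight_cells(self, network_bt):
        table = joint_distribution(network_bt, SourceTargetPair(sources=(2,), target=5))
        assert table.shape == (2, 2, 2)

    def test_all_zero_bits_single_cell(self):
        bt = bits_trace(np.zeros((24, 4, 16)))
        table = joint_distribution(bt, SourceTargetPair(sources=(1,), target=0))
        assert table[0, 0, 0] == 1.0
        assert table.sum() == 1.0

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            SourceTargetPair(sources=(1, 2), target=2)
        with pytest.raises(ValueError):
            SourceTargetPair(sources=(), target=0)


class TestTransferEntropy:
    def test_deterministic_copy_is_one_bit(self):
        # x^j_{t+1} copies a fair-coin source; x^j_t independent fair coin
        table = np.zeros((2, 2, 2))
        for xj in range(2):
            for xs in range(2):
                table[xs, xj, xs] = 0.25
        assert transfer_entropy(table) == pytest.approx(1.0)

    def test_conditional_independence_is_zero(self):
        # x^j_{t+1} depends only on x^j_t; source independent
        table = np.zeros((2, 2, 2))
        for xn in range(2):
            for xj in range(2):
                p_next = 0.8 if xn == xj else 0.2
                for xs in range(2):
                    table[xn, xj, xs] = 0.25 * p_next
        assert transfer_entropy(table) == pytest.approx(0.0, abs=1e-12)

    def test_xor_cryptic_encoding(self):
        # j_{t+1} = i_t XOR k_t with uniform inputs: single-input TE vanishes,
        # the two-input set TE is exactly 1 bit
        bits = []
        for i, k, jprev in itertools.product(range(2), repeat=3):
            row = np.zeros((2, 16), dtype=np.uint8)
            row[0, 0], row[0, 1], row[0, 2] = i, k, jprev
            row[1, 2] = i ^ k
            bits.append(row)
        bt = bits_trace(np.stack(bits))
        te_single = te_from_bits(bt, SourceTargetPair(sources=(0,), target=2))
        te_pair = te_from_bits(bt, SourceTargetPair(sources=(0, 1), target=2))
        assert te_single == pytest.approx(0.0, abs=1e-12)
        assert te_pair == pytest.approx(1.0, abs=1e-12)

    def test_unnormalised_table_rejected(self):
        with pytest.raises(ValueError):
            transfer_entropy(np.full((2, 2, 2), 0.2))

    @pytest.mark.parametrize("size", [1, 2, 3, 4])
    def test_oracle_equivalence_on_network_traces(self, network_bt, size):
        # both computation routes against the brute-force termwise oracle
        rng = np.random.default_rng(size)
        for pair in sample_pairs(size, 10, rng):
            table = joint_distribution(network_bt, pair)
            expected = te_oracle(table)
            assert transfer_entropy(table) == pytest.approx(expected, abs=1e-12)
            assert te_from_bits(network_bt, pair) == pytest.approx(expected, abs=1e-12)

    def test_monotone_under_source_refinement(self, network_bt):
        # S subset of S' with the same target: TE(S) <= TE(S')
        rng = np.random.default_rng(5)
        for _ in range(30):
            nodes = rng.choice(16, size=6, replace=False)
            target = int(nodes[-1])
            small = SourceTargetPair(sources=tuple(nodes[:2]), target=target)
            large = SourceTargetPair(sources=tuple(nodes[:5]), target=target)
            assert te_from_bits(network_bt, small) <= te_from_bits(network_bt, large) + 1e-12

    def test_upper_bound_conditional_entropy(self, network_bt):
        # TE <= empirical H(X^j_{t+1} | X^j_t)
        frm, to = network_bt.transitions
        rng = np.random.default_rng(9)
        for pair in sample_pairs(4, 20, rng):
            j_now = frm[:, pair.target].astype(int)
            j_next = to[:, pair.target].astype(int)
            joint = np.zeros((2, 2))
            np.add.at(joint, (j_next, j_now), 1.0)
            joint /= joint.sum()
            p_now = joint.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                cond = joint * np.log2(joint / p_now[None, :])
            h_cond = -np.nansum(cond)
            assert te_from_bits(network_bt, pair) <= h_cond + 1e-12

    def test_plugin_bias_small_on_iid_traces(self):
        # i.i.d. uniform bits carry no true information flow; the plug-in
        # estimate at |S|=1 over 72 transitions is positive but small
        rng = np.random.default_rng(123)
        vals = []
        for _ in range(1000):
            bt = bits_trace(rng.integers(0, 2, (24, 4, 16)))
            vals.append(te_from_bits(bt, SourceTargetPair(sources=(0,), target=1)))
        mean_bias = float(np.mean(vals))
        assert 0 < mean_bias < 0.15


class TestSampling:
    def test_count_and_disjointness(self):
        rng = np.random.default_rng(0)
        pairs = sample_pairs(4, 100, rng)
        assert len(pairs) == 100
        assert all(p.target not in p.sources and p.size == 4 for p in pairs)

    def test_size_15_forces_target(self):
        rng = np.random.default_rng(1)
        for p in sample_pairs(15, 10, rng):
            assert set(p.sources) | {p.target} == set(range(16))

    def test_invalid_sizes_rejected(self):
        rng = np.random.default_rng(2)
        for bad in (0, 16):
            with pytest.raises(ValueError):
                sample_pairs(bad, 1, rng)

    def test_deterministic_given_seed(self):
        a = sample_pairs(3, 20, np.random.default_rng(7))
        b = sample_pairs(3, 20, np.random.default_rng(7))
        assert a == b


class TestProfile:
    def test_profile_records(self, data):
        trace = record_traces(init_network(1), data)
        records = te_profile(
            trace, sizes=[1, 5], count_per_size=10, rng=np.random.default_rng(3)
        )
        assert len(records) == 20
        assert all(r.te_bits >= 0 for r in records)
        assert all(r.te_per_node == pytest.approx(r.te_bits / r.pair.size) for r in records)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_te_nonnegative_on_random_bit_traces(self, seed):
        rng = np.random.default_rng(seed)
        bt = bits_trace(rng.integers(0, 2, (6, 4, 16)))
        pair = sample_pairs(3, 1, rng)[0]
        assert te_from_bits(bt, pair) >= 0
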