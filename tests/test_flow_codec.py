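import lzma

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ioncram import (
    BinningSpec,
    CorruptionError,
    bin_value,
    bin_vector,
    decode_block,
    deserialize_block,
    encode_block,
    median_reference,
    serialize_block,
)
from ioncram.bam_io import FlowSignalVector
from ioncram.blocks import Block
from ioncram.flow_codec import serialize_raw_vectors, zigzag_decode, zigzag_encode


def block_of(vector_lists, tag_positions=None):
    """Build a Block from plain lists; None entries model missing ZM."""
    members = []
    for i, values in enumerate(vector_lists):
        if values is None:
            members.append((None, None))
        else:
            tp = tag_positions[i] if tag_positions else 0
            members.append(
                (None, FlowSignalVector(values=np.array(values, dtype=np.int64),
                                        read_index=i, tag_position=tp))
            )
    return Block(members=members, locus=(0, 0, 0))


def decoded_values(block, strategy):
    out = decode_block(encode_block(block, strategy))
    return [None if fv is None else fv.values.tolist() for fv in out]


# strategy for ragged, possibly-absent flow vectors
vector_st = st.one_of(
    st.none(),
    st.lists(st.integers(min_value=-3000, max_value=3000), min_size=0, max_size=30),
)
blocks_st = st.lists(vector_st, min_size=1, max_size=8)


class TestEncodeDecode:
    def test_first_strategy_reference_and_delta(self):
        enc = encode_block(block_of([[5, 3], [4, 4]]), "first")
        assert enc.reference.tolist() == [5, 3]
        assert enc.deltas[0].values.tolist() == [1, -1]

    def test_decode_applies_reference_minus_delta(self):
        # reconstructing the second vector from reference [5,3] and delta [1,-1]
        enc = encode_block(block_of([[5, 3], [4, 4]]), "first")
        assert decoded_values(block_of([[5, 3], [4, 4]]), "first") == [[5, 3], [4, 4]]
        assert (enc.reference - enc.deltas[0].values).tolist() == [4, 4]

    def test_identical_vectors_give_zero_deltas(self):
        enc = encode_block(block_of([[7, 7, 7]] * 4), "first")
        assert all(not d.values.any() and not len(d.tail) for d in enc.deltas)

    def test_ragged_lengths_store_common_prefix_plus_tail(self):
        enc = encode_block(block_of([[5, 3, 7], [5, 3]]), "first")
        assert enc.deltas[0].values.tolist() == [0, 0]
        assert enc.deltas[0].tail.tolist() == []
        assert enc.lengths == [3, 2]
        assert decoded_values(block_of([[5, 3, 7], [5, 3]]), "first") == [[5, 3, 7], [5, 3]]

    def test_growing_lengths_keep_the_tail(self):
        assert decoded_values(block_of([[5], [5, 9, -1]]), "first") == [[5], [5, 9, -1]]

    def test_single_present_vector_returned_unchanged(self):
        enc = encode_block(block_of([[1, 2, 3]]), "first")
        assert enc.deltas == []
        assert [fv.values.tolist() for fv in decode_block(enc)] == [[1, 2, 3]]

    def test_all_absent_block_is_legal(self):
        enc = encode_block(block_of([None, None]), "first")
        assert enc.reference is None and enc.deltas == []
        assert decode_block(enc) == [None, None]

    def test_absent_members_are_skipped_by_the_chain(self):
        vals = [[10, 10], None, [12, 9], None, [11, 11]]
        assert decoded_values(block_of(vals), "first") == vals

    @pytest.mark.parametrize("strategy", ["first", "median"])
    @given(vectors=blocks_st)
    @settings(max_examples=150, deadline=None)
    def test_round_trip_is_identity(self, vectors, strategy):
        block = block_of(vectors)
        assert decoded_values(block, strategy) == vectors

    def test_tag_positions_survive_the_round_trip(self):
        block = block_of([[1, 2], [3, 4]], tag_positions=[2, 5])
        out = decode_block(encode_block(block, "first"))
        assert [fv.tag_position for fv in out] == [2, 5]


class TestMedian:
    def test_exact_mean(self):
        ref = median_reference([FlowSignalVector(np.array([2, 4])),
                                FlowSignalVector(np.array([4, 6]))])
        assert ref.values.tolist() == [3, 5]

    def test_single_vector_is_its_own_reference(self):
        ref = median_reference([FlowSignalVector(np.array([9, -1, 0]))])
        assert ref.values.tolist() == [9, -1, 0]

    def test_halves_round_away_from_zero(self):
        ref = median_reference([FlowSignalVector(np.array([1, 1])),
                                FlowSignalVector(np.array([2, 2]))])
        assert ref.values.tolist() == [2, 2]
        neg = median_reference([FlowSignalVector(np.array([-1])),
                                FlowSignalVector(np.array([-2]))])
        assert neg.values.tolist() == [-2]

    @given(vectors=st.lists(
        st.lists(st.integers(min_value=-500, max_value=500), min_size=1, max_size=12),
        min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_high_precision_mean_oracle(self, vectors):
        from fractions import Fraction

        fvs = [FlowSignalVector(np.array(v)) for v in vectors]
        ref = median_reference(fvs)
        n = max(len(v) for v in vectors)
        for i in range(n):
            covering = [v[i] for v in vectors if len(v) > i]
            mean = Fraction(sum(covering), len(covering))
            expected = int(mean) if mean.denominator == 1 else None
            if expected is None:
                # round half away from zero on the exact rational
                sign = 1 if mean >= 0 else -1
                expected = sign * int(abs(mean) + Fraction(1, 2))
            assert ref.values[i] == expected

    def test_median_strategy_deltas_are_against_fixed_reference(self):
        block = block_of([[0, 0], [10, 10], [20, 20]])
        enc = encode_block(block, "median")
        assert enc.reference.tolist() == [10, 10]
        assert len(enc.deltas) == 3
        assert [d.values.tolist() for d in enc.deltas] == [[10, 10], [0, 0], [-10, -10]]


class TestSerialization:
    def test_zigzag_mapping(self):
        assert [zigzag_encode(n) for n in (0, -1, 1, -2)] == [0, 1, 2, 3]
        for n in range(-70, 70):
            assert zigzag_decode(zigzag_encode(n)) == n

    @pytest.mark.parametrize("strategy", ["first", "median"])
    @given(vectors=blocks_st)
    @settings(max_examples=150, deadline=None)
    def test_serialize_round_trip(self, vectors, strategy):
        enc = encode_block(block_of(vectors), strategy)
        data = serialize_block(enc)
        dec, consumed = deserialize_block(data)
        assert consumed == len(data)
        out = decode_block(dec)
        assert [None if fv is None else fv.values.tolist() for fv in out] == vectors

    def test_concatenated_blocks_are_self_delimiting(self):
        b1 = serialize_block(encode_block(block_of([[1, 2], [1, 3]]), "first"))
        b2 = serialize_block(encode_block(block_of([[9]]), "first"))
        stream = b1 + b2
        _, off = deserialize_block(stream, 0)
        assert off == len(b1)
        _, end = deserialize_block(stream, off)
        assert end == len(stream)

    @pytest.mark.parametrize("cut", [1, 3, 7])
    def test_truncated_bytes_always_error(self, cut):
        data = serialize_block(encode_block(block_of([[100, -200, 300], [99, -199, 301]])))
        with pytest.raises(CorruptionError):
            deserialize_block(data[: len(data) - cut])

    def test_all_zero_deltas_serialize_below_fixed_width(self):
        # 10 identical length-8 vectors: raw fixed-width int16 needs 160 bytes
        block = block_of([[100] * 8] * 10)
        data = serialize_block(encode_block(block, "first"))
        assert len(data) < len(serialize_raw_vectors(block.vectors())) == 160

    def test_delta_form_compresses_better_than_raw_under_xz(self):
        # shared template of length 400 plus per-read integer noise (sd 10):
        # the mechanism the whole tool is built on
        rng = np.random.default_rng(2024)
        template = rng.integers(0, 1200, size=400)
        vecs = [template + np.rint(rng.normal(0, 10, 400)).astype(np.int64)
                for _ in range(50)]
        block = block_of([v.tolist() for v in vecs])
        delta = lzma.compress(serialize_block(encode_block(block, "first")), preset=9)
        raw = lzma.compress(serialize_raw_vectors(block.vectors()), preset=9)
        assert len(delta) < len(raw)


class TestBinning:
    def test_rounds_up_to_bin_boundary(self):
        assert bin_value(17, BinningSpec(x=10, enabled=True)) == 20

    def test_negatives_go_to_zero(self):
        spec = BinningSpec(x=7, enabled=True)
        assert bin_value(-3, spec) == 0
        assert bin_value(-1000, spec) == 0

    def test_idempotent_on_boundaries(self):
        spec = BinningSpec(x=10, enabled=True)
        assert bin_value(20, spec) == 20
        assert bin_value(bin_value(17, spec), spec) == bin_value(17, spec)

    def test_vectorized_matches_scalar(self):
        spec = BinningSpec(x=5, enabled=True)
        values = np.arange(-50, 51)
        assert bin_vector(values, spec).tolist() == [bin_value(int(y), spec) for y in values]

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError):
            BinningSpec(x=0, enabled=True)

    @given(y=st.integers(min_value=-10_000, max_value=10_000),
           x=st.integers(min_value=1, max_value=200))
    @settings(max_examples=200, deadline=None)
    def test_bound_and_monotonicity(self, y, x):
        spec = BinningSpec(x=x, enabled=True)
        z = bin_value(y, spec)
        assert z % x == 0 and z >= 0
        if y > 0:
            assert y <= z < y + x
        assert bin_value(y + 1, spec) >= z
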