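"""Delta encoding of flow-signal vectors within a block.

This is the heart of the compressor.  Reads mapped to the same locus carry
near-identical flow vectors F_1 .. F_k, so instead of storing each vector
raw, a block stores one reference vector plus difference vectors whose
entries cluster tightly around zero — which the general-purpose backends
then compress far better than the raw values.

Two reference strategies are supported:

``first``
    The default.  The reference is F_1 (the block's first vector) and the
    differences are chained: D_i = F_i - F_{i+1}.  Decoding walks the chain
    forward: F_2 = F_1 - D_1, F_3 = F_2 - D_2, and so on.

``median``
    The reference is the position-wise average of all vectors in the block
    (rounded half away from zero to an integer) and every member's
    difference is taken against that fixed reference, non-chained.

Vectors in one block may have different lengths (reads end at different
flows): differences are taken over the common prefix and the trailing
remainder of the longer vector is stored raw, so encoding is lossless for
any length pattern.  Members without a flow vector are flagged in a
presence map and skipped by the chain.

Serialized blocks use zig-zag + LEB128 varint integers: near-zero deltas
dominate in practice and encode in a single byte.

The lossy binning transform (an explicit opt-in, applied before encoding)
maps each value y to ceil(y/x)*x and forces negative values to zero,
collapsing sensor noise into shared bin boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bam_io import FlowSignalVector
from .blocks import Block
from .errors import ConsistencyError, CorruptionError

__all__ = [
    "STRATEGIES",
    "DeltaVector",
    "EncodedBlock",
    "BinningSpec",
    "MedianReference",
    "median_reference",
    "encode_block",
    "decode_block",
    "serialize_block",
    "deserialize_block",
    "bin_value",
    "bin_vector",
    "zigzag_encode",
    "zigzag_decode",
]

STRATEGIES = ("first", "median")
_STRATEGY_CODE = {"first": 0, "median": 1}
_STRATEGY_NAME = {v: k for k, v in _STRATEGY_CODE.items()}


@dataclass
class DeltaVector:
    """Difference between two vectors over their common prefix.

    ``values[j] = earlier[j] - later[j]`` for j in the common range;
    ``tail`` holds the later vector's raw entries beyond that range.
    """

    values: np.ndarray
    tail: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.tail = np.asarray(self.tail, dtype=np.int64)


@dataclass
class MedianReference:
    """Position-wise rounded average of a block's vectors (strategy 'median')."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BinningSpec:
    """Lossy binning: y -> ceil(y/x)*x, negatives to zero; off by default."""

    x: int = 10
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.x < 1:
            raise ValueError(f"bin width must be >= 1, got {self.x}")


@dataclass
class EncodedBlock:
    """A block's flow vectors in delta-encoded form.

    ``lengths`` and ``presence`` have one entry per block member (length 0
    for absent members); ``tag_positions`` has one entry per *present*
    member and records where the ZM tag sat in that read's tag list.
    ``reference`` is None only when no member has a vector.
    """

    strategy: str
    presence: List[bool]
    lengths: List[int]
    tag_positions: List[int]
    reference: Optional[np.ndarray]
    deltas: List[DeltaVector]

    @property
    def member_count(self) -> int:
        return len(self.presence)


def bin_value(y: int, spec: BinningSpec) -> int:
    """Bin one value: negatives to zero, else round y up to a multiple of x."""
    if y < 0:
        return 0
    x = spec.x
    return -(-y // x) * x


def bin_vector(values: np.ndarray, spec: BinningSpec) -> np.ndarray:
    """Elementwise :func:`bin_value` (vectorized)."""
    v = np.asarray(values, dtype=np.int64)
    x = spec.x
    binned = ((v + x - 1) // x) * x
    return np.where(v < 0, 0, binned)


def median_reference(vectors: Sequence[FlowSignalVector]) -> MedianReference:
    """Position-wise arithmetic mean of the vectors, as integers.

    The mean at position i runs over the vectors long enough to reach i and
    is rounded half away from zero.  Rounding is done in exact integer
    arithmetic: for sum s over c vectors, |m| = (2|s| + c) // (2c).
    """
    if not vectors:
        raise ValueError("median_reference requires at least one vector")
    n = max(len(v) for v in vectors)
    sums = np.zeros(n, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for v in vectors:
        sums[: len(v)] += v.values
        counts[: len(v)] += 1
    covered = counts > 0
    s, c = sums[covered], counts[covered]
    mags = (2 * np.abs(s) + c) // (2 * c)
    out = np.zeros(n, dtype=np.int64)
    out[covered] = np.sign(s) * mags
    return MedianReference(values=out)


def _chain_deltas(present: List[np.ndarray]) -> List[DeltaVector]:
    deltas = []
    for prev, nxt in zip(present, present[1:]):
        m = min(len(prev), len(nxt))
        deltas.append(DeltaVector(values=prev[:m] - nxt[:m], tail=nxt[m:]))
    return deltas


def encode_block(block: Block, strategy: str = "first") -> EncodedBlock:
    """Delta-encode a block's flow vectors.

    With ``strategy='first'`` the reference is the first present vector and
    differences chain through consecutive present vectors; with ``'median'``
    the reference is the block average and every present member is
    differenced against it.  Absent vectors are flagged and skipped.  A
    block with no vectors at all encodes to an empty (still legal) form.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if block.size == 0:
        raise ValueError("cannot encode an empty block")

    vectors = block.vectors()
    presence = [fv is not None for fv in vectors]
    lengths = [len(fv) if fv is not None else 0 for fv in vectors]
    tag_positions = [fv.tag_position for fv in vectors if fv is not None]
    present = [fv.values for fv in vectors if fv is not None]

    if not present:
        return EncodedBlock(strategy, presence, lengths, tag_positions, None, [])

    if strategy == "first":
        reference = present[0]
        deltas = _chain_deltas(present)
    else:
        ref = median_reference([fv for fv in vectors if fv is not None])
        reference = ref.values
        # Non-chained: the reference spans the longest member, so each delta
        # covers the full member and has no tail.
        deltas = [DeltaVector(values=reference[: len(v)] - v) for v in present]
    return EncodedBlock(strategy, presence, lengths, tag_positions, reference, deltas)


def decode_block(enc: EncodedBlock) -> List[Optional[FlowSignalVector]]:
    """Exact inverse of :func:`encode_block`.

    Chained form reconstructs F_{i+1} = F_i - D_i over the common prefix
    and appends the stored tail; median form computes member = ref - delta.
    Returned vectors are in member order, None for absent members, with
    ``tag_position`` restored (``read_index`` is left at -1; callers map
    members to reads positionally).
    """
    n_present = sum(enc.presence)
    if len(enc.lengths) != enc.member_count:
        raise CorruptionError(
            f"block bookkeeping mismatch: {len(enc.lengths)} lengths for "
            f"{enc.member_count} members"
        )
    if len(enc.tag_positions) != n_present:
        raise CorruptionError(
            f"block bookkeeping mismatch: {len(enc.tag_positions)} tag "
            f"positions for {n_present} present members"
        )
    if n_present == 0:
        return [None] * enc.member_count
    if enc.reference is None:
        raise CorruptionError("block has present members but no reference vector")

    expected = n_present - 1 if enc.strategy == "first" else n_present
    if len(enc.deltas) != expected:
        raise CorruptionError(
            f"block bookkeeping mismatch: {len(enc.deltas)} deltas for "
            f"{n_present} present members (strategy {enc.strategy!r})"
        )

    present_lengths = [l for p, l in zip(enc.presence, enc.lengths) if p]
    decoded: List[np.ndarray] = []
    if enc.strategy == "first":
        cur = np.asarray(enc.reference, dtype=np.int64)
        if len(cur) != present_lengths[0]:
            raise CorruptionError(
                f"reference length {len(cur)} != recorded length {present_lengths[0]}"
            )
        decoded.append(cur)
        for d, target_len in zip(enc.deltas, present_lengths[1:]):
            m = len(d.values)
            if m > len(cur) or m + len(d.tail) != target_len:
                raise CorruptionError("delta/tail lengths inconsistent with bookkeeping")
            nxt = np.concatenate([cur[:m] - d.values, d.tail])
            decoded.append(nxt)
            cur = nxt
    else:
        ref = np.asarray(enc.reference, dtype=np.int64)
        for d, target_len in zip(enc.deltas, present_lengths):
            if len(d.values) != target_len or len(d.values) > len(ref) or len(d.tail):
                raise CorruptionError("median-strategy delta inconsistent with bookkeeping")
            decoded.append(ref[: target_len] - d.values)

    out: List[Optional[FlowSignalVector]] = []
    it = iter(zip(decoded, enc.tag_positions))
    for present in enc.presence:
        if present:
            values, tag_pos = next(it)
            out.append(FlowSignalVector(values=values, tag_position=tag_pos))
        else:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# Wire format: zig-zag + LEB128 varints, self-delimiting per block.
# ---------------------------------------------------------------------------

def zigzag_encode(n: int) -> int:
    """Map signed to unsigned so small magnitudes stay small: 0,−1,1,−2 → 0,1,2,3."""
    return (n << 1) ^ (n >> 63)


def zigzag_decode(z: int) -> int:
    return (z >> 1) ^ -(z & 1)


def _write_uvarint(buf: bytearray, n: int) -> None:
    if n < 0:
        raise ValueError("uvarint cannot encode negative values")
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def _read_uvarint(data: memoryview, off: int) -> Tuple[int, int]:
    result = 0
    shift = 0
    while True:
        if off >= len(data):
            raise CorruptionError("truncated varint in serialized block")
        b = data[off]
        off += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, off
        shift += 7
        if shift > 70:
            raise CorruptionError("overlong varint in serialized block")


def _write_ivec(buf: bytearray, arr: np.ndarray) -> None:
    for z in ((arr.astype(np.int64) << 1) ^ (arr.astype(np.int64) >> 63)).tolist():
        _write_uvarint(buf, z)


def _read_ivec(data: memoryview, off: int, count: int) -> Tuple[np.ndarray, int]:
    out = np.empty(count, dtype=np.int64)
    for i in range(count):
        z, off = _read_uvarint(data, off)
        out[i] = zigzag_decode(z)
    return out, off


def serialize_block(enc: EncodedBlock) -> bytes:
    """Serialize an encoded block to a self-delimiting byte string."""
    buf = bytearray()
    m = enc.member_count
    _write_uvarint(buf, m)
    buf.append(_STRATEGY_CODE[enc.strategy])
    bitmap = bytearray((m + 7) // 8)
    for i, p in enumerate(enc.presence):
        if p:
            bitmap[i // 8] |= 1 << (i % 8)
    buf += bitmap
    for l in enc.lengths:
        _write_uvarint(buf, l)
    for tp in enc.tag_positions:
        _write_uvarint(buf, tp)
    if enc.reference is not None:
        if enc.strategy == "median":
            _write_uvarint(buf, len(enc.reference))
        _write_ivec(buf, np.asarray(enc.reference, dtype=np.int64))
        for d in enc.deltas:
            _write_ivec(buf, d.values)
            _write_ivec(buf, d.tail)
    return bytes(buf)


def deserialize_block(data: bytes, offset: int = 0) -> Tuple[EncodedBlock, int]:
    """Inverse of :func:`serialize_block`.

    Returns the block and the offset just past it, so blocks can be read
    back from a concatenated stream.  Truncated or inconsistent input
    raises :class:`CorruptionError`; it never returns wrong data silently.
    """
    mv = memoryview(data)
    off = offset
    m, off = _read_uvarint(mv, off)
    if m == 0:
        raise CorruptionError("serialized block with zero members")
    if off >= len(mv):
        raise CorruptionError("truncated block: missing strategy byte")
    code = mv[off]
    off += 1
    if code not in _STRATEGY_NAME:
        raise CorruptionError(f"unknown strategy code {code} in serialized block")
    strategy = _STRATEGY_NAME[code]

    nbytes = (m + 7) // 8
    if off + nbytes > len(mv):
        raise CorruptionError("truncated block: incomplete presence bitmap")
    presence = [bool(mv[off + i // 8] >> (i % 8) & 1) for i in range(m)]
    off += nbytes

    lengths = []
    for _ in range(m):
        l, off = _read_uvarint(mv, off)
        lengths.append(l)
    n_present = sum(presence)
    tag_positions = []
    for _ in range(n_present):
        tp, off = _read_uvarint(mv, off)
        tag_positions.append(tp)

    present_lengths = [l for p, l in zip(presence, lengths) if p]
    reference: Optional[np.ndarray] = None
    deltas: List[DeltaVector] = []
    if n_present:
        if strategy == "median":
            ref_len, off = _read_uvarint(mv, off)
        else:
            ref_len = present_lengths[0]
        reference, off = _read_ivec(mv, off, ref_len)
        if strategy == "first":
            prev_len = present_lengths[0]
            for target_len in present_lengths[1:]:
                common = min(prev_len, target_len)
                values, off = _read_ivec(mv, off, common)
                tail, off = _read_ivec(mv, off, target_len - common)
                deltas.append(DeltaVector(values=values, tail=tail))
                prev_len = target_len
        else:
            for target_len in present_lengths:
                if target_len > ref_len:
                    raise CorruptionError(
                        "member longer than median reference in serialized block"
                    )
                values, off = _read_ivec(mv, off, target_len)
                deltas.append(DeltaVector(values=values))
    enc = EncodedBlock(strategy, presence, lengths, tag_positions, reference, deltas)
    return enc, off


def serialize_raw_vectors(vectors: Sequence[Optional[FlowSignalVector]]) -> bytes:
    """Fixed-width little-endian int16 concatenation of the vectors, no
    deltas — the naive form used as a comparison baseline for measuring
    what the delta transform buys."""
    parts = [
        np.asarray(fv.values, dtype="<i2").tobytes()
        for fv in vectors
        if fv is not None
    ]
    return b"".join(parts)
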