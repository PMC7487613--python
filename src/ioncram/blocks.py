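"""Read ordering and same-locus block construction.

Reads aligned to the same locus come from near-identical template
fragments, so their flow-signal vectors are highly similar.  To exploit
that similarity the records are sorted — first by genomic coordinates,
then by CIGAR text so reads with the same alignment shape sit together —
and the sorted stream is cut into blocks of reads sharing one locus.
Each block's flow vectors are later co-compressed by the delta codec.

A locus is the (contig, leftmost position, strand) triple: reverse-strand
reads store their sequence reverse-complemented but their flow signals in
sequencing order, so vectors from opposite strands are dissimilar and are
kept in separate blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .bam_io import FlowSignalVector, ReadRecord
from .errors import ConsistencyError

__all__ = [
    "DEFAULT_MAX_BLOCK_SIZE",
    "UNMAPPED_PREFIX_LENGTH",
    "read_key",
    "Block",
    "Permutation",
    "sort_records",
    "apply_permutation",
    "build_blocks",
]

#: Blocks are split at this many members; caps memory and bounds how far a
#: corrupt value could propagate along a delta chain.
DEFAULT_MAX_BLOCK_SIZE = 65535

#: Unmapped reads have no coordinates; they are ordered by this many bases
#: of sequence prefix (then read name) so similar unaligned reads still end
#: up adjacent.
UNMAPPED_PREFIX_LENGTH = 32

#: (reference_rank, position, strand, cigar, seq_prefix, name, original_index)
ReadKey = Tuple[int, int, int, str, str, str, int]


def read_key(record: ReadRecord) -> ReadKey:
    """Total-order sort key: coordinates, strand, CIGAR, then tiebreaks.

    Unmapped reads sort after every contig and are keyed by sequence prefix
    instead of coordinates.  (read name, original_index) breaks all
    remaining ties so the order is deterministic and no two records ever
    compare equal.
    """
    if record.is_mapped:
        return (
            record.reference_rank,
            record.position or 0,
            1 if record.is_reverse else 0,
            record.cigar_text,
            "",
            record.name,
            record.original_index,
        )
    return (
        record.reference_rank,
        0,
        0,
        "",
        record.sequence[:UNMAPPED_PREFIX_LENGTH],
        record.name,
        record.original_index,
    )


@dataclass
class Permutation:
    """Mapping from sorted rank to original_index (a bijection on 0..N-1)."""

    order: List[int]

    def __len__(self) -> int:
        return len(self.order)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Permutation) and self.order == other.order

    def is_identity(self) -> bool:
        return all(v == i for i, v in enumerate(self.order))


@dataclass
class Block:
    """A run of sorted reads sharing one locus, with their flow vectors.

    ``locus`` is (reference_rank, position, strand) for mapped members and
    None for unmapped blocks.  Members keep their sorted order; a member's
    vector entry is None when the read carried no ZM tag.
    """

    members: List[Tuple[ReadRecord, Optional[FlowSignalVector]]]
    locus: Optional[Tuple[int, int, int]]

    @property
    def size(self) -> int:
        return len(self.members)

    def vectors(self) -> List[Optional[FlowSignalVector]]:
        return [fv for _, fv in self.members]


def sort_records(
    records: Sequence[ReadRecord],
) -> Tuple[List[ReadRecord], Permutation]:
    """Sort records by :func:`read_key`; the permutation restores file order.

    Sorting is stable and deterministic for a fixed input, so a given BAM
    always produces the same sorted stream (and hence the same archive).
    """
    ordered = sorted(records, key=read_key)
    perm = Permutation(order=[r.original_index for r in ordered])
    return ordered, perm


def apply_permutation(
    sorted_records: Sequence[ReadRecord], perm: Permutation
) -> List[ReadRecord]:
    """Rearrange a sorted stream back into original file order."""
    if len(sorted_records) != len(perm):
        raise ConsistencyError(
            f"permutation length {len(perm)} != record count {len(sorted_records)}"
        )
    out: List[Optional[ReadRecord]] = [None] * len(perm)
    for rank, rec in enumerate(sorted_records):
        out[perm.order[rank]] = rec
    if any(r is None for r in out):
        raise ConsistencyError("permutation is not a bijection on 0..N-1")
    return out  # type: ignore[return-value]


def _locus(record: ReadRecord) -> Optional[Tuple[int, int, int]]:
    if not record.is_mapped:
        return None
    return (
        record.reference_rank,
        record.position or 0,
        1 if record.is_reverse else 0,
    )


def build_blocks(
    sorted_pairs: Sequence[Tuple[ReadRecord, Optional[FlowSignalVector]]],
    max_block_size: int = DEFAULT_MAX_BLOCK_SIZE,
) -> List[Block]:
    """Cut a sorted (record, flow-vector) stream into same-locus blocks.

    Consecutive mapped reads sharing (contig rank, position, strand) form
    one block, split into chunks of at most ``max_block_size``.  Unmapped
    reads (which sort after all contigs) are blocked purely by size.
    Concatenating the blocks reproduces the input stream exactly.

    Raises
    ------
    ConsistencyError
        If the input is not in :func:`read_key` order.
    ValueError
        If ``max_block_size`` is not positive.
    """
    if max_block_size < 1:
        raise ValueError(f"max_block_size must be >= 1, got {max_block_size}")

    blocks: List[Block] = []
    current: List[Tuple[ReadRecord, Optional[FlowSignalVector]]] = []
    current_locus: Optional[Tuple[int, int, int]] = None
    prev_key: Optional[ReadKey] = None

    def flush() -> None:
        nonlocal current
        if current:
            blocks.append(Block(members=current, locus=current_locus))
            current = []

    for rec, fv in sorted_pairs:
        key = read_key(rec)
        if prev_key is not None and key < prev_key:
            raise ConsistencyError(
                f"records not in sorted order at read {rec.name!r} "
                f"(original_index {rec.original_index})"
            )
        prev_key = key
        locus = _locus(rec)
        # A mapped locus change always starts a new block; within one locus
        # (or within the unmapped tail) only the size cap splits.
        if current and (locus != current_locus or len(current) >= max_block_size):
            flush()
        current_locus = locus
        current.append((rec, fv))
    flush()
    return blocks
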