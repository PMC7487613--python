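"""BAM/SAM input and output and flow-signal (ZM tag) handling.

Ion Torrent BAM files carry a per-read vector of processed flow signals in
the ``ZM`` auxiliary tag: one signed integer per nucleotide flow, roughly
proportional to the length of the homopolymer incorporated at that flow,
with small (possibly negative) noise at non-incorporating flows.  The flow
cycle (``FO``) and the key sequence (``KS``, typically ``TCAG``) live in the
header read groups.

This module reads and writes alignment records, extracts flow vectors from
and re-attaches them to records, and splits a record stream into a
flow-free "body" plus a table of flow vectors — the two halves that are
compressed separately downstream.
"""

from __future__ import annotations

import array
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pysam

from .errors import ConsistencyError, FormatError

__all__ = [
    "RunMetadata",
    "ReadRecord",
    "FlowSignalVector",
    "BamData",
    "read_records",
    "write_records",
    "extract_flow_vector",
    "strip_flow_signals",
    "reattach_flow_signals",
]

ZM_TAG = "ZM"

#: SAM "B" array integer subtypes, all accepted on read.
_INT_ARRAY_TYPECODES = frozenset("bBhHiIlLqQ")

_INT16_MIN, _INT16_MAX = -(2**15), 2**15 - 1


@dataclass(frozen=True)
class RunMetadata:
    """Per-read-group run description from the BAM header.

    ``flow_order`` is the flow cycle — the cyclic order in which nucleotides
    are introduced by the sequencer.  ``key_sequence`` is the control prefix
    ligated before each fragment (Ion Torrent libraries use ``TCAG``).
    Either may be absent in non-Ion headers.
    """

    read_group_id: str
    flow_order: Optional[str] = None
    key_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.flow_order is not None:
            if not self.flow_order or set(self.flow_order) - set("ACGT"):
                raise FormatError(
                    f"read group {self.read_group_id!r}: flow order must be a "
                    f"non-empty string over ACGT, got {self.flow_order!r}"
                )
        if self.key_sequence is not None and set(self.key_sequence) - set("ACGT"):
            raise FormatError(
                f"read group {self.read_group_id!r}: key sequence must be a "
                f"nucleotide string, got {self.key_sequence!r}"
            )


@dataclass
class ReadRecord:
    """One alignment record plus its rank in the source file.

    Wraps a :class:`pysam.AlignedSegment`; ``original_index`` is the 0-based
    position of the record in the file it was read from and is the stable
    identity used to key flow vectors and to restore file order.
    """

    segment: pysam.AlignedSegment
    original_index: int

    @property
    def name(self) -> str:
        return self.segment.query_name or ""

    @property
    def is_mapped(self) -> bool:
        return not self.segment.is_unmapped

    @property
    def reference_rank(self) -> int:
        """Ordinal of the contig in header order; unmapped reads sort last."""
        rid = self.segment.reference_id
        return rid if rid >= 0 else 2**31

    @property
    def reference_name(self) -> Optional[str]:
        return self.segment.reference_name if self.is_mapped else None

    @property
    def position(self) -> Optional[int]:
        """0-based leftmost mapped coordinate, or None when unmapped."""
        return self.segment.reference_start if self.is_mapped else None

    @property
    def is_reverse(self) -> bool:
        return self.segment.is_reverse

    @property
    def cigar_text(self) -> str:
        return self.segment.cigarstring or ""

    @property
    def sequence(self) -> str:
        return self.segment.query_sequence or ""

    def tags(self) -> List[Tuple[str, object, str]]:
        """Auxiliary tags as ordered (key, value, type-code) triples."""
        return self.segment.get_tags(with_value_type=True)

    def to_sam_line(self) -> str:
        return self.segment.to_string()


@dataclass
class FlowSignalVector:
    """One read's ordered flow measurements (the per-read flowgram).

    ``values`` is a signed-integer array, one entry per executed flow;
    negative entries are legitimate noise at non-incorporating flows.
    ``tag_position`` remembers where in the read's tag list the ZM tag sat,
    so re-attachment restores the exact original record layout.
    """

    values: np.ndarray
    read_index: int = -1
    tag_position: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlowSignalVector):
            return NotImplemented
        return (
            self.read_index == other.read_index
            and self.tag_position == other.tag_position
            and np.array_equal(self.values, other.values)
        )


@dataclass
class BamData:
    """A fully read BAM/SAM file: header, run metadata, and records."""

    header: pysam.AlignmentHeader
    run_metadata: List[RunMetadata]
    records: List[ReadRecord] = field(default_factory=list)


def _metadata_from_header(header: pysam.AlignmentHeader) -> List[RunMetadata]:
    out = []
    for rg in header.to_dict().get("RG", []):
        out.append(
            RunMetadata(
                read_group_id=rg.get("ID", ""),
                flow_order=rg.get("FO"),
                key_sequence=rg.get("KS"),
            )
        )
    return out


def read_records(path: str) -> BamData:
    """Read a BAM or SAM file fully into memory.

    Records are returned in file order with ``original_index`` assigned
    0, 1, 2, …  Header read-group FO/KS fields populate the run metadata
    when present.

    Raises
    ------
    FormatError
        If the file cannot be opened or parsed as BAM/SAM.
    """
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot open {path!r} as BAM/SAM: {exc}") from exc
    with af:
        header = af.header
        metadata = _metadata_from_header(header)
        records: List[ReadRecord] = []
        try:
            for i, seg in enumerate(af):
                records.append(ReadRecord(segment=seg, original_index=i))
        except (OSError, ValueError) as exc:
            raise FormatError(
                f"truncated or unparseable record stream in {path!r} "
                f"after {len(records)} records: {exc}"
            ) from exc
    return BamData(header=header, run_metadata=metadata, records=records)


def write_records(
    path: str,
    records: Iterable[ReadRecord],
    header: pysam.AlignmentHeader,
    mode: str = "wb",
) -> int:
    """Write records to *path*; ``mode`` as in pysam ('wb' BAM, 'wbu'
    uncompressed BAM, 'w' SAM).  Returns the number written."""
    n = 0
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in records:
            out.write(rec.segment)
            n += 1
    return n


def extract_flow_vector(record: ReadRecord) -> Optional[FlowSignalVector]:
    """Pull the flow-signal vector out of a record's ZM tag.

    Returns None when the tag is absent.  The record itself is never
    modified.  Any SAM "B" integer-array subtype is accepted; a ZM tag of a
    non-integer-array type is a format error.
    """
    for pos, (key, value, vtype) in enumerate(record.tags()):
        if key != ZM_TAG:
            continue
        if vtype != "B" or not isinstance(value, array.array) \
                or value.typecode not in _INT_ARRAY_TYPECODES:
            raise FormatError(
                f"read {record.name!r}: ZM tag is not an integer array "
                f"(type code {vtype!r})"
            )
        return FlowSignalVector(
            values=np.asarray(value, dtype=np.int64),
            read_index=record.original_index,
            tag_position=pos,
        )
    return None


def set_tags(segment: pysam.AlignedSegment, tags: List[Tuple[str, object, str]]) -> None:
    """Set a segment's tags from (key, value, type) triples as produced by
    ``get_tags(with_value_type=True)``.

    pysam reports array tags with type code 'B' but will not accept 'B'
    back; the subtype is carried by the array's own typecode instead.
    """
    segment.set_tags(
        [(k, v, None if t == "B" else t) for k, v, t in tags]
    )


def _zm_array(values: np.ndarray, read_name: str) -> array.array:
    """Encode flow values as the on-disk ZM array (int16 subtype 's').

    Values outside the signed 16-bit range cannot be represented in the
    canonical Ion dialect and are rejected rather than silently truncated.
    """
    if len(values) and (values.min() < _INT16_MIN or values.max() > _INT16_MAX):
        raise FormatError(
            f"read {read_name!r}: flow-signal values outside the signed "
            f"16-bit range cannot be written to a ZM tag"
        )
    return array.array("h", [int(v) for v in values])


def strip_flow_signals(
    records: Iterable[ReadRecord],
) -> Tuple[List[ReadRecord], Dict[int, FlowSignalVector]]:
    """Split a record stream into a ZM-free body and a flow-vector table.

    The ZM tag is removed *in place* from each record's segment (callers
    that need the original should re-read the file); every other tag,
    field, and the record order are untouched.  The returned table maps
    ``original_index`` to the extracted :class:`FlowSignalVector` for each
    record that carried ZM.
    """
    body: List[ReadRecord] = []
    flows: Dict[int, FlowSignalVector] = {}
    for rec in records:
        fv = extract_flow_vector(rec)
        if fv is not None:
            flows[rec.original_index] = fv
            kept = [t for t in rec.segment.get_tags(with_value_type=True)
                    if t[0] != ZM_TAG]
            set_tags(rec.segment, kept)
        body.append(rec)
    return body, flows


def reattach_flow_signals(
    body: Iterable[ReadRecord],
    flows: Dict[int, FlowSignalVector],
) -> List[ReadRecord]:
    """Exact inverse of :func:`strip_flow_signals`.

    Re-inserts each flow vector as a ZM tag at its recorded tag position.
    Records are modified in place and returned in input order.

    Raises
    ------
    ConsistencyError
        If a flow-table key matches no record, or two records claim the
        same original_index present in the table.
    """
    out: List[ReadRecord] = []
    seen: set = set()
    for rec in body:
        idx = rec.original_index
        fv = flows.get(idx)
        if fv is not None:
            if idx in seen:
                raise ConsistencyError(
                    f"duplicate original_index {idx} while re-attaching flow signals"
                )
            seen.add(idx)
            tags = rec.segment.get_tags(with_value_type=True)
            pos = min(fv.tag_position, len(tags))
            tags.insert(pos, (ZM_TAG, _zm_array(fv.values, rec.name), "B"))
            set_tags(rec.segment, tags)
        out.append(rec)
    missing = set(flows) - seen
    if missing:
        raise ConsistencyError(
            f"flow table references original_index values with no matching "
            f"record: {sorted(missing)[:5]}"
        )
    return out
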