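"""End-to-end archive compression and decompression.

An archive is a single POSIX-pax tar file holding:

* ``manifest.json`` — first member, so streaming readers see it early:
  format version, backend, strategy, chunk index, checksums.
* ``header.sam`` — the source BAM header, restored verbatim on output.
* ``body.*`` — the ZM-stripped records in sorted order, either as CRAM
  produced by an external ``samtools`` converter (reference-based
  compression of the non-flow fields) or, when no converter is available
  or requested, the uncompressed BAM re-compressed by the backend.
* ``flows/chunk-NNNNN.*`` — serialized delta-encoded flow-signal blocks,
  concatenated into chunks (16 MiB before compression by default) and
  compressed by the backend.  Chunks are independent: they may be
  compressed and decompressed in any order or in parallel without
  changing the output.
* ``order.*`` — optional permutation restoring the original record order.
* ``tagorder.*`` — per-read auxiliary-tag key order, stored when the body
  goes through CRAM because CRAM codecs canonicalize tag order; restoring
  it keeps the round trip exact to the tag level.

Decompression verifies every member's content digest before writing any
output, reverses the pipeline, and re-attaches flow vectors to their
reads.  Lossless mode reproduces the source records field-for-field; with
the lossy binning option the archive stores (and faithfully restores) the
binned values.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
import shutil
import subprocess
import sys
import tarfile
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from . import __version__ as _pkg_version
from . import bam_io, blocks, flow_codec
from .backends import BackendSpec, compress_bytes, decompress_bytes
from .blocks import DEFAULT_MAX_BLOCK_SIZE, Permutation
from .errors import ConfigurationError, CorruptionError, FormatError, IonCramError
from .flow_codec import BinningSpec

__all__ = [
    "FORMAT_VERSION",
    "DEFAULT_CHUNK_SIZE",
    "Manifest",
    "compress_archive",
    "decompress_archive",
    "read_manifest",
]

FORMAT_VERSION = 1
DEFAULT_CHUNK_SIZE = 16 * 1024 * 1024

_MANIFEST_NAME = "manifest.json"
_HEADER_NAME = "header.sam"


@dataclass
class Manifest:
    """Archive-level description; serialized as the first tar member."""

    format_version: int
    backend: BackendSpec
    strategy: str
    body_codec: str  # "external_cram" | "fallback_bam"
    body_member: str
    chunk_index: List[Dict[str, int]]  # {"name", "first_block", "n_blocks"}
    permutation_member: Optional[str]
    tagorder_member: Optional[str]
    binning: Optional[int]  # bin width, or None for lossless
    source_record_count: int
    flow_record_count: int
    block_count: int
    source_bam_bytes: int
    checksums: Dict[str, str]
    component_sizes: Dict[str, int]
    reference: Optional[Dict[str, str]] = None
    tool_versions: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> bytes:
        d = dict(self.__dict__)
        d["backend"] = {"algorithm": self.backend.algorithm, "level": self.backend.level}
        return json.dumps(d, indent=1, sort_keys=True).encode()

    @classmethod
    def from_json(cls, raw: bytes) -> "Manifest":
        try:
            d = json.loads(raw.decode())
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise CorruptionError(f"unreadable archive manifest: {exc}") from exc
        if d.get("format_version") != FORMAT_VERSION:
            raise CorruptionError(
                f"unsupported archive format version {d.get('format_version')!r}; "
                f"this build reads version {FORMAT_VERSION}"
            )
        d["backend"] = BackendSpec(**d["backend"])
        return cls(**d)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _samtools() -> Optional[str]:
    return shutil.which("samtools")


def _samtools_version(exe: str) -> str:
    try:
        out = subprocess.run(
            [exe, "--version"], capture_output=True, text=True, check=True
        ).stdout
        return out.splitlines()[0].strip()
    except (OSError, subprocess.SubprocessError):
        return "unknown"


def _encode_permutation(perm: Permutation) -> bytes:
    buf = bytearray()
    flow_codec._write_uvarint(buf, len(perm))
    arr = np.asarray(perm.order, dtype=np.int64)
    flow_codec._write_ivec(buf, np.diff(arr, prepend=0))
    return bytes(buf)


def _decode_permutation(raw: bytes) -> Permutation:
    mv = memoryview(raw)
    n, off = flow_codec._read_uvarint(mv, 0)
    diffs, off = flow_codec._read_ivec(mv, off, n)
    return Permutation(order=np.cumsum(diffs).astype(int).tolist())


def _encode_tag_orders(orders: List[Tuple[str, ...]]) -> bytes:
    buf = bytearray()
    flow_codec._write_uvarint(buf, len(orders))
    for keys in orders:
        flow_codec._write_uvarint(buf, len(keys))
        for k in keys:
            buf += k.encode("ascii")
    return bytes(buf)


def _decode_tag_orders(raw: bytes) -> List[Tuple[str, ...]]:
    mv = memoryview(raw)
    n, off = flow_codec._read_uvarint(mv, 0)
    out: List[Tuple[str, ...]] = []
    for _ in range(n):
        k, off = flow_codec._read_uvarint(mv, off)
        keys = []
        for _ in range(k):
            if off + 2 > len(mv):
                raise CorruptionError("truncated tag-order stream")
            keys.append(bytes(mv[off : off + 2]).decode("ascii"))
            off += 2
        out.append(tuple(keys))
    return out


def _reorder_tags(segment: pysam.AlignedSegment, key_order: Tuple[str, ...]) -> None:
    """Restore a record's auxiliary tags to their original key order.

    Keys absent from the record are skipped; tags the stored order does not
    mention are appended at the end (lenient, in case the body codec adds
    derived tags)."""
    tags = segment.get_tags(with_value_type=True)
    by_key = {t[0]: t for t in tags}
    ordered = [by_key.pop(k) for k in key_order if k in by_key]
    ordered.extend(t for t in tags if t[0] in by_key)
    bam_io.set_tags(segment, ordered)


def _reference_digest(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# body codec
# ---------------------------------------------------------------------------

def _encode_body(
    body_records: List[bam_io.ReadRecord],
    header: pysam.AlignmentHeader,
    body_codec: str,
    backend: BackendSpec,
    reference: Optional[str],
    threads: int,
    tmpdir: str,
    log,
) -> Tuple[str, str, bytes, Dict[str, str]]:
    """Compress the ZM-free body; returns (codec, member name, bytes, tool versions)."""
    raw_path = os.path.join(tmpdir, "body_raw.bam")
    bam_io.write_records(raw_path, body_records, header, mode="wbu")

    exe = _samtools()
    if body_codec == "auto":
        body_codec = "external_cram" if exe else "fallback_bam"
    if body_codec == "external_cram" and exe is None:
        log("external CRAM converter (samtools) not found; "
            "falling back to backend-compressed BAM body")
        body_codec = "fallback_bam"

    if body_codec == "external_cram":
        cram_path = os.path.join(tmpdir, "body.cram")
        # Relative paths + cwd=tmpdir keep the @PG command line in the CRAM
        # header independent of the temporary directory, so identical inputs
        # yield byte-identical archives.
        cmd = [exe, "view", "-C", "-@", str(max(1, threads)),
               "--output-fmt-option", "use_lzma=1",
               "--output-fmt-option", "level=9"]
        if reference:
            cmd += ["-T", os.path.abspath(reference)]
        else:
            cmd += ["--output-fmt-option", "no_ref=1"]
        cmd += ["-o", "body.cram", "body_raw.bam"]
        try:
            subprocess.run(cmd, check=True, capture_output=True, cwd=tmpdir)
        except subprocess.CalledProcessError as exc:
            raise IonCramError(
                f"external CRAM converter failed: {exc.stderr.decode(errors='replace')}"
            ) from exc
        with open(cram_path, "rb") as fh:
            payload = fh.read()
        return "external_cram", "body.cram", payload, {"samtools": _samtools_version(exe)}

    if body_codec != "fallback_bam":
        raise ConfigurationError(f"unknown body codec {body_codec!r}")
    with open(raw_path, "rb") as fh:
        raw = fh.read()
    payload = compress_bytes(raw, backend)
    return "fallback_bam", f"body.bam.{backend.extension}", payload, {}


def _decode_body(
    body_codec: str,
    payload: bytes,
    backend: BackendSpec,
    reference: Optional[str],
    threads: int,
    tmpdir: str,
) -> bam_io.BamData:
    if body_codec == "external_cram":
        exe = _samtools()
        if exe is None:
            raise IonCramError(
                "archive body is CRAM but no external converter (samtools) is available"
            )
        cram_path = os.path.join(tmpdir, "body.cram")
        bam_path = os.path.join(tmpdir, "body.bam")
        with open(cram_path, "wb") as fh:
            fh.write(payload)
        cmd = [exe, "view", "-b", "-@", str(max(1, threads))]
        if reference:
            cmd += ["-T", reference]
        cmd += ["-o", bam_path, cram_path]
        try:
            subprocess.run(cmd, check=True, capture_output=True)
        except subprocess.CalledProcessError as exc:
            raise CorruptionError(
                f"external CRAM converter failed to decode the archive body: "
                f"{exc.stderr.decode(errors='replace')}"
            ) from exc
        return bam_io.read_records(bam_path)
    bam_path = os.path.join(tmpdir, "body.bam")
    with open(bam_path, "wb") as fh:
        fh.write(decompress_bytes(payload, backend))
    return bam_io.read_records(bam_path)


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

def compress_archive(
    bam_path: str,
    out_path: str,
    backend: BackendSpec = BackendSpec(),
    strategy: str = "first",
    max_block_size: int = DEFAULT_MAX_BLOCK_SIZE,
    binning: Optional[BinningSpec] = None,
    threads: int = 1,
    keep_order: bool = True,
    body_codec: str = "auto",
    reference: Optional[str] = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    log=None,
) -> Manifest:
    """Compress a BAM into a single-file archive; returns the manifest.

    Pipeline: read -> strip ZM -> sort by (coordinates, strand, CIGAR) ->
    same-locus blocks -> (optional lossy binning) -> delta encode ->
    serialize -> chunk -> backend compress; body records go to the body
    codec in the same sorted order.  With ``keep_order`` (default) the
    original record order is stored and restored at decompression.

    The output is written atomically: a failed run leaves no partial
    archive behind.
    """
    log = log or (lambda msg: None)
    if strategy not in flow_codec.STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    if binning is not None and not binning.enabled:
        binning = None

    data = bam_io.read_records(bam_path)
    source_bytes = os.path.getsize(bam_path)
    tag_orders: Dict[int, Tuple[str, ...]] = {
        rec.original_index: tuple(t[0] for t in rec.tags()) for rec in data.records
    }
    body, flows = bam_io.strip_flow_signals(data.records)
    if binning is not None:
        for fv in flows.values():
            fv.values = flow_codec.bin_vector(fv.values, binning)
    sorted_records, perm = blocks.sort_records(body)
    pairs = [(rec, flows.get(rec.original_index)) for rec in sorted_records]
    block_list = blocks.build_blocks(pairs, max_block_size=max_block_size)

    # serialize blocks into chunks of at most chunk_size pre-compression bytes
    chunks: List[bytes] = []
    chunk_first_block: List[int] = []
    chunk_n_blocks: List[int] = []
    current = bytearray()
    current_first = 0
    current_n = 0
    for bi, blk in enumerate(block_list):
        payload = flow_codec.serialize_block(flow_codec.encode_block(blk, strategy))
        if current and len(current) + len(payload) > chunk_size:
            chunks.append(bytes(current))
            chunk_first_block.append(current_first)
            chunk_n_blocks.append(current_n)
            current = bytearray()
            current_first = bi
            current_n = 0
        current += payload
        current_n += 1
    if current:
        chunks.append(bytes(current))
        chunk_first_block.append(current_first)
        chunk_n_blocks.append(current_n)

    if threads > 1 and len(chunks) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            compressed_chunks = list(
                pool.map(lambda c: compress_bytes(c, backend), chunks)
            )
    else:
        compressed_chunks = [compress_bytes(c, backend) for c in chunks]

    members: List[Tuple[str, bytes]] = []
    with tempfile.TemporaryDirectory(dir=os.path.dirname(os.path.abspath(out_path)) or ".") as tmpdir:
        codec, body_member, body_bytes, tools = _encode_body(
            sorted_records, data.header, body_codec, backend, reference,
            threads, tmpdir, log,
        )
        members.append((_HEADER_NAME, str(data.header).encode()))
        members.append((body_member, body_bytes))

        chunk_index = []
        for i, comp in enumerate(compressed_chunks):
            name = f"flows/chunk-{i:05d}.{backend.extension}"
            members.append((name, comp))
            chunk_index.append(
                {"name": name, "first_block": chunk_first_block[i],
                 "n_blocks": chunk_n_blocks[i]}
            )

        permutation_member = None
        if keep_order:
            permutation_member = f"order.{backend.extension}"
            members.append(
                (permutation_member, compress_bytes(_encode_permutation(perm), backend))
            )

        tagorder_member = None
        if codec == "external_cram":
            tagorder_member = f"tagorder.{backend.extension}"
            stream = _encode_tag_orders(
                [tag_orders[rec.original_index] for rec in sorted_records]
            )
            members.append((tagorder_member, compress_bytes(stream, backend)))

        if reference:
            ref_info = {"name": os.path.basename(reference),
                        "md5": _reference_digest(reference)}
        else:
            ref_info = None

        manifest = Manifest(
            format_version=FORMAT_VERSION,
            backend=backend,
            strategy=strategy,
            body_codec=codec,
            body_member=body_member,
            chunk_index=chunk_index,
            permutation_member=permutation_member,
            tagorder_member=tagorder_member,
            binning=binning.x if binning is not None else None,
            source_record_count=len(data.records),
            flow_record_count=len(flows),
            block_count=len(block_list),
            source_bam_bytes=source_bytes,
            checksums={name: _sha256(payload) for name, payload in members},
            component_sizes={name: len(payload) for name, payload in members},
            reference=ref_info,
            tool_versions={"ioncram": _pkg_version, **tools},
        )

        tmp_out = os.path.join(tmpdir, "archive.tar")
        try:
            with tarfile.open(tmp_out, "w", format=tarfile.PAX_FORMAT) as tar:
                _add_member(tar, _MANIFEST_NAME, manifest.to_json())
                for name, payload in members:
                    _add_member(tar, name, payload)
            shutil.move(tmp_out, out_path)
        except OSError:
            if os.path.exists(out_path):
                os.unlink(out_path)
            raise
    for name, payload in members:
        log(f"component {name}: {len(payload)} bytes")
    return manifest


def _add_member(tar: tarfile.TarFile, name: str, payload: bytes) -> None:
    info = tarfile.TarInfo(name=name)
    info.size = len(payload)
    info.mtime = 0
    info.uid = info.gid = 0
    info.uname = info.gname = ""
    tar.addfile(info, io.BytesIO(payload))


# ---------------------------------------------------------------------------
# decompression
# ---------------------------------------------------------------------------

def read_manifest(archive_path: str) -> Manifest:
    """Read just the manifest from an archive."""
    try:
        with tarfile.open(archive_path, "r") as tar:
            fh = tar.extractfile(_MANIFEST_NAME)
            if fh is None:
                raise CorruptionError(f"{archive_path!r} has no {_MANIFEST_NAME}")
            return Manifest.from_json(fh.read())
    except tarfile.TarError as exc:
        raise CorruptionError(f"{archive_path!r} is not a readable archive: {exc}") from exc


def decompress_archive(
    archive_path: str,
    out_bam_path: str,
    reference: Optional[str] = None,
    threads: int = 1,
    log=None,
) -> int:
    """Restore the BAM from an archive; returns the record count written.

    Every member's checksum is verified before any output is produced.
    Records come back field-for-field equal to the source (the binned
    values, if the archive was made with lossy binning), in original file
    order when the archive stores a permutation, else in sorted order.
    """
    log = log or (lambda msg: None)
    try:
        with tarfile.open(archive_path, "r") as tar:
            payloads: Dict[str, bytes] = {}
            for member in tar.getmembers():
                fh = tar.extractfile(member)
                if fh is not None:
                    payloads[member.name] = fh.read()
    except tarfile.TarError as exc:
        raise CorruptionError(f"{archive_path!r} is not a readable archive: {exc}") from exc

    if _MANIFEST_NAME not in payloads:
        raise CorruptionError(f"{archive_path!r} has no {_MANIFEST_NAME}")
    manifest = Manifest.from_json(payloads[_MANIFEST_NAME])

    for name, digest in manifest.checksums.items():
        if name not in payloads:
            raise CorruptionError(f"archive member {name!r} is missing")
        actual = _sha256(payloads[name])
        if actual != digest:
            raise CorruptionError(
                f"checksum mismatch for archive member {name!r}: "
                f"expected {digest[:12]}…, got {actual[:12]}…"
            )

    if manifest.reference is not None and reference is None:
        raise IonCramError(
            f"archive body was compressed against reference "
            f"{manifest.reference['name']!r}; pass the reference FASTA to decompress"
        )

    backend = manifest.backend
    with tempfile.TemporaryDirectory() as tmpdir:
        body = _decode_body(
            manifest.body_codec, payloads[manifest.body_member], backend,
            reference, threads, tmpdir,
        )
        if len(body.records) != manifest.source_record_count:
            raise CorruptionError(
                f"body has {len(body.records)} records; manifest expects "
                f"{manifest.source_record_count}"
            )

        # decode flow chunks (independent; order fixed by the chunk index)
        chunk_payloads = [payloads[ci["name"]] for ci in manifest.chunk_index]
        if threads > 1 and len(chunk_payloads) > 1:
            with ThreadPoolExecutor(max_workers=threads) as pool:
                raw_chunks = list(
                    pool.map(lambda c: decompress_bytes(c, backend), chunk_payloads)
                )
        else:
            raw_chunks = [decompress_bytes(c, backend) for c in chunk_payloads]

        flows: Dict[int, bam_io.FlowSignalVector] = {}
        rank = 0
        n_blocks_seen = 0
        for raw in raw_chunks:
            off = 0
            while off < len(raw):
                enc, off = flow_codec.deserialize_block(raw, off)
                for fv in flow_codec.decode_block(enc):
                    if fv is not None:
                        fv.read_index = rank
                        flows[rank] = fv
                    rank += 1
                n_blocks_seen += 1
        if n_blocks_seen != manifest.block_count:
            raise CorruptionError(
                f"decoded {n_blocks_seen} flow blocks; manifest expects "
                f"{manifest.block_count}"
            )
        if rank != manifest.source_record_count:
            raise CorruptionError(
                f"flow blocks cover {rank} records; manifest expects "
                f"{manifest.source_record_count}"
            )
        if len(flows) != manifest.flow_record_count:
            raise CorruptionError(
                f"decoded {len(flows)} flow vectors; manifest expects "
                f"{manifest.flow_record_count}"
            )

        records = bam_io.reattach_flow_signals(body.records, flows)

        if manifest.tagorder_member:
            orders = _decode_tag_orders(
                decompress_bytes(payloads[manifest.tagorder_member], backend)
            )
            if len(orders) != len(records):
                raise CorruptionError("tag-order stream length mismatch")
            for rec, keys in zip(records, orders):
                _reorder_tags(rec.segment, keys)

        if manifest.permutation_member:
            perm = _decode_permutation(
                decompress_bytes(payloads[manifest.permutation_member], backend)
            )
            records = blocks.apply_permutation(records, perm)

        header = pysam.AlignmentHeader.from_text(payloads[_HEADER_NAME].decode())
        try:
            n = bam_io.write_records(out_bam_path, records, header)
        except Exception:
            if os.path.exists(out_bam_path):
                os.unlink(out_bam_path)
            raise
    log(f"restored {n} records to {out_bam_path}")
    return n
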