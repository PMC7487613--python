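"""General-purpose compression backends: gzip, xz, zstd.

The flow-signal streams (and the fallback body) are handed to one of three
dictionary-based compressors behind a single byte-in/byte-out contract.
xz at level 9 is the default — it consistently gives the best ratios on
delta-encoded flow data — with gzip (fast, weakest) and zstd (near-xz
ratios at its ultra levels) as alternatives.  Streams are standard
single-member formats (gzip member, xz container, zstd frame) so archive
components remain inspectable with ordinary command-line tools.
"""

from __future__ import annotations

import gzip
import lzma
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import zstandard

from .errors import ConfigurationError, CorruptionError

__all__ = ["ALGORITHMS", "BackendSpec", "compress_bytes", "decompress_bytes"]

#: algorithm -> (default level, (min level, max level))
ALGORITHMS: Dict[str, Tuple[int, Tuple[int, int]]] = {
    "gzip": (9, (1, 9)),
    "xz": (9, (0, 9)),
    "zstd": (22, (1, 22)),  # 22 is the top of zstd's --ultra range
}

_EXTENSION = {"gzip": "gz", "xz": "xz", "zstd": "zst"}


@dataclass(frozen=True)
class BackendSpec:
    """A compressor choice plus its level; defaults are maximum compression."""

    algorithm: str = "xz"
    level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unsupported compression algorithm {self.algorithm!r}; "
                f"choose from {sorted(ALGORITHMS)}"
            )
        default, (lo, hi) = ALGORITHMS[self.algorithm]
        if self.level is None:
            object.__setattr__(self, "level", default)
        elif not lo <= self.level <= hi:
            raise ConfigurationError(
                f"{self.algorithm} level {self.level} outside legal range [{lo}, {hi}]"
            )

    @property
    def extension(self) -> str:
        return _EXTENSION[self.algorithm]


def compress_bytes(payload: bytes, spec: BackendSpec) -> bytes:
    """Compress *payload* into a standard single-member stream.

    Output is deterministic for a fixed (payload, spec) within one library
    version; the algorithm identity is recorded by the caller (in the
    archive manifest), never sniffed from the stream.
    """
    if spec.algorithm == "gzip":
        return gzip.compress(payload, compresslevel=spec.level, mtime=0)
    if spec.algorithm == "xz":
        return lzma.compress(payload, format=lzma.FORMAT_XZ, preset=spec.level)
    cctx = zstandard.ZstdCompressor(level=spec.level, write_content_size=True)
    return cctx.compress(payload)


def decompress_bytes(payload: bytes, spec: BackendSpec) -> bytes:
    """Inverse of :func:`compress_bytes`; corrupt or wrong-format streams
    raise :class:`CorruptionError` and never yield partial output."""
    try:
        if spec.algorithm == "gzip":
            return gzip.decompress(payload)
        if spec.algorithm == "xz":
            return lzma.decompress(payload, format=lzma.FORMAT_XZ)
        dctx = zstandard.ZstdDecompressor()
        return dctx.decompress(payload)
    except (OSError, EOFError, lzma.LZMAError, zstandard.ZstdError, ValueError) as exc:
        raise CorruptionError(
            f"cannot decompress {spec.algorithm} stream: {exc}"
        ) from exc
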