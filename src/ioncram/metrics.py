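"""Evaluation quantities: space saving and flow-signal content fractions.

Space saving is 1 - compressed/uncompressed (equivalently
1 - 1/compression-ratio), reported as a percentage because it maps
directly to saved physical storage.  The flow fraction of a file is the
share of its bytes attributable to the flow signals, measured by the
strip-and-rediff convention: re-encode the records with and without their
ZM tags under identical writer settings and difference the sizes.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Tuple

from . import bam_io
from .errors import IonCramError

__all__ = [
    "SizeReport",
    "space_saving",
    "flow_fraction",
    "round_percent",
    "measure_flow_content",
]


@dataclass
class SizeReport:
    """Byte accounting for one compressed artifact and its components."""

    uncompressed_bytes: int
    compressed_bytes: int
    component_bytes: Dict[str, int] = field(default_factory=dict)

    @property
    def percent_saving(self) -> float:
        return space_saving(self.compressed_bytes, self.uncompressed_bytes)[1]


def space_saving(compressed_bytes: float, uncompressed_bytes: float) -> Tuple[float, float]:
    """Return (fraction, percent) space saving.

    Negative values (expansion) are reported as such, not clamped.
    """
    if uncompressed_bytes <= 0:
        raise IonCramError(
            f"space saving undefined for uncompressed size {uncompressed_bytes}"
        )
    frac = 1.0 - compressed_bytes / uncompressed_bytes
    return frac, 100.0 * frac


def round_percent(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used for reported tables."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


def flow_fraction(flow_bytes: float, total_bytes: float) -> float:
    """Percent of a file's bytes occupied by flow signals, to one decimal."""
    if total_bytes <= 0:
        raise IonCramError(f"flow fraction undefined for total size {total_bytes}")
    return round_percent(100.0 * flow_bytes / total_bytes)


def measure_flow_content(bam_path: str) -> SizeReport:
    """Measure how many of a BAM's bytes the ZM tags account for.

    Both the original records and their ZM-stripped counterparts are
    re-encoded with identical BGZF writer settings; the size difference is
    the flow-signal content.  Re-encoding both sides makes the measurement
    independent of the source file's own compression level.
    """
    data = bam_io.read_records(bam_path)
    with tempfile.TemporaryDirectory() as tmp:
        full = os.path.join(tmp, "full.bam")
        stripped = os.path.join(tmp, "stripped.bam")
        bam_io.write_records(full, data.records, data.header)
        body, _ = bam_io.strip_flow_signals(data.records)
        bam_io.write_records(stripped, body, data.header)
        full_sz = os.path.getsize(full)
        stripped_sz = os.path.getsize(stripped)
    flow_bytes = full_sz - stripped_sz
    return SizeReport(
        uncompressed_bytes=full_sz,
        compressed_bytes=stripped_sz,
        component_bytes={"flow_signals": flow_bytes, "body": stripped_sz},
    )
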