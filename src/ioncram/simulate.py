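"""Synthetic Ion Torrent flowgram and BAM fixture generation.

Emulates what matters about Ion Torrent output for testing a flow-signal
compressor: a cyclic flow order, the TCAG key prefix, integer flow signals
proportional to homopolymer length with near-zero (possibly negative)
noise at non-incorporating flows, and multiple reads covering the same
locus with similar-but-not-identical signals.  It deliberately does not
model instrument error profiles, chip physics, or raw-signal processing.

The signal scale (counts per incorporated base) is a package convention,
not an instrument constant: only the relative similarity of same-locus
vectors matters to the codec, and the scale is configurable.

A simple threshold base-caller is included as the inverse check: at zero
noise, calling bases on a simulated flowgram recovers the source sequence
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import numpy as np
import pysam

from .errors import FormatError
from .bam_io import FlowSignalVector

__all__ = [
    "SimulationSpec",
    "sequence_to_flowgram",
    "call_bases",
    "generate_bam_fixture",
    "FixtureSummary",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_INT16_MIN, _INT16_MAX = -(2**15), 2**15 - 1


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic sequencing run.

    depth is the mean number of reads per locus (per-locus counts are
    Poisson, minimum 1); noise_sd is the standard deviation of the
    additive, integer-rounded Gaussian noise on every flow value;
    negative_noise permits sub-zero values at non-incorporating flows,
    as seen in real processed flow signals.  The seed fixes the entire
    generated byte stream.
    """

    reference_length: int = 10_000
    depth: float = 20.0
    read_length: int = 200
    flow_order: str = "TACG"
    key_sequence: str = "TCAG"
    signal_scale: int = 256
    noise_sd: float = 10.0
    negative_noise: bool = True
    unmapped_fraction: float = 0.01
    missing_zm_fraction: float = 0.01
    n_loci: Optional[int] = None
    reverse_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_scale < 1:
            raise ValueError("signal_scale must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.flow_order or set(self.flow_order) - set(_BASES):
            raise ValueError("flow_order must be a non-empty string over ACGT")

    @property
    def loci(self) -> int:
        if self.n_loci is not None:
            return self.n_loci
        return max(1, self.reference_length // max(1, 2 * self.read_length))


def sequence_to_flowgram(
    seq: str,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> FlowSignalVector:
    """Simulate the flowgram an Ion sequencer would record for *seq*.

    Walks the flow order cyclically; each flow incorporates the full
    homopolymer of the flowed base at the current template position, giving
    a signal of signal_scale x (homopolymer length) plus rounded Gaussian
    noise.  Non-incorporating flows emit noise around zero (clipped at zero
    unless negative_noise).  The walk stops at the end of the cycle in
    which the template is consumed, so every flowgram covers whole cycles.
    """
    if not seq:
        raise FormatError("cannot simulate a flowgram for an empty sequence")
    bad = set(seq) - set(_BASES)
    if bad:
        raise FormatError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    cycle = spec.flow_order
    incorporated = []
    pos = 0
    while pos < len(seq):
        progressed = False
        for base in cycle:
            run = 0
            while pos + run < len(seq) and seq[pos + run] == base:
                run += 1
            incorporated.append(run)
            pos += run
            progressed = progressed or run > 0
            # keep emitting the rest of the cycle even once consumed
        if not progressed and pos < len(seq):
            raise FormatError(
                f"flow order {cycle!r} can never incorporate base {seq[pos]!r}"
            )
    signal = np.asarray(incorporated, dtype=np.int64) * spec.signal_scale
    if spec.noise_sd > 0:
        noise = np.rint(rng.normal(0.0, spec.noise_sd, len(signal))).astype(np.int64)
        signal = signal + noise
        if not spec.negative_noise:
            signal = np.maximum(signal, 0)
    return FlowSignalVector(values=np.clip(signal, _INT16_MIN, _INT16_MAX))


def call_bases(flowgram: FlowSignalVector, flow_order: str, spec: SimulationSpec) -> str:
    """Threshold base-caller: round(value / scale) copies of each flowed base.

    Rounding implements the half-scale incorporation threshold; at zero
    noise this is the exact inverse of :func:`sequence_to_flowgram`.
    """
    out = []
    scale = spec.signal_scale
    for i, v in enumerate(np.asarray(flowgram.values)):
        n = int(np.rint(v / scale))
        if n > 0:
            out.append(flow_order[i % len(flow_order)] * n)
    return "".join(out)


@dataclass(frozen=True)
class FixtureSummary:
    read_count: int
    locus_count: int
    mapped_count: int
    zm_count: int


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_bam_fixture(
    spec: SimulationSpec,
    out_path: str,
    sidecar: bool = False,
) -> FixtureSummary:
    """Write a coordinate-plausible synthetic Ion Torrent BAM.

    A random reference is drawn, loci are sampled along it, and each locus
    receives ~depth reads whose template is key_sequence + the reference
    substring (reverse-complemented for reverse-strand reads, since flow
    signals follow sequencing order, not reference orientation).  Each read
    gets independent noise, so same-locus reads have similar but
    non-identical flowgrams.  Configurable fractions of reads are left
    unmapped or stripped of their ZM tag.  The header carries FO/KS in a
    read group.  Output is byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    ref = "".join(rng.choice(list(_BASES), size=spec.reference_length))
    L = min(spec.read_length, spec.reference_length)
    max_start = max(1, spec.reference_length - L)
    starts = np.sort(rng.integers(0, max_start, size=spec.loci))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "ref1", "LN": spec.reference_length}],
            "RG": [
                {
                    "ID": "rg1",
                    "SM": "synthetic",
                    "PL": "IONTORRENT",
                    "FO": spec.flow_order,
                    "KS": spec.key_sequence,
                }
            ],
        }
    )

    mapped = zm = total = 0
    with pysam.AlignmentFile(out_path, "wb", header=header) as out:
        unmapped_buffer = []
        read_serial = 0
        for locus_i, start in enumerate(starts):
            # mean `depth` reads per locus, never zero; depth 1 is exactly one
            # read per locus (degenerate single-member blocks downstream)
            n_reads = 1 + int(rng.poisson(max(0.0, spec.depth - 1.0)))
            substring = ref[start : start + L]
            for _ in range(n_reads):
                name = f"SYN{spec.seed:04d}:{read_serial:07d}"
                read_serial += 1
                is_unmapped = rng.random() < spec.unmapped_fraction
                is_reverse = (not is_unmapped) and rng.random() < spec.reverse_fraction
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.mapping_quality = 0 if is_unmapped else 60
                if is_unmapped:
                    seq = "".join(rng.choice(list(_BASES), size=L))
                    a.flag = 4
                else:
                    seq = substring
                    a.flag = 16 if is_reverse else 0
                    a.reference_id = 0
                    a.reference_start = int(start)
                    a.cigartuples = [(0, L)]
                a.query_sequence = seq
                quals = 20 + np.clip(
                    np.rint(rng.normal(10, 4, L)).astype(np.int64), -15, 13
                )
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(33 + q) for q in quals)
                )
                a.set_tag("RG", "rg1")
                if rng.random() >= spec.missing_zm_fraction:
                    template = spec.key_sequence + (_revcomp(seq) if is_reverse else seq)
                    fv = sequence_to_flowgram(template, spec, rng=rng)
                    a.set_tag("ZM", _as_int16_array(fv.values))
                    zm += 1
                if is_unmapped:
                    unmapped_buffer.append(a)
                else:
                    mapped += 1
                    out.write(a)
                total += 1
        for a in unmapped_buffer:
            out.write(a)

    if sidecar:
        with open(str(out_path) + ".params.json", "w") as fh:
            json.dump(asdict(spec), fh, indent=2, sort_keys=True)
    return FixtureSummary(
        read_count=total, locus_count=spec.loci, mapped_count=mapped, zm_count=zm
    )


def _as_int16_array(values: np.ndarray):
    import array as _array

    return _array.array("h", [int(v) for v in values])
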