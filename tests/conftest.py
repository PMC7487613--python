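import array

import pysam
import pytest

from ioncram import SimulationSpec, generate_bam_fixture
from ioncram.bam_io import ReadRecord

_HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 100_000}, {"SN": "chr2", "LN": 50_000}],
        "RG": [{"ID": "rg1", "FO": "TACG", "KS": "TCAG"}],
    }
)


@pytest.fixture
def header():
    return _HEADER


def make_record(
    name="r0",
    index=0,
    rid=0,
    pos=100,
    reverse=False,
    mapped=True,
    cigar=None,
    seq="ACGTACGTAC",
    zm=None,
    extra_tags=(),
):
    """Build an in-memory alignment record for unit tests."""
    a = pysam.AlignedSegment(_HEADER)
    a.query_name = name
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if mapped:
        a.flag = 16 if reverse else 0
        a.reference_id = rid
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigarstring = cigar if cigar is not None else f"{len(seq)}M"
    else:
        a.flag = 4
    tags = [("RG", "rg1", "Z")]
    if zm is not None:
        tags.append(("ZM", array.array("h", zm), None))
    tags.extend(extra_tags)
    a.set_tags(tags)
    return ReadRecord(segment=a, original_index=index)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def fixture_bam(tmp_path):
    """Factory: write a synthetic Ion Torrent BAM and return its path."""
    counter = [0]

    def _make(**kwargs):
        defaults = dict(
            reference_length=2000,
            depth=8.0,
            read_length=100,
            noise_sd=10.0,
            seed=1,
        )
        defaults.update(kwargs)
        spec = SimulationSpec(**defaults)
        counter[0] += 1
        path = tmp_path / f"fixture{counter[0]}.bam"
        summary = generate_bam_fixture(spec, str(path))
        return str(path), spec, summary

    return _make


def sam_lines(bam_path):
    """All record lines of a BAM as SAM text, in file order."""
    from ioncram import read_records

    return [rec.to_sam_line() for rec in read_records(bam_path).records]
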