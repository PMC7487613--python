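"""Generate a synthetic Ion Torrent BAM and measure its flow-signal content.

Builds a small deep-coverage fixture (flow cycle TACG, key sequence TCAG,
homopolymer-proportional ZM signals with Gaussian noise), then measures
what fraction of the file's bytes the ZM tags occupy — the quantity that
motivates compressing flow signals separately.
"""

import os
import tempfile

from ioncram import (
    SimulationSpec,
    flow_fraction,
    generate_bam_fixture,
    measure_flow_content,
    read_records,
)

with tempfile.TemporaryDirectory() as tmp:
    bam = os.path.join(tmp, "panel.bam")
    spec = SimulationSpec(reference_length=10_000, depth=40.0, read_length=200,
                          noise_sd=10.0, seed=11)
    summary = generate_bam_fixture(spec, bam)
    print(f"wrote {summary.read_count} reads over {summary.locus_count} loci, "
          f"{summary.zm_count} carrying ZM flow vectors")

    meta = read_records(bam).run_metadata[0]
    print(f"header: flow order {meta.flow_order!r}, key sequence {meta.key_sequence!r}")

    rec = read_records(bam).records[0]
    from ioncram import extract_flow_vector
    fv = extract_flow_vector(rec)
    print(f"first read {rec.name}: {len(fv)} flows, values start {fv.values[:8].tolist()}")

    report = measure_flow_content(bam)
    pct = flow_fraction(report.component_bytes["flow_signals"],
                        report.uncompressed_bytes)
    print(f"flow signals occupy {pct}% of the BAM "
          f"({report.component_bytes['flow_signals']} of "
          f"{report.uncompressed_bytes} bytes)")
    # ~75-80%: the flow vectors dwarf every other per-read field, which is
    # why a flow-aware compressor beats a generic one on Ion Torrent data.
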