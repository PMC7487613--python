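import tarfile

import pytest

from ioncram import (
    BackendSpec,
    BinningSpec,
    CorruptionError,
    compress_archive,
    decompress_archive,
    read_manifest,
    read_records,
    sort_records,
)
from ioncram.blocks import read_key

from conftest import sam_lines


def roundtrip(bam, tmp_path, tag="rt", **opts):
    arc = str(tmp_path / f"{tag}.ioncram")
    out = str(tmp_path / f"{tag}.out.bam")
    manifest = compress_archive(bam, arc, **opts)
    n = decompress_archive(arc, out, reference=opts.get("reference"))
    return arc, out, manifest, n


class TestRoundTrip:
    @pytest.mark.parametrize("body_codec", ["external_cram", "fallback_bam"])
    def test_records_restored_field_for_field(self, fixture_bam, tmp_path, body_codec):
        bam, _, _ = fixture_bam(depth=10, seed=42, unmapped_fraction=0.05,
                                missing_zm_fraction=0.05)
        _, out, manifest, n = roundtrip(bam, tmp_path, tag=body_codec,
                                        body_codec=body_codec)
        assert manifest.body_codec == body_codec
        assert n == manifest.source_record_count
        assert sam_lines(out) == sam_lines(bam)

    def test_header_restored_verbatim(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(seed=3)
        _, out, _, _ = roundtrip(bam, tmp_path)
        assert str(read_records(out).header) == str(read_records(bam).header)

    def test_zero_zm_input_round_trips(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(missing_zm_fraction=1.0, seed=6)
        _, out, manifest, _ = roundtrip(bam, tmp_path)
        assert manifest.flow_record_count == 0
        assert sam_lines(out) == sam_lines(bam)

    def test_empty_bam_round_trips(self, tmp_path, header):
        from ioncram import write_records

        bam = str(tmp_path / "empty.bam")
        write_records(bam, [], header)
        _, out, manifest, n = roundtrip(bam, tmp_path)
        assert n == 0 == manifest.source_record_count
        assert sam_lines(out) == []

    def test_median_strategy_round_trips(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(depth=15, seed=44)
        _, out, manifest, _ = roundtrip(bam, tmp_path, strategy="median")
        assert manifest.strategy == "median"
        assert sam_lines(out) == sam_lines(bam)

    def test_small_block_cap_round_trips(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(depth=25, seed=45)
        _, out, manifest, _ = roundtrip(bam, tmp_path, max_block_size=4)
        assert sam_lines(out) == sam_lines(bam)

    def test_without_keep_order_output_is_in_sorted_order(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(depth=10, seed=46, unmapped_fraction=0.05)
        _, out, manifest, _ = roundtrip(bam, tmp_path, keep_order=False)
        assert manifest.permutation_member is None
        assert sorted(sam_lines(out)) == sorted(sam_lines(bam))
        out_records = read_records(out).records
        keys = [read_key(r)[:5] for r in out_records]
        assert keys == sorted(keys)

    def test_multi_chunk_archives_round_trip(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(depth=20, seed=47)
        arc, out, manifest, _ = roundtrip(bam, tmp_path, chunk_size=4096,
                                          threads=2)
        assert len(manifest.chunk_index) > 1
        assert sam_lines(out) == sam_lines(bam)

    def test_archive_is_deterministic(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(depth=12, seed=48)
        a1 = str(tmp_path / "d1.ioncram")
        a2 = str(tmp_path / "d2.ioncram")
        compress_archive(bam, a1)
        compress_archive(bam, a2)
        assert open(a1, "rb").read() == open(a2, "rb").read()


class TestBinning:
    def test_binned_values_are_nonnegative_bin_multiples(self, fixture_bam, tmp_path):
        from ioncram import extract_flow_vector

        bam, _, _ = fixture_bam(depth=10, noise_sd=20.0, seed=50)
        _, out, manifest, _ = roundtrip(
            bam, tmp_path, binning=BinningSpec(x=10, enabled=True)
        )
        assert manifest.binning == 10
        seen = 0
        for rec in read_records(out).records:
            fv = extract_flow_vector(rec)
            if fv is not None:
                assert all(v >= 0 and v % 10 == 0 for v in fv.values.tolist())
                seen += 1
        assert seen > 0

    def test_binned_archive_round_trips_its_own_values(self, fixture_bam, tmp_path):
        # binning is applied once, at compression; the archive itself is a
        # faithful container for the binned values
        bam, _, _ = fixture_bam(depth=10, noise_sd=20.0, seed=51)
        arc, out1, _, _ = roundtrip(bam, tmp_path, tag="b1",
                                    binning=BinningSpec(x=10, enabled=True))
        arc2 = str(tmp_path / "b2.ioncram")
        out2 = str(tmp_path / "b2.out.bam")
        compress_archive(out1, arc2)
        decompress_archive(arc2, out2)
        assert sam_lines(out2) == sam_lines(out1)

    def test_binning_shrinks_the_flow_component(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(depth=20, noise_sd=20.0, seed=52)
        _, _, lossless, _ = roundtrip(bam, tmp_path, tag="ll")
        arcb = str(tmp_path / "lb.ioncram")
        lossy = compress_archive(bam, arcb, binning=BinningSpec(x=10, enabled=True))

        def flow_bytes(m):
            return sum(s for name, s in m.component_sizes.items()
                       if name.startswith("flows/"))

        assert flow_bytes(lossy) < flow_bytes(lossless)


class TestIntegrity:
    def test_tampered_chunk_is_detected_before_output(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(depth=10, seed=60)
        arc = str(tmp_path / "t.ioncram")
        compress_archive(bam, arc)
        with tarfile.open(arc) as tar:
            member = next(m for m in tar.getmembers()
                          if m.name.startswith("flows/"))
            offset = member.offset_data
        raw = bytearray(open(arc, "rb").read())
        raw[offset + 5] ^= 0xFF
        open(arc, "wb").write(bytes(raw))
        out = tmp_path / "t.out.bam"
        with pytest.raises(CorruptionError, match="checksum"):
            decompress_archive(arc, str(out))
        assert not out.exists()

    def test_not_an_archive_errors_cleanly(self, tmp_path):
        bogus = tmp_path / "x.ioncram"
        bogus.write_bytes(b"not a tar archive")
        with pytest.raises(CorruptionError):
            decompress_archive(str(bogus), str(tmp_path / "y.bam"))

    def test_manifest_is_first_member_and_readable(self, fixture_bam, tmp_path):
        bam, _, _ = fixture_bam(seed=61)
        arc = str(tmp_path / "m.ioncram")
        written = compress_archive(bam, arc)
        with tarfile.open(arc) as tar:
            assert tar.getmembers()[0].name == "manifest.json"
        manifest = read_manifest(arc)
        assert manifest.checksums == written.checksums
        assert manifest.backend == BackendSpec("xz", 9)

    def test_unsupported_version_errors(self, fixture_bam, tmp_path):
        import json

        bam, _, _ = fixture_bam(seed=62)
        arc = str(tmp_path / "v.ioncram")
        compress_archive(bam, arc)
        raw = read_manifest(arc).to_json()
        doc = json.loads(raw)
        doc["format_version"] = 99
        from ioncram.container import Manifest

        with pytest.raises(CorruptionError, match="version"):
            Manifest.from_json(json.dumps(doc).encode())


class TestBackendsThroughTheContainer:
    @pytest.mark.parametrize("algo", ["gzip", "xz", "zstd"])
    def test_every_backend_round_trips(self, fixture_bam, tmp_path, algo):
        bam, _, _ = fixture_bam(depth=10, seed=70)
        _, out, manifest, _ = roundtrip(bam, tmp_path, tag=algo,
                                        backend=BackendSpec(algo),
                                        body_codec="fallback_bam")
        assert manifest.backend.algorithm == algo
        assert sam_lines(out) == sam_lines(bam)
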