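# Methods

## Data model

An Ion Torrent BAM is modelled as a flow-free *body* (all SAM fields and
auxiliary tags except `ZM`) plus a table of per-read *flow-signal
vectors*: ordered signed integers, one per nucleotide flow, taken from
the `ZM` tag.  `ZM` is read and written as a SAM `B` array of signed
16-bit integers (subtype `s`), the de-facto Torrent Suite dialect; other
integer subtypes are accepted on read and normalized on write, and values
that do not fit 16 bits are rejected rather than truncated.  Reads
without `ZM` are legal and tracked through a presence map.  The flow
cycle (`FO`) and key sequence (`KS`) are carried as read-group metadata
only; `FO` is never validated against vector lengths because no
reconciliation rule exists — the stored vector length is authoritative.
Coordinates are 0-based internally and converted at the SAM boundary.

## Sorting and blocks

Records are sorted by (contig rank, leftmost position, strand, CIGAR
text, read name, original index).  CIGAR comparison is plain
lexicographic on the text — it only needs to co-locate reads with the
same alignment shape, not define alignment semantics.  Strand is part of
the block key because reverse-strand reads store their sequence
reverse-complemented while `ZM` stays in sequencing order, so vectors
from opposite strands are dissimilar and would pollute each other's delta
chains.  Unmapped reads sort after all contigs, keyed by a 32-base
sequence prefix and name, and are blocked purely by size.  The final
(name, original index) tiebreak makes the sort — and therefore the whole
archive — deterministic, byte for byte, for a fixed input and settings.

Blocks split at `max_block_size` = 65535 members (configurable).  The cap
bounds memory per block and limits how far a corrupted value could
propagate along a delta chain; the exact value is a container constraint,
not a modelling choice.

## Delta codec

Within a block the default `first` strategy stores the first present
vector F₁ and chained differences Dᵢ = Fᵢ − Fᵢ₊₁; decoding computes
Fᵢ₊₁ = Fᵢ − Dᵢ.  The subtraction orientation is fixed by the decoder's
equation, and the encoder is written to match it.  Members without a
vector are flagged and skipped, keeping the chain between present
neighbours rather than resetting it — with 1%-scale missing rates the
difference is negligible and skipping is simpler.  Vectors of unequal
length are differenced over the common prefix with the remainder stored
raw and true lengths recorded, so any length pattern round-trips exactly.

The alternative `median` strategy replaces F₁ by the position-wise
arithmetic mean of the block's vectors (over the vectors covering each
position), rounded half away from zero in exact integer arithmetic
(|m| = (2|s| + c) / (2c), floor), and differences every member against
that fixed reference, non-chained — chaining against a synthetic
reference has no natural definition.  In practice `first` compresses as
well or better (locality favours the downstream LZ compressors) and is
the default.

Serialization uses zig-zag mapping (0, −1, 1, −2 → 0, 1, 2, 3) plus
LEB128 varints: near-zero deltas dominate for similar reads and encode in
one byte.  Each block is self-delimiting (member count, strategy,
presence bitmap, lengths, ZM tag positions, reference, deltas), so chunks
are just concatenations.  Truncated input always raises a corruption
error; the deserializer derives every count from the recorded lengths and
never guesses.

## Binning (lossy, opt-in)

Binning maps y → ⌈y/x⌉·x for y ≥ 0 and forces negative values to zero,
applied elementwise to the flow table before delta encoding.  It is
idempotent, monotone, and bounded by y ≤ bin(y) < y + x for y > 0.  It is
never enabled by default: the archive is a clinical archival format and
lossless is the contract; the manifest records the bin width so a lossy
archive is self-describing.  The archive itself remains a faithful
container — decompression returns exactly the binned values it stored.

## Backends and chunking

gzip, xz and zstd are exposed behind one byte-in/byte-out contract with
maximum-compression defaults (gzip 9, xz 9, zstd 22 — the top of the
ultra range).  Streams are standard single-member formats so archive
components can be inspected with ordinary tools; the algorithm identity
lives in the manifest, never sniffed.  Serialized blocks are pooled into
chunks of at most 16 MiB before compression: per-block compression would
waste dictionary warm-up on small blocks, while one monolithic stream
would serialize poorly across workers.  Chunks are independent, so
compression and decompression parallelize per chunk with output invariant
to scheduling; chunk boundaries (first block ordinal, block count) are in
the manifest.

## Container

The archive is a POSIX-pax tar with `manifest.json` first, then the
header text, the body, the flow chunks, an optional permutation, and an
optional tag-order stream.  Design choices:

* **Body codec.**  When `samtools` is available the ZM-stripped body goes
  through CRAM with lzma at level 9 (embedded-sequence `no_ref` mode
  unless a reference FASTA is supplied, keeping archives self-contained;
  a supplied reference is recorded by name and MD5, not embedded).
  Otherwise the body is the uncompressed BAM bytes run through the
  backend (`fallback_bam`).  CRAM internals are deliberately delegated,
  not reimplemented.
* **Tag order.**  CRAM codecs canonicalize auxiliary-tag order (e.g. `RG`
  moves to the end).  Because the lossless contract here is field-for-
  field *including tag order*, archives with a CRAM body carry a small
  per-read tag-key-order stream (a few bytes per read before compression)
  used to restore the original layout exactly.
* **Record order.**  The body is stored in sorted order (which CRAM also
  prefers); by default a delta+varint-encoded permutation restores the
  original file order.  `keep_order=False` drops it for a slightly
  smaller archive and emits sorted order.
* **Integrity.**  Every component has a SHA-256 digest in the manifest,
  verified before any output is written; archival use demands detecting
  bit rot before it propagates.  Compression writes the archive
  atomically (temp file + rename), leaving no partial output on failure.

## Synthetic data generator

The generator emulates exactly the features the codec depends on: a
cyclic flow order (default the 4-base cycle `TACG`; real instruments use
longer scrambled orders, configurable), the `TCAG` key prefix on every
template, flow signals of `signal_scale` × homopolymer length (default
256 per base — a package convention, since only relative similarity
matters to the codec) plus independent integer-rounded Gaussian noise per
flow and per read (default sd 10, ~4% of one incorporation), negative
values permitted at non-incorporating flows, loci sampled along a random
reference with Poisson(depth − 1) + 1 reads each (so depth 1 is exactly
one read per locus), reverse-strand reads simulated with
reverse-complemented templates, and configurable fractions (default 1%)
of unmapped and ZM-less reads.  Flowgrams cover whole cycles: the walk
stops at the end of the cycle in which the template is consumed.

It does **not** model instrument error profiles, indels (simulated CIGARs
are full-length matches — the codec never interprets CIGAR beyond
sorting), chip physics, barcodes, or the true Torrent Suite signal
scaling.  Passing tests therefore demonstrate correctness of the
machinery and the similarity-exploiting mechanism on data with the right
statistical shape, not the absolute ratios achievable on real
multi-gigabyte clinical files, which additionally depend on the external
CRAM converter's version.  Fixture generation is byte-deterministic in
the spec (including seed).

The bundled base-caller emits round(value/scale) copies of each flowed
base — an implicit half-scale incorporation threshold — and is the exact
inverse of the simulator at zero noise; under moderate noise (sd =
scale/8) it recovers ≥ 90% of length-50 sequences, measured empirically
before the test bound was frozen.

## Problem sizes

Tests and the acceptance script run on desk-scale fixtures: 2 kb
references with ~100–2 000 reads for the round-trip matrix, and 20 kb
references at depth 50–75 (~2 500–3 700 reads, 200 bp reads, ~330 flows
per read) for the mechanism and content measurements.  At this scale the
flow signals occupy ~78% of the BAM, the chained-delta stream is ~20%
smaller under xz than raw fixed-width serialization, and the lossless
archive saves ~35% relative to the BAM; deeper files compress better
because reference vectors amortize over more reads per block.

## Known limitations

* The whole file is held in memory during compression; fine for panels
  and desk-scale work, but a streaming implementation would be needed for
  50 GB exomes on small machines.
* `first`-strategy chains make a block's later vectors depend on all
  earlier deltas; the size cap bounds, but does not eliminate, error
  propagation within a block (checksums detect, not correct).
* Reference-based CRAM bodies require the same reference at
  decompression; the manifest records name and MD5 so a mismatch is
  detected, not silently accepted.
* Unaligned-only BAMs are accepted (sequence-prefix blocking) but the
  similarity assumption that drives the delta gain is weaker there.
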