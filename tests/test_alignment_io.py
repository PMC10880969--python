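"""MAF preprocessing rules, pattern encoding and track serialisation."""

import numpy as np
import pytest

from ilshmm.alignment_io import (
    AlignmentSegment,
    encode_alignment,
    encode_patterns,
    merge_and_filter,
    preprocess_maf,
    read_fasta_alignment,
    read_posterior_tsv,
    write_posterior,
)
from ilshmm.emissions import MISSING_BASE

SPECIES = ("hg", "pt", "gg", "po")


def _maf_block(start: int, size: int, base: str = "A", strand: str = "+") -> str:
    seq = base * size
    lines = [f"a score=0.0"]
    lines.append(f"s hg.chr1 {start} {size} {strand} 248956422 {seq}")
    for sp in ("pt", "gg", "po"):
        lines.append(f"s {sp}.chr1 {start} {size} + 100000000 {seq}")
    return "\n".join(lines) + "\n"


def _write_maf(path, blocks: list[str]) -> str:
    path.write_text("##maf version=1\n\n" + "\n".join(blocks))
    return str(path)


class TestPreprocess:
    def test_nearby_blocks_merge_with_n_fill(self, tmp_path):
        """Two 1,500-bp blocks 150 bp apart become one retained 3,150-bp
        segment."""
        maf = _write_maf(
            tmp_path / "m.maf",
            [_maf_block(0, 1500, "A"), _maf_block(1650, 1500, "C")],
        )
        segs = preprocess_maf(maf, SPECIES)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.ref_span == 3150
        assert seg.sequences["hg"][1500:1650] == "N" * 150
        assert seg.sequences["hg"][:1500] == "A" * 1500
        assert seg.sequences["po"][1650:] == "C" * 1500

    def test_short_lone_block_dropped(self, tmp_path):
        maf = _write_maf(tmp_path / "m.maf", [_maf_block(0, 1999)])
        assert preprocess_maf(maf, SPECIES) == []

    def test_distant_short_blocks_both_dropped(self, tmp_path):
        maf = _write_maf(
            tmp_path / "m.maf",
            [_maf_block(0, 1500), _maf_block(1750, 1500)],  # gap 250 > 200
        )
        assert preprocess_maf(maf, SPECIES) == []

    def test_block_missing_species_dropped(self, tmp_path):
        ok = _maf_block(0, 2500)
        broken = "\n".join(
            line for line in _maf_block(3000, 2500).splitlines()
            if not line.startswith("s po")
        ) + "\n"
        maf = _write_maf(tmp_path / "m.maf", [ok, broken])
        segs = preprocess_maf(maf, SPECIES)
        assert [s.ref_start for s in segs] == [0]

    def test_reference_minus_strand_rejected(self, tmp_path):
        maf = _write_maf(tmp_path / "m.maf", [_maf_block(0, 2500, strand="-")])
        with pytest.raises(ValueError):
            preprocess_maf(maf, SPECIES)

    def test_idempotent(self, tmp_path):
        maf = _write_maf(
            tmp_path / "m.maf",
            [_maf_block(0, 1500), _maf_block(1650, 1500), _maf_block(9000, 2200)],
        )
        segs = preprocess_maf(maf, SPECIES)
        again = merge_and_filter(segs, merge_gap=200, min_len=2000)
        assert [(s.ref_start, s.ref_span) for s in again] == [
            (s.ref_start, s.ref_span) for s in segs
        ]

    def test_retained_bases_monotone_in_min_len(self, tmp_path):
        maf = _write_maf(
            tmp_path / "m.maf",
            [_maf_block(0, 2100), _maf_block(5000, 2600), _maf_block(9000, 3500)],
        )
        totals = []
        for min_len in (1000, 2200, 2700, 4000):
            segs = preprocess_maf(maf, SPECIES, min_len=min_len)
            totals.append(sum(s.ref_span for s in segs))
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_hardmask_lowercase(self, tmp_path):
        block = _maf_block(0, 2500, "A").replace("A" * 2500, "a" * 2500)
        maf = _write_maf(tmp_path / "m.maf", [block])
        soft = preprocess_maf(maf, SPECIES)[0]
        hard = preprocess_maf(maf, SPECIES, hardmask_lowercase=True)[0]
        assert set(soft.sequences["hg"]) == {"A"}
        assert set(hard.sequences["hg"]) == {"N"}


class TestEncoding:
    def test_constant_columns(self):
        codes = encode_alignment(["A", "A", "A", "A"])
        assert codes[0] == 0
        codes = encode_alignment(["T", "T", "T", "T"])
        assert codes[0] == 255

    def test_base4_order(self):
        # (A, C, G, T) -> 0*64 + 1*16 + 2*4 + 3
        assert encode_alignment(["A", "C", "G", "T"])[0] == 27

    def test_missing_column_mask(self):
        # (A, -, C, G): present mask A|C|D = 1 + 4 + 8 = 13
        code = encode_alignment(["A", "-", "C", "G"])[0]
        partial = 0 * 64 + 0 * 16 + 1 * 4 + 2
        assert code == MISSING_BASE + 13 * 256 + partial

    def test_unexpected_character_raises(self):
        with pytest.raises(ValueError):
            encode_alignment(["A", "A", "A", "X"])

    def test_segment_roundtrip_through_fasta(self, tmp_path):
        fasta = tmp_path / "aln.fa"
        fasta.write_text(">A\nACGTN\n>B\nACGT-\n>C\nACGTA\n>D\nACGTC\n")
        seg = read_fasta_alignment(fasta, ("A", "B", "C", "D"))
        codes = encode_patterns(seg, ("A", "B", "C", "D"))
        assert len(codes) == 5
        assert codes[0] == 0
        assert codes[3] == 255
        assert codes[4] >= MISSING_BASE


class TestTrackOutput:
    @pytest.fixture()
    def segment(self, sim100kb):
        seqs = {sp: sim100kb.alignment[sp][:5000] for sp in "ABCD"}
        return AlignmentSegment(
            ref_name="A", ref_start=1000, ref_span=5000, sequences=seqs
        )

    @pytest.fixture()
    def track(self, model33, segment):
        return model33.posterior(encode_patterns(segment, ("A", "B", "C", "D")))

    def test_tsv_round_trip(self, tmp_path, track, segment, grid33):
        out = tmp_path / "post.tsv"
        write_posterior(track, segment, out, format="tsv")
        df = read_posterior_tsv(out)
        assert len(df) == segment.length
        assert df["start"].iloc[0] == 1000
        np.testing.assert_allclose(df["V2"], track.topology[:, 2], atol=1e-6)
        n_value_cols = len(df.columns) - 3  # chrom, start, end
        assert n_value_cols == 4 + (grid33.n_ab + grid33.n_abc) + grid33.n_abc

    def test_bedgraph_partitions_segment(self, tmp_path, track, segment):
        out = tmp_path / "post.bedgraph"
        write_posterior(track, segment, out, format="bedgraph")
        rows = [line.split("\t") for line in out.read_text().splitlines()]
        starts = [int(r[1]) for r in rows]
        ends = [int(r[2]) for r in rows]
        assert starts[0] == segment.ref_start
        assert ends[-1] == segment.ref_start + segment.length
        assert all(e == s for e, s in zip(ends[:-1], starts[1:]))

    def test_length_mismatch_rejected(self, tmp_path, track, segment):
        short = AlignmentSegment(
            ref_name="A", ref_start=0, ref_span=10,
            sequences={sp: segment.sequences[sp][:10] for sp in segment.sequences},
        )
        with pytest.raises(ValueError):
            write_posterior(track, short, tmp_path / "x.tsv")
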