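"""Alignment input, preprocessing, pattern encoding and track output.

MAF preprocessing follows the standard comparative-genomics recipe for
human-referenced multiz alignments: restrict blocks to the four species
of interest, merge consecutive syntenic blocks separated by at most
``merge_gap`` reference bases (the gap is filled with N in every
species), and drop merged segments whose reference span is below
``min_len``.  FASTA input (four equal-length aligned sequences) covers
simulated data.  Posterior tracks are written as TSV or bedGraph with
0-based half-open reference coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .emissions import MISSING_BASE, PosteriorTrack

__all__ = [
    "AlignmentSegment",
    "preprocess_maf",
    "merge_and_filter",
    "read_fasta_alignment",
    "encode_patterns",
    "encode_alignment",
    "write_posterior",
    "read_posterior_tsv",
]

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN-")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class AlignmentSegment:
    """A contiguous aligned region anchored on the reference species.

    Reference coordinates are 0-based half-open; all per-species
    sequences have equal (alignment) length and use {A,C,G,T,N,-} only.
    """

    ref_name: str
    ref_start: int
    ref_span: int
    sequences: dict[str, str]
    sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        for name, seq in self.sequences.items():
            bad = set(seq) - _ALLOWED
            if bad:
                raise ValueError(f"{name}: unexpected characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span


def _normalise(seq: str, hardmask_lowercase: bool) -> str:
    if hardmask_lowercase:
        seq = "".join("N" if c.islower() else c for c in seq)
    return seq.upper()


def preprocess_maf(
    maf_path: str | Path,
    species: tuple[str, str, str, str],
    merge_gap: int = 200,
    min_len: int = 2000,
    hardmask_lowercase: bool = False,
) -> list[AlignmentSegment]:
    """Read and filter a MAF file into analysis-ready segments.

    The first entry of ``species`` is the reference; blocks with the
    reference on the minus strand are rejected, and blocks missing any
    of the four species are dropped (counted in the log).
    """
    ref = species[0]
    blocks: list[AlignmentSegment] = []
    dropped = 0
    for block_no, msa in enumerate(AlignIO.parse(str(maf_path), "maf")):
        rows = {}
        for rec in msa:
            sp = rec.id.split(".", 1)[0]
            if sp in species and sp not in rows:
                rows[sp] = rec
        if set(rows) != set(species):
            dropped += 1
            continue
        ref_rec = rows[ref]
        if ref_rec.annotations.get("strand", 1) == -1:
            raise ValueError(
                f"block {block_no}: reference on minus strand is not supported"
            )
        blocks.append(
            AlignmentSegment(
                ref_name=ref_rec.id,
                ref_start=int(ref_rec.annotations["start"]),
                ref_span=int(ref_rec.annotations["size"]),
                sequences={
                    sp: _normalise(str(rows[sp].seq), hardmask_lowercase)
                    for sp in species
                },
                sources=[f"block{block_no}"],
            )
        )
    if dropped:
        logger.info("dropped %d block(s) missing one of %s", dropped, species)
    return merge_and_filter(blocks, merge_gap=merge_gap, min_len=min_len)


def merge_and_filter(
    segments: list[AlignmentSegment], merge_gap: int = 200, min_len: int = 2000
) -> list[AlignmentSegment]:
    """Merge near-adjacent segments and drop short ones (idempotent).

    Segments on the same reference sequence whose reference gap is at
    most ``merge_gap`` are concatenated with the gap N-filled in every
    species; merged segments spanning fewer than ``min_len`` reference
    bases are discarded.
    """
    segs = sorted(segments, key=lambda s: (s.ref_name, s.ref_start))
    merged: list[AlignmentSegment] = []
    for seg in segs:
        if merged:
            prev = merged[-1]
            gap = seg.ref_start - prev.ref_end
            if seg.ref_name == prev.ref_name and 0 <= gap <= merge_gap:
                fill = "N" * gap
                merged[-1] = AlignmentSegment(
                    ref_name=prev.ref_name,
                    ref_start=prev.ref_start,
                    ref_span=prev.ref_span + gap + seg.ref_span,
                    sequences={
                        sp: prev.sequences[sp] + fill + seg.sequences[sp]
                        for sp in prev.sequences
                    },
                    sources=prev.sources + seg.sources,
                )
                continue
        merged.append(seg)
    return [s for s in merged if s.ref_span >= min_len]


def read_fasta_alignment(
    fasta_path: str | Path,
    species: tuple[str, str, str, str],
    ref_name: str | None = None,
    hardmask_lowercase: bool = False,
) -> AlignmentSegment:
    """Four equal-length aligned sequences from FASTA (simulated data)."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    missing = [sp for sp in species if sp not in records]
    if missing:
        raise ValueError(f"FASTA is missing species {missing}")
    seqs = {sp: _normalise(records[sp], hardmask_lowercase) for sp in species}
    return AlignmentSegment(
        ref_name=ref_name or species[0],
        ref_start=0,
        ref_span=len(seqs[species[0]]),
        sequences=seqs,
        sources=[str(fasta_path)],
    )


def encode_alignment(seqs: list[str]) -> np.ndarray:
    """Encode aligned (A, B, C, outgroup) sequences as pattern codes.

    Complete columns map to 0..255 in base 4 (A=0, C=1, G=2, T=3); a
    column with any missing tip maps to 256 + 256*mask + partial code,
    where bit i of the mask marks species i present.
    """
    if len(seqs) != 4 or len({len(s) for s in seqs}) != 1:
        raise ValueError("need 4 equal-length sequences")
    rows = []
    for seq in seqs:
        a = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        row = np.full(a.shape, -1, dtype=np.int32)
        for base, code in _BASE_CODE.items():
            row[a == ord(base)] = code
        unexpected = ~np.isin(a, [ord(c) for c in _ALLOWED])
        if unexpected.any():
            pos = int(np.where(unexpected)[0][0])
            raise ValueError(f"unexpected character {chr(a[pos])!r} at column {pos}")
        rows.append(row)
    M = np.stack(rows)  # (4, L), -1 for missing
    present = M >= 0
    mask = (present * np.array([[1], [2], [4], [8]])).sum(axis=0)
    digits = np.where(present, M, 0)
    base4 = ((digits[0] * 4 + digits[1]) * 4 + digits[2]) * 4 + digits[3]
    codes = np.where(mask == 15, base4, MISSING_BASE + mask * 256 + base4)
    return codes.astype(np.int64)


def encode_patterns(
    segment: AlignmentSegment, species_order: tuple[str, str, str, str] | None = None
) -> np.ndarray:
    """Column codes of a segment in (A, B, C, outgroup) order."""
    order = species_order or tuple(segment.sequences)
    return encode_alignment([segment.sequences[sp] for sp in order])


def _track_frame(track: PosteriorTrack, segment: AlignmentSegment) -> pd.DataFrame:
    if len(track) != segment.length:
        raise ValueError(
            f"track length {len(track)} != segment length {segment.length}"
        )
    start = segment.ref_start
    data = {
        "chrom": segment.ref_name,
        "start": np.arange(start, start + len(track)),
        "end": np.arange(start + 1, start + len(track) + 1),
    }
    for i in range(4):
        data[f"V{i}"] = track.topology[:, i]
    for i in range(track.first.shape[1]):
        data[f"F{i + 1}"] = track.first[:, i]
    for i in range(track.second.shape[1]):
        data[f"S{i + 1}"] = track.second[:, i]
    return pd.DataFrame(data)


def write_posterior(
    track: PosteriorTrack,
    segment: AlignmentSegment,
    out_path: str | Path,
    format: str = "tsv",
) -> None:
    """Write grouped posterior tracks (tsv) or the run-length-encoded
    ILS posterior V2+V3 (bedgraph), 0-based half-open coordinates."""
    if format == "tsv":
        df = _track_frame(track, segment)
        df.to_csv(out_path, sep="\t", index=False, float_format="%.8f")
    elif format == "bedgraph":
        if len(track) != segment.length:
            raise ValueError("track/segment length mismatch")
        ils = np.round(track.topology[:, 2] + track.topology[:, 3], 6)
        edges = np.flatnonzero(np.diff(ils)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [len(track)]])
        with open(out_path, "w") as fh:
            for s, e in zip(starts, ends):
                fh.write(
                    f"{segment.ref_name}\t{segment.ref_start + s}\t"
                    f"{segment.ref_start + e}\t{ils[s]:.6f}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_posterior_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
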