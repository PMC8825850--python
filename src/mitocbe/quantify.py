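"""Read placement, quality-filtered pileups, and per-site editing frequencies.

The aligner is a gapless seed-and-extend placement adequate for amplicon
reads: exact k-mer seeds locate candidate starts, full-length Hamming
extension scores them, and a read is kept only if it has a unique best
placement with mismatch fraction below a threshold.  Unique placements get a
mapping-quality proxy of 60; reads aligned externally can be ingested from
SAM instead, in which case the recorded MAPQ is honoured.

Pileups tabulate A/C/G/T counts per reference position on the plus strand.
A base contributes only if its read's mapping quality passes
``min_mapping_quality`` and its own Phred score passes ``min_base_quality``
(both default 30); raw depth counts every aligned base regardless.
Editing frequency at a target site is then T/depth for a plus-strand C and
A/depth for a minus-strand C (which the reference shows as G).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .design import EditSite
from .errors import DataError
from .reference import MitoGenome, reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_UNIQUE_MAPQ = 60


@dataclass
class AlignedRead:
    """A gapless read placement, stored in plus-strand (reference) orientation."""

    read_id: str
    ref_start: int  # 1-based
    strand: str
    sequence: str  # reference-oriented
    qualities: np.ndarray  # Phred scores, reference-oriented
    mapq: int = _UNIQUE_MAPQ

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise DataError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass
class AlignmentResult:
    alignments: list[AlignedRead]
    n_total: int
    n_unaligned: int
    n_skipped_indel: int = 0

    @property
    def n_aligned(self) -> int:
        return len(self.alignments)


def read_fastq(path) -> list[tuple[str, str, np.ndarray]]:
    """(id, sequence, Phred array) triples from a Sanger-encoded FASTQ."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            (rec.id, str(rec.seq).upper(), np.array(rec.letter_annotations["phred_quality"]))
        )
    return out


def _seed_index(seq: str, k: int, circular: bool) -> dict[str, list[int]]:
    ext = seq + seq[: k - 1] if circular else seq
    index: dict[str, list[int]] = {}
    n_starts = len(seq) if circular else len(seq) - k + 1
    for i in range(max(n_starts, 0)):
        index.setdefault(ext[i : i + k], []).append(i)
    return index


def align_reads(
    genome: MitoGenome,
    reads,
    k: int = 20,
    max_mismatch_frac: float = 0.1,
) -> AlignmentResult:
    """Place reads on the reference by exact k-mer seeding + gapless extension.

    ``reads`` is a FASTQ path or an iterable of (id, sequence, Phred array).
    Both orientations are tried; seeds are taken every k bases plus the read
    tail.  Reads with no seed hit, with mismatch fraction above the
    threshold, or with a tied best placement are left unaligned.
    """
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = read_fastq(reads)
    L = genome.length
    index = _seed_index(genome.sequence, k, genome.circular)
    ext_seq = genome.sequence * 2 if genome.circular else genome.sequence
    ext_arr = np.frombuffer(ext_seq.encode(), dtype=np.uint8)
    aligned: list[AlignedRead] = []
    n_total = n_unaligned = 0
    for read_id, seq, quals in reads:
        n_total += 1
        n = len(seq)
        if n < k or n > L:
            n_unaligned += 1
            continue
        candidates: set[tuple[int, str]] = set()
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            offsets = list(range(0, n - k + 1, k))
            if offsets[-1] != n - k:
                offsets.append(n - k)
            for off in offsets:
                for hit in index.get(oriented[off : off + k], ()):
                    start = (hit - off) % L if genome.circular else hit - off
                    if genome.circular or (0 <= start and start + n <= L):
                        candidates.add((start, strand))
        if not candidates:
            n_unaligned += 1
            continue
        best_mm, best = None, []
        for start, strand in sorted(candidates):
            oriented = seq if strand == "+" else reverse_complement(seq)
            read_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            mm = int((ext_arr[start : start + n] != read_arr).sum())
            if best_mm is None or mm < best_mm:
                best_mm, best = mm, [(start, strand)]
            elif mm == best_mm:
                best.append((start, strand))
        if len(best) != 1 or best_mm / n > max_mismatch_frac:
            n_unaligned += 1
            continue
        start, strand = best[0]
        if strand == "+":
            ref_seq, ref_quals = seq, quals
        else:
            ref_seq, ref_quals = reverse_complement(seq), quals[::-1]
        aligned.append(AlignedRead(read_id, start + 1, strand, ref_seq, ref_quals))
    return AlignmentResult(aligned, n_total, n_unaligned)


def write_sam(path, genome: MitoGenome, result: AlignmentResult) -> None:
    """Minimal SAM: one @SQ line, gapless CIGARs, reverse flag for minus reads."""
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": genome.name, "LN": genome.length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in result.alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.reference_id = 0
            seg.reference_start = a.ref_start - 1  # SAM is 0-based
            seg.mapping_quality = a.mapq
            seg.cigarstring = f"{len(a.sequence)}M"
            seg.flag = 16 if a.strand == "-" else 0
            # SAM stores the read in reference orientation, as we do
            seg.query_sequence = a.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in a.qualities)
            )
            fh.write(seg)


def ingest_sam(path, genome: MitoGenome) -> AlignmentResult:
    """Convert gapless (or soft-clip-only) SAM records to :class:`AlignedRead`.

    Unmapped records are dropped; records with indel CIGAR operations are
    skipped and counted.  The reference name and length must match.
    """
    n_total = n_unaligned = n_indel = 0
    aligned: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        sq = fh.header.get("SQ", [])
        if not sq or sq[0]["SN"] != genome.name or sq[0]["LN"] != genome.length:
            raise DataError(
                f"{path}: SAM reference does not match genome "
                f"{genome.name!r} (length {genome.length})"
            )
        for seg in fh:
            n_total += 1
            if seg.is_unmapped:
                n_unaligned += 1
                continue
            ops = {op for op, _ in (seg.cigartuples or [])}
            if ops - {0, 4, 7, 8}:  # anything beyond M/S/=/X
                n_indel += 1
                continue
            seq = seg.query_alignment_sequence
            quals = np.array(seg.query_alignment_qualities)
            aligned.append(
                AlignedRead(
                    seg.query_name,
                    seg.reference_start + 1,
                    "-" if seg.is_reverse else "+",
                    seq.upper(),
                    quals,
                    mapq=seg.mapping_quality,
                )
            )
    return AlignmentResult(aligned, n_total, n_unaligned, n_skipped_indel=n_indel)


@dataclass
class PileupTable:
    """Per-position filtered base counts (plus strand) over the whole reference."""

    genome_name: str
    length: int
    counts: np.ndarray  # (length, 4) int64, A/C/G/T after filters
    raw_depth: np.ndarray  # (length,) int64, all aligned bases
    min_base_quality: int = 30
    min_mapping_quality: int = 30

    @property
    def filtered_depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def base_count(self, position: int, base: str) -> int:
        return int(self.counts[position - 1, _BASE_INDEX[base]])

    def depth(self, position: int) -> int:
        return int(self.filtered_depth[position - 1])

    def __add__(self, other: "PileupTable") -> "PileupTable":
        if (self.genome_name, self.length) != (other.genome_name, other.length):
            raise DataError("cannot add pileups over different references")
        return PileupTable(
            self.genome_name,
            self.length,
            self.counts + other.counts,
            self.raw_depth + other.raw_depth,
            self.min_base_quality,
            self.min_mapping_quality,
        )

    def to_dataframe(self, genome: MitoGenome | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "A": self.counts[:, 0],
                "C": self.counts[:, 1],
                "G": self.counts[:, 2],
                "T": self.counts[:, 3],
                "depth_raw": self.raw_depth,
                "depth_filtered": self.filtered_depth,
            }
        )
        if genome is not None:
            df.insert(1, "ref", list(genome.sequence))
        return df

    def to_tsv(self, path, genome: MitoGenome | None = None) -> None:
        self.to_dataframe(genome).to_csv(path, sep="\t", index=False)


def build_pileup(
    genome: MitoGenome,
    alignments: AlignmentResult | list[AlignedRead],
    min_base_quality: int = 30,
    min_mapping_quality: int = 30,
) -> PileupTable:
    """Tabulate per-position base counts after mapping- and base-quality filters."""
    if isinstance(alignments, AlignmentResult):
        alignments = alignments.alignments
    L = genome.length
    counts = np.zeros((L, 4), dtype=np.int64)
    raw = np.zeros(L, dtype=np.int64)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    for a in alignments:
        n = len(a.sequence)
        idx = (a.ref_start - 1 + np.arange(n)) % L
        np.add.at(raw, idx, 1)
        if a.mapq < min_mapping_quality:
            continue
        bi = lut[np.frombuffer(a.sequence.encode(), dtype=np.uint8)]
        keep = (np.asarray(a.qualities) >= min_base_quality) & (bi >= 0)
        np.add.at(counts, (idx[keep], bi[keep]), 1)
    return PileupTable(genome.name, L, counts, raw, min_base_quality, min_mapping_quality)


@dataclass
class EditingEntry:
    site: EditSite
    numerator: int
    denominator: int
    frequency: float | None  # None when depth is zero (undefined, not 0)

    @property
    def defined(self) -> bool:
        return self.frequency is not None


def site_editing_frequency(pileup: PileupTable, site: EditSite) -> EditingEntry:
    """Editing frequency at one target cytosine.

    Plus-strand C: T count / filtered depth.  Minus-strand C (reference
    shows G): A count / filtered depth.  Zero depth yields an undefined
    entry rather than 0.
    """
    edited_base = "T" if site.edited_strand == "+" else "A"
    num = pileup.base_count(site.position, edited_base)
    den = pileup.depth(site.position)
    return EditingEntry(site, num, den, (num / den) if den else None)


def editing_profile(pileup: PileupTable, sites: list[EditSite]) -> list[EditingEntry]:
    return [site_editing_frequency(pileup, s) for s in sites]
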