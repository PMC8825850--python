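"""Circular mitochondrial reference genomes: coordinates, strands, and the
vertebrate mitochondrial genetic code.

Conventions used throughout the package
---------------------------------------
* Coordinates are 1-based and inclusive, matching the mitochondrial
  ``m.####`` notation used in clinical and experimental genetics.
* The "plus" strand is the strand stored in the FASTA record.  For the
  mouse/human mitochondrial references this is the light (L) strand, and
  "minus" is the heavy (H) strand; the L/H labels are aliases configured per
  genome rather than hard-wired.
* On a circular genome an interval with ``start > end`` denotes wrap-around
  through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import CoordinateError, FormatError

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval; ``start > end`` means wrap-around (circular only)."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"positions are 1-based, got {self.start}..{self.end}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError("wrap-around interval length requires the genome length")
        return (self.end - self.start) % genome_length + 1

    def positions(self, genome_length: int | None = None) -> list[int]:
        """Plus-strand positions in 5'->3' plus order (wrapping through the origin)."""
        if not self.wraps:
            return list(range(self.start, self.end + 1))
        if genome_length is None:
            raise CoordinateError("wrap-around interval requires the genome length")
        n = self.length(genome_length)
        return [(self.start - 1 + i) % genome_length + 1 for i in range(n)]

    def contains(self, position: int, genome_length: int | None = None) -> bool:
        if not self.wraps:
            return self.start <= position <= self.end
        if genome_length is None:
            raise CoordinateError("wrap-around interval requires the genome length")
        return (position - self.start) % genome_length <= (self.end - self.start) % genome_length


@dataclass
class MitoGenome:
    """A (typically circular) reference sequence with 1-based coordinates.

    ``strand_aliases`` maps the biological strand names onto ``+``/``-``; for
    the rodent and primate mitochondrial references the stored strand is the
    light strand, so the default is ``{"L": "+", "H": "-"}``.
    """

    name: str
    sequence: str
    circular: bool = True
    strand_aliases: dict[str, str] = field(default_factory=lambda: {"L": "+", "H": "-"})

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"genome {self.name!r} has an empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"genome {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Plus-strand base at a 1-based position (wrapping if circular)."""
        if self.circular:
            return self.sequence[(position - 1) % self.length]
        if not 1 <= position <= self.length:
            raise CoordinateError(
                f"position {position} outside linear genome of length {self.length}"
            )
        return self.sequence[position - 1]


def load_fasta(
    path,
    circular: bool = True,
    record_name: str | None = None,
    strand_aliases: dict[str, str] | None = None,
) -> MitoGenome:
    """Read a FASTA reference into a :class:`MitoGenome`.

    A single-record file is read as-is; for multi-record files ``record_name``
    selects the record.  Sequences are uppercased; anything outside A/C/G/T/N
    is rejected.  Circularity is metadata supplied by the caller (FASTA does
    not encode it).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if record_name is None:
        if len(records) > 1:
            raise FormatError(
                f"{path}: {len(records)} records present; pass record_name to choose one"
            )
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_name]
        if not matches:
            raise FormatError(f"{path}: no record named {record_name!r}")
        rec = matches[0]
    kwargs = {} if strand_aliases is None else {"strand_aliases": strand_aliases}
    return MitoGenome(name=rec.id, sequence=str(rec.seq), circular=circular, **kwargs)


def write_fasta(path, genome: MitoGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def fetch(genome: MitoGenome, interval: GenomicInterval) -> str:
    """Sequence of an interval; minus-strand requests return the reverse complement.

    Wrap-around (``start > end``) is honoured only on circular genomes.
    """
    L = genome.length
    if not (1 <= interval.start <= L and 1 <= interval.end <= L):
        raise CoordinateError(
            f"interval {interval.start}..{interval.end} outside genome of length {L}"
        )
    if interval.wraps:
        if not genome.circular:
            raise CoordinateError(
                f"wrap-around interval {interval.start}..{interval.end} on a linear genome"
            )
        plus = genome.sequence[interval.start - 1 :] + genome.sequence[: interval.end]
    else:
        plus = genome.sequence[interval.start - 1 : interval.end]
    return reverse_complement(plus) if interval.strand == "-" else plus


# ---------------------------------------------------------------------------
# Vertebrate mitochondrial genetic code (NCBI translation table 2).
#
# Deviations from the standard code: AGA/AGG are stop codons, ATA codes for
# methionine, and TGA codes for tryptophan.  STOP is written "*".
# ---------------------------------------------------------------------------

_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_MITO_OVERRIDES = {"AGA": "*", "AGG": "*", "ATA": "M", "TGA": "W"}

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


class MitoCodonTable:
    """All 64 codons mapped under the vertebrate mitochondrial code."""

    def __init__(self) -> None:
        self.mapping = dict(_STANDARD_CODE)
        self.mapping.update(_MITO_OVERRIDES)

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise FormatError(f"cannot translate ambiguous or non-triplet codon {codon!r}")
        return self.mapping[codon]

    def translate3(self, codon: str) -> str:
        return THREE_LETTER[self.translate(codon)]


VERTEBRATE_MITO_CODE = MitoCodonTable()


def translate_codon(codon: str, table: MitoCodonTable = VERTEBRATE_MITO_CODE) -> str:
    """One-letter amino acid (``*`` for stop) of a codon under the mito code."""
    return table.translate(codon)


def count_cg_sites(genome: MitoGenome, exclude: set[int] | None = None) -> int:
    """Number of reference positions whose base is C or G.

    Each position is counted once on the reference strand (a C:G pair is one
    site).  ``N`` positions never count; ``exclude`` optionally removes
    further 1-based positions (e.g. primer-binding regions) from the tally.
    """
    if exclude:
        return sum(
            1
            for i, b in enumerate(genome.sequence, start=1)
            if b in "CG" and i not in exclude
        )
    return sum(1 for b in genome.sequence if b in "CG")
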