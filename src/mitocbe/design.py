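"""DdCBE target design: pair geometry, TC-context scanning of the spacer,
spacer-index arithmetic, and protein-level outcome prediction.

A DdCBE is a pair of TALE-fusion monomers flanking a spacer; the split
double-stranded cytidine deaminase (DddA_tox) reassembles over the spacer and
deaminates cytosines in TC context on either strand.  Two split points
(G1333, G1397) times two orientations of the N-/C-terminal halves give four
possible configurations per TALE geometry.

Spacer indexing: index 1 is the spacer base adjacent to the plus(L)-strand
TALE window, increasing toward the minus(H)-strand window.

TC context: a cytosine is editable when its 5' neighbour on the same strand
is T, or when it belongs to a contiguous run of cytosines whose 5'-most C is
preceded by T (both cytosines of a T-preceded CC doublet are deaminated by
current editors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import CoordinateError, GeometryError
from .reference import GenomicInterval, MitoCodonTable, MitoGenome, VERTEBRATE_MITO_CODE

SPLITS = ("G1333", "G1397")
ORIENTATIONS = ("N-on-L", "N-on-H")


@dataclass(frozen=True)
class EditSite:
    """A cytosine in the spacer, addressed both by spacer index and genome coordinate."""

    spacer_index: int
    position: int
    edited_strand: str  # strand carrying the C ('+' or '-')
    context_ok: bool

    def __post_init__(self) -> None:
        if self.edited_strand not in ("+", "-"):
            raise CoordinateError(f"edited_strand must be '+' or '-', got {self.edited_strand!r}")


@dataclass(frozen=True)
class DdcbePair:
    name: str
    tale_L_window: GenomicInterval
    tale_H_window: GenomicInterval
    spacer: GenomicInterval
    split: str
    orientation: str
    catalytically_active: bool = True
    # editing-window preference of each split/orientation is descriptive
    # metadata only; it is never used to score designs
    window_preference: str = ""


@dataclass(frozen=True)
class OutcomePrediction:
    edited_sites: tuple[EditSite, ...]
    codon_before: str
    codon_after: str
    aa_change: str
    notation: tuple[str, ...]


def _relative_offset(pos: int, anchor: int, genome_length: int | None) -> int:
    if genome_length is None:
        return pos - anchor
    return (pos - anchor) % genome_length


def enumerate_pairs(
    tale_L: GenomicInterval,
    tale_H: GenomicInterval,
    spacer: GenomicInterval,
    genome_length: int | None = None,
    name_prefix: str = "pair",
) -> list[DdcbePair]:
    """All four split x orientation configurations for one TALE geometry.

    Geometry requirement: walking 5'->3' along the plus strand from the
    L-window start, the layout is L window, then spacer, then H window, with
    no overlaps.  Ordered G1333 before G1397, N-on-L before N-on-H.
    """
    anchor = tale_L.start
    l_end = _relative_offset(tale_L.end, anchor, genome_length)
    s_start = _relative_offset(spacer.start, anchor, genome_length)
    s_end = _relative_offset(spacer.end, anchor, genome_length)
    h_start = _relative_offset(tale_H.start, anchor, genome_length)
    h_end = _relative_offset(tale_H.end, anchor, genome_length)
    if not (0 <= l_end < s_start <= s_end < h_start <= h_end):
        raise GeometryError(
            "invalid layout: spacer must lie strictly between the L- and H-strand "
            f"TALE windows without overlap (L={tale_L.start}..{tale_L.end}, "
            f"spacer={spacer.start}..{spacer.end}, H={tale_H.start}..{tale_H.end})"
        )
    pairs = []
    for i, (split, orientation) in enumerate(
        [(s, o) for s in SPLITS for o in ORIENTATIONS], start=1
    ):
        pairs.append(
            DdcbePair(
                name=f"{name_prefix}-{i}",
                tale_L_window=tale_L,
                tale_H_window=tale_H,
                spacer=spacer,
                split=split,
                orientation=orientation,
            )
        )
    return pairs


def _tc_context_plus(genome: MitoGenome, pos: int) -> bool:
    """True if the plus-strand C at ``pos`` sits in (extended) TC context."""
    L = genome.length
    q = pos - 1
    steps = 0
    while True:
        if q < 1:
            if not genome.circular:
                return False
            q += L
        b = genome.base(q)
        if b == "C":
            q -= 1
            steps += 1
            if steps >= L:  # all-C circular genome
                return False
            continue
        return b == "T"


def _tc_context_minus(genome: MitoGenome, pos: int) -> bool:
    """True if the minus-strand C (plus-strand G) at ``pos`` sits in TC context.

    The 5' direction on the minus strand corresponds to increasing plus
    coordinates; T on the minus strand reads A on the plus strand.
    """
    L = genome.length
    q = pos + 1
    steps = 0
    while True:
        if q > L:
            if not genome.circular:
                return False
            q -= L
        b = genome.base(q)
        if b == "G":
            q += 1
            steps += 1
            if steps >= L:
                return False
            continue
        return b == "A"


def scan_tc_sites(
    genome: MitoGenome,
    spacer: GenomicInterval,
    include_non_tc: bool = False,
) -> list[EditSite]:
    """Editable cytosines in the spacer on either strand.

    Returns every spacer C whose (run-extended) 5' neighbour on its own
    strand is T with ``context_ok=True``; with ``include_non_tc`` the
    remaining spacer cytosines are also returned, flagged ``context_ok=False``.
    The context neighbour may lie one or more bases outside the spacer.
    """
    L = genome.length
    sites: list[EditSite] = []
    for index, pos in enumerate(spacer.positions(L), start=1):
        base = genome.base(pos)
        if base == "C":
            ok = _tc_context_plus(genome, pos)
            if ok or include_non_tc:
                sites.append(EditSite(index, pos, "+", ok))
        elif base == "G":
            ok = _tc_context_minus(genome, pos)
            if ok or include_non_tc:
                sites.append(EditSite(index, pos, "-", ok))
    return sites


def spacer_index_to_coord(
    spacer: GenomicInterval, index: int, genome_length: int | None = None
) -> int:
    """Genome coordinate of a 1-based spacer index (C_12 -> m.9576 style)."""
    n = spacer.length(genome_length)
    if not 1 <= index <= n:
        raise CoordinateError(f"spacer index {index} outside 1..{n}")
    if genome_length is None:
        return spacer.start + index - 1
    return (spacer.start - 1 + index - 1) % genome_length + 1


def _edited_plus_base(genome: MitoGenome, site: EditSite) -> str:
    """Plus-strand base after deamination of the site's C (C->T, i.e. G->A on plus)."""
    ref = genome.base(site.position)
    if site.edited_strand == "+":
        if ref != "C":
            raise CoordinateError(f"position {site.position} is {ref}, not C, on the plus strand")
        return "T"
    if ref != "G":
        raise CoordinateError(f"position {site.position} is {ref}, not G (minus-strand C)")
    return "A"


def hgvs_notation(genome: MitoGenome, site: EditSite) -> str:
    """m.####C>T / m.####G>A string for the edit at a site (plus-strand sense)."""
    ref = genome.base(site.position)
    return f"m.{site.position}{ref}>{'T' if ref == 'C' else 'A'}"


def predict_outcomes(
    genome: MitoGenome,
    codon_frame: tuple[int, str],
    sites: list[EditSite],
    aa_number: int | None = None,
    table: MitoCodonTable = VERTEBRATE_MITO_CODE,
) -> list[OutcomePrediction]:
    """Amino-acid consequences of every non-empty edit combination in one codon.

    ``codon_frame`` is (plus-strand position of the codon's first base, mRNA
    sense strand).  Sites outside the codon are ignored; for each non-empty
    subset of the in-frame sites the post-edit codon and amino-acid change
    (``G40K``-style when ``aa_number`` is given, ``G>K`` otherwise) are
    reported.  Bases outside the edited subset are never altered.
    """
    start, mrna_strand = codon_frame
    L = genome.length
    codon_iv = GenomicInterval(start, (start - 1 + 2) % L + 1 if genome.circular else start + 2)
    codon_positions = codon_iv.positions(L)
    if any(not 1 <= p <= L for p in codon_positions):
        raise CoordinateError(f"codon frame at {start} extends outside the genome")
    in_frame = [s for s in sites if s.position in codon_positions]
    in_frame.sort(key=lambda s: codon_positions.index(s.position))
    plus_codon = [genome.base(p) for p in codon_positions]

    def orient(bases: list[str]) -> str:
        s = "".join(bases)
        if mrna_strand == "-":
            from .reference import reverse_complement

            return reverse_complement(s)
        return s

    codon_before = orient(plus_codon)
    aa_before = table.translate(codon_before)
    num = str(aa_number) if aa_number is not None else ">"
    out: list[OutcomePrediction] = []
    n = len(in_frame)
    for mask in range(1, 2**n):
        subset = tuple(in_frame[i] for i in range(n) if mask >> i & 1)
        after = list(plus_codon)
        for s in subset:
            after[codon_positions.index(s.position)] = _edited_plus_base(genome, s)
        codon_after = orient(after)
        aa_after = table.translate(codon_after)
        out.append(
            OutcomePrediction(
                edited_sites=subset,
                codon_before=codon_before,
                codon_after=codon_after,
                aa_change=f"{aa_before}{num}{aa_after}",
                notation=tuple(hgvs_notation(genome, s) for s in subset),
            )
        )
    out.sort(key=lambda p: (len(p.edited_sites), tuple(s.spacer_index for s in p.edited_sites)))
    return out


# ---------------------------------------------------------------------------
# TargetSpec: the serialized description of one editing target
# ---------------------------------------------------------------------------


@dataclass
class TargetSpec:
    """Everything the downstream stages need to know about one DdCBE target."""

    genome_name: str
    tale_L_window: GenomicInterval
    tale_H_window: GenomicInterval
    spacer: GenomicInterval
    sites: list[EditSite] = field(default_factory=list)
    codon_start: int | None = None
    mrna_strand: str = "+"
    aa_number: int | None = None
    # indices (into ``sites``) of the two cytosines whose co-editing defines
    # the read-level haplotype classes; by spacer order
    primary_site_indices: tuple[int, int] | None = None

    def primary_sites(self) -> list[EditSite]:
        if self.primary_site_indices is None:
            raise GeometryError("TargetSpec has no primary (haplotype-defining) sites")
        return [self.sites[i] for i in self.primary_site_indices]

    def to_dict(self) -> dict:
        def iv(i: GenomicInterval) -> dict:
            return {"start": i.start, "end": i.end, "strand": i.strand}

        return {
            "genome_name": self.genome_name,
            "tale_L_window": iv(self.tale_L_window),
            "tale_H_window": iv(self.tale_H_window),
            "spacer": iv(self.spacer),
            "sites": [
                {
                    "spacer_index": s.spacer_index,
                    "position": s.position,
                    "edited_strand": s.edited_strand,
                    "context_ok": s.context_ok,
                }
                for s in self.sites
            ],
            "codon_start": self.codon_start,
            "mrna_strand": self.mrna_strand,
            "aa_number": self.aa_number,
            "primary_site_indices": list(self.primary_site_indices)
            if self.primary_site_indices is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetSpec":
        def iv(x: dict) -> GenomicInterval:
            return GenomicInterval(x["start"], x["end"], x.get("strand", "+"))

        return cls(
            genome_name=d["genome_name"],
            tale_L_window=iv(d["tale_L_window"]),
            tale_H_window=iv(d["tale_H_window"]),
            spacer=iv(d["spacer"]),
            sites=[
                EditSite(s["spacer_index"], s["position"], s["edited_strand"], s["context_ok"])
                for s in d.get("sites", [])
            ],
            codon_start=d.get("codon_start"),
            mrna_strand=d.get("mrna_strand", "+"),
            aa_number=d.get("aa_number"),
            primary_site_indices=tuple(d["primary_site_indices"])
            if d.get("primary_site_indices")
            else None,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TargetSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_bed(self, path) -> None:
        """Windows and sites in BED (0-based half-open) coordinates."""
        with open(path, "w") as fh:
            for label, iv in (
                ("TALE_L", self.tale_L_window),
                ("spacer", self.spacer),
                ("TALE_H", self.tale_H_window),
            ):
                fh.write(f"{self.genome_name}\t{iv.start - 1}\t{iv.end}\t{label}\t0\t+\n")
            for s in self.sites:
                fh.write(
                    f"{self.genome_name}\t{s.position - 1}\t{s.position}\t"
                    f"C{s.spacer_index}\t0\t{s.edited_strand}\n"
                )
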