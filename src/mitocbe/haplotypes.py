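"""Per-read co-editing haplotype classification by exact flank matching.

Mirrors the zero-error exact-substring procedure used on real amplicon data:
a short window spanning both target cytosines plus fixed flanks is built for
every edit combination (both edited -> G40K, only the second -> G40E, only
the first -> G40*, neither -> WT), and a read is labelled by the single
pattern it contains verbatim (either orientation).  A read matching no
pattern — e.g. one with a sequencing error inside the window, or one not
spanning the window — is "unclassified" and excluded from distributions.

The default 4-base flanks give a 10-nt window for a two-base target.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import EditSite
from .errors import ConfigError
from .quantify import AlignedRead
from .reference import GenomicInterval, MitoGenome, fetch, reverse_complement

EDITED_LABELS = ("G40K", "G40E", "G40*")
DEFAULT_LABEL_MAP = {(): "WT", (0,): "G40*", (1,): "G40E", (0, 1): "G40K"}


@dataclass(frozen=True)
class ClassPattern:
    label: str
    sequence: str
    window: GenomicInterval
    edited_positions: tuple[int, ...]


@dataclass(frozen=True)
class ReadClassCall:
    read_id: str
    label: str  # a pattern label or "unclassified"
    offset: int | None = None  # match offset within the read (as sequenced)


def build_patterns(
    genome: MitoGenome,
    sites: list[EditSite],
    flank: int = 4,
    label_map: dict[tuple[int, ...], str] | None = None,
) -> list[ClassPattern]:
    """One exact-match pattern per edit-site subset over a common window.

    ``sites`` are the haplotype-defining cytosines (two for the canonical
    G40K/G40E/G40*/WT scheme); the window runs from ``flank`` bases before
    the first to ``flank`` bases after the last on the plus strand.
    ``label_map`` maps subsets (as sorted tuples of indices into ``sites``)
    to labels; by default the canonical two-site labels.  A generalized
    N-site scheme is obtained by passing an explicit map over all 2^N
    subsets.
    """
    if not sites:
        raise ConfigError("at least one haplotype-defining site is required")
    ordered = sorted(sites, key=lambda s: s.spacer_index)
    if label_map is None:
        if len(ordered) != 2:
            raise ConfigError(
                "the default G40K/G40E/G40*/WT labelling requires exactly two sites; "
                "pass label_map for other designs"
            )
        label_map = DEFAULT_LABEL_MAP
    L = genome.length
    positions = [s.position for s in ordered]
    lo = positions[0] - flank
    hi = positions[-1] + flank
    if genome.circular:
        window = GenomicInterval((lo - 1) % L + 1, (hi - 1) % L + 1)
    else:
        if lo < 1 or hi > L:
            raise ConfigError("pattern window extends beyond the linear reference")
        window = GenomicInterval(lo, hi)
    win_positions = window.positions(L)
    ref_window = fetch(genome, window)
    patterns: list[ClassPattern] = []
    for subset, label in label_map.items():
        chars = list(ref_window)
        edited = []
        for i in subset:
            s = ordered[i]
            j = win_positions.index(s.position)
            chars[j] = "T" if s.edited_strand == "+" else "A"
            edited.append(s.position)
        patterns.append(ClassPattern(label, "".join(chars), window, tuple(sorted(edited))))
    seqs = [p.sequence for p in patterns]
    if len(set(seqs)) != len(seqs):
        raise ConfigError("patterns are not pairwise distinct")
    return patterns


def _read_iter(reads):
    for r in reads:
        if isinstance(r, AlignedRead):
            yield r.read_id, r.sequence
        elif isinstance(r, tuple):
            yield r[0], r[1]
        else:  # simulate.SimRead or anything with read_id/sequence
            yield r.read_id, r.sequence


def classify_reads(reads, patterns: list[ClassPattern]) -> list[ReadClassCall]:
    """Label each read by the unique pattern it contains as an exact substring.

    Both the read and its reverse complement are searched.  Patterns differ
    within one window, so a read cannot match two of them there; a read that
    matches none (or, pathologically, more than one elsewhere) is
    "unclassified".
    """
    calls: list[ReadClassCall] = []
    for read_id, seq in _read_iter(reads):
        seq = seq.upper()
        rc = reverse_complement(seq)
        matches: list[tuple[str, int]] = []
        for p in patterns:
            off = seq.find(p.sequence)
            if off < 0:
                off = rc.find(p.sequence)
            if off >= 0:
                matches.append((p.label, off))
        if len(matches) == 1:
            calls.append(ReadClassCall(read_id, matches[0][0], matches[0][1]))
        else:
            calls.append(ReadClassCall(read_id, "unclassified"))
    return calls


@dataclass
class OutcomeDistribution:
    counts: dict[str, int]  # per label, including WT and unclassified
    fractions: dict[str, float] | None  # among edited reads only
    n_edited: int

    @property
    def defined(self) -> bool:
        return self.fractions is not None


def outcome_distribution(
    calls: list[ReadClassCall],
    edited_labels: tuple[str, ...] = EDITED_LABELS,
) -> OutcomeDistribution:
    """Distribution of edit combinations among reads carrying at least one edit.

    The denominator is the number of reads with an edited label (WT and
    unclassified reads are excluded); with zero edited reads the
    distribution is undefined rather than zero.
    """
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.label] = counts.get(c.label, 0) + 1
    n_edited = sum(counts.get(l, 0) for l in edited_labels)
    if n_edited == 0:
        return OutcomeDistribution(counts, None, 0)
    fractions = {l: counts.get(l, 0) / n_edited for l in edited_labels}
    return OutcomeDistribution(counts, fractions, n_edited)


def calls_to_tsv(calls: list[ReadClassCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlabel\n")
        for c in calls:
            fh.write(f"{c.read_id}\t{c.label}\n")
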