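"""Synthetic amplicon FASTQ generator with a machine-readable truth file.

Emulates deep amplicon sequencing of a base-edited mitochondrial genome:

* each sequenced molecule carries one of the co-editing haplotypes
  (both target cytosines edited / only one / neither), drawn from a
  configurable joint distribution — this is what makes the two adjacent
  target edits *linked* within reads, as they are on real molecules;
* low-frequency background C:G->T:A substitutions are injected independently
  at non-target C·G sites (natural heteroplasmy / deaminase off-targets),
  strand-consistently: a minus-strand C->T is observed as G->A on the plus
  strand;
* uniform per-base substitution sequencing error with flat Phred qualities.

Draw order per read is fixed (start position -> haplotype -> off-target
flips -> errors) from a single seeded generator, so a given seed yields
byte-identical FASTQ and truth files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .design import EditSite
from .errors import ConfigError
from .reference import GenomicInterval, MitoGenome, fetch, reverse_complement

CANONICAL_HAPLOTYPES = ("G40K", "G40E", "G40*", "WT")


@dataclass
class SimConfig:
    """Study conditions for one simulated amplicon library.

    ``haplotype_probs`` maps labels to probabilities; ``haplotype_edits``
    maps each label to the target positions edited on molecules of that
    class.  For the canonical two-site case the default mapping is
    G40K={both}, G40E={second site}, G40*={first site}, WT={} with sites in
    spacer order.  ``offtarget_rate`` is the per-site per-read probability of
    a background C->T (edited-strand sense) at non-target C·G sites;
    ``error_rate`` the per-base uniform substitution error probability.
    """

    reference: MitoGenome
    amplicon: GenomicInterval
    target_sites: list[EditSite]
    haplotype_probs: dict[str, float]
    n_reads: int
    read_length: int | None = None  # None => full-amplicon reads
    paired: bool = False
    offtarget_rate: float = 0.0
    error_rate: float = 0.001
    base_quality: int = 30
    seed: int = 0
    haplotype_edits: dict[str, tuple[int, ...]] | None = None
    # relaxed when the config is a template for a multi-amplicon tiling run
    check_targets_in_amplicon: bool = True

    def __post_init__(self) -> None:
        total = sum(self.haplotype_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"haplotype probabilities sum to {total}, not 1")
        for r in (self.offtarget_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"rate {r} outside [0, 1]")
        if self.n_reads <= 0:
            raise ConfigError("n_reads must be positive")
        L = self.reference.length
        amp_len = self.amplicon.length(L)
        if self.read_length is None:
            self.read_length = amp_len
        if self.read_length > amp_len:
            raise ConfigError(
                f"read_length {self.read_length} exceeds amplicon length {amp_len}"
            )
        if self.check_targets_in_amplicon:
            amp_positions = set(self.amplicon.positions(L))
            for s in self.target_sites:
                if s.position not in amp_positions:
                    raise ConfigError(
                        f"target site at position {s.position} outside the amplicon"
                    )
        if self.haplotype_edits is None:
            self.haplotype_edits = default_haplotype_edits(self.target_sites)
        unknown = set(self.haplotype_probs) - set(self.haplotype_edits)
        if unknown:
            raise ConfigError(f"haplotypes without an edit mapping: {sorted(unknown)}")


def default_haplotype_edits(sites: list[EditSite]) -> dict[str, tuple[int, ...]]:
    """Canonical label -> edited-positions map for a two-site target."""
    if len(sites) != 2:
        raise ConfigError(
            "default haplotype labels require exactly two target sites; "
            "supply haplotype_edits explicitly for other designs"
        )
    first, second = sorted(sites, key=lambda s: s.spacer_index)
    return {
        "G40K": (first.position, second.position),
        "G40E": (second.position,),
        "G40*": (first.position,),
        "WT": (),
    }


@dataclass
class TruthRecord:
    read_id: str
    haplotype: str
    start: int  # 1-based plus-strand start of the read's span
    strand: str
    offtarget_positions: list[int] = field(default_factory=list)
    error_positions: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "read_id": self.read_id,
                "haplotype": self.haplotype,
                "start": self.start,
                "strand": self.strand,
                "offtarget_positions": self.offtarget_positions,
                "error_positions": self.error_positions,
            }
        )


@dataclass
class SimRead:
    read_id: str
    sequence: str  # as sequenced (minus-strand reads are reverse-complemented)
    quality: str
    truth: TruthRecord


def _edited_base(ref_base: str) -> str:
    # C->T on the strand carrying the C; a minus-strand C shows as plus G->A
    return "T" if ref_base == "C" else "A"


def _simulate_batch(
    cfg: SimConfig,
    rng: np.random.Generator,
    amplicon: GenomicInterval,
    n_reads: int,
    id_prefix: str,
) -> list[SimRead]:
    genome = cfg.reference
    L = genome.length
    amp_pos = amplicon.positions(L)  # plus-strand genomic position per amplicon offset
    amp_seq = fetch(genome, GenomicInterval(amplicon.start, amplicon.end, "+"))
    amp_len = len(amp_seq)
    rl = cfg.read_length
    target_positions = {s.position for s in cfg.target_sites}
    # offsets within the amplicon eligible for background flips
    cg_offsets = np.array(
        [
            j
            for j, b in enumerate(amp_seq)
            if b in "CG" and amp_pos[j] not in target_positions
        ],
        dtype=np.int64,
    )
    labels = list(cfg.haplotype_probs)
    probs = np.array([cfg.haplotype_probs[l] for l in labels])
    cum = np.cumsum(probs)
    edits_by_label = {
        l: [(p, _edited_base(genome.base(p))) for p in cfg.haplotype_edits[l]]
        for l in labels
    }
    qual_char = chr(cfg.base_quality + 33)
    span = 2 * rl if cfg.paired else rl
    if span > amp_len:
        raise ConfigError("paired fragments (2 x read_length) exceed the amplicon")
    reads: list[SimRead] = []
    for i in range(n_reads):
        offset = int(rng.integers(0, amp_len - span + 1)) if amp_len > span else 0
        label = labels[int(np.searchsorted(cum, rng.random(), side="right"))]
        frag = list(amp_seq[offset : offset + span])
        frag_pos = amp_pos[offset : offset + span]
        pos_to_off = {p: j for j, p in enumerate(frag_pos)}
        for p, b in edits_by_label[label]:
            j = pos_to_off.get(p)
            if j is not None:
                frag[j] = b
        # background C:G->T:A flips at non-target C·G sites in the span
        in_span = cg_offsets[(cg_offsets >= offset) & (cg_offsets < offset + span)]
        ot_positions: list[int] = []
        if cfg.offtarget_rate > 0 and in_span.size:
            hits = in_span[rng.random(in_span.size) < cfg.offtarget_rate]
            for j in hits:
                frag[j - offset] = _edited_base(amp_seq[j])
                ot_positions.append(amp_pos[j])
        # uniform substitution sequencing errors
        err_positions: list[int] = []
        if cfg.error_rate > 0:
            err = np.nonzero(rng.random(span) < cfg.error_rate)[0]
            for j in err:
                current = frag[j]
                choices = [b for b in "ACGT" if b != current]
                frag[j] = choices[int(rng.integers(0, 3))]
                err_positions.append(frag_pos[j])
        frag_seq = "".join(frag)
        qual = qual_char * rl
        if cfg.paired:
            rid = f"{id_prefix}{i:06d}"
            t1 = TruthRecord(rid + "/1", label, frag_pos[0], "+",
                             [p for p in ot_positions if p in set(frag_pos[:rl])],
                             [p for p in err_positions if p in set(frag_pos[:rl])])
            t2 = TruthRecord(rid + "/2", label, frag_pos[rl], "-",
                             [p for p in ot_positions if p in set(frag_pos[rl:])],
                             [p for p in err_positions if p in set(frag_pos[rl:])])
            reads.append(SimRead(t1.read_id, frag_seq[:rl], qual, t1))
            reads.append(SimRead(t2.read_id, reverse_complement(frag_seq[rl:]), qual, t2))
        else:
            rid = f"{id_prefix}{i:06d}"
            truth = TruthRecord(rid, label, frag_pos[0], "+", ot_positions, err_positions)
            reads.append(SimRead(rid, frag_seq, qual, truth))
    return reads


def simulate_reads(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[SimRead]:
    """In-memory simulation of one amplicon library (see module docstring)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return _simulate_batch(cfg, rng, cfg.amplicon, cfg.n_reads, "read_")


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.truth.to_json() + "\n")


def read_truth(path) -> dict[str, dict]:
    out = {}
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out[d["read_id"]] = d
    return out


def simulate_amplicon(cfg: SimConfig, fastq_path, truth_path) -> tuple[str, str]:
    """Simulate one amplicon library and write FASTQ (+33 qualities) + JSONL truth."""
    reads = simulate_reads(cfg)
    write_fastq(reads, fastq_path)
    write_truth(reads, truth_path)
    return str(fastq_path), str(truth_path)


def simulate_genomewide_reads(
    cfg: SimConfig,
    amplicons: list[GenomicInterval],
    region: GenomicInterval | None = None,
) -> list[SimRead]:
    """Tile the genome (or ``region``) with overlapping long amplicons.

    ``cfg.n_reads`` is the total library size, split across amplicons in
    proportion to their length; off-target injection applies at every
    non-target C·G site each amplicon covers.  Raises if the amplicons do
    not jointly cover the requested region.
    """
    L = cfg.reference.length
    covered: set[int] = set()
    for amp in amplicons:
        covered.update(amp.positions(L))
    if region is None:
        wanted = set(range(1, L + 1))
    else:
        wanted = set(region.positions(L))
    missing = wanted - covered
    if missing:
        raise ConfigError(
            f"amplicons leave {len(missing)} position(s) of the requested region uncovered "
            f"(first missing: {min(missing)})"
        )
    rng = np.random.default_rng(cfg.seed)
    lengths = np.array([a.length(L) for a in amplicons], dtype=float)
    alloc = np.floor(cfg.n_reads * lengths / lengths.sum()).astype(int)
    alloc[0] += cfg.n_reads - alloc.sum()
    all_reads: list[SimRead] = []
    for k, (amp, n) in enumerate(zip(amplicons, alloc)):
        amp_len = amp.length(L)
        sub = SimConfig(
            reference=cfg.reference,
            amplicon=amp,
            target_sites=[s for s in cfg.target_sites if amp.contains(s.position, L)],
            haplotype_probs=dict(cfg.haplotype_probs),
            n_reads=max(int(n), 1),
            read_length=min(cfg.read_length or amp_len, amp_len),
            paired=cfg.paired,
            offtarget_rate=cfg.offtarget_rate,
            error_rate=cfg.error_rate,
            base_quality=cfg.base_quality,
            seed=cfg.seed,
            haplotype_edits=cfg.haplotype_edits,
        )
        all_reads.extend(_simulate_batch(sub, rng, amp, sub.n_reads, f"amp{k}_read_"))
    return all_reads


def simulate_genomewide(
    cfg: SimConfig,
    amplicons: list[GenomicInterval],
    fastq_path,
    truth_path,
    region: GenomicInterval | None = None,
) -> tuple[str, str]:
    """File-writing wrapper around :func:`simulate_genomewide_reads`."""
    all_reads = simulate_genomewide_reads(cfg, amplicons, region)
    write_fastq(all_reads, fastq_path)
    write_truth(all_reads, truth_path)
    return str(fastq_path), str(truth_path)
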