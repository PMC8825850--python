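"""End-to-end orchestration: config, fixture generation, and the full run.

A run goes: reference -> (simulate | FASTQ | SAM) -> align -> pileup ->
per-site editing frequencies -> per-read haplotype classification ->
genome-wide off-target profile and summary -> JSON report.  Every stage
writes its artifact into the output directory, and the report echoes the
full effective configuration, so a run is reproducible from the report
alone.  Reports are byte-stable for a fixed config and seed.

``make_fixture`` builds a self-contained toy study: a 2-kb circular genome
with one planted editing target laid out like a real DdCBE locus (16-bp TALE
windows flanking a 19-bp spacer with five TC-context cytosines at spacer
indices 6/12/13/17/18 and a GGA glycine codon at indices 12-14), plus
simulation configs for an active editor and two controls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .design import EditSite, TargetSpec, scan_tc_sites
from .errors import ConfigError
from .haplotypes import (
    build_patterns,
    calls_to_tsv,
    classify_reads,
    outcome_distribution,
)
from .offtarget import genomewide_profile, mean_offtarget_frequency
from .quantify import (
    align_reads,
    build_pileup,
    editing_profile,
    ingest_sam,
    read_fastq,
    write_sam,
)
from .reference import GenomicInterval, MitoGenome, load_fasta, reverse_complement, write_fasta
from .simulate import (
    SimConfig,
    simulate_genomewide_reads,
    simulate_reads,
    write_fastq,
    write_truth,
)

logger = logging.getLogger("mitocbe")

DEFAULT_THRESHOLDS = {
    "min_base_quality": 30,
    "min_mapping_quality": 30,
    "min_depth": 100,
    "max_mismatch_frac": 0.1,
    "seed_k": 20,
}

# Study-condition defaults for the packaged toy fixture.  The active library
# mirrors a mid-efficiency editor: 35% of molecules edited, split
# 0.53/0.455/0.015 between the double-edit, second-site-only and
# first-site-only classes, over a background substitution rate of 3e-4 per
# C·G site; the controls carry background only.  The active background is
# 7x the control background, the contrast seen between long-exposure active
# samples and vehicle/inactive controls.
FIXTURE_EDITED_FRACTION = 0.35
FIXTURE_EDITED_SPLIT = {"G40K": 0.53, "G40E": 0.455, "G40*": 0.015}
FIXTURE_BACKGROUND_RATE = 3e-4
FIXTURE_ACTIVE_OFFTARGET_RATE = 7 * FIXTURE_BACKGROUND_RATE
FIXTURE_ERROR_RATE = 0.001
FIXTURE_N_READS = 20_000

_FIXTURE_SPACER = "TATTAGATATTGGATTGGA"  # 19 bp; minus-strand TC sites at 6/12/13/17/18


@dataclass
class PipelineConfig:
    reference: str
    target_spec: str
    output_dir: str
    circular: bool = True
    reads: str | None = None  # FASTQ input
    sam: str | None = None  # pre-aligned input
    simulate: str | None = None  # SimConfig YAML
    group: str = "sample"
    seed: int = 0
    flank: int = 4
    mask: list[int] = field(default_factory=list)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        th = dict(DEFAULT_THRESHOLDS)
        th.update(self.thresholds or {})
        self.thresholds = th
        for k, v in th.items():
            if v < 0:
                raise ConfigError(f"threshold {k} must be non-negative, got {v}")
        if sum(x is not None for x in (self.reads, self.sam, self.simulate)) != 1:
            raise ConfigError(
                "exactly one of 'reads', 'sam' or 'simulate' must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: not a mapping")
        for required in ("reference", "target_spec", "output_dir"):
            if required not in raw:
                raise ConfigError(f"{path}: missing required field '{required}'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown fields {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**raw)
        # paths are relative to the config file
        for attr in ("reference", "target_spec", "reads", "sam", "simulate"):
            v = getattr(cfg, attr)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, attr, str(base / v))
        if not Path(cfg.output_dir).is_absolute():
            cfg.output_dir = str(base / cfg.output_dir)
        return cfg

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "target_spec": self.target_spec,
            "output_dir": self.output_dir,
            "circular": self.circular,
            "reads": self.reads,
            "sam": self.sam,
            "simulate": self.simulate,
            "group": self.group,
            "seed": self.seed,
            "flank": self.flank,
            "mask": list(self.mask),
            "thresholds": dict(self.thresholds),
        }


def load_sim_config(
    path, genome: MitoGenome, target_sites: list[EditSite], seed: int | None = None
) -> tuple[SimConfig, list[GenomicInterval] | None]:
    """Read a SimConfig YAML.

    Returns ``(config, None)`` for a single-amplicon library, or
    ``(config, amplicons)`` when the YAML lists several ``amplicons`` tiling
    the genome (the long-amplicon off-target design).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for required in ("n_reads", "haplotype_probs"):
        if required not in raw:
            raise ConfigError(f"{path}: missing required field '{required}'")
    if "amplicons" in raw:
        amplicons = [GenomicInterval(a["start"], a["end"]) for a in raw["amplicons"]]
        amp = raw["amplicons"][0]
    elif "amplicon" in raw:
        amplicons = None
        amp = raw["amplicon"]
    else:
        raise ConfigError(f"{path}: missing 'amplicon' or 'amplicons'")
    cfg = SimConfig(
        reference=genome,
        amplicon=GenomicInterval(amp["start"], amp["end"]),
        target_sites=target_sites,
        haplotype_probs={str(k): float(v) for k, v in raw["haplotype_probs"].items()},
        n_reads=int(raw["n_reads"]),
        read_length=raw.get("read_length"),
        paired=bool(raw.get("paired", False)),
        offtarget_rate=float(raw.get("offtarget_rate", 0.0)),
        error_rate=float(raw.get("error_rate", FIXTURE_ERROR_RATE)),
        base_quality=int(raw.get("base_quality", 30)),
        seed=int(raw["seed"] if seed is None else seed),
        check_targets_in_amplicon=amplicons is None,
    )
    return cfg, amplicons


@dataclass
class RunReport:
    config: dict
    version: str
    read_accounting: dict
    site_frequencies: list[dict]
    outcome_distribution: dict
    offtarget_summary: dict
    artifacts: dict

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "read_accounting": self.read_accounting,
            "site_frequencies": self.site_frequencies,
            "outcome_distribution": self.outcome_distribution,
            "offtarget_summary": self.offtarget_summary,
            "artifacts": self.artifacts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all intermediate artifacts + report.json."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    logger.info(
        "thresholds: base quality >= %d, mapping quality >= %d, min depth %d, "
        "seed k = %d, max mismatch fraction %.3f",
        th["min_base_quality"], th["min_mapping_quality"], th["min_depth"],
        th["seed_k"], th["max_mismatch_frac"],
    )
    for label, p in (("reference", config.reference), ("target_spec", config.target_spec)):
        if not Path(p).exists():
            raise ConfigError(f"config field '{label}': no such file: {p}")
    genome = load_fasta(config.reference, circular=config.circular)
    spec = TargetSpec.from_yaml(config.target_spec)
    artifacts: dict[str, str] = {}

    # --- obtain reads -----------------------------------------------------
    if config.simulate is not None:
        if not Path(config.simulate).exists():
            raise ConfigError(f"config field 'simulate': no such file: {config.simulate}")
        sim_cfg, amplicons = load_sim_config(config.simulate, genome, spec.primary_sites(),
                                             seed=config.seed)
        if amplicons is None:
            sim_reads = simulate_reads(sim_cfg)
        else:
            sim_reads = simulate_genomewide_reads(sim_cfg, amplicons)
        fastq = outdir / "reads.fastq"
        truth = outdir / "truth.jsonl"
        write_fastq(sim_reads, fastq)
        write_truth(sim_reads, truth)
        artifacts["fastq"] = str(fastq)
        artifacts["truth"] = str(truth)
        raw_reads = [(r.read_id, r.sequence, np.full(len(r.sequence), sim_cfg.base_quality))
                     for r in sim_reads]
    elif config.reads is not None:
        if not Path(config.reads).exists():
            raise ConfigError(f"config field 'reads': no such file: {config.reads}")
        raw_reads = read_fastq(config.reads)
        artifacts["fastq"] = str(config.reads)
    else:
        raw_reads = None

    # --- align ------------------------------------------------------------
    if config.sam is not None:
        if not Path(config.sam).exists():
            raise ConfigError(f"config field 'sam': no such file: {config.sam}")
        result = ingest_sam(config.sam, genome)
        artifacts["sam"] = str(config.sam)
        raw_reads = [(a.read_id, a.sequence, a.qualities) for a in result.alignments]
    else:
        result = align_reads(genome, raw_reads, k=th["seed_k"],
                             max_mismatch_frac=th["max_mismatch_frac"])
        sam = outdir / "aligned.sam"
        write_sam(sam, genome, result)
        artifacts["sam"] = str(sam)

    # --- pileup and per-site editing frequencies --------------------------
    pileup = build_pileup(genome, result, th["min_base_quality"], th["min_mapping_quality"])
    pileup_tsv = outdir / "pileup.tsv"
    pileup.to_tsv(pileup_tsv, genome)
    artifacts["pileup"] = str(pileup_tsv)
    entries = editing_profile(pileup, spec.sites)
    site_rows = [
        {
            "spacer_index": e.site.spacer_index,
            "position": e.site.position,
            "edited_strand": e.site.edited_strand,
            "frequency": e.frequency,
            "numerator": e.numerator,
            "denominator": e.denominator,
        }
        for e in entries
    ]

    # --- per-read haplotype classification (on raw reads) ------------------
    patterns = build_patterns(genome, spec.primary_sites(), flank=config.flank)
    calls = classify_reads([(rid, seq) for rid, seq, _ in raw_reads], patterns)
    calls_tsv = outdir / "calls.tsv"
    calls_to_tsv(calls, calls_tsv)
    artifacts["calls"] = str(calls_tsv)
    dist = outcome_distribution(calls)
    n_unclassified = dist.counts.get("unclassified", 0)

    # --- genome-wide off-target -------------------------------------------
    target_positions = {s.position for s in spec.sites}
    profile = genomewide_profile(
        pileup, genome, min_depth=th["min_depth"],
        mask_positions=target_positions | set(config.mask),
    )
    profile_tsv = outdir / "snv_profile.tsv"
    profile.to_tsv(profile_tsv)
    artifacts["snv_profile"] = str(profile_tsv)
    summary = mean_offtarget_frequency(profile, genome, target_positions, group=config.group)

    report = RunReport(
        config=config.to_dict(),
        version=__version__,
        read_accounting={
            "total": result.n_total,
            "aligned": result.n_aligned,
            "unaligned": result.n_unaligned,
            "skipped_indel": result.n_skipped_indel,
            "classified": len(calls) - n_unclassified,
            "unclassified": n_unclassified,
        },
        site_frequencies=site_rows,
        outcome_distribution={
            "counts": dist.counts,
            "fractions": dist.fractions,
            "n_edited": dist.n_edited,
        },
        offtarget_summary={
            "mean_frequency": summary.mean_frequency,
            "mean_percent": summary.mean_percent,
            "numerator_sum": summary.numerator_sum,
            "denominator_cg_sites": summary.denominator,
            "n_sites_used": summary.n_sites_used,
            "group": summary.group,
        },
        artifacts=artifacts,
    )
    report.to_json(outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# Toy fixture
# ---------------------------------------------------------------------------


def _fixture_genome(seed: int, length: int = 2000) -> tuple[MitoGenome, TargetSpec]:
    """Random circular genome with one planted DdCBE target locus.

    Layout (1-based): TALE-L window 901-916, spacer 917-935 (19 bp),
    TALE-H window 936-951.  The spacer carries minus-strand TC-context
    cytosines at spacer indices 6, 12, 13, 17, 18 and the GGA codon at
    indices 12-14, so editing indices 12+13 / 13 / 12 produces the
    G40K / G40E / G40* amino-acid outcomes.  Regenerates with shifted seeds
    until the four 10-nt classification windows are unique genome-wide.
    """
    tale_l = GenomicInterval(901, 916)
    spacer = GenomicInterval(917, 935)
    tale_h = GenomicInterval(936, 951)
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        bases = rng.choice(list("ACGT"), size=length)
        seq = "".join(bases)
        seq = seq[: spacer.start - 1] + _FIXTURE_SPACER + seq[spacer.end :]
        genome = MitoGenome("toy_mito", seq, circular=True)
        sites = scan_tc_sites(genome, spacer)
        if [s.spacer_index for s in sites] != [6, 12, 13, 17, 18]:
            continue
        primary = [s for s in sites if s.spacer_index in (12, 13)]
        try:
            patterns = build_patterns(genome, primary, flank=4)
        except ConfigError:
            continue
        doubled = seq + seq
        rc_doubled = reverse_complement(doubled)
        ok = True
        for p in patterns:
            n_occ = doubled.count(p.sequence) + rc_doubled.count(p.sequence)
            expected = 2 if p.label == "WT" else 0  # doubled genome sees it twice
            if n_occ != expected:
                ok = False
                break
        if not ok:
            continue
        spec = TargetSpec(
            genome_name=genome.name,
            tale_L_window=tale_l,
            tale_H_window=tale_h,
            spacer=spacer,
            sites=sites,
            codon_start=spacer.start + 11,  # spacer index 12
            mrna_strand="+",
            aa_number=40,
            primary_site_indices=(
                [s.spacer_index for s in sites].index(12),
                [s.spacer_index for s in sites].index(13),
            ),
        )
        return genome, spec
    raise RuntimeError("could not generate a collision-free fixture genome")


def make_fixture(outdir, seed: int = 0) -> dict[str, str]:
    """Write the toy study into ``outdir``: genome, target spec, sim configs.

    Three simulation configs are produced: ``active`` (edited molecules plus
    elevated background), and ``inactive``/``vehicle`` controls (wild type
    with background substitutions only).  Regeneration with the same seed is
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, spec = _fixture_genome(seed)
    paths: dict[str, str] = {}
    fasta = outdir / "genome.fa"
    write_fasta(fasta, genome)
    paths["genome"] = str(fasta)
    target_yaml = outdir / "target.yaml"
    spec.to_yaml(target_yaml)
    paths["target_spec"] = str(target_yaml)
    spec.to_bed(outdir / "target.bed")
    paths["target_bed"] = str(outdir / "target.bed")

    amplicon = {"start": 801, "end": 1040}  # 240 bp spanning the whole locus
    e = FIXTURE_EDITED_FRACTION
    active_probs = {
        label: round(e * frac, 12) for label, frac in FIXTURE_EDITED_SPLIT.items()
    }
    active_probs["WT"] = round(1.0 - sum(active_probs.values()), 12)
    sims = {
        "active": {
            "amplicon": amplicon,
            "n_reads": FIXTURE_N_READS,
            "haplotype_probs": active_probs,
            "offtarget_rate": FIXTURE_ACTIVE_OFFTARGET_RATE,
            "error_rate": FIXTURE_ERROR_RATE,
            "base_quality": 30,
            "seed": seed,
        },
        "inactive": {
            "amplicon": amplicon,
            "n_reads": FIXTURE_N_READS,
            "haplotype_probs": {"WT": 1.0},
            "offtarget_rate": FIXTURE_BACKGROUND_RATE,
            "error_rate": FIXTURE_ERROR_RATE,
            "base_quality": 30,
            "seed": seed + 1,
        },
        "vehicle": {
            "amplicon": amplicon,
            "n_reads": FIXTURE_N_READS,
            "haplotype_probs": {"WT": 1.0},
            "offtarget_rate": FIXTURE_BACKGROUND_RATE,
            "error_rate": FIXTURE_ERROR_RATE,
            "base_quality": 30,
            "seed": seed + 2,
        },
    }
    for name, sim in sims.items():
        sim_path = outdir / f"sim_{name}.yaml"
        with open(sim_path, "w") as fh:
            yaml.safe_dump(sim, fh, sort_keys=False)
        paths[f"sim_{name}"] = str(sim_path)
        cfg_path = outdir / f"pipeline_{name}.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(
                {
                    "reference": "genome.fa",
                    "target_spec": "target.yaml",
                    "simulate": f"sim_{name}.yaml",
                    "output_dir": f"out_{name}",
                    "group": name,
                    "seed": sim["seed"],
                },
                fh,
                sort_keys=False,
            )
        paths[f"pipeline_{name}"] = str(cfg_path)
    return paths
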