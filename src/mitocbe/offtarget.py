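"""Genome-wide C:G->T:A off-target quantification and summary statistics.

The headline statistic is the mean off-target frequency: the sum of C->T and
G->A frequencies over non-target C·G sites, divided by the genome's total
C·G site count.  Per the printed formula the denominator is the *total* C·G
count even though on-target (and masked) sites are excluded from the
numerator; both choices are exposed as flags.  Sequencing-error background
is deliberately not subtracted per site — vehicle/catalytically-inactive
control libraries are compared at the summary level instead, which is how
DdCBE-induced variants are distinguished from natural background
heteroplasmy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .quantify import PileupTable, align_reads, build_pileup
from .reference import MitoGenome

_OFF_BASE = {"C": "T", "G": "A"}


@dataclass
class SnvProfile:
    """Per-C·G-site off-base frequencies over a reference."""

    genome_name: str
    positions: np.ndarray  # 1-based positions of C/G sites
    ref_bases: np.ndarray  # 'C' or 'G' per site
    numerators: np.ndarray  # off-base count (T at C sites, A at G sites)
    depths: np.ndarray  # filtered depth per site
    masked: np.ndarray  # bool; True = excluded (on-target, low depth, user mask)
    min_depth: int

    @property
    def frequencies(self) -> np.ndarray:
        """Off-base frequency per site; NaN where masked or depth is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.numerators / self.depths.astype(float)
        f[self.masked | (self.depths == 0)] = np.nan
        return f

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "ref": self.ref_bases,
                "off_base": [_OFF_BASE[b] for b in self.ref_bases],
                "numerator": self.numerators,
                "depth": self.depths,
                "frequency": self.frequencies,
                "masked": self.masked,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def genomewide_profile(
    pileup: PileupTable,
    genome: MitoGenome,
    min_depth: int = 100,
    mask_positions: set[int] | None = None,
) -> SnvProfile:
    """Off-base frequency at every C·G site of the reference.

    At a C position the off-base is T; at a G position it is A (the plus-
    strand reading of a minus-strand C->T).  Sites in ``mask_positions``,
    N-containing positions, and sites below ``min_depth`` filtered coverage
    are masked.
    """
    mask_positions = mask_positions or set()
    pos, ref, num, dep, masked = [], [], [], [], []
    for p, b in enumerate(genome.sequence, start=1):
        if b not in "CG":
            continue
        d = pileup.depth(p)
        pos.append(p)
        ref.append(b)
        num.append(pileup.base_count(p, _OFF_BASE[b]))
        dep.append(d)
        masked.append(p in mask_positions or d < min_depth)
    return SnvProfile(
        genome.name,
        np.array(pos, dtype=np.int64),
        np.array(ref),
        np.array(num, dtype=np.int64),
        np.array(dep, dtype=np.int64),
        np.array(masked, dtype=bool),
        min_depth,
    )


@dataclass
class OffTargetSummary:
    mean_frequency: float  # fraction
    numerator_sum: float  # sum of unmasked off-target per-site frequencies
    denominator: int  # total C·G sites in the genome
    n_sites_used: int
    group: str = ""

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean_frequency


def mean_offtarget_frequency(
    profile: SnvProfile,
    genome: MitoGenome,
    on_target_positions: set[int] | None = None,
    group: str = "",
    exclude_targets_from_numerator: bool = True,
    denominator_mode: str = "total",
) -> OffTargetSummary:
    """Sum of off-target C->T / G->A frequencies over the total C·G site count.

    ``on_target_positions`` (the editor's intended sites) are excluded from
    the numerator by default; masked/undefined sites contribute nothing.
    ``denominator_mode`` is ``"total"`` (every C·G site in the genome, as the
    formula is printed) or ``"unmasked"`` (only sites that could contribute).
    """
    if genome.length == 0:
        raise DataError("empty genome")
    on_target = on_target_positions or set()
    freqs = profile.frequencies
    use = ~np.isnan(freqs)
    if exclude_targets_from_numerator and on_target:
        use &= ~np.isin(profile.positions, sorted(on_target))
    numerator = float(np.nansum(freqs[use])) if use.any() else 0.0
    from .reference import count_cg_sites

    if denominator_mode == "total":
        denominator = count_cg_sites(genome)
    elif denominator_mode == "unmasked":
        denominator = int(use.sum())
    else:
        raise ConfigError(f"unknown denominator_mode {denominator_mode!r}")
    if denominator == 0:
        raise DataError("genome has no C·G sites")
    return OffTargetSummary(
        mean_frequency=numerator / denominator,
        numerator_sum=numerator,
        denominator=denominator,
        n_sites_used=int(use.sum()),
        group=group,
    )


@dataclass
class ControlComparison:
    fold_change: float  # may be math.inf when controls are all zero
    active_mean: float
    control_means: list[float]
    groups: list[str] = field(default_factory=list)

    @property
    def infinite(self) -> bool:
        return math.isinf(self.fold_change)


def compare_to_controls(
    active: OffTargetSummary, controls: list[OffTargetSummary]
) -> ControlComparison:
    """Fold change of the active sample's mean over the mean of control means."""
    if not controls:
        raise ConfigError("at least one control summary is required")
    control_means = [c.mean_frequency for c in controls]
    denom = float(np.mean(control_means))
    fold = math.inf if denom == 0 else active.mean_frequency / denom
    return ControlComparison(
        fold_change=fold,
        active_mean=active.mean_frequency,
        control_means=control_means,
        groups=[active.group] + [c.group for c in controls],
    )


@dataclass
class CorrelationResult:
    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None

    @property
    def defined(self) -> bool:
        return self.pearson_r is not None


def ontarget_offtarget_correlation(
    samples: list[tuple[float, float]],
) -> CorrelationResult:
    """Pearson and Spearman correlation between on-target editing and mean
    off-target frequency across samples (both reported; neither is canonical)."""
    if len(samples) < 3:
        raise ConfigError("need at least 3 samples for a correlation")
    x = np.array([s[0] for s in samples], dtype=float)
    y = np.array([s[1] for s in samples], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(None, None, None, None)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(float(pr.statistic), float(pr.pvalue),
                             float(sr.statistic), float(sr.pvalue))


@dataclass
class NumtSiteCall:
    position: int
    frequency: float | None
    depth: int
    above_background: bool


def numt_check(
    region: MitoGenome,
    reads,
    homologous_sites: list,
    background_mean: float,
    background_sd: float,
    min_base_quality: int = 30,
    min_mapping_quality: int = 30,
    k: int = 20,
) -> list[NumtSiteCall]:
    """Editing check at a nuclear mitochondrial pseudogene (NUMT).

    ``region`` is the nuclear homology region as its own *linear* reference
    and ``reads`` an amplicon library specific to it.  Each homologous site
    (an :class:`~mitocbe.design.EditSite`-like object with ``position`` and
    ``edited_strand``) is quantified with the same pileup machinery and
    flagged ``above_background`` iff its frequency exceeds
    ``background_mean + 3 * background_sd`` from control libraries.
    """
    from .quantify import site_editing_frequency

    for s in homologous_sites:
        if not 1 <= s.position <= region.length:
            raise DataError(f"homologous site {s.position} outside the NUMT region")
    result = align_reads(region, reads, k=k)
    pileup = build_pileup(region, result, min_base_quality, min_mapping_quality)
    threshold = background_mean + 3.0 * background_sd
    calls = []
    for s in homologous_sites:
        e = site_editing_frequency(pileup, s)
        calls.append(
            NumtSiteCall(
                position=s.position,
                frequency=e.frequency,
                depth=e.denominator,
                above_background=(e.frequency is not None and e.frequency > threshold),
            )
        )
    return calls
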