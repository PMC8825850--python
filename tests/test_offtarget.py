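"""Genome-wide off-target statistics, control comparison, NUMT checks."""

import math

import numpy as np
import pytest

from mitocbe import (
    ConfigError,
    EditSite,
    GenomicInterval,
    MitoGenome,
    SimConfig,
    compare_to_controls,
    count_cg_sites,
    fetch,
    genomewide_profile,
    mean_offtarget_frequency,
    numt_check,
    ontarget_offtarget_correlation,
    site_editing_frequency,
)
from mitocbe.offtarget import OffTargetSummary, SnvProfile
from mitocbe.quantify import AlignedRead, build_pileup
from mitocbe.simulate import simulate_genomewide_reads

Q30 = lambda n: np.full(n, 30)


def _ref_reads(genome, start, length, n, mutate=None):
    out = []
    for i in range(n):
        seq = list(fetch(genome, GenomicInterval(start, (start + length - 2) % genome.length + 1)))
        if mutate:
            mutate(i, seq)
        out.append(AlignedRead(f"r{i}", start, "+", "".join(seq), Q30(length)))
    return out


def _profile_from(freq_by_pos, genome, min_depth=100, depth=1000):
    """Hand-built profile: every C·G site at the given depth."""
    pos, ref, num, dep, masked = [], [], [], [], []
    for p, b in enumerate(genome.sequence, start=1):
        if b not in "CG":
            continue
        f = freq_by_pos.get(p, 0.0)
        pos.append(p)
        ref.append(b)
        num.append(int(round(f * depth)))
        dep.append(depth)
        masked.append(False)
    return SnvProfile(genome.name, np.array(pos), np.array(ref), np.array(num),
                      np.array(dep), np.array(masked, dtype=bool), min_depth)


class TestGenomewideProfile:
    def test_all_reference_reads_give_zero_frequencies(self, fixture_genome):
        reads = _ref_reads(fixture_genome, 501, 100, 150)
        profile = genomewide_profile(build_pileup(fixture_genome, reads), fixture_genome)
        f = profile.frequencies
        assert np.nansum(f) == 0.0

    def test_direct_frequency_arithmetic(self, fixture_genome):
        pos = next(p for p in range(521, 600) if fixture_genome.base(p) == "C")
        off = pos - 501

        def mutate(i, seq):
            if i < 10:
                seq[off] = "T"

        reads = _ref_reads(fixture_genome, 501, 100, 1000, mutate)
        profile = genomewide_profile(build_pileup(fixture_genome, reads), fixture_genome)
        idx = int(np.where(profile.positions == pos)[0][0])
        assert profile.frequencies[idx] == pytest.approx(0.01)

    def test_low_depth_sites_are_masked(self, fixture_genome):
        reads = _ref_reads(fixture_genome, 501, 50, 20)  # depth 20 < 100
        profile = genomewide_profile(build_pileup(fixture_genome, reads), fixture_genome)
        assert profile.masked.all()

    def test_matches_naive_per_position_loop(self):
        rng = np.random.default_rng(12)
        g = MitoGenome("toy", "".join(rng.choice(list("ACGT"), size=500)), circular=True)
        reads = []
        for i in range(60):
            start = int(rng.integers(1, g.length))
            seq = list(fetch(g, GenomicInterval(start, (start + 98) % g.length + 1)))
            for j in rng.integers(0, 100, size=3):
                seq[j] = "ACGT"[rng.integers(0, 4)]
            reads.append(AlignedRead(f"r{i}", start, "+", "".join(seq), Q30(100)))
        pileup = build_pileup(g, reads)
        profile = genomewide_profile(pileup, g, min_depth=1)
        off_base = {"C": "T", "G": "A"}
        for idx, p in enumerate(profile.positions):
            b = g.base(int(p))
            num = den = 0
            for a in reads:
                j = (int(p) - a.ref_start) % g.length
                if j < len(a.sequence):
                    den += 1
                    if a.sequence[j] == off_base[b]:
                        num += 1
            if den == 0:
                assert np.isnan(profile.frequencies[idx])
            else:
                assert profile.numerators[idx] == num
                assert profile.depths[idx] == den


class TestMeanOfftargetFrequency:
    def test_printed_formula_arithmetic(self):
        rng = np.random.default_rng(1)
        # genome with exactly 100 C·G sites
        seq = "AC" * 100 + "AT" * 50
        g = MitoGenome("toy", seq, circular=True)
        assert count_cg_sites(g) == 100
        two_sites = {2: 0.01, 4: 0.01}
        profile = _profile_from(two_sites, g)
        summary = mean_offtarget_frequency(profile, g)
        assert summary.mean_frequency == pytest.approx(2e-4)
        assert summary.mean_percent == pytest.approx(0.02)

    def test_all_zero_profile_gives_zero(self):
        g = MitoGenome("toy", "ACGT" * 50, circular=True)
        summary = mean_offtarget_frequency(_profile_from({}, g), g)
        assert summary.mean_frequency == 0.0

    def test_linearity_in_per_site_frequencies(self):
        g = MitoGenome("toy", "ACGT" * 50, circular=True)
        freqs = {5 + 4 * i: 0.002 for i in range(10)}
        one = mean_offtarget_frequency(_profile_from(freqs, g), g)
        doubled = mean_offtarget_frequency(
            _profile_from({k: 2 * v for k, v in freqs.items()}, g), g
        )
        assert doubled.mean_frequency == pytest.approx(2 * one.mean_frequency)

    def test_masking_reduces_numerator_but_not_denominator(self):
        g = MitoGenome("toy", "ACGT" * 50, circular=True)
        freqs = {2: 0.01, 3: 0.01}
        full = mean_offtarget_frequency(_profile_from(freqs, g), g)
        masked = mean_offtarget_frequency(
            _profile_from(freqs, g), g, on_target_positions={2}
        )
        assert masked.numerator_sum < full.numerator_sum
        assert masked.denominator == full.denominator

    def test_simulated_background_recovers_planted_rate(
        self, fixture_genome, fixture_spec
    ):
        rate = 3e-4
        amps = [GenomicInterval(1, 1200), GenomicInterval(1001, 2000)]
        cfg = SimConfig(
            reference=fixture_genome,
            amplicon=amps[0],
            target_sites=fixture_spec.primary_sites(),
            haplotype_probs={"WT": 1.0},
            n_reads=20_000,
            read_length=200,
            offtarget_rate=rate,
            error_rate=0.0,
            seed=31,
            check_targets_in_amplicon=False,
        )
        reads = simulate_genomewide_reads(cfg, amps)
        pileup = build_pileup(
            fixture_genome,
            [AlignedRead(r.read_id, r.truth.start, "+", r.sequence, Q30(len(r.sequence)))
             for r in reads],
        )
        targets = {s.position for s in fixture_spec.sites}
        profile = genomewide_profile(pileup, fixture_genome, mask_positions=targets)
        summary = mean_offtarget_frequency(profile, fixture_genome, targets)
        n_unmasked = int((~np.isnan(profile.frequencies)).sum())
        expected = rate * n_unmasked / summary.denominator
        # CI: each unmasked site contributes Binomial(depth, rate)/depth
        depths = profile.depths[~profile.masked]
        var = (rate * (1 - rate) / depths).sum() / summary.denominator**2
        assert abs(summary.mean_frequency - expected) <= 4 * math.sqrt(var)


class TestCompareToControls:
    def test_sevenfold_example(self):
        active = OffTargetSummary(0.0028, 0, 100, 100, "active")
        controls = [OffTargetSummary(0.0003, 0, 100, 100, "vehicle"),
                    OffTargetSummary(0.0005, 0, 100, 100, "inactive")]
        cmp = compare_to_controls(active, controls)
        assert cmp.fold_change == pytest.approx(7.0)

    def test_equal_means_give_fold_one(self):
        s = OffTargetSummary(0.001, 0, 100, 100)
        assert compare_to_controls(s, [s]).fold_change == pytest.approx(1.0)

    def test_zero_control_mean_is_flagged_infinite(self):
        active = OffTargetSummary(0.001, 0, 100, 100)
        zero = OffTargetSummary(0.0, 0, 100, 100)
        cmp = compare_to_controls(active, [zero])
        assert cmp.infinite

    def test_requires_a_control(self):
        with pytest.raises(ConfigError):
            compare_to_controls(OffTargetSummary(0.001, 0, 100, 100), [])


class TestCorrelation:
    def test_perfectly_linear_data(self):
        res = ontarget_offtarget_correlation([(0.1, 0.001), (0.2, 0.002), (0.3, 0.003)])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_anti_monotone_data(self):
        res = ontarget_offtarget_correlation([(0.1, 0.009), (0.2, 0.004), (0.3, 0.001)])
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        res = ontarget_offtarget_correlation([(0.1, 0.001), (0.1, 0.002), (0.1, 0.003)])
        assert not res.defined

    def test_shared_intensity_factor_detected_in_most_replicates(self):
        # samples share a latent editing-intensity factor scaling both the
        # on-target fraction and the background rate; binomial sampling noise
        rng = np.random.default_rng(77)
        detected = 0
        n_replicates = 100
        for _ in range(n_replicates):
            samples = []
            for _ in range(6):
                lam = rng.uniform(0.5, 2.0)
                on = rng.binomial(5000, min(0.3 * lam, 1.0)) / 5000
                off = rng.binomial(200_000, 1e-3 * lam) / 200_000
                samples.append((on, off))
            res = ontarget_offtarget_correlation(samples)
            if res.pearson_r > 0 and res.spearman_rho > 0:
                detected += 1
        assert detected >= 95


class TestNumtCheck:
    @pytest.fixture()
    def numt(self, fixture_genome):
        # nuclear homolog: the target locus embedded in a linear context
        seq = fetch(fixture_genome, GenomicInterval(850, 1000))
        return MitoGenome("numt_chr1", seq, circular=False)

    def _reads(self, numt, n, edit_offset=None, edit_fraction=0.0):
        out = []
        for i in range(n):
            seq = list(numt.sequence)
            if edit_offset is not None and i < edit_fraction * n:
                seq[edit_offset] = "A"
            out.append((f"r{i}", "".join(seq), Q30(len(seq))))
        return out

    def test_reference_reads_show_no_editing(self, numt, fixture_spec):
        sites = [EditSite(1, s.position - 849, s.edited_strand, True)
                 for s in fixture_spec.primary_sites()]
        calls = numt_check(numt, self._reads(numt, 200), sites,
                           background_mean=3e-4, background_sd=1e-4)
        assert all(c.frequency == 0.0 and not c.above_background for c in calls)

    def test_planted_editing_is_flagged(self, numt, fixture_spec):
        c12 = fixture_spec.primary_sites()[0]
        site = EditSite(1, c12.position - 849, c12.edited_strand, True)
        reads = self._reads(numt, 200, edit_offset=site.position - 1, edit_fraction=0.05)
        (call,) = numt_check(numt, reads, [site],
                             background_mean=3e-4, background_sd=1e-4)
        assert call.frequency == pytest.approx(0.05)
        assert call.above_background

    def test_empty_read_set_is_undefined(self, numt, fixture_spec):
        c12 = fixture_spec.primary_sites()[0]
        site = EditSite(1, c12.position - 849, c12.edited_strand, True)
        (call,) = numt_check(numt, [], [site], background_mean=3e-4, background_sd=1e-4)
        assert call.frequency is None and not call.above_background

    def test_site_outside_region_is_rejected(self, numt):
        from mitocbe import DataError

        with pytest.raises(DataError):
            numt_check(numt, [], [EditSite(1, 10_000, "-", True)],
                       background_mean=0.0, background_sd=0.0)
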