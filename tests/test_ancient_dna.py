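"""Damage profiling, quality rescaling, pileup calling and filtering."""

import math

import pytest

from paleovar import ancient_dna as ad
from paleovar.ancient_dna import (
    AlignedRead,
    AncientSample,
    DamageProfile,
    SupportingRead,
    VariantCall,
    chronology_summary,
    damage_filter,
    estimate_damage_profile,
    fit_damage_model,
    match_catalog,
    pileup_call,
    rescale_qualities,
)
from paleovar.synthetic_data import SimConfig, make_reference, simulate_ancient_reads
from paleovar.variant_catalog import VariantRecord


def fread(rid, pos, seq, qual=37, reverse=False):
    return AlignedRead(
        id=rid, chrom="ref1", pos=pos, reverse=reverse,
        sequence=seq, qualities=[qual] * len(seq),
    )


class TestDamageProfile:
    def test_undamaged_reads_have_zero_rates(self):
        reference = "ACGTACGTACGTACGTACGT"
        reads = [fread(f"r{i}", 1, reference) for i in range(5)]
        profile = estimate_damage_profile(reads, reference, max_offset=10)
        assert all(r == 0.0 for r in profile.ct5 if r is not None)
        assert all(r == 0.0 for r in profile.ga3 if r is not None)

    def test_offsets_without_opportunities_are_missing_not_zero(self):
        reference = "AATT" * 5  # no C anywhere
        reads = [fread("r0", 1, reference)]
        profile = estimate_damage_profile(reads, reference, max_offset=5)
        assert all(r is None for r in profile.ct5)

    def test_known_mismatch_counted_at_molecule_offset(self):
        # forward read: T over reference C at offset 0
        reference = "CCCCAAAA"
        reads = [fread("r0", 1, "TCCCAAAA")]
        profile = estimate_damage_profile(reads, reference, max_offset=3)
        assert profile.ct5[0] == 1.0
        assert profile.ct5[1] == 0.0

    def test_reverse_read_offsets_flip_to_molecule_coordinates(self):
        # reverse read: molecule 5' end = rightmost reference base.
        # Reference G at the right end reads as molecule C; a forward A
        # there is molecule T over C at molecule offset 0.
        reference = "TTTTG"
        reads = [fread("r0", 1, "TTTTA", reverse=True)]
        profile = estimate_damage_profile(reads, reference, max_offset=2)
        assert profile.ct5[0] == 1.0

    def test_no_usable_reads_raises(self):
        with pytest.raises(ValueError, match="usable"):
            estimate_damage_profile([], "ACGT")


class TestParameterRecovery:
    def test_d0_and_lambda_recovered_from_50k_reads(self, tmp_path):
        """50k simulated reads at d0=0.3, lambda=0.3: the profile at offset 0
        sits within 3 binomial SE of the planted rate (oracle: truth-set
        artifact counts over opportunities), and the fitted decay recovers
        lambda within 20%."""
        config = SimConfig(seed=3, ref_length=6000, coverage=500.0)
        reference = make_reference(config)
        sams, truth = simulate_ancient_reads(
            config, reference, carriers={}, sample_ids=["S1"]
        )
        sam_path = tmp_path / "S1.sam"
        sam_path.write_text(sams["S1"])
        reads = ad.read_sam(sam_path)
        assert len(reads) == 50_000
        profile = estimate_damage_profile(reads, reference)

        # oracle: rate from the simulator's own artifact log at offset 0
        ct0_truth = sum(
            1 for _, off, sub in truth.damage_artifacts["S1"]
            if sub == "C>T" and off == 0
        )
        n_opp = profile.ct5_opportunities[0]
        assert profile.ct5_counts[0] == ct0_truth  # estimator finds every artifact
        se = math.sqrt(0.3 * 0.7 / n_opp)
        assert abs(profile.ct5[0] - 0.3) <= 3 * se

        d0_hat, lam_hat = fit_damage_model(profile)
        assert abs(lam_hat - 0.3) / 0.3 <= 0.20
        assert abs(d0_hat - 0.3) <= 3 * se + 0.01

    def test_artifact_rate_nonincreasing_in_offset(self):
        """Damage monotonicity under binomial noise: no significant rate
        increase between successive offsets."""
        config = SimConfig(seed=4, ref_length=6000, coverage=200.0)
        reference = make_reference(config)
        _, truth = simulate_ancient_reads(config, reference, {}, sample_ids=["S1"])
        counts = [0] * 12
        for _, off, sub in truth.damage_artifacts["S1"]:
            if sub == "C>T" and off < 12:
                counts[off] += 1
        # opportunity count per offset ~ n_reads * P(C) is flat; compare
        # counts directly with 3-sigma Poisson slack
        for o in range(11):
            slack = 3 * math.sqrt(max(counts[o + 1], 1))
            assert counts[o] >= counts[o + 1] - slack


class TestRescaling:
    def test_zero_profile_is_identity(self):
        profile = DamageProfile(ct5=[0.0] * 5, ga3=[0.0] * 5)
        read = fread("r0", 1, "TCGA")
        out = rescale_qualities(read, profile, "CCGA")
        assert out.qualities == read.qualities

    def test_candidate_capped_at_phred_of_rate(self):
        """ct5[0] = 0.5 caps a T-over-C at offset 0 to -10*log10(0.5) = 3."""
        profile = DamageProfile(ct5=[0.5, 0.1], ga3=[0.0, 0.0])
        out = rescale_qualities(fread("r0", 1, "TA"), profile, "CA")
        assert out.qualities[0] == 3

    def test_non_candidate_bases_never_change(self):
        profile = DamageProfile(ct5=[0.9] * 4, ga3=[0.9] * 4)
        # G over reference C is not a deamination product
        out = rescale_qualities(fread("r0", 1, "GAAA"), profile, "CAAA")
        assert out.qualities == [37, 37, 37, 37]

    def test_reverse_read_candidates_use_molecule_orientation(self):
        """A forward A-over-G at the left end of a reverse-aligned read is
        a molecule T-over-C far from the molecule 5' end: the cap must use
        the ct5 rate at molecule offset 3, not offset 0."""
        profile = DamageProfile(ct5=[0.5, 0.4, 0.3, 0.2], ga3=[0.0] * 4)
        out = rescale_qualities(fread("r0", 1, "ATTT", reverse=True), profile, "GTTT")
        assert out.qualities[0] == 7  # round(-10*log10(0.2))


class TestPileup:
    def test_all_reference_reads_no_calls(self):
        reference = "ACGTACGT"
        reads = [fread(f"r{i}", 1, reference) for i in range(4)]
        assert pileup_call(reads, reference) == []

    def test_manual_pileup_depth_and_alt_count(self):
        """5 reads over a C site, 3 read T mid-read: C>T, depth 5, alt 3."""
        reference = "AACAA"
        reads = [fread(f"r{i}", 1, "AATAA") for i in range(3)]
        reads += [fread(f"r{i+3}", 1, "AACAA") for i in range(2)]
        (call,) = pileup_call(reads, reference)
        assert (call.pos, call.ref, call.alt) == (3, "C", "T")
        assert call.depth == 5
        assert call.alt_count == 3

    def test_quality_zero_excluded_at_min_bq_1(self):
        reference = "AACAA"
        good = fread("r0", 1, "AATAA")
        bad = fread("r1", 1, "AATAA", qual=0)
        calls = pileup_call([good, bad], reference, min_bq=1)
        (call,) = calls
        assert call.alt_count == 1  # the q0 base does not count
        assert call.depth == 1

    def test_allele_counts_sum_to_depth(self, sim, ancient_results):
        for calls, _ in ancient_results.values():
            for call in calls[:20]:
                assert call.alt_count <= call.depth

    def test_min_alt_monotonicity(self):
        reference = "AACAA"
        reads = [fread(f"r{i}", 1, "AATAA") for i in range(3)]
        n1 = len(pileup_call(reads, reference, min_alt=1))
        n4 = len(pileup_call(reads, reference, min_alt=4))
        assert n4 <= n1

    def test_duplicates_excluded(self):
        reference = "AACAA"
        dup = fread("r0", 1, "AATAA")
        dup.duplicate = True
        assert pileup_call([dup], reference) == []


class TestDamageFilter:
    def call_with(self, sub, supports):
        ref, alt = sub.split(">")
        return VariantCall(
            chrom="ref1", pos=10, ref=ref, alt=alt,
            depth=len(supports), alt_count=len(supports), support=supports,
        )

    def test_terminal_only_ct_call_excluded(self):
        """C>T supported only by reads with the site at their first bases
        is a deamination look-alike: DAMAGE."""
        sup = [
            SupportingRead("r0", offset5=0, offset3=40, reverse=False),
            SupportingRead("r1", offset5=1, offset3=39, reverse=False),
        ]
        call = damage_filter(self.call_with("C>T", sup))
        assert call.filter == "DAMAGE"

    def test_mixed_support_passes_with_reduced_count(self):
        sup = [
            SupportingRead("r0", offset5=0, offset3=40, reverse=False),
            SupportingRead("r1", offset5=20, offset3=20, reverse=False),
        ]
        call = damage_filter(self.call_with("C>T", sup))
        assert call.filter == "PASS"
        assert call.alt_count == 1

    def test_rule_scope_excludes_other_substitutions(self):
        sup = [SupportingRead("r0", offset5=0, offset3=40, reverse=False)]
        call = damage_filter(self.call_with("A>G", sup))
        assert call.filter == "PASS"
        assert call.alt_count == 1

    def test_ga_uses_three_prime_offsets(self):
        sup = [SupportingRead("r0", offset5=30, offset3=1, reverse=False)]
        assert damage_filter(self.call_with("G>A", sup)).filter == "DAMAGE"
        sup = [SupportingRead("r0", offset5=1, offset3=30, reverse=False)]
        assert damage_filter(self.call_with("G>A", sup)).filter == "PASS"

    def test_reverse_read_terminal_detection_is_molecule_relative(self):
        # reverse-aligned read supporting a forward C>T: the molecule shows
        # G>A, so the damage-relevant end is the molecule 3' (offset3)
        sup = [SupportingRead("r0", offset5=30, offset3=0, reverse=True)]
        assert damage_filter(self.call_with("C>T", sup)).filter == "DAMAGE"


class TestMatchCatalog:
    def pv(self, pos, ref, alt):
        return VariantRecord(
            gene="G1", chrom="ref1", pos=pos, ref=ref, alt=alt,
            hgvs_c=f"c.{pos}", clin_class="PV",
        )

    def passing_call(self, pos, ref, alt):
        return VariantCall(
            chrom="ref1", pos=pos, ref=ref, alt=alt, depth=5, alt_count=2
        )

    def test_exact_match_and_alt_mismatch(self):
        catalog = [self.pv(10, "C", "T")]
        hit = match_catalog([self.passing_call(10, "C", "T")], catalog)
        miss = match_catalog([self.passing_call(10, "C", "G")], catalog)
        assert len(hit["PV"]) == 1
        assert miss["PV"] == []

    def test_non_pass_calls_never_match(self):
        catalog = [self.pv(10, "C", "T")]
        call = self.passing_call(10, "C", "T")
        call.filter = "DAMAGE"
        assert match_catalog([call], catalog)["PV"] == []

    def test_checksum_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="checksum"):
            match_catalog([], [], reference="ACGT", expected_checksum="bogus")

    def test_planted_cohort_carriers_all_recovered(self, sim, ancient_results):
        """Every planted (sample, PV) pair is found by the full pipeline."""
        for sid, planted in sim.truth.carriers.items():
            found = set(ancient_results[sid][1]["PV"])
            assert set(planted) <= found, f"{sid} missing {set(planted) - found}"

    def test_alt_read_with_interior_site_exists_for_carriers(self, sim):
        """At 30x a planted mid-reference variant is supported by at least
        one read holding the site >2 bp from both ends (direct SAM check)."""
        sid, planted = next(
            (s, p) for s, p in sim.truth.carriers.items() if p
        )
        rec = next(r for r in sim.records if r.variant_id == planted[0])
        reads = ad.read_sam(sim.outdir / "samples" / f"{sid}.sam")
        interior = 0
        for read in reads:
            i = rec.pos - read.pos
            if 0 <= i < len(read) and read.sequence[i] == rec.alt:
                if min(read.offset5(i), read.offset3(i)) >= 2:
                    interior += 1
        assert interior >= 1


class TestChronology:
    def sample(self, sid, lo, hi, group="modern_human", region="Europe", pvs=("pv1",)):
        return AncientSample(
            id=sid, date_lo=lo, date_hi=hi, lat=50.0, lon=10.0,
            region=region, group=group, shared_pvs=list(pvs),
        )

    def test_midpoint_binning_fifty_percent(self):
        samples = [
            self.sample("a", 4000, 6000),  # midpoint 5000
            self.sample("b", 14000, 16000),  # midpoint 15000
        ]
        out = chronology_summary(samples)
        assert out["carrier_within_percent"] == 50.0

    def test_reported_fraction_119_of_121(self):
        """The headline ratio: 119 of 121 within the cutoff prints 98.3%."""
        samples = [
            self.sample(f"s{i}", 4000, 6000, pvs=(f"pv{i}",)) for i in range(119)
        ] + [
            self.sample(f"old{i}", 24000, 26000, pvs=(f"pv{200+i}",))
            for i in range(2)
        ]
        out = chronology_summary(samples)
        assert out["n_shared_pvs"] == 121
        assert out["pv_within_percent"] == 98.3

    def test_cutoff_tie_counts_within(self):
        out = chronology_summary([self.sample("a", 9000, 11000)])  # midpoint 10000
        assert out["carriers_within_cutoff"] == 1

    def test_archaic_samples_never_in_modern_time_bins(self):
        samples = [
            self.sample("n", 40000, 44000, group="neanderthal"),
            self.sample("m", 4000, 6000),
        ]
        out = chronology_summary(samples)
        assert out["n_sharing_modern"] == 1
        assert out["per_group"]["neanderthal"] == 1
        assert out["per_region"] == {"Europe": 1}

    def test_pv_dated_by_oldest_modern_carrier(self):
        samples = [
            self.sample("young", 2000, 2600, pvs=("pvX",)),
            self.sample("old", 30000, 36000, pvs=("pvX",)),
        ]
        out = chronology_summary(samples)
        assert out["pvs_within_cutoff"] == 0  # oldest carrier beyond cutoff
        assert out["carriers_within_cutoff"] == 1

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            AncientSample(id="x", date_lo=500, date_hi=100, lat=0, lon=0, region="r")
        with pytest.raises(ValueError):
            AncientSample(id="x", date_lo=1, date_hi=2, lat=99, lon=0, region="r")
        with pytest.raises(ValueError):
            AncientSample(
                id="x", date_lo=1, date_hi=2, lat=0, lon=0, region="r", group="alien"
            )
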