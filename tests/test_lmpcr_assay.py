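"""Restriction digestion, junction-primer design, assay and excision readouts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from temeth import (DPNI, PVUII, GenomeBuild, Feature, Linker,
                    MethylationTrajectory, default_dpni_design,
                    design_excision_primers, design_junction_primer,
                    detect_excision, digest_molecule, excised_locus_sequence,
                    find_sites, fold_change, fragments, sample_molecules,
                    sample_pool, simulate_assay, site_fraction)
from temeth.errors import SiteError, SpecificityError, UndefinedRatioError
from temeth.lmpcr_assay import LINKER_ARM_B, AssayReadout

TE = MethylationTrajectory.te_active()


class TestFindSites:
    def test_simple_site(self):
        assert find_sites("AAGATCTT", DPNI) == [2]

    def test_no_site(self):
        assert find_sites("AAAAAAA", DPNI) == []

    def test_overlapping_sites_found(self):
        assert find_sites("GATCAGCTGATC", DPNI) == [0, 8]
        assert find_sites("CAGCAGCTGCTG", PVUII) == [3]

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            find_sites("AANGATC", DPNI)

    def test_matches_naive_scan_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        for enz in (DPNI, PVUII):
            naive = [i for i in range(len(seq))
                     if seq[i:i + len(enz.recognition)] == enz.recognition]
            assert find_sites(seq, enz) == naive


class TestDigest:
    def test_methylated_site_cut_rule(self):
        cuts = digest_molecule("AAGATCAA", {2: True}, DPNI)
        assert cuts == [4]
        assert fragments("AAGATCAA", cuts) == ["AAGA", "TCAA"]

    def test_unmethylated_site_not_cut(self):
        assert digest_molecule("AAGATCAA", {2: False}, DPNI) == []
        assert fragments("AAGATCAA", []) == ["AAGATCAA"]

    def test_pvuii_cuts_unconditionally(self):
        assert digest_molecule("ACAGCTGA", None, PVUII) == [4]

    def test_two_methylated_sites_three_fragments(self):
        seq = "TTGATCTTTTGATCTT"
        cuts = digest_molecule(seq, {2: True, 10: True}, DPNI)
        assert len(fragments(seq, cuts)) == 3

    def test_mask_key_must_be_a_site(self):
        with pytest.raises(SiteError):
            digest_molecule("AAGATCAA", {0: True}, DPNI)

    @given(seq=st.text(alphabet="ACGT", min_size=0, max_size=200),
           mask_bits=st.lists(st.booleans(), min_size=0, max_size=60))
    @settings(derandomize=True, max_examples=120, deadline=None)
    def test_boundaries_match_exhaustive_rescan(self, seq, mask_bits):
        sites = [i for i in range(len(seq)) if seq[i:i + 4] == "GATC"]
        mask = {s: bit for s, bit in zip(sites, mask_bits)}
        cuts = digest_molecule(seq, mask, DPNI)
        expected = sorted(s + 2 for s in sites if mask.get(s, False))
        assert cuts == expected
        assert "".join(fragments(seq, cuts)) == seq


class TestJunctionPrimerDesign:
    def test_linker_primer_arm_constant(self):
        assert Linker().arm_b == "TATGAAACTCTCTTACCGTTAGGTCAGATCTA"

    def test_reconstructs_tc1_dpni_forward_primer(self, world):
        design = default_dpni_design(world, "Tc1-like")
        assert design.forward_primer.sequence == \
            "TCTTACCGTTAGGTCAGATCTATCC"
        assert design.forward_primer.linker_tail == LINKER_ARM_B[-22:]
        assert design.forward_primer.genomic_head == "TCC"

    def test_pvuii_control_head_is_ctg(self, world):
        design = default_dpni_design(world, "Tc1-like")
        assert design.control_forward.genomic_head == "CTG"
        assert design.control_forward.sequence == \
            "TGAAACTCTCTTACCGTTAGGTCAGATCTACTG"

    def test_te_targeted_primer_is_multicopy_hence_nonunique(self, world):
        design = default_dpni_design(world, "Tc1-like")
        assert not design.forward_primer.unique

    def test_zero_head_is_linker_only_and_nonspecific(self, world):
        design = default_dpni_design(world, "Tc1-like")
        primer = design_junction_primer(world, (design.chrom, design.site_start),
                                        DPNI, tail_len=22, head_len=0)
        assert primer.sequence == LINKER_ARM_B[-22:]
        assert not primer.unique

    def test_non_site_coordinate_rejected(self, world):
        chrom = next(iter(world.sequences))
        bad = world.sequences[chrom].find("GATC") + 1
        with pytest.raises(SiteError):
            design_junction_primer(world, (chrom, bad), DPNI)


class TestAssaySimulation:
    def test_no_methylation_zero_level(self, world):
        design = default_dpni_design(world, "Tc1-like")
        pool = sample_molecules(0.0, 10_000, seed=1)
        assert simulate_assay(pool, design).relative_level == 0.0

    def test_full_methylation_unit_level(self, world):
        design = default_dpni_design(world, "Tc1-like")
        pool = sample_molecules(1.0, 10_000, seed=1)
        assert simulate_assay(pool, design).relative_level == 1.0

    def test_linear_regime_recovers_methylated_fraction_exactly(self, world):
        design = default_dpni_design(world, "Tc1-like")
        pool = sample_molecules(0.165, 10_000, seed=7)
        readout = simulate_assay(pool, design)
        assert readout.relative_level == pool.methylated_fraction
        se = math.sqrt(0.165 * 0.835 / 10_000)
        assert abs(readout.relative_level - 0.165) < 3 * se

    def test_saturated_control_warns(self, world):
        from dataclasses import replace
        design = replace(default_dpni_design(world, "Tc1-like"), saturation=1e5)
        pool = sample_molecules(0.001, 10_000, seed=3)
        with pytest.warns(UserWarning, match="saturated"):
            simulate_assay(pool, design, cycles=5)

    def test_fold_change_identity_and_zero_guard(self):
        r = AssayReadout(5.0, 10.0)
        assert fold_change(r, r) == 1.0
        with pytest.raises(UndefinedRatioError):
            fold_change(r, AssayReadout(0.0, 10.0))

    def test_daf2_fold_matches_closed_form(self, world):
        # trajectory closed form: 1 + 10 * (0.45 / 2) = 3.25
        assert site_fraction(TE, 11, "daf-2") / site_fraction(TE, 1, "daf-2") \
            == pytest.approx(3.25, abs=1e-12)
        design = default_dpni_design(world, "Tc1-like")
        readouts = {day: simulate_assay(
            sample_pool(TE, day, "daf-2", 100_000, seed=40 + day), design)
            for day in (1, 11)}
        assert fold_change(readouts[11], readouts[1]) == pytest.approx(3.25, rel=0.05)

    def test_genotype_separation_flat_high_vs_near_zero(self, world):
        design = default_dpni_design(world, "Tc1-like")
        levels = {}
        for genotype in ("nmad-1", "damt-1"):
            for day in (1, 5):
                pool = sample_pool(TE, day, genotype, 50_000, seed=100 + day)
                levels[genotype, day] = simulate_assay(pool, design).relative_level
        # demethylase-null: constant high across days 1 and 5
        assert levels["nmad-1", 5] == pytest.approx(levels["nmad-1", 1], rel=0.1)
        assert levels["nmad-1", 1] > 0.1
        # methyltransferase-null: weak at day 1, near zero by day 5
        assert levels["damt-1", 1] < 0.02
        assert levels["damt-1", 5] < 0.005


class TestExcisionAssay:
    @pytest.fixture
    def toy_build(self, rng):
        # flanks are the only A/T-containing stretches outside the element,
        # so flank-derived primers cannot collide with the GC-only padding
        up = "ACGTTGCAGGTTACAT"
        down = "TTCCGGAACCTTGGAA"
        element = "".join(rng.choice(list("GC"), size=300))
        pad_l = "".join(rng.choice(list("GC"), size=60))
        pad_r = "".join(rng.choice(list("GC"), size=60))
        seq = pad_l + up + element + down + pad_r
        start = len(pad_l) + len(up)
        feat = Feature("el_1", "chrT", start, start + 300, "+", "te_copy", "toy")
        return GenomeBuild({"chrT": seq}, [feat], {}), feat

    def test_junction_primer_construction(self, toy_build):
        build, feat = toy_build
        design = design_excision_primers(build, feat, flank_len=8)
        assert design.junction_primer == "GGTTACAT" + "TTCCGGAA"
        assert design.upstream_flank == "GGTTACAT"
        assert design.downstream_flank == "TTCCGGAA"

    def test_junction_primer_absent_from_intact_genome(self, toy_build):
        build, feat = toy_build
        design = design_excision_primers(build, feat, flank_len=8)
        assert design.junction_primer not in build.sequences["chrT"]

    def test_junction_primer_unique_in_excised_molecule(self, toy_build):
        build, feat = toy_build
        design = design_excision_primers(build, feat, flank_len=8)
        excised = excised_locus_sequence(build, feat)
        assert excised.count(design.junction_primer) == 1

    def test_internal_control_only_in_intact_molecule(self, toy_build):
        build, feat = toy_build
        design = design_excision_primers(build, feat, flank_len=8)
        assert design.internal_forward in build.feature_sequence(feat)
        assert design.internal_forward not in excised_locus_sequence(build, feat)

    def test_repeated_flank_rejected(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=300))
        dup = "ACGTACGTACGTACGTACGT"
        seq = dup + core + dup + "TTGGCCAATTGGCCAA"
        feat = Feature("el", "chrT", len(dup), len(dup) + 300, "+", "te_copy")
        with pytest.raises(SpecificityError):
            design_excision_primers(GenomeBuild({"chrT": seq}, [feat], {}),
                                    feat, flank_len=20)

    def test_all_intact_pool_not_detected(self, toy_build):
        build, feat = toy_build
        design = design_excision_primers(build, feat, flank_len=8)
        pool = sample_molecules(0.03, 10_000, seed=1)
        assert detect_excision(pool, design) == (False, 0.0)

    def test_day1_undetectable_day14_detectable(self, toy_build):
        build, feat = toy_build
        design = design_excision_primers(build, feat, flank_len=8)
        day1 = sample_pool(TE, 1, "wildtype", 100_000, seed=8)
        day14 = sample_pool(TE, 14, "wildtype", 100_000, seed=9)
        detected1, est1 = detect_excision(day1, design)
        detected14, est14 = detect_excision(day14, design)
        assert not detected1
        assert detected14
        assert est14 > est1
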