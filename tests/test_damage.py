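"""Damage statistics, Welch comparison and variant authentication."""

import math

import pytest
from scipy import stats

import paleocoat as pc
from paleocoat.damage_profile import (
    authenticate_variant,
    consensus_from_pileups,
    estimate_damage,
    welch_t_test,
)
from paleocoat.locus_model import LocusDefinition

from conftest import make_readset, mc1r_damage_profiles


@pytest.fixture(scope="module")
def toy_locus():
    # SNP at position 0 so every other site is damage-eligible; two C and
    # two G sites away from the variant
    return LocusDefinition(
        name="TOY", gene="TOY", reference_seq="ACCTGGAT",
        variant_kind="snp", variant_start=0, variant_length=1,
        ref_allele="A", alt_allele="G", ref_label="A", alt_label="G",
    )


def welch_oracle(a, b):
    """Textbook Welch statistic, Welch-Satterthwaite df, two-sided p."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestEstimateDamage:
    def test_clean_reads_give_zero_damage(self, toy_locus):
        p = pc.build_pileup(make_readset([toy_locus.reference_seq] * 10, locus="TOY"), toy_locus)
        prof = estimate_damage([p], toy_locus, toy_locus.reference_seq)
        assert prof.pct_degraded == 0.0 and prof.pct_ct == 0.0
        # variant position excluded: 7 usable positions x 10 reads
        assert prof.n_observations == 70

    def test_single_ct_mismatch_arithmetic(self, toy_locus):
        ref = toy_locus.reference_seq
        damaged = ref[:1] + "T" + ref[2:]  # C->T at position 1
        reads = [ref] * 9 + [damaged]
        p = pc.build_pileup(make_readset(reads, locus="TOY"), toy_locus)
        prof = estimate_damage([p], toy_locus, ref)
        # 1 mismatch / 70 observations; 1 C->T / 20 forward C-site obs
        assert prof.pct_degraded == pytest.approx(100 / 70)
        assert prof.pct_ct == pytest.approx(100 * 1 / 20)
        assert prof.n_ct_observations == 20

    def test_reverse_orientation_ga_counts_as_deamination(self, toy_locus):
        ref = toy_locus.reference_seq
        damaged = ref[:4] + "A" + ref[5:]  # G->A at position 4
        reads = [ref] * 9 + [damaged]
        p = pc.build_pileup(
            make_readset(reads, orientations=["-"] * 10, locus="TOY"), toy_locus
        )
        prof = estimate_damage([p], toy_locus, ref)
        assert prof.pct_ct == pytest.approx(100 * 1 / 20)

    def test_read_and_replicate_order_invariance(self, toy_locus):
        ref = toy_locus.reference_seq
        damaged = ref[:1] + "T" + ref[2:]
        r1 = make_readset([ref, damaged, ref], locus="TOY", rep=1)
        r2 = make_readset([damaged, ref], locus="TOY", rep=2)
        p1, p2 = (pc.build_pileup(r, toy_locus) for r in (r1, r2))
        a = estimate_damage([p1, p2], toy_locus, ref)
        b = estimate_damage([p2, p1], toy_locus, ref)
        assert (a.pct_degraded, a.pct_ct) == (b.pct_degraded, b.pct_ct)

    def test_variant_and_excluded_sites_do_not_count(self, mc1r_loci):
        # a hom-alt sample: without exclusion the alt reads would look damaged
        lead = mc1r_loci[0]
        cfg = pc.SimulationConfig(
            genotypes={"MC1R_R301C": ("T", "T")},
            deamination_rate=0.0, base_error_rate=0.0,
            n_replicates=1, reads_per_replicate=200, seed=8,
        )
        reads, _ = pc.simulate_sample(mc1r_loci, cfg)
        p = pc.build_pileup(reads[0], lead)
        cons = consensus_from_pileups([p], lead)
        extra = [q for l in mc1r_loci[1:] for q in l.variant_window]
        prof = estimate_damage([p], lead, cons, extra_exclude=extra)
        assert prof.pct_degraded == 0.0

    def test_recovers_simulated_deamination_rate(self, mc1r_loci):
        profiles, _ = mc1r_damage_profiles(
            mc1r_loci, [{}], delta=0.01, reads=3000, reps=2, seed=13
        )
        prof = profiles[0]
        se = 100 * math.sqrt(0.01 * 0.99 / prof.n_ct_observations)
        assert abs(prof.pct_ct - 1.0) <= 3 * se

    def test_no_usable_observations_is_an_error(self, toy_locus):
        p = pc.build_pileup(make_readset([toy_locus.reference_seq], locus="TOY"), toy_locus)
        with pytest.raises(ValueError, match="no usable observations"):
            estimate_damage([p], toy_locus, toy_locus.reference_seq,
                            extra_exclude=range(8))

    def test_consensus_length_checked(self, toy_locus):
        p = pc.build_pileup(make_readset([toy_locus.reference_seq], locus="TOY"), toy_locus)
        with pytest.raises(ValueError, match="length"):
            estimate_damage([p], toy_locus, "ACCT")


class TestConsensus:
    def test_majority_base_wins(self, toy_locus):
        ref = toy_locus.reference_seq
        variant = ref[:4] + "A" + ref[5:]
        p = pc.build_pileup(make_readset([variant] * 8 + [ref] * 2, locus="TOY"), toy_locus)
        cons = consensus_from_pileups([p], toy_locus)
        assert cons == variant

    def test_tie_resolves_to_reference(self, toy_locus):
        ref = toy_locus.reference_seq
        variant = ref[:4] + "A" + ref[5:]
        p = pc.build_pileup(make_readset([variant] * 5 + [ref] * 5, locus="TOY"), toy_locus)
        assert consensus_from_pileups([p], toy_locus) == ref


class TestWelch:
    def test_identical_groups(self):
        cmp = welch_t_test([1, 2, 3], [1, 2, 3])
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_zero_variance_identical_groups(self):
        cmp = welch_t_test([0, 0, 0, 0], [0, 0, 0, 0])
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_zero_variance_different_means(self):
        cmp = welch_t_test([1, 1], [2, 2])
        assert cmp.p_value == 0.0 and cmp.t_statistic == -math.inf

    def test_matches_textbook_formula(self):
        cases = [
            ([1.0, 1.2, 0.9], [2.0, 2.4, 2.1]),
            ([0.5, 0.7, 0.55, 0.62], [0.58, 0.61]),
            ([3.0, 2.0, 4.0, 5.0], [3.5, 2.5, 4.5]),
        ]
        for a, b in cases:
            cmp = welch_t_test(a, b)
            t, df, p = welch_oracle(a, b)
            assert cmp.t_statistic == pytest.approx(t)
            assert cmp.df == pytest.approx(df)
            assert cmp.p_value == pytest.approx(p)

    def test_antisymmetric_in_group_order(self):
        a, b = [1.0, 1.2, 0.9], [2.0, 2.4, 2.1]
        ab, ba = welch_t_test(a, b), welch_t_test(b, a)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            welch_t_test([1.0], [1.0, 2.0])


class TestAuthenticateVariant:
    def test_single_carrier_is_inconclusive(self):
        verdict = authenticate_variant([], [], {})
        assert verdict.verdict == "inconclusive"
        assert "carrier" in verdict.reason

    def test_single_replicate_is_inconclusive(self, mc1r_loci):
        profiles, _ = mc1r_damage_profiles(
            mc1r_loci, [{}] * 4, delta=0.02, reads=80, reps=2, seed=21
        )
        verdict = authenticate_variant(
            profiles[:2], profiles[2:], {"S0": [0.5]}
        )
        assert verdict.verdict == "inconclusive"
        assert "replicate" in verdict.reason

    def test_simulated_authentic_het_variant(self, mc1r_loci):
        het = {"MC1R_R301C": ("C", "T")}
        profiles, freqs = mc1r_damage_profiles(
            mc1r_loci, [het] * 4 + [{}] * 4, delta=0.02, reads=200, reps=3, seed=31
        )
        verdict = authenticate_variant(
            profiles[:4], profiles[4:],
            {f"S{i}": freqs[i] for i in range(4)}, variant="MC1R_R301C",
        )
        assert verdict.verdict == "authentic"
        assert verdict.damage_association_pass
        assert verdict.replicate_concordance_pass
        assert verdict.frequency_level_pass

    def test_simulated_damage_artifact(self, mc1r_loci):
        # "carriers" are hom-ref samples whose apparent alt frequency is pure
        # deamination (~delta/2) -- far below the het window and commensurate
        # with the measured damage
        profiles, freqs = mc1r_damage_profiles(
            mc1r_loci, [{}] * 8, delta=0.03, reads=200, reps=3, seed=32
        )
        verdict = authenticate_variant(
            profiles[:4], profiles[4:],
            {f"S{i}": freqs[i] for i in range(4)}, variant="MC1R_R301C",
        )
        assert verdict.verdict == "artifact"
        assert not verdict.frequency_level_pass

    def test_subhet_but_damage_incompatible_is_inconclusive(self, mc1r_loci):
        profiles, _ = mc1r_damage_profiles(
            mc1r_loci, [{}] * 4, delta=0.01, reads=120, reps=2, seed=33
        )
        verdict = authenticate_variant(
            profiles[:2], profiles[2:],
            {"S0": [0.18, 0.20], "S1": [0.17, 0.19]},  # 20x the damage rate
        )
        assert verdict.verdict == "inconclusive"
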