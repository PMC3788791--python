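"""Affine-gap alignment and pileup construction."""

import sys
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, strategies as st

import paleocoat as pc
import paleocoat.read_alignment as ra
from paleocoat.genotyping import alt_frequency

from conftest import make_readset

NEG = -(10**9)


def oracle_align_score(a, b, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Independent brute-force scorer: forward recursion over alignment
    columns with the gap state carried explicitly (gap of length L costs
    open + (L-1)*extend)."""

    @lru_cache(maxsize=None)
    def go(i, j, state):
        if i == len(a) and j == len(b):
            return 0
        best = NEG
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            best = max(best, s + go(i + 1, j + 1, 0))
        if i < len(a):
            best = max(best, (gap_extend if state == 1 else gap_open) + go(i + 1, j, 1))
        if j < len(b):
            best = max(best, (gap_extend if state == 2 else gap_open) + go(i, j + 1, 2))
        return best

    sys.setrecursionlimit(20000)
    return go(0, 0, 0)


def _dp_symbols(read, ref):
    """Pileup column extraction straight from the DP alignment (no fast path)."""
    aln = pc.align_read(read, ref)
    sym = np.full(len(ref), ra.SYM_OTHER, dtype=np.uint8)
    pos = 0
    for rc, qc in zip(aln.ref_row, aln.read_row):
        if rc == "-":
            continue
        sym[pos] = ra.SYM_GAP if qc == "-" else ra._ENCODE[ord(qc)]
        pos += 1
    return sym


class TestAlignRead:
    def test_identity_alignment(self):
        res = pc.align_read("ACGTACGT", "ACGTACGT")
        assert res.score == 8
        assert "-" not in res.ref_row + res.read_row
        assert res.read_row == res.ref_row

    def test_deletion_read_gets_single_left_normalized_gap(self, k_locus):
        ref = k_locus.reference_seq
        ws, we = k_locus.variant_start, k_locus.variant_start + 3
        read = ref[:ws] + ref[we:]
        res = pc.align_read(read, ref)
        assert res.ref_row == ref  # no insertions
        assert res.read_row == ref[:ws] + "---" + ref[we:]
        assert res.score == len(read) - 6  # all matches, one 3-nt gap

    def test_gap_in_homopolymer_is_left_normalized(self):
        # deleting any one A of AAAA is score-equivalent; placement must be
        # the leftmost one
        res = pc.align_read("GCAAAT", "GCAAAAT")
        assert res.read_row == "GC-AAAT"

    def test_scores_match_bruteforce_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n1 = int(rng.integers(1, 31))
            n2 = int(rng.integers(1, 31))
            a = "".join(rng.choice(list("ACGT"), n1))
            b = "".join(rng.choice(list("ACGT"), n2))
            assert pc.align_read(a, b).score == oracle_align_score(b, a), (a, b)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=25),
           st.text(alphabet="ACGT", min_size=1, max_size=25))
    def test_score_symmetric_under_reverse_complement(self, read, ref):
        comp = str.maketrans("ACGT", "TGCA")
        rc = lambda s: s.translate(comp)[::-1]
        assert pc.align_read(read, ref).score == pc.align_read(rc(read), rc(ref)).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pc.align_read("", "ACGT")
        with pytest.raises(ValueError, match="empty"):
            pc.align_read("ACGT", "")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError, match="ACGTN"):
            pc.align_read("ACGU", "ACGT")

    def test_alignment_rows_replay_to_score(self):
        # row pair must be a valid alignment achieving the reported score
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 20))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 20))))
            res = pc.align_read(a, b)
            assert res.ref_row.replace("-", "") == b
            assert res.read_row.replace("-", "") == a
            score, in_gap = 0, None
            for rc, qc in zip(res.ref_row, res.read_row):
                assert not (rc == "-" and qc == "-")
                if rc == "-" or qc == "-":
                    which = "ref" if rc == "-" else "read"
                    score += -1 if in_gap == which else -4
                    in_gap = which
                else:
                    score += 1 if rc == qc else -1
                    in_gap = None
            assert score == res.score


class TestFastPath:
    def test_fast_symbols_agree_with_full_dp(self, k_locus):
        """The shortcut for near-reference and single-3-gap reads must be
        column-identical to the DP alignment."""
        ref = k_locus.reference_seq
        ws = k_locus.variant_start
        del_hap = ref[:ws] + ref[ws + 3 :]
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(300):
            hap = del_hap if rng.random() < 0.5 else ref
            r = list(hap)
            for _k in range(int(rng.integers(0, 3))):
                r[int(rng.integers(len(r)))] = "ACGT"[int(rng.integers(4))]
            read = "".join(r)
            fast = ra._fast_symbols(read, ref)
            if fast is None:
                continue
            checked += 1
            assert np.array_equal(fast, _dp_symbols(read, ref)), read
        assert checked > 200  # the shortcut must actually cover most reads


class TestBuildPileup:
    def test_identical_reads_fill_reference_columns(self, loci_by_name):
        locus = loci_by_name["MC1R_R301C"]
        p = pc.build_pileup(make_readset([locus.reference_seq] * 10), locus)
        assert p.n_reads == 10
        for pos, base in enumerate(locus.reference_seq):
            assert p.counts["ACGT".index(base), pos] == 10
        assert (p.column_sums() == 10).all()

    def test_deletion_reads_flagged_by_construction(self, k_locus):
        ref = k_locus.reference_seq
        ws = k_locus.variant_start
        del_read = ref[:ws] + ref[ws + 3 :]
        p = pc.build_pileup(make_readset([ref] * 5 + [del_read] * 5, locus="CBD103"), k_locus)
        assert p.n_deletion_reads == 5
        assert alt_frequency(p, k_locus) == 0.5
        assert (p.column_sums() == 10).all()

    def test_partial_window_gap_is_other_not_deletion(self, k_locus):
        ref = k_locus.reference_seq
        ws = k_locus.variant_start
        two_nt_del = ref[: ws + 1] + ref[ws + 3 :]  # only 2 of the 3 window nt
        p = pc.build_pileup(make_readset([two_nt_del], locus="CBD103"), k_locus)
        assert p.n_deletion_reads == 0
        window = p.counts[:, ws : ws + 3]
        assert window[ra.SYM_GAP].sum() == 0
        assert window[ra.SYM_OTHER].sum() == 2

    def test_het_snp_pileup_matches_binomial_oracle(self, loci, loci_by_name):
        locus = loci_by_name["MC1R_R301C"]
        cfg = pc.SimulationConfig(
            genotypes={"MC1R_R301C": ("C", "T")},
            n_replicates=1, reads_per_replicate=1000,
            deamination_rate=0.0, base_error_rate=0.0, seed=5,
        )
        reads, _ = pc.simulate_sample([l for l in loci if l.gene == "MC1R"], cfg)
        p = pc.build_pileup(reads[0], locus)
        alt = p.counts["ACGT".index("T"), locus.variant_start]
        se = (1000 * 0.25) ** 0.5
        assert abs(alt - 500) <= 3 * se

    def test_column_conservation_with_noise(self, loci, k_locus):
        cfg = pc.SimulationConfig(
            genotypes={"CBD103_DG23": ("GGG", "-")},
            n_replicates=1, reads_per_replicate=400,
            deamination_rate=0.05, base_error_rate=0.01, seed=11,
        )
        reads, _ = pc.simulate_sample([k_locus], cfg)
        p = pc.build_pileup(reads[0], k_locus)
        assert (p.column_sums() == p.n_reads).all()

    def test_n_heavy_reads_skipped_with_warning(self, loci_by_name, caplog):
        locus = loci_by_name["MC1R_R301C"]
        ref = locus.reference_seq
        n_read = "N" * 30 + ref[30:]  # 38% N
        with caplog.at_level("WARNING"):
            p = pc.build_pileup(make_readset([ref] * 3 + [n_read]), locus)
        assert p.n_reads == 3
        assert p.n_skipped == 1
        assert "skipping" in caplog.text
        assert (p.column_sums() == 3).all()

    def test_empty_read_set_rejected(self, loci_by_name):
        with pytest.raises(ValueError, match="empty read set"):
            pc.build_pileup(make_readset([]), loci_by_name["MC1R_R301C"])

    def test_merge_pileups_adds_counts(self, loci_by_name):
        locus = loci_by_name["MC1R_R301C"]
        p1 = pc.build_pileup(make_readset([locus.reference_seq] * 4), locus)
        p2 = pc.build_pileup(make_readset([locus.reference_seq] * 6), locus)
        merged = pc.merge_pileups([p1, p2])
        assert merged.n_reads == 10
        assert (merged.column_sums() == 10).all()
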