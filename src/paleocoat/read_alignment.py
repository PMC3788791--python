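"""Global affine-gap read alignment and per-position pileups.

Reads are full-length PCR amplicons, so alignment is global (Needleman-
Wunsch with Gotoh affine gaps) rather than local.  Default scores are
match +1, mismatch -1, gap open -4, gap extend -1; a gap of length L costs
``gap_open + (L-1) * gap_extend``.  With these scores an equal-length read
can never be assigned a gapped alignment in preference to substitutions
(any gapped equal-length alignment scores at most n-9 while <=4 mismatches
score >= n-8), which is what keeps deamination damage from masquerading as
the 3-nt K-locus deletion.

Tie-breaking is deterministic: diagonal (match/mismatch) moves are
preferred over gaps during traceback, and gap runs are then left-normalised
(shifted to the leftmost score-equivalent placement), the standard indel
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .locus_model import LocusDefinition, ReplicateReadSet

__all__ = [
    "AlignmentScoring",
    "AlignmentResult",
    "PileupMatrix",
    "align_read",
    "build_pileup",
    "merge_pileups",
    "SYMBOLS",
]

logger = logging.getLogger(__name__)

#: pileup row symbols: bases, gap, and "other" (N or partial-window gaps)
SYMBOLS = ("A", "C", "G", "T", "gap", "other")
SYM_GAP = 4
SYM_OTHER = 5

_NEG = np.int64(-(10**9))

_ENCODE = np.full(256, SYM_OTHER, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment as two equal-length gapped rows."""

    ref_row: str
    read_row: str
    score: int

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.read_row):
            raise ValueError("alignment rows differ in length")


def align_read(
    read: str,
    ref: str,
    *,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> AlignmentResult:
    """Optimal global affine-gap alignment of ``read`` against ``ref``.

    Both sequences must be non-empty over {A,C,G,T,N}; N scores as a
    mismatch against everything.  Ties are broken deterministically
    (substitution preferred over gap, gaps left-normalised).
    """
    if not read or not ref:
        raise ValueError("cannot align an empty sequence")
    for seq, which in ((read, "read"), (ref, "ref")):
        if set(seq.upper()) - set("ACGTN"):
            raise ValueError(f"{which} contains characters outside ACGTN")
    sc = AlignmentScoring(match, mismatch, gap_open, gap_extend)
    ref_row, read_row, score = _gotoh_align(read.upper(), ref.upper(), sc)
    ref_row, read_row = _left_normalize(ref_row, read_row)
    return AlignmentResult(ref_row=ref_row, read_row=read_row, score=int(score))


def _gotoh_align(read: str, ref: str, sc: AlignmentScoring) -> tuple[str, str, int]:
    """Gotoh DP over (M, X, Y) states with full traceback.

    State M aligns ref[i-1] to read[j-1]; X is a gap in the read row
    (consuming ref); Y is a gap in the ref row (consuming read).  Rows are
    vectorised over the read axis; the within-row Y recurrence uses the
    running-maximum closed form ``Y[i,j] = max_{k<j} B[i,k] + open +
    (j-1-k)*extend`` with ``B = max(M, X)``.
    """
    n, m = len(ref), len(read)
    op, ex = sc.gap_open, sc.gap_extend
    ref_b = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    read_b = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    is_match = (ref_b[:, None] == read_b[None, :]) & (ref_b[:, None] != ord("N"))
    smat = np.where(is_match, sc.match, sc.mismatch).astype(np.int64)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    jj = np.arange(m + 1, dtype=np.int64)
    Y[0, 1:] = op + (jj[1:] - 1) * ex
    ii = np.arange(n + 1, dtype=np.int64)
    X[1:, 0] = op + (ii[1:] - 1) * ex
    y_base = op + (jj[1:] - 1) * ex

    for i in range(1, n + 1):
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        X[i, 1:] = np.maximum(np.maximum(Mp[1:], Yp[1:]) + op, Xp[1:] + ex)
        prev = np.maximum(np.maximum(Mp[:-1], Xp[:-1]), Yp[:-1])
        M[i, 1:] = prev + smat[i - 1]
        c = np.maximum(M[i], X[i]) - jj * ex
        Y[i, 1:] = y_base + np.maximum.accumulate(c[:-1])

    return _traceback(read, ref, sc, M, X, Y)


def _traceback(
    read: str,
    ref: str,
    sc: AlignmentScoring,
    M: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
) -> tuple[str, str, int]:
    n, m = len(ref), len(read)
    op, ex = sc.gap_open, sc.gap_extend
    # tie preference: substitution (M) over gap states
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    score = int(max(M[n, m], X[n, m], Y[n, m]))
    i, j = n, m
    ref_row: list[str] = []
    read_row: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: ref[i-1] vs read[j-1]
            ref_row.append(ref[i - 1])
            read_row.append(read[j - 1])
            target = M[i, j] - _pair_score(ref[i - 1], read[j - 1], sc)
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], target)
        elif state == 1:  # X: gap in read row
            ref_row.append(ref[i - 1])
            read_row.append("-")
            here = X[i, j]
            i -= 1
            if M[i, j] + op == here:
                state = 0
            elif X[i, j] + ex == here:
                state = 1
            else:
                state = 2
        else:  # Y: gap in ref row
            ref_row.append("-")
            read_row.append(read[j - 1])
            here = Y[i, j]
            j -= 1
            if M[i, j] + op == here:
                state = 0
            elif Y[i, j] + ex == here:
                state = 2
            else:
                state = 1
    return "".join(reversed(ref_row)), "".join(reversed(read_row)), score


def _pair_score(a: str, b: str, sc: AlignmentScoring) -> int:
    return sc.match if (a == b and a != "N") else sc.mismatch


def _pick_state(m: int, x: int, y: int, target: int) -> int:
    if m == target:
        return 0
    if x == target:
        return 1
    return 2


def _left_normalize(ref_row: str, read_row: str) -> tuple[str, str]:
    """Shift gap runs to their leftmost score-equivalent placement."""
    a, b = list(ref_row), list(read_row)
    a, b = _shift_gaps_left(a, b)  # gaps in read row
    b, a = _shift_gaps_left(b, a)  # gaps in ref row
    return "".join(a), "".join(b)


def _shift_gaps_left(other: list[str], gapped: list[str]) -> tuple[list[str], list[str]]:
    """Left-shift gap runs in ``gapped`` while alignment score is preserved.

    A run covering columns [s, e) can move one column left when column s-1
    is aligned in both rows and ``other[s-1] == other[e-1]`` (the displaced
    character meets an identical partner, so match status is unchanged).
    """
    changed = True
    while changed:
        changed = False
        i = 0
        n = len(gapped)
        while i < n:
            if gapped[i] != "-":
                i += 1
                continue
            s = i
            while i < n and gapped[i] == "-":
                i += 1
            e = i
            while (
                s > 0
                and gapped[s - 1] != "-"
                and other[s - 1] != "-"
                and other[s - 1] == other[e - 1]
            ):
                gapped[e - 1] = gapped[s - 1]
                gapped[s - 1] = "-"
                s, e = s - 1, e - 1
                changed = True
    return other, gapped


# ---------------------------------------------------------------------------
# pileups


@dataclass
class PileupMatrix:
    """Per-reference-position symbol counts across aligned reads.

    ``counts_fwd``/``counts_rev`` are (6, L) arrays over :data:`SYMBOLS`
    split by read orientation; every non-skipped read contributes exactly
    one symbol per reference position, so each column of
    ``counts_fwd + counts_rev`` sums to ``n_reads``.  ``n_deletion_reads``
    counts reads whose alignment gaps out the entire variant window.
    """

    locus: str
    reference: str
    counts_fwd: np.ndarray
    counts_rev: np.ndarray
    n_reads: int
    n_deletion_reads: int
    n_skipped: int = 0

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fwd + self.counts_rev

    @property
    def length(self) -> int:
        return len(self.reference)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self):
        """Pileup as a pandas DataFrame with 1-based positions (for reports)."""
        import pandas as pd

        c = self.counts
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "ref": list(self.reference),
                **{sym: c[k] for k, sym in enumerate(SYMBOLS)},
            }
        )


def _fast_symbols(read: str, ref: str) -> np.ndarray | None:
    """Score-optimal alignment columns without the DP, where provable.

    Valid only for the default scoring (+1/-1, gaps -4/-1).  Two cases:

    * equal length, <=4 substitutions: the ungapped alignment scores
      ``n - 2m >= n - 8`` while any gapped equal-length alignment scores at
      most ``n - 9`` (>=1 gap column in each row costs >=8 and forfeits a
      match), so ungapped is optimal;
    * read shorter by exactly 3 with a single-3-gap placement leaving <=1
      substitution: the best single-gap alignment scores
      ``(n-3) - 6 - 2m*``; any multi-gap structure pays >=9 in gap costs
      and so can win only if it saves >=2 substitutions, impossible for
      ``m* <= 1``.  The leftmost minimising placement coincides with
      left-normalisation (score ties are exactly mismatch-count ties).

    Returns None when optimality cannot be established cheaply.
    """
    L = len(ref)
    ref_arr = _encode(ref)
    if len(read) == L:
        arr = _encode(read)
        if int(np.count_nonzero(arr != ref_arr)) <= 4:
            return arr.copy()
        return None
    if len(read) == L - 3 and len(read) > 0:
        arr = _encode(read)
        d_pre = (arr != ref_arr[: L - 3]).astype(np.int64)
        d_suf = (arr != ref_arr[3:]).astype(np.int64)
        pre = np.concatenate(([0], np.cumsum(d_pre)))  # mism. of read[:p] vs ref[:p]
        suf = np.concatenate((np.cumsum(d_suf[::-1])[::-1], [0]))  # read[p:] vs ref[p+3:]
        m = pre + suf  # mismatches with the 3-gap starting at each position
        p = int(np.argmin(m))
        if m[p] <= 1:
            out = np.empty(L, dtype=np.uint8)
            out[:p] = arr[:p]
            out[p : p + 3] = SYM_GAP
            out[p + 3 :] = arr[p:]
            return out
    return None


# Cache alignment column extraction per unique (read, ref) pair: amplicon
# read pools are dominated by duplicate sequences.
@lru_cache(maxsize=300_000)
def _aligned_symbols_cached(
    read: str, ref: str, window: tuple[int, int], sc: AlignmentScoring
) -> tuple[bytes, bool]:
    symbols = _fast_symbols(read, ref) if sc == DEFAULT_SCORING else None
    if symbols is None:
        aln = align_read(
            read,
            ref,
            match=sc.match,
            mismatch=sc.mismatch,
            gap_open=sc.gap_open,
            gap_extend=sc.gap_extend,
        )
        symbols = np.full(len(ref), SYM_OTHER, dtype=np.uint8)
        pos = 0
        for rc, qc in zip(aln.ref_row, aln.read_row):
            if rc == "-":
                continue  # insertion relative to the reference: no pileup column
            symbols[pos] = SYM_GAP if qc == "-" else _ENCODE[ord(qc)]
            pos += 1
    ws, we = window
    win = symbols[ws:we]
    flag = bool(we > ws and np.all(win == SYM_GAP))
    if not flag and np.any(win == SYM_GAP):
        # partial gap over the variant window: not the deletion allele
        symbols[ws:we][win == SYM_GAP] = SYM_OTHER
    return symbols.tobytes(), flag


def build_pileup(
    read_set: ReplicateReadSet,
    locus: LocusDefinition,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    *,
    max_n_fraction: float = 0.2,
) -> PileupMatrix:
    """Align every read of one replicate to the locus reference and tally.

    Reads with more than ``max_n_fraction`` N bases are skipped with a
    logged warning.  A read is flagged as carrying the deletion allele iff
    its alignment places a gap across the entire variant window; 1-2 nt
    partial gaps there are tallied as "other".
    """
    if len(read_set) == 0:
        raise ValueError("cannot build a pileup from an empty read set")
    ref = locus.reference_seq
    L = len(ref)
    window = (locus.variant_start, locus.variant_start + locus.variant_length) \
        if locus.variant_kind == "deletion" else (0, 0)
    counts = {"+": np.zeros((6, L), dtype=np.int64), "-": np.zeros((6, L), dtype=np.int64)}
    orientations = read_set.orientations or ["+"] * len(read_set)
    pos_idx = np.arange(L)
    n_reads = 0
    n_del = 0
    n_skipped = 0

    from collections import Counter

    for (seq, orient), mult in Counter(zip(read_set.sequences, orientations)).items():
        if seq.count("N") > max_n_fraction * max(len(seq), 1):
            n_skipped += mult
            logger.warning(
                "skipping %d read(s) with >%d%% N in %s/%s rep %s",
                mult, int(max_n_fraction * 100), read_set.sample_id,
                read_set.locus, read_set.replicate_id,
            )
            continue
        sym_bytes, flag = _aligned_symbols_cached(seq, ref, window, scoring)
        sym = np.frombuffer(sym_bytes, dtype=np.uint8)
        counts[orient][sym, pos_idx] += mult
        if flag:
            n_del += mult
        n_reads += mult

    return PileupMatrix(
        locus=locus.name,
        reference=ref,
        counts_fwd=counts["+"],
        counts_rev=counts["-"],
        n_reads=n_reads,
        n_deletion_reads=n_del,
        n_skipped=n_skipped,
    )


def merge_pileups(pileups: Sequence[PileupMatrix]) -> PileupMatrix:
    """Pool pileups (e.g. across replicates) built against the same reference."""
    if not pileups:
        raise ValueError("no pileups to merge")
    first = pileups[0]
    if any(p.reference != first.reference for p in pileups):
        raise ValueError("pileups built against different references")
    return PileupMatrix(
        locus=first.locus,
        reference=first.reference,
        counts_fwd=sum(p.counts_fwd for p in pileups),
        counts_rev=sum(p.counts_rev for p in pileups),
        n_reads=sum(p.n_reads for p in pileups),
        n_deletion_reads=sum(p.n_deletion_reads for p in pileups),
        n_skipped=sum(p.n_skipped for p in pileups),
    )
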