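"""Degradation statistics and damage-aware variant authentication.

Post-mortem cytosine deamination is the dominant ancient-DNA artifact: it
is read as C->T on one orientation and G->A on the other, and at typical
rates of 1-5% per site it can mimic a low-frequency C->T variant.  A
candidate variant is therefore authenticated by three screens:

1. *damage association*: carriers of the variant must not show elevated
   damage overall — Welch two-sample comparisons of per-sample %C->T and
   %degraded-sites between carriers and non-carriers must both be
   non-significant (family-wise level ``alpha`` across the two correlated
   statistics, i.e. alpha/2 each);
2. *replicate concordance*: within each carrier, the variant's alt-allele
   frequency must agree across independent amplification products (max-min
   spread <= ``concordance_tol``);
3. *frequency level*: each carrier's mean alt frequency must reach the
   heterozygote lower bound — deamination produces per-site rates of a few
   percent, never the >=25% of a genuine allele.

All three pass -> ``authentic``.  If the frequency screen fails while the
observed frequencies are commensurate with the sample's measured damage
rate, the variant is labelled ``artifact``; anything else (including
insufficient carriers or replicates) is ``inconclusive``.

Degradation percentages are computed per read-site *observation* (not per
consensus site): every aligned base at a non-variant position counts once,
which uses all coverage and is well defined at any depth.  The per-sample
consensus is the majority base per position with ties resolved to the
reference, and variant sites are excluded so genuine alleles are never
counted as damage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .locus_model import LocusDefinition
from .read_alignment import PileupMatrix, merge_pileups

__all__ = [
    "DamageProfile",
    "GroupComparison",
    "AuthenticationVerdict",
    "consensus_from_pileups",
    "estimate_damage",
    "welch_t_test",
    "authenticate_variant",
]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class DamageProfile:
    """Per-sample degradation summary over one amplicon.

    ``pct_degraded``: % of read-site observations mismatching the sample
    consensus at non-variant positions.  ``pct_ct``: % of forward-read
    observations at consensus-C sites read as T, pooled with reverse-read
    observations at consensus-G sites read as A (the two faces of the same
    deamination chemistry).  Both on a 0-100 scale.
    """

    sample_id: str
    locus: str
    pct_degraded: float
    pct_ct: float
    n_observations: int
    n_ct_observations: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_degraded <= 100.0 and 0.0 <= self.pct_ct <= 100.0):
            raise ValueError("damage percentages must be within [0, 100]")


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison of per-sample percentages."""

    mean_a: float
    mean_b: float
    t_statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class AuthenticationVerdict:
    """Outcome of the three-screen authentication of one variant."""

    variant: str
    damage_association_pass: bool | None
    replicate_concordance_pass: bool | None
    frequency_level_pass: bool | None
    verdict: str  # "authentic" | "artifact" | "inconclusive"
    reason: str = ""


def consensus_from_pileups(
    pileups: Sequence[PileupMatrix], locus: LocusDefinition
) -> str:
    """Majority base per position across pooled pileups; ties -> reference."""
    merged = merge_pileups(list(pileups))
    base_counts = merged.counts[:4]  # A,C,G,T rows
    best = base_counts.max(axis=0)
    out = []
    for pos, ref_char in enumerate(locus.reference_seq):
        col = base_counts[:, pos]
        top = np.flatnonzero(col == best[pos])
        ref_idx = _BASE_IDX[ref_char]
        if best[pos] == 0 or ref_idx in top or len(top) > 1:
            out.append(ref_char)  # no coverage, ref is (co-)majority, or tie
        else:
            out.append("ACGT"[top[0]])
    return "".join(out)


def estimate_damage(
    pileups: Sequence[PileupMatrix],
    locus: LocusDefinition,
    consensus: str,
    *,
    extra_exclude: Iterable[int] = (),
    sample_id: str = "",
) -> DamageProfile:
    """Estimate %degraded and %C->T for one sample from replicate pileups.

    Variant positions (the locus window plus ``extra_exclude``, e.g. the
    second variant on a shared amplicon) are excluded.  Raises
    ``ValueError`` when no usable observations remain.
    """
    if len(consensus) != len(locus.reference_seq):
        raise ValueError("consensus length must equal reference length")
    merged = merge_pileups(list(pileups))
    L = merged.length
    exclude = np.zeros(L, dtype=bool)
    exclude[list(locus.variant_window)] = True
    for pos in extra_exclude:
        exclude[pos] = True
    keep = ~exclude

    cons_idx = np.array([_BASE_IDX.get(c, -1) for c in consensus])
    total = merged.counts[:4]  # base observations only
    obs_per_pos = total.sum(axis=0)
    cons_counts = np.where(
        cons_idx >= 0, total[np.clip(cons_idx, 0, 3), np.arange(L)], 0
    )
    n_obs = int(obs_per_pos[keep].sum())
    if n_obs == 0:
        raise ValueError(f"no usable observations for {sample_id or 'sample'} at {locus.name}")
    n_mismatch = int((obs_per_pos[keep] - cons_counts[keep]).sum())
    pct_degraded = 100.0 * n_mismatch / n_obs

    c_sites = (cons_idx == _BASE_IDX["C"]) & keep
    g_sites = (cons_idx == _BASE_IDX["G"]) & keep
    fwd, rev = merged.counts_fwd[:4], merged.counts_rev[:4]
    ct_num = int(fwd[_BASE_IDX["T"], c_sites].sum() + rev[_BASE_IDX["A"], g_sites].sum())
    ct_den = int(fwd[:, c_sites].sum() + rev[:, g_sites].sum())
    pct_ct = 100.0 * ct_num / ct_den if ct_den else 0.0

    return DamageProfile(
        sample_id=sample_id,
        locus=locus.name,
        pct_degraded=pct_degraded,
        pct_ct=pct_ct,
        n_observations=n_obs,
        n_ct_observations=ct_den,
    )


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance two-sample t test (two-sided).

    Each group needs >=2 finite values.  The degenerate zero-variance case
    with equal means returns t=0, p=1 (identical groups carry no evidence
    of a difference); zero variance with different means returns p=0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires >=2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("welch_t_test requires finite values")
    df_fallback = float(a.size + b.size - 2)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(float(a.mean()), float(b.mean()), 0.0, df_fallback, 1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return GroupComparison(float(a.mean()), float(b.mean()), float(t), df_fallback, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def authenticate_variant(
    profiles_carriers: Sequence[DamageProfile],
    profiles_noncarriers: Sequence[DamageProfile],
    replicate_freqs: dict[str, Sequence[float]],
    *,
    variant: str = "",
    alpha: float = 0.05,
    concordance_tol: float = 0.25,
    het_lower: float = 0.25,
    damage_factor: float = 3.0,
) -> AuthenticationVerdict:
    """Run the three authentication screens for one candidate variant.

    ``replicate_freqs`` maps carrier sample_id -> per-replicate alt-allele
    frequencies.  Insufficient inputs (fewer than 2 carriers or
    non-carriers, or a carrier with <2 replicates) yield an
    ``inconclusive`` verdict with a reason, never an exception.
    """
    if len(profiles_carriers) < 2 or len(profiles_noncarriers) < 2:
        return AuthenticationVerdict(
            variant=variant,
            damage_association_pass=None,
            replicate_concordance_pass=None,
            frequency_level_pass=None,
            verdict="inconclusive",
            reason="need >=2 carriers and >=2 non-carriers",
        )
    if any(len(f) < 2 for f in replicate_freqs.values()) or not replicate_freqs:
        return AuthenticationVerdict(
            variant=variant,
            damage_association_pass=None,
            replicate_concordance_pass=None,
            frequency_level_pass=None,
            verdict="inconclusive",
            reason="each carrier needs >=2 replicate frequencies",
        )

    ct_cmp = welch_t_test(
        [p.pct_ct for p in profiles_carriers], [p.pct_ct for p in profiles_noncarriers]
    )
    deg_cmp = welch_t_test(
        [p.pct_degraded for p in profiles_carriers],
        [p.pct_degraded for p in profiles_noncarriers],
    )
    # two correlated screens at family-wise level alpha (Bonferroni)
    damage_pass = ct_cmp.p_value > alpha / 2 and deg_cmp.p_value > alpha / 2

    spreads = {s: max(f) - min(f) for s, f in replicate_freqs.items()}
    concordance_pass = all(v <= concordance_tol for v in spreads.values())

    means = {s: float(np.mean(f)) for s, f in replicate_freqs.items()}
    frequency_pass = all(m >= het_lower for m in means.values())

    if damage_pass and concordance_pass and frequency_pass:
        verdict, reason = "authentic", "all screens passed"
    elif not frequency_pass:
        mean_freq = float(np.mean(list(means.values())))
        carrier_damage = float(np.mean([p.pct_ct for p in profiles_carriers])) / 100.0
        if mean_freq <= damage_factor * carrier_damage:
            verdict = "artifact"
            reason = (
                f"alt frequency {mean_freq:.3f} is commensurate with the "
                f"measured C->T damage rate {carrier_damage:.3f}"
            )
        else:
            verdict, reason = "inconclusive", "sub-het frequencies exceed damage expectation"
    else:
        verdict = "inconclusive"
        failed = []
        if not damage_pass:
            failed.append("damage association")
        if not concordance_pass:
            failed.append("replicate concordance")
        reason = "failed: " + ", ".join(failed)

    return AuthenticationVerdict(
        variant=variant,
        damage_association_pass=damage_pass,
        replicate_concordance_pass=concordance_pass,
        frequency_level_pass=frequency_pass,
        verdict=verdict,
        reason=reason,
    )
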