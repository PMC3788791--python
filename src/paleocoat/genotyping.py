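"""Replicate-concordant diploid genotype calling from amplicon pileups.

A sample's allelic state at a locus is read off the alt-allele frequency of
each independent amplification product.  With ~400 reads per product a
heterozygote sits near 50% with a binomial standard error of ~2.5%, while
deamination artifacts stay in the low single digits, so simple frequency
windows separate the states:

* ``f < t_low`` (default 0.10)          -> homozygous reference
* ``t_het_low <= f < t_het_high``       -> heterozygous (defaults 0.25/0.75)
* ``f >= t_het_high``                   -> homozygous alternate
* ``t_low <= f < t_het_low``            -> ambiguous (excluded from the vote)

The het lower bound anchors to the published 25-100% carrier frequency
range; the hom-ref ceiling sits above plausible deamination but below the
het window.  A call is issued only when at least ``min_replicates``
non-ambiguous products exist and all of them agree; anything else is ND —
the deliberate failure mode, mirroring the requirement of at least two
independent amplifications per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .locus_model import (
    LocusDefinition,
    ReplicateReadSet,
    Zygosity,
    loci_by_gene,
    zygosity_to_state,
)
from .read_alignment import AlignmentScoring, DEFAULT_SCORING, PileupMatrix, build_pileup

__all__ = [
    "CallThresholds",
    "GenotypeCall",
    "alt_frequency",
    "classify_frequency",
    "call_genotype",
    "genotype_cohort",
]

logger = logging.getLogger(__name__)

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CallThresholds:
    """Frequency windows for replicate classification."""

    t_low: float = 0.10
    t_het_low: float = 0.25
    t_het_high: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_low <= self.t_het_low <= self.t_het_high <= 1.0:
            raise ValueError("thresholds must satisfy 0 <= t_low <= t_het_low <= t_het_high <= 1")


DEFAULT_THRESHOLDS = CallThresholds()


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid allelic state at one locus for one sample."""

    sample_id: str
    locus: str
    zygosity: Zygosity
    alleles: tuple[str, str] | None  # printed labels, None iff ND
    replicate_freqs: tuple[float, ...]
    n_replicates_positive: int
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.alleles is None) != (self.zygosity is Zygosity.ND):
            raise ValueError("allele pair must be absent exactly when zygosity is ND")
        if any(not 0.0 <= f <= 1.0 for f in self.replicate_freqs):
            raise ValueError("replicate frequencies must lie in [0, 1]")

    @property
    def state(self) -> str:
        return "ND" if self.alleles is None else "/".join(self.alleles)


def alt_frequency(pileup: PileupMatrix, locus: LocusDefinition) -> float:
    """Alt-allele frequency of one amplification product at one locus.

    SNP: alt-base count over ref+alt counts at the variant position.
    Deletion: reads whose alignment gaps the whole window over all reads.
    Zero coverage at the variant raises ``ValueError``.
    """
    if locus.variant_kind == "deletion":
        if pileup.n_reads == 0:
            raise ValueError(f"{locus.name}: no reads covering the variant window")
        return pileup.n_deletion_reads / pileup.n_reads
    pos = locus.variant_start
    col = pileup.counts[:, pos]
    ref_n = int(col[_BASE_IDX[locus.ref_allele]])
    alt_n = int(col[_BASE_IDX[locus.alt_allele]])
    if ref_n + alt_n == 0:
        raise ValueError(f"{locus.name}: zero ref+alt coverage at variant position {pos + 1}")
    return alt_n / (ref_n + alt_n)


def classify_frequency(f: float, thresholds: CallThresholds = DEFAULT_THRESHOLDS) -> Zygosity | str:
    """Classify one replicate's alt frequency, or return ``"ambiguous"``."""
    if f < thresholds.t_low:
        return Zygosity.HOM_REF
    if f < thresholds.t_het_low:
        return AMBIGUOUS
    if f < thresholds.t_het_high:
        return Zygosity.HET
    return Zygosity.HOM_ALT


def call_genotype(
    freqs: Sequence[float],
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    min_replicates: int = 2,
    *,
    sample_id: str = "",
    locus: LocusDefinition | None = None,
) -> GenotypeCall:
    """Combine per-replicate frequencies into one diploid call.

    Ambiguous-zone replicates are excluded from the agreement vote; the call
    is the shared class iff >= ``min_replicates`` non-ambiguous replicates
    exist and all agree, otherwise ND.  Never raises: ND is the failure mode.
    """
    classes = [classify_frequency(f, thresholds) for f in freqs]
    votes = [c for c in classes if c != AMBIGUOUS]
    locus_name = locus.name if locus is not None else ""
    if len(votes) < min_replicates:
        zyg, reason = Zygosity.ND, f"only {len(votes)} usable replicate(s)"
    elif len(set(votes)) > 1:
        zyg, reason = Zygosity.ND, "discordant replicates"
    else:
        zyg, reason = votes[0], "concordant replicates"
    alleles: tuple[str, str] | None = None
    if zyg is not Zygosity.ND and locus is not None:
        state = zygosity_to_state(zyg, locus)
        alleles = tuple(state.split("/"))  # type: ignore[assignment]
    elif zyg is not Zygosity.ND:
        generic = {Zygosity.HOM_REF: ("ref", "ref"), Zygosity.HET: ("ref", "alt"),
                   Zygosity.HOM_ALT: ("alt", "alt")}
        alleles = generic[zyg]
    return GenotypeCall(
        sample_id=sample_id,
        locus=locus_name,
        zygosity=zyg,
        alleles=alleles,
        replicate_freqs=tuple(float(f) for f in freqs),
        n_replicates_positive=len(freqs),
        reason=reason,
    )


def genotype_cohort(
    read_sets: Sequence[ReplicateReadSet],
    loci: Sequence[LocusDefinition],
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    min_replicates: int = 2,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    *,
    pileup_cache: dict | None = None,
) -> list[GenotypeCall]:
    """Call every sample x locus present in ``read_sets``.

    Pileups are built once per sample x amplicon x replicate and shared by
    co-located loci (the two Mc1r variants are called independently on the
    same pileups).  Per-sample failures are logged and yield ND; the cohort
    run never aborts.  ``pileup_cache`` (keyed by sample_id, gene,
    replicate_id) is filled when supplied, for reuse by damage profiling.
    """
    by_gene = loci_by_gene(loci)
    grouped: dict[tuple[str, str], list[ReplicateReadSet]] = {}
    sample_order: list[str] = []
    for rs in read_sets:
        key = (rs.sample_id, rs.locus)
        grouped.setdefault(key, []).append(rs)
        if rs.sample_id not in sample_order:
            sample_order.append(rs.sample_id)

    calls: list[GenotypeCall] = []
    for sample_id in sample_order:
        for gene in sorted(by_gene):
            gene_loci = by_gene[gene]
            reps = grouped.get((sample_id, gene), [])
            pileups: list[PileupMatrix] = []
            for rs in sorted(reps, key=lambda r: r.replicate_id):
                try:
                    p = build_pileup(rs, gene_loci[0], scoring)
                except ValueError as exc:
                    logger.warning("pileup failed for %s/%s rep %s: %s",
                                   sample_id, gene, rs.replicate_id, exc)
                    continue
                if pileup_cache is not None:
                    pileup_cache[(sample_id, gene, rs.replicate_id)] = p
                pileups.append(p)
            for locus in gene_loci:
                freqs: list[float] = []
                for p in pileups:
                    try:
                        freqs.append(alt_frequency(p, locus))
                    except ValueError as exc:
                        logger.warning("frequency failed for %s/%s: %s",
                                       sample_id, locus.name, exc)
                calls.append(
                    call_genotype(
                        freqs, thresholds, min_replicates,
                        sample_id=sample_id, locus=locus,
                    )
                )
    return calls
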