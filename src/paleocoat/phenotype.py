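"""Coat-color inference from Mc1r and K-locus genotypes, and cohort summaries.

Canid pigment-type switching involves an epistatic pair: loss-of-function
*Mc1r* (allele e, the R306ter stop) fixes phaeomelanin production and gives
recessive yellow regardless of everything else, while the dominant K-locus
allele K^B (the 3-nt *CBD103* deletion) forces eumelanin — black — whenever
at least one functional Mc1r copy (E) is present.  Wild type at both loci
gives the banded agouti pattern.  Rule precedence:

1. R306ter e/e                       -> recessive yellow (masks the K locus)
2. >=1 K^B and >=1 E                 -> black (K^B is dominant)
3. K^y/K^y and >=1 E                 -> agouti / wild type
4. a genotype needed by the first applicable rule is ND -> undetermined

The new R301C substitution never enters the rules: its effect on coat color
alone is not established.  The agouti phenotype carries the display alias
"Yellow (wild type)" used by the cohort table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .locus_model import CohortTable, Zygosity

__all__ = [
    "Phenotype",
    "CoatColorCall",
    "CohortSummary",
    "infer_coat_color",
    "phenotype_table",
    "summarize_cohort",
    "PHENOTYPE_DISPLAY",
]


class Phenotype(str, enum.Enum):
    BLACK = "black"
    AGOUTI_WILD_TYPE = "agouti_wild_type"
    RECESSIVE_YELLOW = "recessive_yellow"
    UNDETERMINED = "undetermined"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: printed labels matching the cohort table ("?" for undetermined)
PHENOTYPE_DISPLAY = {
    Phenotype.BLACK: "Black",
    Phenotype.AGOUTI_WILD_TYPE: "Yellow (wild type)",
    Phenotype.RECESSIVE_YELLOW: "Yellow (recessive)",
    Phenotype.UNDETERMINED: "?",
}


@dataclass(frozen=True)
class CoatColorCall:
    sample_id: str
    phenotype: Phenotype
    rule_fired: str

    @property
    def display(self) -> str:
        return PHENOTYPE_DISPLAY[self.phenotype]


def _zygosity_of(value) -> Zygosity:
    if isinstance(value, Zygosity):
        return value
    zyg = getattr(value, "zygosity", None)
    if isinstance(zyg, Zygosity):
        return zyg
    raise TypeError(f"expected Zygosity or GenotypeCall, got {type(value)!r}")


def infer_coat_color(r306ter, k_locus, sample_id: str = "") -> CoatColorCall:
    """Hypothetical coat color from R306ter and K-locus allelic states.

    Accepts :class:`~paleocoat.locus_model.Zygosity` values or
    :class:`~paleocoat.genotyping.GenotypeCall` objects.  Every pair in
    {hom_ref, het, hom_alt, ND}^2 maps to exactly one phenotype.
    """
    z_mc1r = _zygosity_of(r306ter)
    z_k = _zygosity_of(k_locus)
    if z_mc1r is Zygosity.ND:
        return CoatColorCall(sample_id, Phenotype.UNDETERMINED, "R306ter undetermined")
    if z_mc1r is Zygosity.HOM_ALT:
        # e/e masks the K locus entirely (no e allele occurs in the packaged
        # cohort, so this branch is exercised only by constructed genotypes)
        return CoatColorCall(sample_id, Phenotype.RECESSIVE_YELLOW, "e/e (recessive yellow, K locus masked)")
    if z_k is Zygosity.ND:
        return CoatColorCall(sample_id, Phenotype.UNDETERMINED, "K locus undetermined")
    if z_k in (Zygosity.HET, Zygosity.HOM_ALT):
        return CoatColorCall(sample_id, Phenotype.BLACK, "dominant K^B with functional Mc1r")
    return CoatColorCall(sample_id, Phenotype.AGOUTI_WILD_TYPE, "wild type at both loci")


def phenotype_table(cohort: CohortTable) -> list[CoatColorCall]:
    """One coat-color call per cohort row, in row order."""
    return [
        infer_coat_color(
            cohort.zygosity(rec.sample_id, "mc1r_r306ter"),
            cohort.zygosity(rec.sample_id, "cbd103_k"),
            sample_id=rec.sample_id,
        )
        for rec in cohort.samples
    ]


@dataclass
class CohortSummary:
    """Determined-genotype, carrier and phenotype tallies for a cohort."""

    n_samples: int = 0
    mc1r_determined: int = 0
    cbd103_determined: int = 0
    both_loci_determined: int = 0
    r301c_carriers: int = 0
    r301c_homozygous: int = 0
    r301c_heterozygous: int = 0
    black_total: int = 0
    black_dog_morphotype: int = 0
    black_wolf_morphotype: int = 0
    agouti_wild_type: int = 0
    recessive_yellow: int = 0
    phenotype_undetermined: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


def summarize_cohort(cohort: CohortTable) -> CohortSummary:
    """Tally determined genotypes, R301C carriers and inferred phenotypes."""
    s = CohortSummary(n_samples=len(cohort))
    calls = {c.sample_id: c for c in phenotype_table(cohort)}
    for rec in cohort.samples:
        z_301 = cohort.zygosity(rec.sample_id, "mc1r_r301c")
        z_306 = cohort.zygosity(rec.sample_id, "mc1r_r306ter")
        z_k = cohort.zygosity(rec.sample_id, "cbd103_k")
        mc1r_ok = z_306 is not Zygosity.ND
        k_ok = z_k is not Zygosity.ND
        s.mc1r_determined += mc1r_ok
        s.cbd103_determined += k_ok
        s.both_loci_determined += mc1r_ok and k_ok
        if z_301 in (Zygosity.HET, Zygosity.HOM_ALT):
            s.r301c_carriers += 1
            if z_301 is Zygosity.HOM_ALT:
                s.r301c_homozygous += 1
            else:
                s.r301c_heterozygous += 1
        ph = calls[rec.sample_id].phenotype
        if ph is Phenotype.BLACK:
            s.black_total += 1
            if rec.morphotype == "wolf":
                s.black_wolf_morphotype += 1
            else:
                s.black_dog_morphotype += 1
        elif ph is Phenotype.AGOUTI_WILD_TYPE:
            s.agouti_wild_type += 1
        elif ph is Phenotype.RECESSIVE_YELLOW:
            s.recessive_yellow += 1
        else:
            s.phenotype_undetermined += 1
    return s
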