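"""Locus definitions, sample metadata and cohort tables.

The pipeline targets two short nuclear amplicons from ancient canid remains:
a 79-nt fragment of *Mc1r* carrying the R301C and R306ter coding variants,
and a 76-nt fragment of *CBD103* carrying the in-frame 3-nt glycine-codon
deletion (the K-locus ``K^B`` allele).  This module holds the frozen domain
records describing those targets, plus the packaged cohort table that
transcribes the published allelic states of 23 ancient individuals.

Coordinates are 0-based half-open internally; human-readable reports convert
to 1-based inclusive positions.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "Zygosity",
    "LocusDefinition",
    "SampleRecord",
    "CohortTable",
    "ReplicateReadSet",
    "CohortParseError",
    "load_cohort_fixture",
    "write_cohort",
    "packaged_cohort",
    "builtin_loci",
    "load_loci",
    "state_to_zygosity",
    "zygosity_to_state",
    "LOCUS_COLUMNS",
    "COLUMN_TO_LOCUS",
]

#: cohort-table columns holding per-locus allelic states, in fixture order
LOCUS_COLUMNS = ("mc1r_r301c", "mc1r_r306ter", "cbd103_k")

#: fixture column -> packaged locus name
COLUMN_TO_LOCUS = {
    "mc1r_r301c": "MC1R_R301C",
    "mc1r_r306ter": "MC1R_R306ter",
    "cbd103_k": "CBD103_DG23",
}

ND = "ND"

_VALID_BASES = frozenset("ACGT")


class CohortParseError(ValueError):
    """Raised when a cohort fixture file cannot be parsed or validated."""


class Zygosity(str, enum.Enum):
    """Diploid allelic state at one locus."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    ND = "ND"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class LocusDefinition:
    """One target amplicon and the variant it carries.

    ``variant_start`` is 0-based in ``reference_seq``; ``variant_length`` is 1
    for a SNP and 3 for the in-frame deletion.  ``ref_label``/``alt_label``
    are the printed allele tokens (e.g. ``GGG`` / ``-`` for the K locus);
    ``ref_alias``/``alt_alias`` carry conventional allele names (``E``/``e``,
    ``K^y``/``K^B``) where the field uses them.
    """

    name: str
    gene: str
    reference_seq: str
    variant_kind: str  # "snp" | "deletion"
    variant_start: int
    variant_length: int
    ref_allele: str
    alt_allele: str
    ref_label: str
    alt_label: str
    ref_alias: str = ""
    alt_alias: str = ""

    def __post_init__(self) -> None:
        if self.variant_kind not in ("snp", "deletion"):
            raise ValueError(f"unknown variant_kind {self.variant_kind!r}")
        if not set(self.reference_seq) <= _VALID_BASES:
            raise ValueError(f"{self.name}: reference contains non-ACGT characters")
        window = self.reference_seq[self.variant_start : self.variant_start + self.variant_length]
        if window != self.ref_allele:
            raise ValueError(
                f"{self.name}: reference window {window!r} does not match ref_allele "
                f"{self.ref_allele!r}"
            )
        if self.variant_kind == "deletion":
            if self.alt_allele != "":
                raise ValueError(f"{self.name}: deletion allele must be empty")
            if self.variant_length != 3:
                raise ValueError(f"{self.name}: deletion window must span 3 nt")
        else:
            if len(self.ref_allele) != self.variant_length or len(self.alt_allele) != self.variant_length:
                raise ValueError(f"{self.name}: SNP alleles must match variant_length")

    @property
    def variant_window(self) -> range:
        """0-based half-open reference window of the variant."""
        return range(self.variant_start, self.variant_start + self.variant_length)

    @property
    def labels(self) -> tuple[str, str]:
        return (self.ref_label, self.alt_label)

    def allele_for_label(self, label: str) -> str:
        """Haplotype sequence fragment for an allele label (or alias)."""
        if label in (self.ref_label, self.ref_alias) and label:
            return self.ref_allele
        if label in (self.alt_label, self.alt_alias) and label:
            return self.alt_allele
        raise ValueError(f"{self.name}: unknown allele label {label!r}")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one ancient specimen."""

    sample_id: str
    morphotype: str  # "dog" | "wolf"
    site_name: str = ""
    site_number: str = ""
    dating: str = ""

    def __post_init__(self) -> None:
        if self.morphotype not in ("dog", "wolf"):
            raise ValueError(f"{self.sample_id}: morphotype must be dog or wolf")


@dataclass
class CohortTable:
    """Per-sample allelic-state strings for the three packaged loci.

    States are kept verbatim as printed tokens (``C/T``, ``GGG/-``, ``ND``)
    so the fixture round-trips byte-identically.
    """

    samples: list[SampleRecord] = field(default_factory=list)
    states: dict[str, dict[str, str]] = field(default_factory=dict)  # sample_id -> column -> state

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_id in cohort")

    def __len__(self) -> int:
        return len(self.samples)

    def state(self, sample_id: str, column: str) -> str:
        return self.states[sample_id][column]

    def zygosity(self, sample_id: str, column: str) -> Zygosity:
        return state_to_zygosity(self.state(sample_id, column), column)


@dataclass
class ReplicateReadSet:
    """Reads from one independent amplification product.

    ``locus`` names the amplicon (gene symbol); ``orientations`` holds
    ``"+"``/``"-"`` per read (sequences are stored in reference orientation,
    the flag records which strand the molecule was read from, which decides
    whether deamination appears as C->T or G->A).
    """

    sample_id: str
    locus: str
    replicate_id: int
    sequences: list[str]
    names: list[str] | None = None
    orientations: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.sequences)
        if self.names is not None and len(self.names) != n:
            raise ValueError("names/sequences length mismatch")
        if self.orientations is not None and len(self.orientations) != n:
            raise ValueError("orientations/sequences length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# allelic-state vocabulary


def _state_vocabulary(column: str) -> dict[str, Zygosity]:
    locus = {c: l for c, l in COLUMN_TO_LOCUS.items()}[column]
    ref, alt = _LOCUS_LABELS[locus]
    return {
        ND: Zygosity.ND,
        f"{ref}/{ref}": Zygosity.HOM_REF,
        f"{ref}/{alt}": Zygosity.HET,
        f"{alt}/{ref}": Zygosity.HET,
        f"{alt}/{alt}": Zygosity.HOM_ALT,
    }


_LOCUS_LABELS = {
    "MC1R_R301C": ("C", "T"),
    "MC1R_R306ter": ("C", "T"),
    "CBD103_DG23": ("GGG", "-"),
}


def state_to_zygosity(state: str, column: str) -> Zygosity:
    """Map a printed allelic-state token to a :class:`Zygosity`."""
    vocab = _state_vocabulary(column)
    try:
        return vocab[state]
    except KeyError:
        raise CohortParseError(f"unknown allelic state {state!r} for column {column!r}") from None


def zygosity_to_state(zyg: Zygosity, locus: LocusDefinition) -> str:
    ref, alt = locus.labels
    return {
        Zygosity.HOM_REF: f"{ref}/{ref}",
        Zygosity.HET: f"{ref}/{alt}",
        Zygosity.HOM_ALT: f"{alt}/{alt}",
        Zygosity.ND: ND,
    }[zyg]


# ---------------------------------------------------------------------------
# cohort fixture I/O

_COHORT_HEADER = (
    "sample_id",
    "morphotype",
    "site",
    "site_no",
    "dating",
    "mc1r_r301c",
    "mc1r_r306ter",
    "cbd103_k",
)


def load_cohort_fixture(path: str | Path) -> CohortTable:
    """Load a cohort allelic-state TSV, validating the closed state vocabulary.

    Raises :class:`CohortParseError` naming the offending line for malformed
    rows or out-of-vocabulary allele tokens.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise CohortParseError(f"{path}: empty cohort file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _COHORT_HEADER:
        raise CohortParseError(
            f"{path}: header {header!r} does not match expected {_COHORT_HEADER!r}"
        )
    samples: list[SampleRecord] = []
    states: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(_COHORT_HEADER):
            raise CohortParseError(
                f"{path}:{lineno}: expected {len(_COHORT_HEADER)} columns, got {len(cells)}"
            )
        row = dict(zip(_COHORT_HEADER, cells))
        try:
            rec = SampleRecord(
                sample_id=row["sample_id"],
                morphotype=row["morphotype"],
                site_name=row["site"],
                site_number=row["site_no"],
                dating=row["dating"],
            )
            row_states = {}
            for col in LOCUS_COLUMNS:
                state_to_zygosity(row[col], col)  # vocabulary check
                row_states[col] = row[col]
        except (ValueError, CohortParseError) as exc:
            raise CohortParseError(f"{path}:{lineno}: {exc}") from None
        if rec.sample_id in states:
            raise CohortParseError(f"{path}:{lineno}: duplicate sample_id {rec.sample_id}")
        samples.append(rec)
        states[rec.sample_id] = row_states
    return CohortTable(samples=samples, states=states)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table back to TSV (inverse of :func:`load_cohort_fixture`)."""
    path = Path(path)
    out = ["\t".join(_COHORT_HEADER)]
    for rec in cohort.samples:
        st = cohort.states[rec.sample_id]
        out.append(
            "\t".join(
                [
                    rec.sample_id,
                    rec.morphotype,
                    rec.site_name,
                    rec.site_number,
                    rec.dating,
                    st["mc1r_r301c"],
                    st["mc1r_r306ter"],
                    st["cbd103_k"],
                ]
            )
        )
    path.write_text("\n".join(out) + "\n")


def _data_path(name: str):
    return importlib.resources.files("paleocoat") / "data" / name


def packaged_cohort() -> CohortTable:
    """The packaged transcription of the published 23-individual cohort."""
    with importlib.resources.as_file(_data_path("cohort_table1.tsv")) as p:
        return load_cohort_fixture(p)


# ---------------------------------------------------------------------------
# locus definitions


def load_loci(fasta_path: str | Path, table_path: str | Path) -> list[LocusDefinition]:
    """Load locus definitions from an amplicon FASTA plus a variant TSV."""
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    loci = []
    lines = Path(table_path).read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        cells += [""] * (len(header) - len(cells))
        row = dict(zip(header, cells))
        gene = row["gene"]
        if gene not in refs:
            raise ValueError(f"locus table references unknown amplicon {gene!r}")
        loci.append(
            LocusDefinition(
                name=row["name"],
                gene=gene,
                reference_seq=refs[gene],
                variant_kind=row["variant_kind"],
                variant_start=int(row["variant_start"]),
                variant_length=int(row["variant_length"]),
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                ref_label=row["ref_label"],
                alt_label=row["alt_label"],
                ref_alias=row.get("ref_alias", ""),
                alt_alias=row.get("alt_alias", ""),
            )
        )
    return loci


def builtin_loci() -> list[LocusDefinition]:
    """The three packaged loci: MC1R_R301C, MC1R_R306ter, CBD103_DG23.

    The bundled amplicon sequences are synthetic stand-ins of the published
    lengths (79 nt Mc1r, 76 nt CBD103); every invariant of
    :class:`LocusDefinition` holds for them.
    """
    with importlib.resources.as_file(_data_path("synthetic_amplicons.fasta")) as fa, \
            importlib.resources.as_file(_data_path("loci.tsv")) as tsv:
        return load_loci(fa, tsv)


def loci_by_name(loci: Iterable[LocusDefinition]) -> dict[str, LocusDefinition]:
    return {l.name: l for l in loci}


def loci_by_gene(loci: Iterable[LocusDefinition]) -> dict[str, list[LocusDefinition]]:
    out: dict[str, list[LocusDefinition]] = {}
    for l in loci:
        out.setdefault(l.gene, []).append(l)
    return out
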