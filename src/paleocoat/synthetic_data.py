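"""Synthetic ancient-DNA amplicon read generation with known truth.

The study's raw 454 read pools were never deposited, only consensus
sequences; this module emulates them so every downstream stage is testable.
Each simulated sample gets >=1 independent amplification replicates per
amplicon at a fixed depth (defaults: 3 replicates of 422 reads, the
published per-amplicon average).  A read is drawn as follows:

1. sample a parental haplotype (allele 1 with probability ``allele_bias``);
   deletion haplotypes simply lack the 3-nt window;
2. sample an orientation (+/- with equal probability);
3. apply cytosine deamination independently per eligible site at rate
   ``deamination_rate`` (C->T on forward-orientation reads, G->A on
   reverse-orientation reads, in reference coordinates);
4. apply a uniform base-calling error at rate ``base_error_rate`` (each hit
   site is replaced by one of the three other bases uniformly).

Deamination is uniform along the read: the amplicons are only 76-79 nt and
the downstream damage statistics are per-sequence averages, so no
end-of-fragment elevation is modelled.  Reads are full-length (amplicons
are sequenced end to end) and FASTQ qualities are a constant 'I' (the
pipeline does not use them).  Identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .locus_model import LocusDefinition, ReplicateReadSet, loci_by_gene

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_sample",
    "simulate_cohort",
    "write_read_sets",
    "read_fastq_readset",
    "haplotype_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sample.

    ``genotypes`` maps locus name -> ordered pair of allele labels (e.g.
    ``{"MC1R_R301C": ("C", "T")}``); loci absent from the mapping default to
    homozygous reference.
    """

    genotypes: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    n_replicates: int = 3
    reads_per_replicate: int = 422
    deamination_rate: float = 0.02
    base_error_rate: float = 0.002
    allele_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("deamination_rate", self.deamination_rate),
            ("base_error_rate", self.base_error_rate),
            ("allele_bias", self.allele_bias),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.reads_per_replicate < 1:
            raise ValueError("reads_per_replicate must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    genotypes: dict[str, tuple[str, str]]  # locus name -> allele label pair
    #: per amplicon, per replicate: 0/1 index of each read's source allele
    read_alleles: dict[str, list[np.ndarray]] = field(default_factory=dict)


def haplotype_sequence(
    loci: Sequence[LocusDefinition], allele_labels: Mapping[str, str]
) -> str:
    """Build one haplotype of an amplicon from per-locus allele labels.

    All loci must share one reference sequence (one amplicon).  Deletion
    alleles remove their window; substitutions are applied in place.
    """
    ref = loci[0].reference_seq
    if any(l.reference_seq != ref for l in loci):
        raise ValueError("haplotype_sequence requires loci on a single amplicon")
    edits = []  # (start, end, replacement)
    for locus in loci:
        label = allele_labels.get(locus.name, locus.ref_label)
        frag = locus.allele_for_label(label)
        edits.append((locus.variant_start, locus.variant_start + locus.variant_length, frag))
    seq = ref
    for start, end, frag in sorted(edits, reverse=True):
        seq = seq[:start] + frag + seq[end:]
    return seq


def _mutate_reads(
    hap: str, k: int, orient: str, delta: float, eps: float, rng: np.random.Generator
) -> list[str]:
    """Vectorised damage + error application to ``k`` copies of a haplotype."""
    base = _ENC[np.frombuffer(hap.encode("ascii"), dtype=np.uint8)]
    mat = np.tile(base, (k, 1))
    L = base.size
    if delta > 0:
        eligible = base == (1 if orient == "+" else 2)  # C on +, G on -
        hit = (rng.random((k, L)) < delta) & eligible
        mat[hit] = 3 if orient == "+" else 0  # C->T on +, G->A on -
    if eps > 0:
        err = rng.random((k, L)) < eps
        shift = rng.integers(1, 4, size=(k, L), dtype=np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat)
    out = _BASES[mat]
    return [bytes(row).decode("ascii") for row in out]


def simulate_sample(
    loci: Sequence[LocusDefinition],
    cfg: SimulationConfig,
    sample_id: str = "S0",
) -> tuple[list[ReplicateReadSet], TruthRecord]:
    """Simulate all replicates of all amplicons for one sample.

    Returns one :class:`ReplicateReadSet` per amplicon x replicate plus a
    :class:`TruthRecord`.  Unknown allele labels raise ``ValueError``.
    """
    by_gene = loci_by_gene(loci)
    # validate labels up front
    genotypes: dict[str, tuple[str, str]] = {}
    by_name = {l.name: l for l in loci}
    for name, pair in cfg.genotypes.items():
        if name not in by_name:
            raise ValueError(f"genotype given for unknown locus {name!r}")
        locus = by_name[name]
        if len(pair) != 2:
            raise ValueError(f"{name}: genotype must be an allele pair")
        for label in pair:
            locus.allele_for_label(label)  # raises on unknown labels
        genotypes[name] = (pair[0], pair[1])
    for locus in loci:
        genotypes.setdefault(locus.name, (locus.ref_label, locus.ref_label))

    rng = np.random.default_rng(cfg.seed)
    read_sets: list[ReplicateReadSet] = []
    truth = TruthRecord(sample_id=sample_id, genotypes=genotypes)

    for gene in sorted(by_gene):
        gene_loci = by_gene[gene]
        haps = [
            haplotype_sequence(gene_loci, {l.name: genotypes[l.name][h] for l in gene_loci})
            for h in (0, 1)
        ]
        truth.read_alleles[gene] = []
        for rep in range(1, cfg.n_replicates + 1):
            n = cfg.reads_per_replicate
            allele = np.where(rng.random(n) < cfg.allele_bias, 0, 1).astype(np.int8)
            orient = np.where(rng.random(n) < 0.5, "+", "-")
            seqs: list[str | None] = [None] * n
            for h in (0, 1):
                for o in ("+", "-"):
                    idx = np.flatnonzero((allele == h) & (orient == o))
                    if idx.size == 0:
                        continue
                    reads = _mutate_reads(
                        haps[h], idx.size, o, cfg.deamination_rate,
                        cfg.base_error_rate, rng,
                    )
                    for i, r in zip(idx, reads):
                        seqs[i] = r
            names = [
                f"{sample_id}:{gene}:rep{rep}:{i}:{orient[i]}" for i in range(n)
            ]
            read_sets.append(
                ReplicateReadSet(
                    sample_id=sample_id,
                    locus=gene,
                    replicate_id=rep,
                    sequences=seqs,  # type: ignore[arg-type]
                    names=names,
                    orientations=list(orient),
                )
            )
            truth.read_alleles[gene].append(allele)
    return read_sets, truth


def simulate_cohort(
    scenario: Sequence[tuple[str, Mapping[str, tuple[str, str]]]],
    loci: Sequence[LocusDefinition],
    base_cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[ReplicateReadSet], list[TruthRecord]]:
    """Simulate many samples from a scenario table.

    ``scenario`` is a sequence of ``(sample_id, genotypes)`` pairs; each
    sample gets a seed derived deterministically from ``seed``, so a rerun
    with the same master seed is byte-identical.  Duplicate sample ids are
    rejected; an empty scenario yields empty outputs.
    """
    ids = [sid for sid, _ in scenario]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample_id in scenario")
    base = base_cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=len(scenario))
    all_reads: list[ReplicateReadSet] = []
    truths: list[TruthRecord] = []
    for (sample_id, genotypes), s in zip(scenario, sample_seeds):
        cfg = SimulationConfig(
            genotypes=dict(genotypes),
            n_replicates=base.n_replicates,
            reads_per_replicate=base.reads_per_replicate,
            deamination_rate=base.deamination_rate,
            base_error_rate=base.base_error_rate,
            allele_bias=base.allele_bias,
            seed=int(s),
        )
        reads, truth = simulate_sample(loci, cfg, sample_id=sample_id)
        all_reads.extend(reads)
        truths.append(truth)
    return all_reads, truths


# ---------------------------------------------------------------------------
# FASTQ I/O


def write_read_sets(read_sets: Iterable[ReplicateReadSet], out_dir: str | Path) -> list[Path]:
    """Write one FASTQ per sample x amplicon x replicate (constant 'I' quality)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rs in read_sets:
        path = out_dir / f"{rs.sample_id}.{rs.locus}.rep{rs.replicate_id}.fastq"
        names = rs.names or [
            f"{rs.sample_id}:{rs.locus}:rep{rs.replicate_id}:{i}:+" for i in range(len(rs))
        ]
        records = [
            SeqRecord(
                Seq(seq),
                id=name,
                description="",
                letter_annotations={"phred_quality": [40] * len(seq)},
            )
            for name, seq in zip(names, rs.sequences)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fastq")
        paths.append(path)
    return paths


def read_fastq_readset(path: str | Path) -> ReplicateReadSet:
    """Load one replicate FASTQ written by :func:`write_read_sets`.

    The filename encodes ``sample.locus.repN.fastq``; read orientation is the
    trailing ``:+``/``:-`` field of each read name (defaulting to ``+``).
    """
    from Bio import SeqIO

    path = Path(path)
    stem = path.name
    if stem.endswith(".fastq"):
        stem = stem[: -len(".fastq")]
    parts = stem.rsplit(".", 2)
    if len(parts) != 3 or not parts[2].startswith("rep"):
        raise ValueError(f"{path}: filename does not match sample.locus.repN.fastq")
    sample_id, locus, rep = parts[0], parts[1], int(parts[2][3:])
    names, seqs, orients = [], [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
        orient = rec.id.rsplit(":", 1)[-1]
        orients.append(orient if orient in "+-" and orient else "+")
    return ReplicateReadSet(
        sample_id=sample_id,
        locus=locus,
        replicate_id=rep,
        sequences=seqs,
        names=names,
        orientations=orients,
    )
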