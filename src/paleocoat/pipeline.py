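"""End-to-end orchestration: simulate -> pileup -> genotype -> damage ->
authenticate -> phenotype -> summarize, with fixed-seed reproducibility.

``run_full`` executes the whole chain on a scenario table and writes the
TSV reports plus a manifest (config hash, package versions, per-stage row
counts).  ``run_table1_reproduction`` recomputes phenotype calls and
summary counts from the packaged 23-individual cohort table and checks
them against the bundled golden file cell by cell.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .damage_profile import authenticate_variant, consensus_from_pileups, estimate_damage
from .genotyping import CallThresholds, GenotypeCall, genotype_cohort
from .locus_model import (
    COLUMN_TO_LOCUS,
    CohortTable,
    LocusDefinition,
    SampleRecord,
    Zygosity,
    builtin_loci,
    loci_by_gene,
    packaged_cohort,
    zygosity_to_state,
)
from .phenotype import phenotype_table, summarize_cohort
from .synthetic_data import SimulationConfig, simulate_cohort, write_read_sets

__all__ = [
    "RunConfig",
    "TableReproReport",
    "load_scenario",
    "run_full",
    "run_table1_reproduction",
]

logger = logging.getLogger(__name__)

REPORT_NAMES = (
    "truth.tsv",
    "genotypes.tsv",
    "replicate_frequencies.tsv",
    "damage.tsv",
    "authentication.tsv",
    "phenotypes.tsv",
    "summary.tsv",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML key-value file)."""

    scenario: str = "packaged:demo_scenario.tsv"
    seed: int = 0
    n_replicates: int = 3
    reads_per_replicate: int = 422
    deamination_rate: float = 0.02
    base_error_rate: float = 0.002
    allele_bias: float = 0.5
    threshold_hom_ref: float = 0.10
    threshold_het_low: float = 0.25
    threshold_het_high: float = 0.75
    min_replicates: int = 2
    alpha: float = 0.05
    concordance_tol: float = 0.25
    write_reads: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    @property
    def thresholds(self) -> CallThresholds:
        return CallThresholds(
            t_low=self.threshold_hom_ref,
            t_het_low=self.threshold_het_low,
            t_het_high=self.threshold_het_high,
        )

    def validate(self) -> None:
        """Check referenced paths before any stage runs."""
        if not self.scenario.startswith("packaged:") and not Path(self.scenario).exists():
            raise FileNotFoundError(f"scenario file not found: {self.scenario}")
        self.thresholds  # range-checks the frequency windows


def _packaged(name: str):
    return importlib.resources.as_file(importlib.resources.files("paleocoat") / "data" / name)


def load_scenario(path_or_tag: str) -> list[tuple[str, dict[str, tuple[str, str]]]]:
    """Load a simulation scenario TSV (columns: sample_id + per-locus states).

    States use the printed allele tokens, e.g. ``C/T`` or ``GGG/-``; the
    ``packaged:`` prefix addresses bundled scenarios.
    """
    if path_or_tag.startswith("packaged:"):
        with _packaged(path_or_tag.split(":", 1)[1]) as p:
            text = Path(p).read_text()
    else:
        text = Path(path_or_tag).read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise ValueError("scenario header must start with sample_id")
    locus_cols = [c for c in header[1:] if c in COLUMN_TO_LOCUS]
    out = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        genotypes = {}
        for col in locus_cols:
            state = row[col]
            if state == "ND":
                continue
            a, b = state.split("/")
            genotypes[COLUMN_TO_LOCUS[col]] = (a, b)
        out.append((row["sample_id"], genotypes))
    return out


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> int:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return len(rows)


def _versions() -> dict[str, str]:
    import Bio
    import numpy
    import pandas
    import scipy

    return {
        "paleocoat": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "biopython": Bio.__version__,
    }


def run_full(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage on the configured scenario and write all reports.

    Deterministic given ``cfg.seed``: a rerun produces byte-identical
    reports.  Stage failures propagate after partial outputs are retained.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loci = builtin_loci()
    by_gene = loci_by_gene(loci)
    row_counts: dict[str, int] = {}

    scenario = load_scenario(cfg.scenario)
    sim_cfg = SimulationConfig(
        n_replicates=cfg.n_replicates,
        reads_per_replicate=cfg.reads_per_replicate,
        deamination_rate=cfg.deamination_rate,
        base_error_rate=cfg.base_error_rate,
        allele_bias=cfg.allele_bias,
    )
    read_sets, truths = simulate_cohort(scenario, loci, sim_cfg, seed=cfg.seed)
    row_counts["truth.tsv"] = _write_tsv(
        out / "truth.tsv",
        ["sample_id", "locus", "allele_1", "allele_2"],
        [
            (t.sample_id, name, pair[0], pair[1])
            for t in truths
            for name, pair in sorted(t.genotypes.items())
        ],
    )
    if cfg.write_reads:
        write_read_sets(read_sets, out / "reads")

    pileup_cache: dict = {}
    calls = genotype_cohort(
        read_sets, loci, cfg.thresholds, cfg.min_replicates, pileup_cache=pileup_cache
    )
    row_counts["genotypes.tsv"] = _write_tsv(
        out / "genotypes.tsv",
        ["sample_id", "locus", "allelic_state", "zygosity", "n_replicates", "reason"],
        [
            (c.sample_id, c.locus, c.state, c.zygosity.value, c.n_replicates_positive, c.reason)
            for c in calls
        ],
    )
    row_counts["replicate_frequencies.tsv"] = _write_tsv(
        out / "replicate_frequencies.tsv",
        ["sample_id", "locus", "replicate", "pct_alt_reads"],
        [
            (c.sample_id, c.locus, i + 1, f"{100 * f:.2f}")
            for c in calls
            for i, f in enumerate(c.replicate_freqs)
        ],
    )

    # damage profiles per sample x amplicon; on the shared Mc1r amplicon both
    # variant windows are excluded from the statistics
    profiles: dict[tuple[str, str], object] = {}
    sample_ids = [t.sample_id for t in truths]
    damage_rows = []
    for sample_id in sample_ids:
        for gene in sorted(by_gene):
            reps = [
                p for (sid, g, _rep), p in sorted(pileup_cache.items())
                if sid == sample_id and g == gene
            ]
            if not reps:
                continue
            gene_loci = by_gene[gene]
            lead = gene_loci[0]
            extra = [p for l in gene_loci[1:] for p in l.variant_window]
            consensus = consensus_from_pileups(reps, lead)
            try:
                prof = estimate_damage(
                    reps, lead, consensus, extra_exclude=extra, sample_id=sample_id
                )
            except ValueError as exc:
                logger.warning("damage profile failed for %s/%s: %s", sample_id, gene, exc)
                continue
            profiles[(sample_id, gene)] = prof
            damage_rows.append(
                (sample_id, gene, f"{prof.pct_degraded:.4f}", f"{prof.pct_ct:.4f}",
                 prof.n_observations)
            )
    row_counts["damage.tsv"] = _write_tsv(
        out / "damage.tsv",
        ["sample_id", "locus", "pct_degraded", "pct_ct", "n_observations"],
        damage_rows,
    )

    # authenticate the R301C candidate against deamination
    call_by = {(c.sample_id, c.locus): c for c in calls}
    carriers = [
        s for s in sample_ids
        if call_by.get((s, "MC1R_R301C"))
        and call_by[(s, "MC1R_R301C")].zygosity in (Zygosity.HET, Zygosity.HOM_ALT)
    ]
    noncarriers = [
        s for s in sample_ids
        if call_by.get((s, "MC1R_R301C"))
        and call_by[(s, "MC1R_R301C")].zygosity is Zygosity.HOM_REF
    ]
    verdict = authenticate_variant(
        [profiles[(s, "MC1R")] for s in carriers if (s, "MC1R") in profiles],
        [profiles[(s, "MC1R")] for s in noncarriers if (s, "MC1R") in profiles],
        {s: call_by[(s, "MC1R_R301C")].replicate_freqs for s in carriers},
        variant="MC1R_R301C",
        alpha=cfg.alpha,
        concordance_tol=cfg.concordance_tol,
        het_lower=cfg.threshold_het_low,
    )
    row_counts["authentication.tsv"] = _write_tsv(
        out / "authentication.tsv",
        ["variant", "damage_association_pass", "replicate_concordance_pass",
         "frequency_level_pass", "verdict", "reason"],
        [(verdict.variant, verdict.damage_association_pass,
          verdict.replicate_concordance_pass, verdict.frequency_level_pass,
          verdict.verdict, verdict.reason)],
    )

    # phenotype + summary from the genotype calls
    cohort = cohort_from_calls(calls, sample_ids, loci)
    pheno = phenotype_table(cohort)
    row_counts["phenotypes.tsv"] = _write_tsv(
        out / "phenotypes.tsv",
        ["sample_id", "mc1r_r306ter", "cbd103_k", "coat_color", "rule_fired"],
        [
            (p.sample_id, cohort.state(p.sample_id, "mc1r_r306ter"),
             cohort.state(p.sample_id, "cbd103_k"), p.display, p.rule_fired)
            for p in pheno
        ],
    )
    summary = summarize_cohort(cohort)
    row_counts["summary.tsv"] = _write_tsv(
        out / "summary.tsv",
        ["key", "value"],
        list(summary.as_dict().items()),
    )

    config_json = json.dumps(asdict(cfg), sort_keys=True)
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": _versions(),
        "row_counts": row_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def cohort_from_calls(
    calls: Sequence[GenotypeCall],
    sample_ids: Sequence[str],
    loci: Sequence[LocusDefinition],
    morphotypes: Mapping[str, str] | None = None,
) -> CohortTable:
    """Assemble a cohort table of printed allelic states from genotype calls."""
    by_name = {l.name: l for l in loci}
    call_by = {(c.sample_id, c.locus): c for c in calls}
    samples = [
        SampleRecord(sample_id=s, morphotype=(morphotypes or {}).get(s, "dog"))
        for s in sample_ids
    ]
    states = {}
    for s in sample_ids:
        row = {}
        for col, locus_name in COLUMN_TO_LOCUS.items():
            call = call_by.get((s, locus_name))
            zyg = call.zygosity if call else Zygosity.ND
            row[col] = zygosity_to_state(zyg, by_name[locus_name])
        states[s] = row
    return CohortTable(samples=samples, states=states)


@dataclass
class TableReproReport:
    """Cell-by-cell comparison of recomputed cohort results vs the golden file."""

    ok: bool
    mismatches: list[str] = field(default_factory=list)
    phenotypes: dict[str, str] = field(default_factory=dict)
    summary: dict[str, int] = field(default_factory=dict)


def run_table1_reproduction(out_dir: str | Path | None = None) -> TableReproReport:
    """Recompute the packaged cohort's phenotype column and summary counts.

    Every cell is compared against the bundled golden file; mismatching
    cells are listed in the report.  Optionally writes the recomputed
    tables to ``out_dir``.
    """
    cohort = packaged_cohort()
    pheno = {p.sample_id: p.display for p in phenotype_table(cohort)}
    summary = summarize_cohort(cohort).as_dict()

    with _packaged("table1_golden.tsv") as p:
        lines = Path(p).read_text().splitlines()
    golden_pheno: dict[str, str] = {}
    golden_summary: dict[str, int] = {}
    for line in lines[1:]:
        section, key, value = line.split("\t")
        if section == "phenotype":
            golden_pheno[key] = value
        else:
            golden_summary[key] = int(value)

    mismatches = []
    for sid, expected in golden_pheno.items():
        got = pheno.get(sid, "<missing>")
        if got != expected:
            mismatches.append(f"phenotype[{sid}]: expected {expected!r}, got {got!r}")
    for sid in set(pheno) - set(golden_pheno):
        mismatches.append(f"phenotype[{sid}]: unexpected extra row")
    for key, expected in golden_summary.items():
        got = summary.get(key)
        if got != expected:
            mismatches.append(f"summary[{key}]: expected {expected}, got {got}")

    report = TableReproReport(
        ok=not mismatches, mismatches=mismatches, phenotypes=pheno, summary=summary
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(out / "table1_phenotypes.tsv", ["sample_id", "coat_color"],
                   list(pheno.items()))
        _write_tsv(out / "table1_summary.tsv", ["key", "value"], list(summary.items()))
    return report
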