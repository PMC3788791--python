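"""Shared fixtures: packaged loci and small simulation helpers."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import paleocoat as pc
from paleocoat.damage_profile import consensus_from_pileups, estimate_damage
from paleocoat.genotyping import alt_frequency
from paleocoat.locus_model import ReplicateReadSet
from paleocoat.read_alignment import build_pileup

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def loci():
    return pc.builtin_loci()


@pytest.fixture(scope="session")
def loci_by_name(loci):
    return {l.name: l for l in loci}


@pytest.fixture(scope="session")
def mc1r_loci(loci):
    return [l for l in loci if l.gene == "MC1R"]


@pytest.fixture(scope="session")
def k_locus(loci_by_name):
    return loci_by_name["CBD103_DG23"]


def make_readset(seqs, orientations=None, sample_id="S0", locus="MC1R", rep=1):
    return ReplicateReadSet(
        sample_id=sample_id,
        locus=locus,
        replicate_id=rep,
        sequences=list(seqs),
        orientations=list(orientations) if orientations is not None else None,
    )


def mc1r_damage_profiles(
    mc1r_loci,
    genotypes: list[dict],
    *,
    delta: float,
    reads: int,
    reps: int,
    seed: int,
    eps: float = 0.0,
):
    """Simulate Mc1r-only samples and return (profiles, R301C replicate freqs).

    Both Mc1r variant windows are excluded from the damage statistics.
    """
    lead = mc1r_loci[0]
    extra = [p for l in mc1r_loci[1:] for p in l.variant_window]
    r301c = next(l for l in mc1r_loci if l.name == "MC1R_R301C")
    profiles, freqs = [], []
    scenario = [(f"S{i}", g) for i, g in enumerate(genotypes)]
    cfg = pc.SimulationConfig(
        n_replicates=reps, reads_per_replicate=reads,
        deamination_rate=delta, base_error_rate=eps,
    )
    read_sets, _ = pc.simulate_cohort(scenario, mc1r_loci, cfg, seed=seed)
    by_sample: dict[str, list] = {}
    for rs in read_sets:
        by_sample.setdefault(rs.sample_id, []).append(rs)
    for sid, _g in scenario:
        piles = [build_pileup(rs, lead) for rs in sorted(by_sample[sid], key=lambda r: r.replicate_id)]
        cons = consensus_from_pileups(piles, lead)
        profiles.append(
            estimate_damage(piles, lead, cons, extra_exclude=extra, sample_id=sid)
        )
        freqs.append([alt_frequency(p, r301c) for p in piles])
    return profiles, freqs
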