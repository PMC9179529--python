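"""Sensitivity and specificity harnesses for the DMR caller.

These run the full generator -> pooling -> window-scan path on small
planted studies, measuring how often a planted differential region is
recovered (sensitivity across seeds) and how often pure sampling noise
is flagged (specificity across many null windows).
"""

from __future__ import annotations

from dataclasses import replace

from . import dmr as dmrm
from .simulate import PlantedDMR, SimulationConfig, simulate_study

#: planted region sits in intergenic space, clear of both gene slots
_RECOVERY_REGION = ("chr1", 25_201, 26_100)


def _recovery_config(seed: int, delta: float, coverage: float,
                     n_replicates: int) -> SimulationConfig:
    chrom, start, end = _RECOVERY_REGION
    return SimulationConfig(
        seed=seed, n_chroms=1, chrom_length_bp=60_000, n_genes=2,
        gene_length_range=(3_000, 5_000), n_repeats={},
        groups=(("DM", "tail_fat", n_replicates), ("MG", "tail_fat", n_replicates)),
        mean_coverage=coverage, contexts=("CG",),
        planted_dmrs=(PlantedDMR(chrom, start, end, "DM", "MG", -abs(delta)),))


def _pooled_pair(study, group_a: str, group_b: str):
    reps = {g: [] for g in (group_a, group_b)}
    for s in study.truth["samples"]:
        if s["group"] in reps:
            reps[s["group"]].append(study.calls[s["sample_id"]])
    return (dmrm.pool_group(reps[group_a]), dmrm.pool_group(reps[group_b]))


def planted_dmr_recovery_rate(n_seeds: int = 50, delta: float = 0.4,
                              coverage: float = 20.0, n_replicates: int = 3,
                              base_seed: int = 0) -> float:
    """Fraction of seeds in which a DMR call overlaps the planted region."""
    chrom, start, end = _RECOVERY_REGION
    hits = 0
    for i in range(n_seeds):
        cfg = _recovery_config(base_seed * 1_000 + i, delta, coverage, n_replicates)
        study = simulate_study(cfg)
        a, b = _pooled_pair(study, "DM", "MG")
        calls = dmrm.call_dmrs(a, b, study.genome.chrom_lengths, "DM", "MG")
        if any(d.chrom == chrom and d.start <= end and d.end >= start for d in calls):
            hits += 1
    return hits / n_seeds


def null_false_flag_rate(seed: int = 0, chrom_length_bp: int = 3_210_000,
                         coverage: float = 20.0,
                         n_replicates: int = 3) -> tuple[float, int]:
    """(fraction of windows flagged, windows compared) with no planted
    difference — both groups share every latent level."""
    cfg = SimulationConfig(
        seed=seed, n_chroms=1, chrom_length_bp=chrom_length_bp, n_genes=2,
        gene_length_range=(5_000, 8_000), n_repeats={},
        groups=(("DM", "tail_fat", n_replicates), ("MG", "tail_fat", n_replicates)),
        mean_coverage=coverage, contexts=("CG",))
    study = simulate_study(cfg)
    a, b = _pooled_pair(study, "DM", "MG")
    lengths = study.genome.chrom_lengths
    n_windows = sum(1 for _ in dmrm.scan_windows(lengths))
    flagged = dmrm.call_dmrs(a, b, lengths, "DM", "MG")
    return len(flagged) / n_windows, n_windows
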