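import numpy as np
import pandas as pd
import pytest

from methkit import core
from methkit.simulate import PlantedDMR, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """A small two-chromosome study with two 3-replicate groups, planted
    promoter classes, repeats of all families, and one planted DMR in
    clear intergenic space (chr1:42,001-42,900, DM vs MG, delta -0.4)."""
    cfg = SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length_bp=600_000,
        n_genes=24,
        gene_length_range=(6_000, 10_000),
        n_repeats={"LINE": 10, "SINE": 40, "LTR": 10, "Simple": 40},
        groups=(("DM", "tail_fat", 3), ("MG", "tail_fat", 3)),
        planted_dmrs=(PlantedDMR("chr1", 42_001, 42_900, "DM", "MG", -0.4),),
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def dm_sites(study):
    """Pooled coverage-filtered sites of the DM group's replicates."""
    frames = [study.calls[s] for s in ("DM_r1", "DM_r2", "DM_r3")]
    return core.filter_sites(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    """The same study written to disk (FASTA, GFF3, BED, CGmaps, truth)."""
    from methkit.simulate import write_calls, write_genome
    import json, os

    d = tmp_path_factory.mktemp("study")
    paths = write_genome(study.genome, d)
    paths.update(write_calls(study.calls, d))
    tj = os.path.join(d, "truth.json")
    with open(tj, "w") as fh:
        json.dump(study.truth, fh)
    paths["truth"] = tj
    return paths


def make_sites(rows):
    """Site table from (chrom, pos, context, level[, meth, total]) tuples."""
    full = []
    for r in rows:
        chrom, pos, ctx, level = r[:4]
        meth, total = (r[4], r[5]) if len(r) > 4 else (round(level * 10), 10)
        full.append((chrom, pos, "+", ctx, level, meth, total))
    return pd.DataFrame(full, columns=["chrom", "pos", "strand", "context",
                                       "level", "meth", "total"])


def random_sites(rng, n, chrom="chr1", span=100_000, context="CG"):
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n, replace=False))
    total = rng.integers(3, 40, size=n)
    meth = rng.binomial(total, rng.random(n))
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "strand": "+", "context": context,
        "level": meth / total, "meth": meth, "total": total,
    })
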