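"""Synthetic WGBS study generator.

Produces a complete toy study — genome FASTA, gene GFF3, repeat BED and
one CGmap call file per biological replicate — whose downstream structure
emulates a two-breed sheep methylome comparison: muscle and tail-fat
tissue groups of 3–4 replicates, ~20.8x mean coverage, bimodal CG
methylation (about two thirds of CGs above 0.5), near-zero CHG/CHH
methylation (~0.05), a TSS-proximal methylation dip whose depth scales
with promoter CG density, repeat-family level ordering
SINE > LINE > LTR > Simple, and optional planted inter-group DMRs.

Latent site-level methylation probabilities are drawn once per genome
and shared by every replicate of every group (planted DMRs shift the
second group of the designated pair); replicates differ only in Poisson
coverage and binomial read sampling, so planted effect sizes are exactly
interpretable.  All randomness flows from ``config.seed``; two runs of
the same config produce byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .io import GeneModel, RepeatElement, write_gene_models_gff3, write_repeats_bed

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CTX_NAMES = np.array(["CG", "CHG", "CHH"])

_REPEAT_LENGTHS = {"SINE": (150, 300), "LINE": (400, 600),
                   "LTR": (300, 500), "Simple": (60, 200)}

#: paper-style group design: label, tissue, replicates
DEFAULT_GROUPS = (
    ("DM3M", "muscle", 3), ("DM12M", "muscle", 3),
    ("MG12M", "muscle", 3), ("F112M", "muscle", 3),
    ("DM", "tail_fat", 3), ("MG", "tail_fat", 4), ("F1TF", "tail_fat", 3),
)


@dataclass(frozen=True)
class PlantedDMR:
    """A latent-level shift of ``delta`` applied to ``group_b`` inside the
    interval; ``group_a`` keeps the shared base level."""

    chrom: str
    start: int
    end: int
    group_a: str
    group_b: str
    delta: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 2_000_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (8_000, 20_000)
    n_repeats: Mapping[str, int] = field(
        default_factory=lambda: {"LINE": 50, "SINE": 50, "LTR": 50, "Simple": 50})
    groups: Sequence[tuple[str, str, int]] = DEFAULT_GROUPS
    mean_coverage: float = 20.78
    # bimodal CG methylation mixture (Beta modes, shared concentration)
    cg_high_mode: float = 0.9
    cg_low_mode: float = 0.1
    p_high: float = 0.68
    beta_concentration: float = 10.0
    chg_chh_level: float = 0.05
    # TSS dip: triangular, depth scaled per promoter CG-density class
    tss_dip_halfwidth_bp: int = 2_000
    tss_dip_depth: float = 0.7
    tss_dip_class_factors: Mapping[str, float] = field(
        default_factory=lambda: {"HCG": 1.0, "ICG": 0.6, "LCG": 0.25})
    # promoter CG-density design: class fractions and planted CGs per 200 bp bin
    promoter_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"HCG": 0.4, "ICG": 0.4, "LCG": 0.2})
    promoter_cg_per_bin: Mapping[str, int] = field(
        default_factory=lambda: {"HCG": 12, "ICG": 6, "LCG": 2})
    # mean latent CG level planted inside each repeat family
    repeat_level_means: Mapping[str, float] = field(
        default_factory=lambda: {"SINE": 0.747, "LINE": 0.72,
                                 "LTR": 0.70, "Simple": 0.567})
    cg_background_keep: float = 0.3   # fraction of random CG dinucleotides kept
    gene_margin_bp: int = 12_000      # keeps TSS +- 10 kb inside its slot
    contexts: Sequence[str] = ("CG", "CHG", "CHH")
    replicate_jitter: float = 0.0     # optional Beta jitter around latent levels
    planted_dmrs: Sequence[PlantedDMR] = ()

    def __post_init__(self):
        for p in (self.p_high, self.cg_high_mode, self.cg_low_mode,
                  self.chg_chh_level, self.tss_dip_depth, self.cg_background_keep):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability-like parameter {p} outside [0, 1]")
        labels = {g[0] for g in self.groups}
        for d in self.planted_dmrs:
            if d.group_a not in labels or d.group_b not in labels:
                raise ValueError(f"planted DMR names unknown group: {d.group_a}/{d.group_b}")
            if not (1 <= d.start <= d.end <= self.chrom_length_bp):
                raise ValueError("planted DMR outside chromosome bounds")

    @property
    def sample_ids(self) -> list[tuple[str, str, str]]:
        """(sample_id, group, tissue) in deterministic order."""
        out = []
        for label, tissue, n in self.groups:
            for r in range(1, n + 1):
                out.append((f"{label}_r{r}", label, tissue))
        return out


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    seqs: dict[str, np.ndarray]          # chrom -> array of S1 bases
    genes: list[GeneModel]
    gene_classes: dict[str, str]         # gene_id -> HCG/ICG/LCG design class
    repeats: list[RepeatElement]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def sequence(self, chrom: str) -> str:
        return self.seqs[chrom].tobytes().decode()


def _beta_from_mode(rng, mode: float, conc: float, size: int) -> np.ndarray:
    a = mode * (conc - 2.0) + 1.0
    b = (1.0 - mode) * (conc - 2.0) + 1.0
    return rng.beta(a, b, size=size)


def _beta_from_mean(rng, mean: float, conc: float, size: int) -> np.ndarray:
    eps = 1e-6
    return rng.beta(max(mean, eps) * conc, max(1.0 - mean, eps) * conc, size=size)


def cg_latent_mixture(rng, n: int, config: SimulationConfig) -> np.ndarray:
    """Draw n latent CG methylation probabilities from the bimodal mixture."""
    high = rng.random(n) < config.p_high
    out = np.empty(n)
    out[high] = _beta_from_mode(rng, config.cg_high_mode, config.beta_concentration,
                                int(high.sum()))
    out[~high] = _beta_from_mode(rng, config.cg_low_mode, config.beta_concentration,
                                 int((~high).sum()))
    return out


# ---------------------------------------------------------------------------
# genome


def _make_sequence(rng, length: int, keep_cg: float) -> np.ndarray:
    seq = rng.choice(_BASES, size=length, p=[0.3, 0.2, 0.2, 0.3])
    # deplete background CG dinucleotides to a mammalian-style low density
    cg = np.nonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))[0]
    drop = cg[rng.random(len(cg)) > keep_cg]
    seq[drop + 1] = rng.choice(np.frombuffer(b"AT", dtype="S1"), size=len(drop))
    return seq


def _plant_promoter(seq: np.ndarray, tss: int, cls_target: int, halfwidth: int = 2_000,
                    bin_bp: int = 200) -> None:
    """Rewrite TSS +- halfwidth so every 200 bp bin holds cls_target CGs."""
    L = len(seq)
    p0 = max(0, tss - 1 - halfwidth)          # 0-based region start
    p1 = min(L - 2, tss - 1 + halfwidth)
    # destroy existing CGs (including one straddling the left boundary)
    lo = max(0, p0 - 1)
    region = np.arange(lo, p1)
    cs = region[(seq[region] == b"C") & (seq[region + 1] == b"G")]
    seq[cs + 1] = b"T"
    if cls_target <= 0:
        return
    spacing = bin_bp / cls_target
    for b0 in range(p0, p1, bin_bp):
        for j in range(cls_target):
            p = b0 + int((j + 0.5) * spacing)
            if p + 1 <= p1:
                seq[p] = b"C"
                seq[p + 1] = b"G"


def _make_exons(rng, start: int, end: int) -> tuple[tuple[int, int], ...]:
    """2–4 exons: first starts at `start`, last ends at `end`, separated by
    introns of at least 1 bp."""
    n_ex = int(rng.integers(2, 5))
    # 2*(n_ex-1) distinct interior cut points; consecutive pairs bound introns
    inner = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (n_ex - 1),
                               replace=False))
    bounds = [start - 1, *inner.tolist(), end]
    exons = []
    for k in range(n_ex):
        exons.append((bounds[2 * k] + 1, bounds[2 * k + 1]))
    return tuple(exons)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Random genome with planted genes, promoter CG-density classes and
    intergenic repeats.  Deterministic under config.seed."""
    rng = np.random.default_rng([config.seed, 17])
    n_per = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        n_per[i] += 1

    # design promoter classes with fixed quotas, shuffled deterministically
    fr = config.promoter_class_fractions
    n_h = round(fr.get("HCG", 0.0) * config.n_genes)
    n_l = round(fr.get("LCG", 0.0) * config.n_genes)
    labels = ["HCG"] * n_h + ["LCG"] * n_l + ["ICG"] * (config.n_genes - n_h - n_l)
    rng.shuffle(labels)

    seqs: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    gene_classes: dict[str, str] = {}
    repeats: list[RepeatElement] = []
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length_bp
        seq = _make_sequence(rng, L, config.cg_background_keep)
        if n_per[ci] > 0:
            slot = L // n_per[ci]
            lo_len, hi_len = config.gene_length_range
            if slot - 2 * config.gene_margin_bp - hi_len < 0:
                raise ValueError(
                    "genes cannot be placed at the requested density; "
                    "use a longer chromosome or fewer/shorter genes")
            for k in range(n_per[ci]):
                glen = int(rng.integers(lo_len, hi_len + 1))
                s0 = k * slot + config.gene_margin_bp
                s1 = (k + 1) * slot - config.gene_margin_bp - glen
                start = int(rng.integers(s0, s1 + 1)) + 1
                end = start + glen - 1
                strand = "+" if gi == 0 else "-" if gi == 1 else ("+", "-")[int(rng.integers(2))]
                gid = f"gene{gi:03d}"
                g = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                              start=start, end=end, exons=_make_exons(rng, start, end))
                genes.append(g)
                gene_classes[gid] = labels[gi]
                _plant_promoter(seq, g.tss, config.promoter_cg_per_bin[labels[gi]])
                gi += 1
        seqs[chrom] = seq

    # repeats go in intergenic space, clear of promoters
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length_bp
        blocked = [(max(1, g.start - 2_500), min(L, g.end + 2_500))
                   for g in genes if g.chrom == chrom]
        allowed = iv.subtract([(1, L)], blocked)
        placed: list[tuple[int, int]] = []
        weights = np.array([e - s + 1 for s, e in allowed], dtype=float)
        weights /= weights.sum()
        for family in ("LINE", "SINE", "LTR", "Simple"):
            want = config.n_repeats.get(family, 0)
            # split evenly across chromosomes
            want = want // config.n_chroms + (1 if ci < want % config.n_chroms else 0)
            lo_len, hi_len = _REPEAT_LENGTHS[family]
            done = 0
            for _ in range(want * 200):
                if done == want:
                    break
                rlen = int(rng.integers(lo_len, hi_len + 1))
                a = allowed[int(rng.choice(len(allowed), p=weights))]
                if a[1] - a[0] + 1 < rlen:
                    continue
                rs = int(rng.integers(a[0], a[1] - rlen + 2))
                re_ = rs + rlen - 1
                if any(not (re_ < s or rs > e) for s, e in placed):
                    continue
                placed.append((rs, re_))
                repeats.append(RepeatElement(chrom=chrom, start=rs, end=re_, family=family))
                done += 1
            if done < want:
                raise ValueError(f"could not place {want} {family} repeats; "
                                 "use a longer chromosome")
    return SimulatedGenome(config=config, seqs=seqs, genes=genes,
                           gene_classes=gene_classes, repeats=repeats)


def write_genome(genome: SimulatedGenome, outdir) -> dict[str, str]:
    """Emit genome.fa, genes.gff3 and repeats.bed; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    fa = os.path.join(outdir, "genome.fa")
    with open(fa, "w") as fh:
        for chrom, seq in genome.seqs.items():
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), 80):
                fh.write(raw[i:i + 80] + "\n")
    gff = os.path.join(outdir, "genes.gff3")
    write_gene_models_gff3(genome.genes, gff)
    bed = os.path.join(outdir, "repeats.bed")
    write_repeats_bed(genome.repeats, bed)
    return {"fasta": fa, "genes": gff, "repeats": bed}


# ---------------------------------------------------------------------------
# cytosine extraction and call simulation


def cytosine_table(seq: np.ndarray) -> dict[str, np.ndarray]:
    """Positions, strands, contexts and dinucleotide strings of every
    cytosine on both strands of a sequence array."""
    n = len(seq)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    u = seq.view(np.uint8)

    is_c = seq == b"C"
    is_g = seq == b"G"
    next_g = np.zeros(n, dtype=bool)
    next_g[:-1] = is_g[1:]
    next2_g = np.zeros(n, dtype=bool)
    next2_g[:-2] = is_g[2:]
    prev_c = np.zeros(n, dtype=bool)
    prev_c[1:] = is_c[:-1]
    prev2_c = np.zeros(n, dtype=bool)
    prev2_c[2:] = is_c[:-2]

    ip = np.nonzero(is_c)[0]
    ctx_p = np.where(next_g[ip], 0, np.where(next2_g[ip], 1, 2)).astype(np.int8)
    im = np.nonzero(is_g)[0]
    ctx_m = np.where(prev_c[im], 0, np.where(prev2_c[im], 1, 2)).astype(np.int8)

    # dinucleotide on the site's own strand
    nxt = np.full(len(ip), ord("N"), dtype=np.uint8)
    ok = ip + 1 < n
    nxt[ok] = u[ip[ok] + 1]
    din_p = np.char.add("C", nxt.view("S1").astype("U1"))
    prv = np.full(len(im), ord("N"), dtype=np.uint8)
    ok = im - 1 >= 0
    prv[ok] = comp[u[im[ok] - 1]]
    din_m = np.char.add("C", prv.view("S1").astype("U1"))

    pos = np.concatenate([ip, im]) + 1
    strand = np.concatenate([np.full(len(ip), "+"), np.full(len(im), "-")])
    ctx = np.concatenate([ctx_p, ctx_m])
    din = np.concatenate([din_p, din_m])
    order = np.argsort(pos, kind="stable")
    return {"pos": pos[order].astype(np.int64), "strand": strand[order],
            "ctx": ctx[order], "dinuc": din[order]}


def _latents_for_chrom(config: SimulationConfig, genome: SimulatedGenome,
                       chrom: str, chrom_idx: int,
                       table: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Base latent levels plus per-group copies carrying planted-DMR shifts."""
    rng = np.random.default_rng([config.seed, 101, chrom_idx])
    pos, ctx = table["pos"], table["ctx"]
    n = len(pos)
    cg = ctx == 0
    base = np.empty(n)
    base[cg] = cg_latent_mixture(rng, int(cg.sum()), config)
    # non-CG latents are strongly zero-inflated (Beta concentration 2):
    # most sites sit near zero with the configured mean preserved
    base[~cg] = _beta_from_mean(rng, config.chg_chh_level, 2.0, int((~cg).sum()))

    for family, mean in config.repeat_level_means.items():
        merged = iv.merge([(r.start, r.end) for r in genome.repeats
                           if r.chrom == chrom and r.family == family])
        if merged:
            m = cg & iv.member_mask(pos, merged)
            base[m] = _beta_from_mean(rng, mean, 30.0, int(m.sum()))

    hw = config.tss_dip_halfwidth_bp
    for g in genome.genes:
        if g.chrom != chrom:
            continue
        f = config.tss_dip_class_factors[genome.gene_classes[g.gene_id]]
        d = np.abs(pos - g.tss)
        sel = cg & (d <= hw)
        if sel.any():
            # quadratic dip: steep right at the TSS, fading to zero at the
            # halfwidth, so the profile minimum localises at the TSS bin
            w = (1.0 - d[sel] / hw) ** 2
            base[sel] *= 1.0 - config.tss_dip_depth * f * w

    latents = {label: base for label, _, _ in config.groups}
    for p in config.planted_dmrs:
        if p.chrom != chrom:
            continue
        arr = latents[p.group_b]
        if arr is base:
            arr = base.copy()
            latents[p.group_b] = arr
        m = cg & (pos >= p.start) & (pos <= p.end)
        arr[m] = np.clip(arr[m] + p.delta, 0.0, 1.0)
    return latents


def simulate_calls(config: SimulationConfig,
                   genome: SimulatedGenome) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate per-replicate call tables for every sample in the design.

    Returns (calls, truth): ``calls`` maps sample_id to a site table with
    an extra ``dinuc`` column for CGmap export; ``truth`` records the
    planted structure for ground-truth tests.
    """
    wanted_ctx = np.array([_CTX_NAMES.tolist().index(c) for c in config.contexts],
                          dtype=np.int8)
    per_sample: dict[str, list[pd.DataFrame]] = {s: [] for s, _, _ in config.sample_ids}
    for chrom_idx, chrom in enumerate(genome.seqs):
        table = cytosine_table(genome.seqs[chrom])
        keep = np.isin(table["ctx"], wanted_ctx)
        table = {k: v[keep] for k, v in table.items()}
        latents = _latents_for_chrom(config, genome, chrom, chrom_idx, table)
        n = len(table["pos"])
        ctx_str = _CTX_NAMES[table["ctx"]]
        for rep_idx, (sid, group, _tissue) in enumerate(config.sample_ids):
            rng = np.random.default_rng([config.seed, 202, rep_idx, chrom_idx])
            lat = latents[group]
            if config.replicate_jitter > 0:
                k = 1.0 / config.replicate_jitter
                lat = rng.beta(np.clip(lat, 1e-9, None) * k,
                               np.clip(1.0 - lat, 1e-9, None) * k)
            cov = rng.poisson(config.mean_coverage, n)
            meth = rng.binomial(cov, lat)
            covered = cov > 0
            per_sample[sid].append(pd.DataFrame({
                "chrom": pd.Categorical([chrom] * int(covered.sum())),
                "pos": table["pos"][covered],
                "strand": pd.Categorical(table["strand"][covered]),
                "context": pd.Categorical(ctx_str[covered]),
                "level": meth[covered] / cov[covered],
                "meth": meth[covered].astype(np.int64),
                "total": cov[covered].astype(np.int64),
                "dinuc": pd.Categorical(table["dinuc"][covered]),
            }))
    calls = {sid: pd.concat(frames, ignore_index=True)
             for sid, frames in per_sample.items()}
    truth = {
        "seed": config.seed,
        "samples": [{"sample_id": s, "group": g, "tissue": t}
                    for s, g, t in config.sample_ids],
        "genes": [{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
                   "end": g.end, "strand": g.strand,
                   "promoter_class": genome.gene_classes[g.gene_id]}
                  for g in genome.genes],
        "planted_dmrs": [asdict(p) for p in config.planted_dmrs],
        "params": {"mean_coverage": config.mean_coverage, "p_high": config.p_high,
                   "cg_high_mode": config.cg_high_mode,
                   "cg_low_mode": config.cg_low_mode,
                   "chg_chh_level": config.chg_chh_level,
                   "tss_dip_depth": config.tss_dip_depth,
                   "repeat_level_means": dict(config.repeat_level_means)},
    }
    return calls, truth


def write_calls(calls: dict[str, pd.DataFrame], outdir, compress: bool = False) -> dict[str, str]:
    """Write one CGmap file per replicate; returns sample_id -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for sid, df in calls.items():
        out = pd.DataFrame({
            "chrom": df["chrom"].astype(str),
            "nuc": np.where(df["strand"].astype(str) == "+", "C", "G"),
            "pos": df["pos"],
            "context": df["context"].astype(str),
            "dinuc": df["dinuc"].astype(str),
            "level": df["level"],
            "meth": df["meth"],
            "total": df["total"],
        })
        path = os.path.join(outdir, f"{sid}.CGmap" + (".gz" if compress else ""))
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")
        paths[sid] = path
    return paths


@dataclass
class SimulatedStudy:
    genome: SimulatedGenome
    calls: dict[str, pd.DataFrame]
    truth: dict
    paths: dict[str, str] | None = None


def simulate_study(config: SimulationConfig, outdir=None,
                   compress: bool = False) -> SimulatedStudy:
    """Run the full generator; optionally write every artifact to outdir."""
    genome = simulate_genome(config)
    calls, truth = simulate_calls(config, genome)
    paths = None
    if outdir is not None:
        paths = write_genome(genome, outdir)
        paths.update(write_calls(calls, outdir, compress=compress))
        tj = os.path.join(outdir, "truth.json")
        with open(tj, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        paths["truth"] = tj
    return SimulatedStudy(genome=genome, calls=calls, truth=truth, paths=paths)
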