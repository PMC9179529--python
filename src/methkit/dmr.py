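"""Sliding-window differential methylation screening and gene annotation.

The genome is scanned with 600 bp windows stepping by 300 bp; a window
enters the comparison only if *both* groups have at least 3 CG sites at
>= 3x coverage inside it, its level being the unweighted mean of those
site levels.  A window is a DMR when the absolute level difference
between the two groups is >= 0.15.  Windows are reported as-is — no
merging of adjacent or overlapping hits.

Group aggregation pools reads per site across a group's replicates
(sum meth and total, then apply the coverage filter to pooled depth);
``replicate_mean`` mode instead averages per-replicate window levels.

DMR-to-gene annotation records any positional intersection, labelled by
the most specific relation: ``dmr_in_gene`` (DMR inside the gene span,
also the tie-break for identical intervals), ``gene_in_dmr``, or plain
``overlap``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .io import GeneModel
from .core import DEFAULT_MIN_COVERAGE

DEFAULT_WINDOW_BP = 600
DEFAULT_STEP_BP = 300
DEFAULT_MIN_CG = 3
DEFAULT_DELTA = 0.15
_DELTA_EPS = 1e-12    # guards the inclusive >= against float round-off

CRITERIA = ("gene_in_dmr", "overlap", "dmr_in_gene")


@dataclass(frozen=True)
class DMR:
    """One differential 600 bp window between two groups."""

    chrom: str
    start: int
    end: int
    group_a: str
    group_b: str
    level_a: float
    level_b: float
    n_cg_a: int
    n_cg_b: int

    @property
    def delta(self) -> float:
        return self.level_a - self.level_b


@dataclass(frozen=True)
class DMRAnnotation:
    dmr: DMR
    gene_id: str | None      # None when the DMR hits no gene
    criterion: str | None


def scan_windows(chrom_lengths: dict[str, int],
                 window_bp: int = DEFAULT_WINDOW_BP,
                 step_bp: int = DEFAULT_STEP_BP,
                 phase: int = 1) -> Iterator[tuple[str, int, int]]:
    """Yield (chrom, start, end) for every full window on each chromosome.

    Windows start at ``phase`` (default 1) and advance by ``step_bp``;
    windows whose end would exceed the chromosome are dropped.
    """
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom}: non-positive length {length}")
        for start in range(phase, length - window_bp + 2, step_bp):
            yield chrom, start, start + window_bp - 1


def pool_group(replicate_sites: list[pd.DataFrame],
               min_coverage: int = DEFAULT_MIN_COVERAGE,
               context: str = "CG") -> pd.DataFrame:
    """Pool reads per site across replicates, then coverage-filter.

    Input tables should be unfiltered (raw coverage); the >= min_coverage
    rule is applied to the *pooled* depth.
    """
    frames = [df[df["context"] == context] for df in replicate_sites]
    allc = pd.concat(frames, ignore_index=True)
    allc = allc.assign(chrom=allc["chrom"].astype(str), strand=allc["strand"].astype(str))
    agg = allc.groupby(["chrom", "pos", "strand"], as_index=False, sort=True,
                       observed=True).agg(meth=("meth", "sum"), total=("total", "sum"))
    agg = agg[agg["total"] >= min_coverage].reset_index(drop=True)
    return pd.DataFrame({
        "chrom": agg["chrom"],
        "pos": agg["pos"].astype(np.int64),
        "strand": agg["strand"],
        "context": context,
        "level": agg["meth"] / agg["total"],
        "meth": agg["meth"],
        "total": agg["total"],
    })


def window_level(sites: pd.DataFrame, chrom: str, start: int, end: int,
                 min_cg: int = DEFAULT_MIN_CG,
                 context: str = "CG") -> tuple[float, int] | None:
    """(mean level, n CG) for one window, or None if < min_cg sites."""
    m = ((sites["chrom"] == chrom) & (sites["context"] == context)
         & (sites["pos"] >= start) & (sites["pos"] <= end))
    vals = sites.loc[m, "level"].to_numpy()
    if len(vals) < min_cg:
        return None
    return float(np.mean(vals)), len(vals)


def _chrom_arrays(sites: pd.DataFrame, context: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    sub = sites[sites["context"] == context]
    out = {}
    for chrom, g in sub.groupby("chrom", observed=True):
        g = g.sort_values("pos", kind="stable")
        out[chrom] = (g["pos"].to_numpy(), g["level"].to_numpy())
    return out


def call_dmrs(sites_a: pd.DataFrame, sites_b: pd.DataFrame,
              chrom_lengths: dict[str, int],
              group_a: str = "A", group_b: str = "B",
              threshold: float = DEFAULT_DELTA,
              min_cg: int = DEFAULT_MIN_CG,
              window_bp: int = DEFAULT_WINDOW_BP,
              step_bp: int = DEFAULT_STEP_BP,
              phase: int = 1) -> list[DMR]:
    """Scan all windows and return those with |level_A - level_B| >= threshold.

    Both groups must have a defined window level (>= min_cg CGs); windows
    defined in only one group are skipped.  Output is in genomic order and
    windows are never merged.
    """
    if group_a == group_b:
        raise ValueError("group labels must differ")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    arr_a = _chrom_arrays(sites_a, "CG")
    arr_b = _chrom_arrays(sites_b, "CG")
    dmrs: list[DMR] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"chromosome {chrom}: non-positive length {length}")
        if chrom not in arr_a or chrom not in arr_b:
            continue
        pos_a, lev_a = arr_a[chrom]
        pos_b, lev_b = arr_b[chrom]
        starts = np.arange(phase, length - window_bp + 2, step_bp, dtype=np.int64)
        if len(starts) == 0:
            continue
        ia0 = np.searchsorted(pos_a, starts, side="left")
        ia1 = np.searchsorted(pos_a, starts + window_bp, side="left")
        ib0 = np.searchsorted(pos_b, starts, side="left")
        ib1 = np.searchsorted(pos_b, starts + window_bp, side="left")
        na = ia1 - ia0
        nb = ib1 - ib0
        defined = (na >= min_cg) & (nb >= min_cg)
        for w in np.nonzero(defined)[0]:
            ma = float(np.mean(lev_a[ia0[w]:ia1[w]]))
            mb = float(np.mean(lev_b[ib0[w]:ib1[w]]))
            if abs(ma - mb) + _DELTA_EPS >= threshold:
                s = int(starts[w])
                dmrs.append(DMR(chrom=chrom, start=s, end=s + window_bp - 1,
                                group_a=group_a, group_b=group_b,
                                level_a=ma, level_b=mb,
                                n_cg_a=int(na[w]), n_cg_b=int(nb[w])))
    return dmrs


def call_dmrs_replicate_mean(replicates_a: list[pd.DataFrame],
                             replicates_b: list[pd.DataFrame],
                             chrom_lengths: dict[str, int],
                             group_a: str = "A", group_b: str = "B",
                             min_coverage: int = DEFAULT_MIN_COVERAGE,
                             **kwargs) -> list[DMR]:
    """Replicate-mean aggregation: per-replicate site levels are averaged
    per site (after per-replicate coverage filtering) before scanning."""
    def per_site_mean(reps: list[pd.DataFrame]) -> pd.DataFrame:
        frames = [df[(df["context"] == "CG") & (df["total"] >= min_coverage)]
                  for df in reps]
        allc = pd.concat(frames, ignore_index=True)
        allc = allc.assign(chrom=allc["chrom"].astype(str), strand=allc["strand"].astype(str))
        agg = allc.groupby(["chrom", "pos", "strand"], as_index=False, sort=True,
                           observed=True).agg(
            level=("level", "mean"), meth=("meth", "sum"), total=("total", "sum"))
        agg["context"] = "CG"
        return agg
    return call_dmrs(per_site_mean(replicates_a), per_site_mean(replicates_b),
                     chrom_lengths, group_a=group_a, group_b=group_b, **kwargs)


def classify_relation(dmr_start: int, dmr_end: int,
                      gene_start: int, gene_end: int) -> str | None:
    """Most specific interval relation, or None if disjoint.

    Containment (either direction) beats plain overlap; identical
    intervals resolve to ``dmr_in_gene``.
    """
    if dmr_end < gene_start or gene_end < dmr_start:
        return None
    if gene_start <= dmr_start and dmr_end <= gene_end:
        return "dmr_in_gene"
    if dmr_start <= gene_start and gene_end <= dmr_end:
        return "gene_in_dmr"
    return "overlap"


def annotate_dmrs(dmrs: list[DMR], genes: list[GeneModel]) -> list[DMRAnnotation]:
    """One annotation per (DMR, gene) intersection; unannotated DMRs get
    a row with gene_id None."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree())[g.start:g.end + 1] = g
    out: list[DMRAnnotation] = []
    for d in dmrs:
        tree = trees.get(d.chrom)
        hits = sorted(tree[d.start:d.end + 1], key=lambda h: h.data.gene_id) if tree else []
        if not hits:
            out.append(DMRAnnotation(dmr=d, gene_id=None, criterion=None))
            continue
        for h in hits:
            g = h.data
            crit = classify_relation(d.start, d.end, g.start, g.end)
            out.append(DMRAnnotation(dmr=d, gene_id=g.gene_id, criterion=crit))
    return out
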