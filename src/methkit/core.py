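"""Site filtering and methylation-level definitions.

The pipeline's working container is the *site table*: a pandas DataFrame
with columns ``chrom, pos, strand, context, level, meth, total`` (one row
per cytosine observation, 1-based positions).  All regional levels are
unweighted arithmetic means of site levels — a site covered 30x counts
the same as one covered 3x; an optional read-weighted mode is provided
for comparison.  A region with no qualifying site has an *undefined*
level, represented as NaN and never conflated with zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 3    # "at least threefold read coverage"
DEFAULT_FLANK_BP = 15_000   # gene-body +- flank defining the genic universe


@dataclass(frozen=True)
class GroupLevel:
    group: str
    tissue: str
    context: str
    level: float      # arithmetic mean of member sample levels
    n_samples: int


@dataclass(frozen=True)
class LevelDistribution:
    """Fraction of sites per methylation-level bin.

    Bins are left-open/right-closed, ``(e[i], e[i+1]]``, except the first
    which also includes its left edge — so with edges ``[0, 0.5, 1]`` the
    two bins are exactly the paper-style "<= 0.5" vs "> 0.5" split.
    """

    context: str
    edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_sites: int

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_sites


def filter_sites(sites: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Retain sites with ``total >= min_coverage``; log drops per context."""
    if min_coverage <= 0:
        return sites
    keep = sites["total"] >= min_coverage
    if not keep.all():
        dropped = sites.loc[~keep, "context"].value_counts()
        logger.info("coverage filter (%dx) dropped %d sites: %s",
                    min_coverage, int((~keep).sum()), dropped.to_dict())
    out = sites[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no sites left after {min_coverage}x coverage filter", stacklevel=2)
    return out


def merge_symmetric_cpg(sites: pd.DataFrame) -> pd.DataFrame:
    """Sum read counts across the two strands of each CpG dinucleotide.

    A forward call at position *i* and a reverse call at *i+1* describe
    the same CpG; this collapses them to one site at the forward C's
    position (strand ``+``).  Non-CG contexts pass through unchanged.
    Apply *before* coverage filtering so the filter sees pooled depth.
    """
    cg = sites[sites["context"] == "CG"].copy()
    rest = sites[sites["context"] != "CG"]
    # anchor: forward C keeps its position, reverse G maps to pos - 1
    cg["chrom"] = cg["chrom"].astype(str)
    cg["anchor"] = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    agg = cg.groupby(["chrom", "anchor"], as_index=False, sort=False,
                     observed=True).agg(meth=("meth", "sum"), total=("total", "sum"))
    merged = pd.DataFrame({
        "chrom": agg["chrom"],
        "pos": agg["anchor"].astype(np.int64),
        "strand": "+",
        "context": "CG",
        "level": np.where(agg["total"] > 0, agg["meth"] / agg["total"].clip(lower=1), 0.0),
        "meth": agg["meth"],
        "total": agg["total"],
    })
    return pd.concat([merged, rest], ignore_index=True)


def region_level(sites: pd.DataFrame, chrom: str, start: int, end: int,
                 context: str = "CG", weighted: bool = False) -> float:
    """Mean methylation level of the sites of one context inside a region.

    Returns NaN (undefined) when no qualifying site falls in
    ``[start, end]`` — never 0.
    """
    if start > end:
        raise ValueError(f"invalid interval: {start} > {end}")
    m = ((sites["chrom"] == chrom) & (sites["context"] == context)
         & (sites["pos"] >= start) & (sites["pos"] <= end))
    sub = sites.loc[m]
    if sub.empty:
        return float("nan")
    if weighted:
        return float(np.sum(sub["meth"]) / np.sum(sub["total"]))
    return float(np.mean(sub["level"].to_numpy()))


def gene_levels(sites: pd.DataFrame, genes: list[GeneModel], context: str = "CG",
                flank_bp: int = DEFAULT_FLANK_BP) -> pd.Series:
    """Per-gene level over the body plus +-flank superinterval (NaN if empty)."""
    vals = {}
    for g in genes:
        vals[g.gene_id] = region_level(sites, g.chrom, max(1, g.start - flank_bp),
                                       g.end + flank_bp, context)
    return pd.Series(vals, name=f"{context}_level")


def sample_level(sites: pd.DataFrame, genes: list[GeneModel], context: str = "CG",
                 flank_bp: int = DEFAULT_FLANK_BP) -> float:
    """Sample-wide level: mean over genes with a defined body+-flank level."""
    lv = gene_levels(sites, genes, context, flank_bp)
    defined = lv.dropna()
    if defined.empty:
        raise ValueError("no gene has a defined methylation level")
    return float(defined.mean())


def group_level(sample_levels: list[float], group: str, tissue: str = "",
                context: str = "CG") -> GroupLevel:
    """Group level: unweighted mean of member sample levels."""
    if not sample_levels:
        raise ValueError(f"group {group!r} has no samples")
    return GroupLevel(group=group, tissue=tissue, context=context,
                      level=float(np.mean(sample_levels)), n_samples=len(sample_levels))


def level_distribution(sites: pd.DataFrame, context: str,
                       edges=(0.0, 0.5, 1.0)) -> LevelDistribution:
    """Histogram of site levels with right-closed bins (see class docs)."""
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    levels = sites.loc[sites["context"] == context, "level"].to_numpy()
    if len(levels) == 0:
        raise ValueError(f"no {context} sites to bin")
    if (levels < edges[0]).any() or (levels > edges[-1]).any():
        raise ValueError("site levels outside the edge range")
    idx = np.searchsorted(np.asarray(edges[1:-1]), levels, side="left")
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return LevelDistribution(context=context, edges=edges,
                             counts=tuple(int(c) for c in counts), n_sites=len(levels))


def context_means(sites: pd.DataFrame) -> dict[str, float]:
    """Genome-wide mean site level per context present in the table."""
    return {ctx: float(sub["level"].mean())
            for ctx, sub in sites.groupby("context", observed=True)}
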