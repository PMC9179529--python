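"""Metagene methylation profiles and per-feature-class level tables.

The metagene profile averages CG methylation along a strand-oriented
super-gene axis: a fixed-width upstream flank (default 15 kb in 200 bp
bins), a length-normalised gene body (default 100 proportional bins),
and a fixed-width downstream flank.  Per-gene bin means are averaged
across genes with data, so every gene contributes equally regardless of
its CG density.

Feature-class levels pool all CG sites falling in any interval of a
class (LINE/SINE/LTR/Simple repeats, intragenic, intergenic flanks,
exon, intron); a per-element mode averages per-element means instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .io import GeneModel, RepeatElement
from .core import DEFAULT_FLANK_BP

FEATURE_CLASSES = ("LINE", "SINE", "LTR", "Simple",
                   "intergenic", "intragenic", "exon", "intron")


@dataclass(frozen=True)
class MetageneScheme:
    flank_bp: int = DEFAULT_FLANK_BP
    flank_bin_bp: int = 200
    body_bins: int = 100

    def __post_init__(self):
        if self.flank_bp % self.flank_bin_bp != 0:
            raise ValueError("flank_bp must be a multiple of flank_bin_bp")

    @property
    def flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    @property
    def total_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


@dataclass
class MetageneProfile:
    scheme: MetageneScheme
    mean: np.ndarray      # per-bin mean of per-gene means; NaN where no gene has data
    n_genes: np.ndarray   # genes contributing to each bin
    n_sites: np.ndarray   # total sites binned (all genes)

    @property
    def upstream(self) -> np.ndarray:
        return self.mean[:self.scheme.flank_bins]

    @property
    def body(self) -> np.ndarray:
        f = self.scheme.flank_bins
        return self.mean[f:f + self.scheme.body_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.mean[self.scheme.flank_bins + self.scheme.body_bins:]

    @property
    def tss_bin(self) -> int:
        """Index of the first gene-body bin (transcription starts here)."""
        return self.scheme.flank_bins


def _gene_bins(g: GeneModel, pos: np.ndarray, scheme: MetageneScheme) -> np.ndarray:
    """Strand-oriented bin index for each position; -1 = outside the axis.

    Bin order is always 5'->3' of transcription: upstream flank bins,
    proportional body bins, downstream flank bins.  Body sites at an
    exact bin boundary go to the lower bin.
    """
    nf, nb = scheme.flank_bins, scheme.body_bins
    w = scheme.flank_bin_bp
    out = np.full(len(pos), -1, dtype=np.int64)
    L = g.length
    if g.strand == "+":
        up = (pos >= g.start - scheme.flank_bp) & (pos < g.start)
        out[up] = (pos[up] - (g.start - scheme.flank_bp)) // w
        body = (pos >= g.start) & (pos <= g.end)
        off = pos[body] - g.start + 1                       # 1..L
        out[body] = nf + np.minimum(nb - 1, np.ceil(off * nb / L).astype(np.int64) - 1)
        down = (pos > g.end) & (pos <= g.end + scheme.flank_bp)
        out[down] = nf + nb + (pos[down] - (g.end + 1)) // w
    else:
        up = (pos > g.end) & (pos <= g.end + scheme.flank_bp)
        out[up] = ((g.end + scheme.flank_bp) - pos[up]) // w
        body = (pos >= g.start) & (pos <= g.end)
        off = g.end - pos[body] + 1
        out[body] = nf + np.minimum(nb - 1, np.ceil(off * nb / L).astype(np.int64) - 1)
        down = (pos < g.start) & (pos >= g.start - scheme.flank_bp)
        out[down] = nf + nb + ((g.start - 1) - pos[down]) // w
    return out


def metagene_profile(sites: pd.DataFrame, genes: list[GeneModel],
                     scheme: MetageneScheme | None = None,
                     context: str = "CG") -> MetageneProfile:
    """Average CG methylation along gene body +- flanks across all genes.

    Minus-strand genes are mirrored onto the transcription axis; flanks
    running off a chromosome end simply collect no sites (missing bins).
    Overlapping genes each see every site independently.
    """
    scheme = scheme or MetageneScheme()
    nbins = scheme.total_bins
    sub = sites[sites["context"] == context]
    by_chrom = {c: g.sort_values("pos") for c, g in sub.groupby("chrom", observed=True)}
    sum_of_means = np.zeros(nbins)
    gene_counts = np.zeros(nbins, dtype=np.int64)
    site_counts = np.zeros(nbins, dtype=np.int64)
    for g in genes:
        tab = by_chrom.get(g.chrom)
        if tab is None:
            continue
        pos = tab["pos"].to_numpy()
        lev = tab["level"].to_numpy()
        lo = np.searchsorted(pos, g.start - scheme.flank_bp, side="left")
        hi = np.searchsorted(pos, g.end + scheme.flank_bp, side="right")
        if hi <= lo:
            continue
        bins = _gene_bins(g, pos[lo:hi], scheme)
        ok = bins >= 0
        bins, vals = bins[ok], lev[lo:hi][ok]
        cnt = np.bincount(bins, minlength=nbins)
        tot = np.bincount(bins, weights=vals, minlength=nbins)
        has = cnt > 0
        sum_of_means[has] += tot[has] / cnt[has]
        gene_counts[has] += 1
        site_counts += cnt
    mean = np.full(nbins, np.nan)
    has = gene_counts > 0
    mean[has] = sum_of_means[has] / gene_counts[has]
    return MetageneProfile(scheme=scheme, mean=mean, n_genes=gene_counts,
                           n_sites=site_counts)


def _class_intervals(genes: list[GeneModel], repeats: list[RepeatElement],
                     flank_bp: int) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Merged per-chromosome interval sets for every feature class."""
    out: dict[str, dict[str, list]] = {c: {} for c in FEATURE_CLASSES}

    def add(cls: str, chrom: str, s: int, e: int):
        out[cls].setdefault(chrom, []).append((max(1, s), e))

    for r in repeats:
        add(r.family, r.chrom, r.start, r.end)
    universe: dict[str, list] = {}
    for g in genes:
        add("intragenic", g.chrom, g.start, g.end)
        universe.setdefault(g.chrom, []).append((max(1, g.start - flank_bp), g.end + flank_bp))
        for s, e in g.exons:
            add("exon", g.chrom, s, e)
        for s, e in g.introns:
            add("intron", g.chrom, s, e)
    for cls in out:
        out[cls] = {c: iv.merge(ivs) for c, ivs in out[cls].items()}
    # intergenic = (+-flank universe) minus merged gene bodies
    out["intergenic"] = {
        c: iv.subtract(iv.merge(ivs), out["intragenic"].get(c, []))
        for c, ivs in universe.items()
    }
    return out


def feature_levels(sites: pd.DataFrame, genes: list[GeneModel],
                   repeats: list[RepeatElement], context: str = "CG",
                   flank_bp: int = DEFAULT_FLANK_BP,
                   per_element: bool = False) -> pd.DataFrame:
    """Mean CG level per feature class.

    Default pools all sites in any interval of the class; with
    ``per_element=True`` each element's mean is computed first and the
    class level is the mean over elements with data.
    """
    classes = _class_intervals(genes, repeats, flank_bp)
    sub = sites[sites["context"] == context]
    by_chrom = {c: (g["pos"].to_numpy(), g["level"].to_numpy())
                for c, g in sub.groupby("chrom", observed=True)}
    rows = []
    for cls in FEATURE_CLASSES:
        if per_element:
            elem_means = []
            n_sites = 0
            for chrom, merged in classes[cls].items():
                if chrom not in by_chrom:
                    continue
                pos, lev = by_chrom[chrom]
                order = np.argsort(pos, kind="stable")
                pos, lev = pos[order], lev[order]
                for s, e in merged:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="right")
                    if hi > lo:
                        elem_means.append(float(np.mean(lev[lo:hi])))
                        n_sites += hi - lo
            level = float(np.mean(elem_means)) if elem_means else float("nan")
            rows.append((cls, level, n_sites))
        else:
            picked = []
            for chrom, merged in classes[cls].items():
                if chrom not in by_chrom:
                    continue
                pos, lev = by_chrom[chrom]
                mask = iv.member_mask(pos, merged)
                if mask.any():
                    picked.append(lev[mask])
            if picked:
                allv = np.concatenate(picked)
                rows.append((cls, float(np.mean(allv)), len(allv)))
            else:
                rows.append((cls, float("nan"), 0))
    return pd.DataFrame(rows, columns=["feature", "level", "n_sites"])
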