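"""Promoter CG-density scanning, classification, and methylation profiles.

Candidate promoters are screened by scanning TSS +- 10 kb in 100
strand-oriented 200 bp subregions and counting CG dinucleotides per
subregion.  The TSS +- 2 kb promoter proper is tiled by 20 consecutive
200 bp bins named bin-10..bin-1 (upstream) and bin1..bin10 (downstream
of the TSS in the direction of transcription; there is no bin0).
Promoters are classified by their mean CG count per bin:

* HCG — strictly more than 8 CGs per 200 bp bin
* ICG — 4 to 8 inclusive
* LCG — strictly fewer than 4

CG dinucleotides are counted on the forward-strand sequence (CG is its
own reverse complement, so the count is strand-independent); a CG
straddling a bin boundary belongs to the bin containing its forward C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel
from .core import region_level

HCG_THRESHOLD = 8.0   # mean CG per 200 bp bin, strictly above -> HCG
LCG_THRESHOLD = 4.0   # strictly below -> LCG
PROMOTER_BIN_BP = 200
PROMOTER_N_EACH = 10      # bins on each side of the TSS
SCAN_FLANK_BP = 10_000
SCAN_N_SUBREGIONS = 100

BIN_INDICES = tuple(range(-PROMOTER_N_EACH, 0)) + tuple(range(1, PROMOTER_N_EACH + 1))


def _chrom_len(fasta, chrom: str) -> int:
    rec = fasta[chrom]
    return len(rec)


def _fetch(fasta, chrom: str, start: int, end: int) -> str:
    """Forward-strand sequence for [start, end], 1-based inclusive, clipped."""
    if chrom not in fasta:
        raise KeyError(f"chromosome {chrom!r} missing from FASTA")
    L = _chrom_len(fasta, chrom)
    s = max(1, start)
    e = min(L, end)
    if s > e:
        return ""
    seq = fasta[chrom][s - 1:e]
    return str(getattr(seq, "seq", seq)).upper()


def count_cg(fasta, chrom: str, start: int, end: int) -> int:
    """CG dinucleotides whose C lies in [start, end] (1-based inclusive)."""
    # include one base past `end` so a CG with its C at `end` is counted
    return _fetch(fasta, chrom, start, end + 1).count("CG")


@dataclass
class TSSScan:
    """CG counts over 100 strand-oriented 200 bp subregions of TSS +- 10 kb."""

    gene_id: str
    bins: pd.DataFrame     # columns: sub_index (0..99, 5'->3'), start, end, cg_count, truncated

    @property
    def counts(self) -> np.ndarray:
        return self.bins["cg_count"].to_numpy()


@dataclass
class PromoterBinGrid:
    """The 20-bin x 200 bp promoter grid of one gene."""

    gene_id: str
    strand: str
    bins: pd.DataFrame     # columns: bin_index (-10..-1, 1..10), start, end, cg_count, level, truncated

    @property
    def mean_cg_per_bin(self) -> float:
        ok = ~self.bins["truncated"]
        return float(self.bins.loc[ok, "cg_count"].mean())

    @property
    def truncated(self) -> bool:
        return bool(self.bins["truncated"].any())


@dataclass(frozen=True)
class PromoterClass:
    gene_id: str
    mean_cg_per_bin: float
    label: str             # HCG / ICG / LCG
    truncated: bool = False


def _oriented_bins(tss: int, strand: str, n_each: int, bin_bp: int) -> list[tuple[int, int, int]]:
    """(bin_index, start, end) for bins -n..-1, 1..n around a TSS.

    On the forward strand bin1 = [tss, tss+199]; on the reverse strand
    transcription runs leftward, so bin1 = [tss-199, tss].
    """
    out = []
    if strand == "+":
        for k in range(-n_each, 0):
            out.append((k, tss + k * bin_bp, tss + (k + 1) * bin_bp - 1))
        for k in range(1, n_each + 1):
            out.append((k, tss + (k - 1) * bin_bp, tss + k * bin_bp - 1))
    else:
        for k in range(-n_each, 0):
            out.append((k, tss - (k + 1) * bin_bp + 1, tss - k * bin_bp))
        for k in range(1, n_each + 1):
            out.append((k, tss - k * bin_bp + 1, tss - (k - 1) * bin_bp))
    return out


def tss_scan(genes: list[GeneModel], fasta,
             flank_bp: int = SCAN_FLANK_BP,
             bin_bp: int = PROMOTER_BIN_BP) -> tuple[list[TSSScan], np.ndarray]:
    """Per-gene CG-count scan of TSS +- flank, plus the per-subregion mean.

    Subregions extending past a chromosome end are counted on the
    available sequence and flagged ``truncated``; the aggregate mean per
    subregion uses non-truncated entries only.
    """
    n_sub = 2 * flank_bp // bin_bp
    scans = []
    agg_sum = np.zeros(n_sub)
    agg_n = np.zeros(n_sub, dtype=np.int64)
    for g in genes:
        L = _chrom_len(fasta, g.chrom) if g.chrom in fasta else None
        if L is None:
            raise KeyError(f"chromosome {g.chrom!r} missing from FASTA")
        rows = []
        n_each = n_sub // 2
        for i, (_, s, e) in enumerate(_oriented_bins(g.tss, g.strand, n_each, bin_bp)):
            trunc = s < 1 or e > L
            rows.append((i, s, e, count_cg(fasta, g.chrom, s, e), trunc))
        bins = pd.DataFrame(rows, columns=["sub_index", "start", "end", "cg_count", "truncated"])
        scans.append(TSSScan(gene_id=g.gene_id, bins=bins))
        ok = ~bins["truncated"].to_numpy()
        agg_sum[ok] += bins["cg_count"].to_numpy()[ok]
        agg_n[ok] += 1
    aggregate = np.full(n_sub, np.nan)
    has = agg_n > 0
    aggregate[has] = agg_sum[has] / agg_n[has]
    return scans, aggregate


def build_promoter_grid(gene: GeneModel, fasta, sites: pd.DataFrame | None = None,
                        bin_bp: int = PROMOTER_BIN_BP,
                        n_each: int = PROMOTER_N_EACH) -> PromoterBinGrid:
    """20-bin promoter grid: per-bin CG count from sequence and mean CG
    methylation from coverage-filtered sites (NaN where no site is covered)."""
    L = _chrom_len(fasta, gene.chrom)
    rows = []
    for k, s, e in _oriented_bins(gene.tss, gene.strand, n_each, bin_bp):
        trunc = s < 1 or e > L
        cg = count_cg(fasta, gene.chrom, s, e)
        if sites is not None and s <= e:
            lv = region_level(sites, gene.chrom, max(1, s), e, context="CG")
        else:
            lv = float("nan")
        rows.append((k, s, e, cg, lv, trunc))
    bins = pd.DataFrame(rows, columns=["bin_index", "start", "end",
                                       "cg_count", "level", "truncated"])
    return PromoterBinGrid(gene_id=gene.gene_id, strand=gene.strand, bins=bins)


def classify_promoter(grid: PromoterBinGrid,
                      hcg_threshold: float = HCG_THRESHOLD,
                      lcg_threshold: float = LCG_THRESHOLD) -> PromoterClass:
    """Classify by mean CG per bin: >8 HCG, <4 LCG, 4-8 inclusive ICG.

    Grids truncated at a chromosome edge are classified on the available
    bins and flagged.
    """
    mean_cg = grid.mean_cg_per_bin
    if mean_cg > hcg_threshold:
        label = "HCG"
    elif mean_cg < lcg_threshold:
        label = "LCG"
    else:
        label = "ICG"
    return PromoterClass(gene_id=grid.gene_id, mean_cg_per_bin=mean_cg,
                         label=label, truncated=grid.truncated)


def class_profiles(grids: list[PromoterBinGrid],
                   classes: list[PromoterClass]) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-class per-bin mean methylation and per-class overall means.

    Bins with no covered CG in a gene are excluded from that bin's mean;
    the overall class mean averages each gene's mean over its defined
    bins.  Empty classes are omitted.
    """
    label_of = {c.gene_id: c.label for c in classes}
    per_bin: dict[str, pd.DataFrame] = {}
    overall: dict[str, float] = {}
    for lab in ("HCG", "ICG", "LCG"):
        members = [g for g in grids if label_of.get(g.gene_id) == lab]
        if not members:
            continue
        mat = np.vstack([g.bins["level"].to_numpy() for g in members])
        with np.errstate(invalid="ignore"):
            per_bin[lab] = pd.DataFrame({
                "bin_index": list(BIN_INDICES),
                "level": np.nanmean(mat, axis=0),
                "n_genes": np.sum(~np.isnan(mat), axis=0),
            })
            gene_means = np.nanmean(mat, axis=1)
        overall[lab] = float(np.nanmean(gene_means))
    table = pd.concat(
        [df.assign(promoter_class=lab) for lab, df in per_bin.items()],
        ignore_index=True)
    return table, overall
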