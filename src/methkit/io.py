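"""Readers and writers for every external file the pipeline touches.

Formats handled
---------------
* CGmap-dialect per-cytosine methylation calls (tab-separated, optionally
  gzipped): ``chrom  nucleotide  pos  context  dinucleotide  level
  meth_reads  total_reads``.  A 7-column variant lacking the ``level``
  column is tolerated (the level is recomputed as ``meth/total``).
* Gene models in GFF3 (via :mod:`gffutils`) or BED12.
* Repeat-element annotations as BED with the family in the name column
  (``SINE``, ``LINE``, ``LTR``, ``Simple``; RepeatMasker-style compound
  names such as ``SINE/Alu`` are reduced to their class prefix).
* The DMR table emitted by :mod:`methkit.dmr`, plus a BED6 export.

All in-memory coordinates are 1-based inclusive; only the BED writers
convert to 0-based half-open at the boundary.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

VALID_CONTEXTS = ("CG", "CHG", "CHH")
REPEAT_FAMILIES = ("LINE", "SINE", "LTR", "Simple")

CGMAP_COLUMNS = [
    "chrom", "nucleotide", "pos", "context", "dinucleotide_context",
    "level", "meth_reads", "total_reads",
]

#: printed precision of the level column; the reader always stores the
#: exact meth/total ratio and uses the file value only for validation
_LEVEL_PRINT_TOL = 5e-7


@dataclass(frozen=True)
class MethylationCall:
    """One cytosine's observation from a bisulfite methylation call file."""

    chrom: str
    pos: int                     # 1-based position of the cytosine
    strand: str                  # '+' (C on the forward strand) or '-'
    context: str                 # CG / CHG / CHH
    dinucleotide_context: str    # raw context string from the call file
    level: float                 # meth_reads / total_reads, in [0, 1]
    meth_reads: int
    total_reads: int

    def __post_init__(self):
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise ValueError(
                f"meth_reads {self.meth_reads} outside [0, {self.total_reads}]")
        if self.total_reads > 0 and abs(self.level - self.meth_reads / self.total_reads) > 1e-9:
            raise ValueError("level inconsistent with read counts")


@dataclass(frozen=True)
class GeneModel:
    """A single-interval gene record with an ordered exon chain."""

    gene_id: str
    chrom: str
    strand: str
    start: int   # 1-based inclusive
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: missing or invalid strand")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s}, {e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int
    end: int
    family: str

    def __post_init__(self):
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"repeat family {self.family!r} not one of {REPEAT_FAMILIES}")
        if self.start > self.end:
            raise ValueError("repeat start > end")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    tissue: str
    group: str
    path: str


@dataclass
class SampleSet:
    """Biological replicates and their tissue/group structure."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            raise ValueError("SampleSet needs at least one sample")
        for g in self.group_labels:
            if not self.for_group(g):
                raise ValueError(f"group {g} has no samples")

    @property
    def group_labels(self) -> list[str]:
        seen = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def for_group(self, group: str) -> list[Sample]:
        return [s for s in self.samples if s.group == group]


def _open_text(path: str | os.PathLike) -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _apply_chrom_prefix(chrom: str, mode: str) -> str:
    if mode == "add":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if mode == "strip":
        return chrom[3:] if chrom.startswith("chr") else chrom
    return chrom


def read_cgmap(path, min_coverage: int = 0, chrom_prefix: str = "keep") -> Iterator[MethylationCall]:
    """Stream methylation calls from a CGmap-dialect file.

    Calls with ``total_reads < min_coverage`` are dropped when
    ``min_coverage > 0``.  Strand is inferred from the nucleotide column
    (``C`` = forward, ``G`` = reverse).  ``chrom_prefix`` may be ``keep``
    (default; exact names), ``add`` or ``strip`` to normalise a ``chr``
    prefix explicitly — no silent renaming is done.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 8:
                chrom, nuc, pos_s, ctx, dinuc, level_s, meth_s, tot_s = fields
            elif len(fields) == 7:
                chrom, nuc, pos_s, ctx, dinuc, meth_s, tot_s = fields
                level_s = None
            else:
                raise ValueError(f"{path}: line {lineno}: expected 7 or 8 columns, got {len(fields)}")
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                total = int(tot_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed integer field") from exc
            if nuc not in ("C", "G"):
                raise ValueError(f"{path}: line {lineno}: nucleotide must be C or G, got {nuc!r}")
            if ctx not in VALID_CONTEXTS:
                raise ValueError(f"{path}: line {lineno}: unknown context {ctx!r}")
            if not (0 <= meth <= total):
                raise ValueError(f"{path}: line {lineno}: meth_reads outside [0, total_reads]")
            exact = meth / total if total > 0 else 0.0
            if level_s is not None:
                try:
                    level = float(level_s)
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: malformed level") from exc
                if not (0.0 <= level <= 1.0):
                    raise ValueError(f"{path}: line {lineno}: level {level} outside [0, 1]")
                if total > 0 and abs(level - exact) > _LEVEL_PRINT_TOL:
                    raise ValueError(f"{path}: line {lineno}: level inconsistent with read counts")
            if min_coverage > 0 and total < min_coverage:
                continue
            yield MethylationCall(
                chrom=_apply_chrom_prefix(chrom, chrom_prefix),
                pos=pos,
                strand="+" if nuc == "C" else "-",
                context=ctx,
                dinucleotide_context=dinuc,
                level=exact,
                meth_reads=meth,
                total_reads=total,
            )


def read_cgmap_frame(path, min_coverage: int = 0, chrom_prefix: str = "keep") -> pd.DataFrame:
    """Vectorised CGmap reader returning the pipeline's site table.

    Columns: chrom, pos, strand, context, level, meth, total.  Same
    semantics as :func:`read_cgmap`; validation is vectorised (the first
    offending line is not named, use :func:`read_cgmap` to locate it).
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    df = pd.read_csv(path, sep="\t", header=None, names=CGMAP_COLUMNS,
                     dtype={"chrom": str, "nucleotide": str, "context": str,
                            "dinucleotide_context": str})
    if df["total_reads"].isna().any():
        # 7-column variant: shift level out, recompute below
        df = pd.read_csv(path, sep="\t", header=None, names=CGMAP_COLUMNS[:5] + CGMAP_COLUMNS[6:],
                         dtype={"chrom": str, "nucleotide": str, "context": str})
        df["level"] = np.nan
    bad_nuc = ~df["nucleotide"].isin(["C", "G"])
    if bad_nuc.any():
        raise ValueError(f"{path}: invalid nucleotide column value(s)")
    if not df["context"].isin(VALID_CONTEXTS).all():
        raise ValueError(f"{path}: unknown context value(s)")
    if ((df["meth_reads"] < 0) | (df["meth_reads"] > df["total_reads"])).any():
        raise ValueError(f"{path}: meth_reads outside [0, total_reads]")
    total = df["total_reads"].to_numpy()
    exact = np.where(total > 0, df["meth_reads"].to_numpy() / np.maximum(total, 1), 0.0)
    file_level = df["level"].to_numpy(dtype=float)
    stated = ~np.isnan(file_level)
    if ((file_level[stated] < 0) | (file_level[stated] > 1)).any():
        raise ValueError(f"{path}: level outside [0, 1]")
    chk = stated & (total > 0)
    if np.abs(file_level[chk] - exact[chk]).max(initial=0.0) > _LEVEL_PRINT_TOL:
        raise ValueError(f"{path}: level column inconsistent with read counts")
    out = pd.DataFrame({
        "chrom": df["chrom"].map(lambda c: _apply_chrom_prefix(c, chrom_prefix)),
        "pos": df["pos"].astype(np.int64),
        "strand": np.where(df["nucleotide"] == "C", "+", "-"),
        "context": df["context"],
        "level": exact,
        "meth": df["meth_reads"].astype(np.int64),
        "total": df["total_reads"].astype(np.int64),
    })
    if min_coverage > 0:
        out = out[out["total"] >= min_coverage].reset_index(drop=True)
    return out


def calls_to_frame(calls: Iterable[MethylationCall]) -> pd.DataFrame:
    rows = [(c.chrom, c.pos, c.strand, c.context, c.level, c.meth_reads, c.total_reads)
            for c in calls]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "level", "meth", "total"])


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path, chrom_prefix: str = "keep") -> list[GeneModel]:
    """Load gene models from GFF3 or BED12, detected by extension."""
    p = os.fspath(path)
    if p.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        genes = _read_gff3(p)
    elif p.endswith((".bed", ".bed12", ".bed.gz")):
        genes = _read_bed12(p)
    else:
        raise ValueError(f"cannot infer annotation format from {p!r} (expect .gff3 or .bed)")
    if chrom_prefix != "keep":
        genes = [GeneModel(g.gene_id, _apply_chrom_prefix(g.chrom, chrom_prefix),
                           g.strand, g.start, g.end, g.exons) for g in genes]
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {feat.id}: missing strand in GFF3")
        exons = sorted((c.start, c.end) for c in db.children(feat, featuretype="exon"))
        if not exons:
            exons = [(feat.start, feat.end)]
        genes.append(GeneModel(gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
                               start=feat.start, end=feat.end, exons=tuple(exons)))
    return genes


def _read_bed12(path: str) -> list[GeneModel]:
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}: line {lineno}: need >=6 BED columns")
            chrom, cstart, cend, name, _score, strand = f[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: missing strand")
            start = int(cstart) + 1     # 0-based half-open -> 1-based inclusive
            end = int(cend)
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(sorted((start + o, start + o + sz - 1)
                                     for o, sz in zip(offs, sizes)))
            else:
                exons = ((start, end),)
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand,
                                   start=start, end=end, exons=exons))
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\tmethkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.chrom}\tmethkit\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")


def write_gene_models_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            sizes = ",".join(str(e - s + 1) for s, e in g.exons) + ","
            offs = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            fh.write("\t".join(map(str, [
                g.chrom, g.start - 1, g.end, g.gene_id, 0, g.strand,
                g.start - 1, g.end, "0,0,0", len(g.exons), sizes, offs])) + "\n")


# ---------------------------------------------------------------------------
# repeats


def read_repeats(path, chrom_prefix: str = "keep") -> list[RepeatElement]:
    """Read repeat elements from BED with the family in the name column.

    Compound RepeatMasker classes like ``SINE/Alu`` are reduced to the
    class prefix; anything outside LINE/SINE/LTR/Simple raises.
    """
    reps = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: need chrom/start/end/family")
            fam = f[3].split("/")[0]
            if fam.startswith("Simple"):    # RepeatMasker "Simple_repeat"
                fam = "Simple"
            if fam not in REPEAT_FAMILIES:
                raise ValueError(f"{path}: line {lineno}: repeat family {f[3]!r} "
                                 f"not one of {REPEAT_FAMILIES}")
            reps.append(RepeatElement(chrom=_apply_chrom_prefix(f[0], chrom_prefix),
                                      start=int(f[1]) + 1, end=int(f[2]), family=fam))
    return reps


def write_repeats_bed(repeats: Iterable[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.family}\n")


# ---------------------------------------------------------------------------
# DMR tables

DMR_TABLE_COLUMNS = ["chrom", "start", "end", "group_A", "group_B", "level_A",
                     "level_B", "delta", "n_CG", "annotated_genes", "criteria"]


def write_dmr_table(dmrs, path, annotations=None) -> None:
    """Write DMRs as a TSV with one row per window.

    ``annotations`` is an optional list of DMRAnnotation records; gene ids
    and criteria of annotations matching a DMR's coordinates are joined
    with ``;`` into the last two columns.
    """
    by_key: dict[tuple, list] = {}
    for a in annotations or []:
        if a.gene_id is not None:
            key = (a.dmr.chrom, a.dmr.start, a.dmr.end, a.dmr.group_a, a.dmr.group_b)
            by_key.setdefault(key, []).append(a)
    with open(path, "w") as fh:
        fh.write("\t".join(DMR_TABLE_COLUMNS) + "\n")
        for d in dmrs:
            key = (d.chrom, d.start, d.end, d.group_a, d.group_b)
            anns = by_key.get(key, [])
            fh.write("\t".join([
                d.chrom, str(d.start), str(d.end), d.group_a, d.group_b,
                f"{d.level_a:.6f}", f"{d.level_b:.6f}", f"{d.delta:.6f}",
                f"{d.n_cg_a},{d.n_cg_b}",
                ";".join(a.gene_id for a in anns),
                ";".join(a.criterion for a in anns),
            ]) + "\n")


def read_dmr_table(path):
    """Re-read a DMR TSV written by :func:`write_dmr_table`."""
    from .dmr import DMR

    dmrs = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DMR_TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected DMR table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            n_a, n_b = (int(x) for x in f[8].split(","))
            dmrs.append(DMR(chrom=f[0], start=int(f[1]), end=int(f[2]),
                            group_a=f[3], group_b=f[4],
                            level_a=float(f[5]), level_b=float(f[6]),
                            n_cg_a=n_a, n_cg_b=n_b))
    return dmrs


def write_dmr_bed(dmrs, path) -> None:
    """BED6 export: 0-based half-open, score = round(1000 * |delta|)."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = min(1000, round(1000 * abs(d.delta)))
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t"
                     f"{d.group_a}_vs_{d.group_b}\t{score}\t.\n")


def read_samples_table(path) -> SampleSet:
    """Read a 4-column TSV: sample_id, tissue, group, path-to-CGmap."""
    samples = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, tissue, group, p = line.split("\t")[:4]
            samples.append(Sample(sid, tissue, group, p))
    return SampleSet(samples)
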