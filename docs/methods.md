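# Methods

## Scope and data model

methkit implements the downstream half of a WGBS study: it consumes
per-cytosine methylation calls and genome annotations; read alignment,
methylation calling and QC are upstream and out of scope. The working
container is a pandas site table (`chrom, pos, strand, context, level,
meth, total`), one row per cytosine observation. All coordinates are
1-based and inclusive on both ends throughout the package, matching
printed genome-browser coordinates; conversion to 0-based half-open BED
happens only in the BED writers. Chromosome names are matched by exact
string equality — a `chr_prefix` loader option adds or strips the
prefix explicitly, but nothing is renamed silently, so
annotation/genome mismatches surface as empty joins rather than being
papered over.

The CGmap dialect read and written here has eight tab-separated
columns: chromosome, nucleotide (C = forward strand, G = reverse),
position, context (CG/CHG/CHH), raw dinucleotide context, level,
methylated reads, total reads. A seven-column variant without the level
column is accepted, the level being recomputed as meth/total. Because
the writer prints levels at six decimals, the reader treats the file's
level column as a checksum (tolerance 5 × 10⁻⁷ against meth/total) and
always stores the exact ratio, so in-memory levels are consistent with
the counts to full precision.

## Level definitions

* A site requires ≥ 3× coverage (configurable) to enter any analysis.
* The level of a region is the **unweighted** mean of the site levels
  of the requested context inside it: a site covered 30× counts the
  same as one covered 3×. A read-weighted mode
  (`region_level(..., weighted=True)`) exists for comparison but is
  never the default.
* A region with no qualifying site has an *undefined* level,
  represented as NaN and excluded from downstream means — zero is a
  valid methylation level and is never used as a placeholder.
* A sample's level is the mean over genes of the level of the gene
  body plus its ±15 kb flanks, computed jointly over the superinterval
  (not body and flanks separately and then combined); genes with no
  qualifying CG are excluded. A group's level is the unweighted mean of
  its member samples.
* The two strands of a CpG dinucleotide are independent sites by
  default; `merge_symmetric_cpg` pools their read counts onto the
  forward C before filtering when strand-collapsed depth is wanted.

## Metagene and feature profiles

The metagene axis is 15 kb upstream (75 × 200 bp bins), the gene body
in 100 proportional bins, and 15 kb downstream, always oriented
5′→3′ of transcription (minus-strand genes are mirrored). Proportional
body bins let genes of different lengths align; a site at an exact
proportional boundary goes to the lower bin, and genes shorter than
100 bp simply spread their sites over the valid bins. Per-gene bin
means are averaged across genes with data, so CG-dense genes do not
dominate; bins with no data stay missing. Overlapping genes each see
every site (no deduplication), and flanks running off a chromosome end
just collect nothing.

Feature-class levels pool all CG sites falling inside any interval of
the class: the four repeat families, intragenic (merged gene bodies),
intergenic (the ±15 kb flank universe minus gene bodies), merged
exons, and introns (gene body minus exons). A site inside two classes
counts in both. Pooling over sites is the default; a per-element mode
(mean of per-element means) is available since the two conventions
differ whenever element sizes vary.

## Promoter analysis

CG dinucleotides are counted on the forward-strand sequence (CG equals
its own reverse complement, so the count is strand-independent, and CG
cannot overlap itself); a CG straddling a bin boundary belongs to the
bin containing its forward C. The TSS ± 10 kb scan uses 100 × 200 bp
strand-oriented subregions; subregions truncated at a chromosome end
are flagged and excluded from the aggregate. The promoter proper is
TSS ± 2 kb in 20 × 200 bp bins named bin−10…bin−1, bin1…bin10 (no
bin0): on the forward strand bin1 = [TSS, TSS+199]; on the reverse
strand bin1 = [TSS−199, TSS].

The classification statistic is the mean CG count per bin over the 20
bins (total/20): HCG strictly above 8, LCG strictly below 4, ICG the
closed interval [4, 8]. The boundary values 4 and 8 are ICG, making the
three classes disjoint and exhaustive; truncated grids are classified
on their available bins and flagged. Per-class methylation profiles
average each bin over genes with data in it, and the per-class overall
mean averages each gene's mean over its defined bins.

## DMR screening

Windows are 600 bp starting at position 1 and stepping 300 bp (the
phase is configurable); windows that would overrun the chromosome are
dropped rather than truncated. Group aggregation defaults to read
pooling: meth and total are summed per site across a group's
replicates and the ≥ 3× filter applies to the pooled depth — this
yields the single level per group per window that a two-sample
comparison needs. A replicate-mean mode (per-replicate filtering, then
per-site level averaging) is provided for comparison. A window enters
the comparison only when both groups have ≥ 3 qualifying CGs in it;
windows defined in one group only are skipped. The difference
threshold |Δ| ≥ 0.15 is inclusive, guarded by a 10⁻¹² epsilon so a
constructed difference of exactly 0.15 is never lost to float
round-off. Flagged windows are reported individually and never merged:
a reported DMR is always one raw 600 bp window. No significance test
is attached — the threshold rule is the entire criterion, and the
caller's operating characteristics are instead quantified by the
sensitivity/specificity harnesses below.

Annotation records every (DMR, gene) pair with positional
intersection, labelled by the most specific relation — `dmr_in_gene`
when the window lies inside the gene span, `gene_in_dmr` for the
converse, `overlap` otherwise; identical intervals resolve to
`dmr_in_gene` for determinism. Unannotated DMRs are kept with an empty
gene field.

## Synthetic study generator

The generator emulates the downstream structure of a two-breed sheep
WGBS comparison at desk scale. Defaults: 2 chromosomes × 2 Mb, 40
genes, 200 repeats, seven groups (four muscle, three tail-fat) of 3–4
replicates, mean coverage 20.78×.

* **Genome.** Random sequence with background CG dinucleotides
  depleted to mammalian-style density (70% of random CGs are mutated
  away). Genes are placed non-overlapping in equal slots with 12 kb
  margins so every TSS ± 10 kb window fits; both strands occur; 2–4
  exons per gene. Each gene is assigned a designed promoter class
  (default 40% HCG / 40% ICG / 20% LCG) and its TSS ± 2 kb is rewritten
  to exactly 12 / 6 / 2 CGs per 200 bp bin, so sequence-based CG
  counting recovers the designed classes exactly. Repeats of the four
  families are placed in intergenic space, clear of promoters.
* **Methylation.** Each site receives one latent methylation
  probability per genome, shared by every replicate of every group —
  replicates differ only in Poisson(coverage) depth and binomial read
  sampling, so planted effects are exactly interpretable (an optional
  Beta jitter per replicate exists but is off by default). CG latents
  come from a bimodal Beta mixture (modes 0.9 / 0.1, 68% high), which
  puts about two thirds of CGs above 0.5 as in real mammalian tissue.
  Non-CG latents are a strongly zero-inflated Beta (concentration 2)
  with mean 0.05 — most CHG/CHH sites sit near zero, though the
  simulated fraction below 0.1 (≈ 86%) remains somewhat smaller than
  in real bisulfite data, where non-CG calls are dominated by
  conversion noise.
* **TSS dip.** Latent CG levels within ±2 kb of each TSS are
  multiplied by 1 − depth·f·(1 − d/2000)², a quadratic dip that is
  steep at the TSS so the metagene minimum localises there. The depth
  factor f scales with the designed promoter class (HCG 1.0, ICG 0.6,
  LCG 0.25), planting the negative CG-density/methylation relationship
  (LCG > ICG > HCG promoter levels).
* **Repeats.** Latent CG levels inside repeats are redrawn around
  family means (SINE 0.747, LINE 0.72, LTR 0.70, Simple 0.567),
  planting the SINE-highest / Simple-lowest ordering.
* **Planted DMRs.** Inside a planted interval the *second* group of
  the pair has its latent levels shifted by delta, clipped to [0, 1];
  clipping means the realised group difference can be smaller than
  |delta| where the base level leaves little headroom, which the
  recovery harness tolerates by design (a 0.4 plant still yields
  window deltas well above 0.15).
* **Determinism.** All randomness derives from `seed` through separate
  named substreams for the genome, the latent field per chromosome and
  each replicate, so a config reproduces byte-identical files.

What the generator does **not** emulate: read-level artifacts
(incomplete bisulfite conversion, mapping bias, SNPs), realistic
chromosome counts and gene density, linkage between neighbouring
sites beyond the planted structure, or tissue differences in non-CG
methylation (tissues share one latent field by default). Passing tests
therefore certify the *procedures* — geometry, filters, thresholds,
aggregation arithmetic, recovery of planted structure — not
quantitative agreement with any real methylome. One visible artifact:
because the planted promoter dip eats into gene-body starts, synthetic
intragenic levels run slightly below intergenic ones, the reverse of
typical real tissue; no test asserts that ordering.

## Problem sizes and harnesses

The test suite and acceptance script choose deliberately small
studies: the shared fixture is 2 × 600 kb with 24 genes and two
3-replicate groups; the acceptance study is 2 × 500 kb, 20 genes, three
tail-fat groups (3/4/3 replicates) with three planted DMRs. The
sensitivity harness replays 50 seeds of a 60 kb genome with a planted
|Δ| = 0.4, 900 bp region at 20× and 3 replicates per group and reports
the fraction of seeds recovering an overlapping call; the specificity
harness scans ≥ 10,000 windows of a 3.21 Mb null genome where both
groups share every latent level, so any flag is pure sampling noise.
With ~13 pooled CGs per window at ~60× pooled depth, the null standard
deviation of a window delta is ≈ 0.025, putting the 0.15 threshold at
six sigma — the observed false-flag rate is zero.

## Numerical and degenerate-input choices

* Window and region means are computed with numpy pairwise summation
  over the same site multiset a brute-force scan would use; oracle
  tests require agreement to 10⁻¹².
* Distribution bins are right-closed, `(eᵢ, eᵢ₊₁]`, with the first bin
  closed on both sides, so the split at 0.5 means "≤ 0.5 vs > 0.5".
* Empty regions, empty bins, empty promoter classes and windows
  defined in one group are missing/skipped, each with a warning or log
  count rather than a zero.
* Gene placement that cannot satisfy the density/margin constraints
  fails fast with a message suggesting a longer chromosome.
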