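# Methods

## Sliding-window enrichment and the ratio-of-ratios

Footprint counts are consumed already assigned to codons (P-site
offsetting of raw reads is an upstream concern). For each codon
position the counts of a sample are summed over a window of
`2 * window_half_width + 1` codons, truncated at gene boundaries
rather than dropping edge positions — truncation keeps the profile
the same length as the gene, at the cost of larger variance near the
ends. Each windowed sum is divided by the sample's total mapped reads;
the reads-per-million constant cancels in every ratio and is omitted
internally. Enrichment at a position is the normalized pulldown window
over the normalized input window. Positions whose input window is
empty are **undefined (NaN), never infinite, and no pseudocount is
added**: the expression filter already removes genes with empty
windows from client calling, and a pseudocount would silently bias the
statistic everywhere else.

The ratio-of-ratios divides the test bait's enrichment by a reference
ER bait's enrichment position by position (defined only where both
are), cancelling generic ER-targeting signal; a gene's score in a
replicate is its maximum over defined positions. Replicates are kept
separate through ranking and only intersected at the final client
call.

Sample totals are carried per sample rather than recomputed from the
profile table, because a profile collection may cover only a subset of
genes while normalization must reflect the whole library.

## Eligibility filters

All boundary semantics are deliberate and tested:

| filter       | rule                                                            | boundary |
|--------------|-----------------------------------------------------------------|----------|
| mappability  | fraction of uniquely mappable read-start positions > 0.80       | strict > |
| expression   | input density > 0.02 reads/codon/million, all input samples; no empty 101-codon window in any sample | strict > |
| localization | pulldown/input RPKM ratio > 1 in ≥ 1 sample pair                | strict > |

Mappability tests every read-length substring of a CDS against the
pool of all sense-strand substrings of the CDS collection (the
analysis universe is the coding sequences the reads were aligned to,
not a genome); a position is unique iff its k-mer occurs exactly once.
Genes shorter than the read length have no testable position and are
unmappable by definition. Gene length cancels in the RPKM ratio, so
the localization filter is equivalently a totals-normalized read-share
ratio; pairs with zero input reads contribute nothing.

## Client calling

Ranking is computed **among eligible genes** (genes surviving all
three filters); ineligible genes have no defined statistic, and genes
whose maximum is undefined in any replicate are recorded as expression
failures. A configuration switch (`rank_among_all`) supports the
alternative reading in which thresholds are computed over all genes
with defined maxima.

The top decile is operationalized as `k = floor(N * (100 − p) / 100)`
slots per replicate (p = 90 by default); the threshold is the k-th
largest maximum and **boundary ties are all included**. This counting
rule is deterministic, guarantees at most 10% of eligible genes per
replicate when values are distinct, selects exactly the top gene for
N = 10, and degrades gracefully under total ties (everything tied at
the threshold is called). When N < 10 no slot exists and no gene is
called. A gene is a client iff it reaches the threshold in **every**
replicate (at least two replicates are required).

## TMD annotations and composition

Two annotation sources are merged: prediction-style spans and
curated-style spans, both in 1-based inclusive protein coordinates
(protein length equals codon count because stop codons are excluded
from gene lengths, so TMD coordinates align 1:1 with profile
coordinates). A predicted span sharing at least one residue with a
curated span of the same gene is dropped in favor of the curated span;
spans from excluded genes (mitochondrially encoded, dubious ORFs,
pseudogenes) are removed.

Composition statistics pool residues across all spans of a set, so
long TMDs weigh more — the unit of observation is the residue, not the
gene. The residue property table is shipped as editable package data
(`data/aa_properties.tsv`): ALIPHATIC {A,V,L,I}; AROMATIC {F,W,Y};
CHARGED {D,E,K,R}; HYDROPHOBIC {A,V,L,I,M,F,W,C}; POLAR
{S,T,N,Q,Y,H,C}. The categories overlap by design (F is aromatic and
hydrophobic); alternative conventions (e.g. histidine charged) are a
one-line edit. G and P carry no property.

The null band resamples `n_bootstrap` subsets of **the same number of
TMD spans as the client set** (span count, not gene count — a
per-gene reading is available by passing one span per gene), drawn
uniformly **without replacement** from the full TMD set; the 5th and
95th percentiles of the resampled fraction ratios form the band. The
band answers "could a random same-size TMD subset show this ratio?",
so under a null client draw it covers the observed ratio ~90% of the
time; this calibration is verified empirically in the tests. Sampling
is chunked internally to bound memory, and a fixed seed reproduces the
drawn subsets bit for bit.

## Metagene curves

Profiles are aligned at the first codon of the earliest TMD (offset
0), default offsets −50..+250 codons — wide enough to span the
targeting ramp (~60 codons downstream) and the later client-specific
rise. Averaging is **unweighted at the gene level** and uses raw
enrichment values; per-gene normalization before averaging is a
different statistic and is deliberately not the default. The rise
midpoint diagnostic takes baseline and plateau as curve means over
offset windows (defaults −40..0 and 90..130) and reports the first
offset crossing their midpoint.

## Proteome partition

Proteins are partitioned on two log2 knockdown-vs-control ratios at an
**inclusive** threshold (default 0.5): down-in-both, up-in-both,
other. "Significant" is operationalized as the fold-change threshold
alone — no replicate-based test statistic is modelled. Subunits of the
depleted complex can be listed for separate reporting, since one
knockdown destabilizes the whole complex. Down-regulated proteins
whose translation also drops by the threshold are flagged as
translationally driven (synthesis, not degradation); records lacking
translation values are skipped and counted. The topology summary
reports ≥1-TMD, multipass (≥2) and soluble counts, plus the same at
the 2-fold (|log2| ≥ 1) stringency.

## The synthetic-data generator

The generator emulates the data-generating process the analysis
assumes, with one seeded `numpy.random.Generator` threaded through all
stages (no hidden global randomness).

**Transcriptome.** Random coding sequences drawn uniformly over the 61
sense codons (translations therefore contain no internal stops). A
fraction of genes (default 0.4) carries TMD architecture: one TMD or,
with probability 0.6, a multipass cluster of 2–5 TMDs of 21 codons
separated by 5–15-codon loops, starting 30–80 codons into the gene.
Gene lengths (uniform 350–800 codons) are resampled, boundedly, until
the cluster plus peak offset plus a 110-codon downstream margin fits,
so a full 101-codon window always lies inside the client peak region.

**Clients.** Planted only among multipass genes, at 0.08 of TMD genes
overall. The rate is kept below the decile capacity of the eligible
set on purpose: the calling rule can select at most `floor(N/10)`
genes per replicate, so planting clients at exactly 10% would make
full recovery impossible whenever the binomial draw overshoots —
recovery would then measure the draw, not the method.

**Profiles.** Input counts per codon are Poisson (or gamma-mixed
Poisson for overdispersion) around `input_depth ×` a log-normal
(σ = 0.5) per-gene expression factor — expression varies so the
expression filter has real work to do. Pulldown means multiply the
input mean by a capture efficiency (0.25 for ER-targeted genes, 0.05
background — the pulldown is composition-shifted toward ER genes,
which is precisely what the localization filter detects) and by a
positional enrichment: 1 before the targeting ramp, a logistic rise
(amplitude 4, width 20 codons) centred 60 codons after the first TMD
for **every** ER bait, further multiplied by the client peak gain
(default 4) from 20 codons after the cluster end onward — for client
genes under the test bait only. The reference bait shares the ramp
but never the peak. The ramp is logistic rather than a step because
the ~60-codon onset is approximate in nature and smoothness avoids
brittle tests. Sample totals are the realistic per-sample sums; a
consequence is that a TMD-less gene's enrichment is a flat constant
below 1 (set by the composition shift), while its ratio-of-ratios —
where that constant cancels — is ~1.

**Analytic mode.** Counts are replaced by their expected rates and
every sample carries a common nominal total (the matched-normalizer
idealization). In this infinite-depth limit the maximum
ratio-of-ratios of a planted client equals the peak gain exactly,
which pins the estimator's closed form against the generator.

**Proteome.** Client proteins shift by −1.0 log2 in both knockdowns;
everything else is N(0, 0.2) noise. A 10% fraction of clients is
translationally driven. With these values the per-client recovery
probability at the 0.5 threshold is Φ(2.5)² ≈ 0.975.

**What the generator does not model** — and hence what passing tests
do not show about real data: codon-level pausing and ribosome dwell
heterogeneity, rRNA contamination, ligation/sequence bias,
UTR-proximal artifacts, correlated replicates, compositional biases of
real TMDs (simulated TMD residues are drawn like any others, which is
what makes the composition null exact), and shared-sequence paralogy
beyond what uniform random sequences produce (mappability failures are
essentially absent in simulation and are exercised by constructed
cases instead).

## Problem sizes and numerical choices

Simulation-based checks use 500 genes × 2 replicates at depth 20 for
client recovery (10 seeds), 300 genes for metagene structure, a
~460-span TMD pool with 40-span subsets × 500 null repetitions at
1,000 resamples for band calibration, and 3 × 1,500 genes for
proteome recovery — sizes chosen so each check is statistically
informative while the whole suite runs in well under a minute per
stage. Windowed sums use cumulative-sum differences (exact for
integer counts); float comparisons in oracle tests are at 1e-12
relative tolerance; undefined values propagate as NaN end to end and
are written as `NA`.

## Known limitations

* Mappability is exact-match and sense-strand only; mismatch-tolerant
  or genome-wide multi-mapping is out of scope.
* No significance model for individual enrichment peaks — the method
  ranks, it does not test; likewise the proteome partition has no
  moderated test statistic.
* The per-position TMD composition variant bins relative position
  (default 7 bins) rather than reproducing any particular published
  binning.
* `run-all` orchestrates the simulated workflow; real-data analyses
  compose the per-stage subcommands or the library API directly.
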