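# Methods

## The measurement model

Tag-based DGE represents each transcript by short restriction-anchored
tags: NlaIII cuts at CATG, MmeI cuts 17 bp downstream, so every observable
tag is a 21-mer beginning with CATG. A library is a multiset of such tags;
expression is estimated by counting tags per gene and normalizing by
library size (tags per million, TPM). Because the measurements are
relative, everything downstream — fold changes, significance — is about
composition, not absolute abundance.

### Virtual tag reference

The mapping reference is the set of all CATG+17 windows of the
transcriptome's sense strand (3′-capture library preparation sequences
sense tags; antisense indexing is deliberately not performed). Sites with
fewer than 17 nt downstream produce no tag; windows containing N are
skipped rather than expanded over IUPAC alternatives, keeping the index
exact. A tag whose sites span more than one gene is flagged ambiguous;
identical tags at several sites of one gene are a single unambiguous entry,
because ambiguity is about gene identity, not position. Coordinates are
0-based half-open internally and 1-based only in human-readable reports.

### Cleaning

Raw reads pass through: 3′-adaptor trimming (a read must be a 21-nt insert
followed by sequence consistent with the adaptor; exact-21-nt reads pass
through; shorter reads are adaptor-only/empty and rejected), quality
filtering, then singleton removal. "Low quality" is operationalized as any
N or any base below Q10 — conservative, because for a 21-nt tag a single
bad base defeats 1-mismatch mapping; the threshold is configurable.
Counting precedes singleton removal so retained copy numbers reflect the
full library, and cleaning is per library. The conservation identity
`total_clean + rejected + singleton_copies = total_raw` holds exactly and
is asserted in tests.

### Mapping

A clean tag is assigned by exact hash lookup first; only if there is no
exact hit are its 63 single-substitution neighbours looked up. This gives
exact-match priority: a perfect hit is never outvoted by neighbours. The
union of hit gene sets decides: one gene → assigned; several → ambiguous,
discarded; none → unmapped. The four outcomes partition the distinct clean
tags. The TPM denominator is by default the total clean-tag count of the
library (mapped or not), with a mapped-only denominator available — the
choice only rescales all TPMs of a library by a common factor and does not
change calls when applied to both libraries.

### Differential expression without replicates

With one sequencing run per condition, the Audic–Claverie exact test is
the appropriate significance measure: conditioned on observing x tags for
a gene in a library of N₁ tags, the posterior-predictive probability of y
tags in a library of N₂ tags is

    P(y | x) = (N₂/N₁)^y (x+y)! / ( x! y! (1 + N₂/N₁)^(x+y+1) )

i.e. y | x ~ NegativeBinomial(x+1, N₂/(N₁+N₂)). The two-sided p-value is
min(1, 2·min(P(Y ≤ y), P(Y ≥ y))), with both tails inclusive of the
observed y. Tail sums are computed in log space (log-gamma terms,
log-sum-exp accumulation); the upper tail is obtained as 1 − P(Y < y) with
non-negativity clamping, avoiding infinite summation. The implementation
agrees with arbitrary-precision rational summation to better than 1e-9
over the tested grid.

One property worth knowing: the statistic conditions on the first
library's count, so it is not exactly symmetric under swapping the
libraries — P(Y ≤ y | x) = 1 − P(X ≤ x | y) (an inclusive/exclusive
offset), and the doubled-min p-values of the two orientations can differ
noticeably at single-digit counts. Log₂ ratios are exactly antisymmetric
under the swap, and calls mirror except for genes sitting exactly at the
FDR boundary. This is inherent to the test, not an implementation detail.

Fold changes are log₂(TPM₂/TPM₁) with both TPMs floored; the default
floor is half a tag's worth of TPM per library (0.5/N·10⁶), so a zero
count yields a finite, depth-dependent extreme rather than ±∞. FDR is
Benjamini–Hochberg step-up over all genes observed in at least one
library; a gene is called up (down) when FDR < 0.05 and the log₂ ratio is
≥ +1 (≤ −1). All thresholds are parameters.

### Enrichment

Term over-representation among DEGs uses the upper-tail hypergeometric
probability P[X ≥ m] for a term with M of N background genes annotated and
m of n DEGs annotated, computed via the survival function of
`scipy.stats.hypergeom`. Term gene sets are intersected with the
background before testing; DEGs outside the background are dropped with a
warning. Following the flagging convention of classic tag-DGE reports, the
enriched flag uses the raw p < 0.05; a BH-adjusted column is emitted
alongside for readers who want it. Annotations are consumed pre-flattened
(no GO DAG propagation).

### qPCR concordance

Relative expression is 2^−ΔΔCt with an assumed amplification efficiency of
exactly 2: replicate Ct values are averaged per (group, gene) first, the
target is normalized against the reference gene within each group, and
each treatment is referenced to the control group. A qPCR/DGE test is
"consistent" when the two log₂ values share a nonzero sign, or when both
magnitudes are below 0.25 (joint no-change); this operationalization — the
band in particular — is this package's definition, chosen because sign
agreement alone is meaningless for genes near zero change.

### Saturation

Detected genes (≥ 1 unambiguously mapped tag) are counted along prefixes
of one fixed random permutation of the raw tag stream; using nested
prefixes makes the curve non-decreasing by construction and reproducible
from the seed.

## The synthetic-data generator

The generator emulates the study design this analysis was built for: one
control and one treated library, no replicates, tag counts only.

* **Transcriptome** — `n_genes` i.i.d. random sequences (default 2,000,
  lengths 300–1,500 nt) with a CATG planted 21 nt from the 3′ end, so
  every gene has a valid, 3′-most tag site and is detectable. Additional
  CATG sites occur by chance and enter the index like real internal sites.
* **Abundances** — log-normal relative abundances (default σ = 1.2,
  spanning roughly three orders of magnitude, typical of tag-DGE
  libraries).
* **Planted differential expression** — a fraction (default 10%) of genes
  receives a log₂ fold change of magnitude 2–5 (configurable). Each DE
  gene's effect is applied as a 2^|lfc| boost to exactly one condition
  (boost in the treated library = up-regulated; boost in the control =
  down-regulated, i.e. the gene rests high and drops), and the side
  assignment uses a greedy mass partition so the total planted tag mass is
  the same in both conditions. After renormalization both conditions are
  proper sampling distributions *and* non-DE genes keep equal relative
  abundance — without the balancing step, large one-sided effects dilute
  every other gene and the recorded truth (log₂ fold change 0 for non-DE
  genes) would be wrong in a relative-abundance world. The residual
  imbalance of the greedy partition is below the smallest planted effect
  mass (relative error ≲ 1e-3).
* **Sampling** — each library is a multinomial draw of the configured size
  (default 200,000) from its condition's abundances; each gene emits its
  3′-most tag (the fragment anchored to the 3′ end is the one the MmeI
  chemistry tags). Every emitted base is substituted independently with
  probability `error_rate` (default 0.005). A fraction of reads (default
  1%) is replaced by random unique 21-mers verified to have no exact or
  1-mismatch hit in the index, so they deterministically exercise the
  singleton-removal and unmapped paths.
* **Annotations** — random term/gene sets (sizes 10–30), with planted
  terms drawing ≥ 80% of their members from DE genes so enrichment
  recovery is testable.
* **qPCR tables** — triplicate Ct values in which each assayed gene's
  measured log₂ fold change equals the planted truth plus N(0, 0.3)
  noise; DE genes are preferentially assayed, mirroring how validation
  panels are chosen.

Everything is a deterministic function of the seed (byte-identical
outputs on re-run).

**What the generator does not model** — PCR amplification bias, indels,
adapter read-through, position- or quality-dependent error profiles,
tag-site preference heterogeneity, and real transcriptome sequence
composition (shared domains, paralogs) that produces ambiguous tags at
realistic rates. Passing tests on synthetic data therefore demonstrate the
correctness of the algorithms and the statistical calibration under the
stated sampling model, not performance on any particular real library.

## Numerical and design choices

* p-values and hypergeometric tails in log space; no NaN for backgrounds
  up to 10⁶ genes.
* BH step-up implemented directly (sorted cummin, capped at 1), verified
  against statsmodels; ties in p receive identical q-values.
* Genes absent from both libraries are untested; the union universe fills
  missing counts with 0.
* The 63-variant neighbourhood enumeration against a hash index is O(1)
  per tag and exactly equivalent to a full Hamming scan (oracle-tested).
* Pipeline outputs are pure functions of config + seed; the run manifest
  records input checksums, parameters, row counts and wall times, and a
  failed stage leaves a FAILED marker naming itself.
* Problem sizes used by the test suite and the acceptance script: 2,000
  genes, libraries of 2×10⁵ (5×10⁵ for recovery), 10–20 seeds for averaged
  properties — large enough for stable proportions, small enough to run
  comfortably on a laptop.

## Known limitations

* The replicate-free test treats all variability as sampling noise;
  biological variability is invisible to it, so its p-values overstate
  certainty for real biological contrasts. This is a property of the
  two-library design it implements, not a fixable bug.
* The AC two-sided p is orientation-dependent at very low counts (see
  above); analyses should fix a consistent library order.
* Ambiguous tags are discarded, not redistributed; genes whose only tags
  are shared with paralogs are undetectable by design.
* Enrichment flags use uncorrected p-values by convention of the original
  report format; treat the flag as a screen, and use the BH column for
  inference.
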