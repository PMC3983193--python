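# tagdge — tag-based digital gene expression analysis

`tagdge` is a reusable, tested implementation of the classic SAGE-style
digital gene expression (DGE) analysis chain used to compare transcriptomes
between two conditions from single sequencing runs, as was standard for
NlaIII/MmeI tag libraries sequenced on early Illumina platforms.

In this protocol, cDNA is digested with NlaIII (which recognizes **CATG**)
and MmeI (which cuts 17 bp downstream), so each transcript is represented by
21-nt tags of the form CATG + 17 nt. Quantification is purely digital: count
tags, map them back to a transcriptome, and compare counts between
libraries. The package covers:

* **Virtual tag reference** — the set of all CATG+17 21-mers extractable
  from a transcriptome FASTA, with per-tag ambiguity flags (a tag occurring
  in more than one gene is ambiguous and never counted).
* **Tag cleaning** — 3′-adaptor trimming, quality/N filtering, and removal
  of copy-number-1 tags (singletons, dominated by sequencing error).
* **Mapping and TPM** — tag-to-gene assignment with at most one mismatch
  (exact hits take priority and are never outvoted by mismatch neighbours),
  per-gene counts of unambiguous tags, and normalization to tags per
  million: `TPM_g = count_g / library_total × 10⁶`.
* **Replicate-free differential expression** — the Audic–Claverie exact
  test. Given x tags for a gene in a library of N₁ total tags, the
  probability of y tags in a second library of N₂ tags is

      P(y | x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1 + N₂/N₁)^(x+y+1) )

  with a two-sided p-value doubling the smaller inclusive tail, capped at 1
  and computed in log-space. Multiplicity is controlled with
  Benjamini–Hochberg step-up FDR, and a gene is called differentially
  expressed when FDR < 0.05 and |log₂(TPM₂/TPM₁)| ≥ 1 (ratios are floored
  so zero counts stay finite).
* **Term enrichment** — upper-tail hypergeometric over-representation of
  annotation terms (GO-like or pathway-like, supplied as flat TSV) among
  DEGs against the transcriptome background, flagged at raw p < 0.05.
* **qPCR concordance** — 2^−ΔΔCt relative quantification from triplicate Ct
  tables (reference gene normalization, control condition ≡ 1) and a
  concordance score against the DGE log₂ ratios.
* **Saturation analysis** — detected-gene count as a function of sequencing
  depth along one fixed random permutation of the tag stream.
* **Synthetic experiments** — a generator producing transcriptomes, paired
  tag libraries with planted fold changes, annotations with planted
  enriched terms, and Ct tables, all with exact ground truth, so the whole
  chain is testable end to end with no external data.

## Worked example

```python
from tagdge import (SyntheticConfig, make_paired_experiment, build_index,
                    build_clean_set, quantify, call_degs)

cfg = SyntheticConfig(n_genes=500, library_sizes=(50_000, 50_000),
                      de_fraction=0.1, de_log2fc_range=(2.0, 5.0), seed=42)
exp = make_paired_experiment(cfg)
index = build_index(exp.transcripts)

clean_a = build_clean_set(exp.reads_a)
clean_b = build_clean_set(exp.reads_b)
prof_a, rep_a = quantify(clean_a, index, "control")
prof_b, _ = quantify(clean_b, index, "treated")
de = call_degs(prof_a, prof_b)   # FDR < 0.05 and |log2 ratio| >= 1
```

This prints (via the survey statements in the example script):

```
virtual tag index: 2232 distinct CATG+17 tags (0 ambiguous)
library A: 50000 raw tags -> 46893 clean (93.8%), 1275 distinct
mapping: 100.0% of distinct tags unambiguous; 489 genes detected
differential expression: 495 genes tested, 25 up- and 28 down-regulated
recovery of planted truth: 50/50 DE genes found, 3 false discoveries
```

Reading: of 50,000 raw tags, 93.8% survive cleaning (the losses are the
simulated noise tags and error singletons); every distinct clean tag maps
to a single gene; 489 of the 500 genes are detected at this depth. The
two-library test recovers all 50 planted DE genes (|log₂ fold change|
between 2 and 5) with 3 false discoveries among 53 calls.

The same chain is available from the shell:

```bash
tagdge simulate --seed 42 --outdir demo/
tagdge index --fasta demo/transcriptome.fasta --out demo/index.tsv
tagdge clean --fastq demo/library_a.fastq --out demo/clean_a.tsv
tagdge map --clean demo/clean_a.tsv --index demo/index.tsv --out demo/a
tagdge de --a demo/a.profile.tsv --b demo/b.profile.tsv --out demo/de.tsv
tagdge run --config pipeline.yaml     # everything, with a run manifest
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its assumptions, numerical conventions, and known
limitations.
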