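"""Synthetic transcriptomes, tag libraries and qPCR tables with known truth.

The generator emulates a two-condition tag-DGE experiment end to end:

* a transcriptome of random-sequence genes, each guaranteed to carry a
  CATG site with 17 nt downstream (every gene is detectable);
* per-gene relative abundances drawn log-normal; a planted fraction of
  genes is differentially expressed.  Each DE gene's fold change is applied
  as a 2^|lfc| boost to exactly one condition (boost in B = up-regulated,
  boost in A = down-regulated), with sides assigned by greedy mass
  partition so the total planted tag mass is the same in both conditions.
  Both conditions are then renormalized to proper distributions; because
  the planted masses balance, non-DE genes keep equal relative abundance
  across conditions and the recorded truth (log2 fold change 0) is exact
  rather than distorted by compositional dilution;
* two raw tag libraries sampled multinomially at the configured depths.
  Each gene emits its 3'-most valid tag (the fragment anchored at the 3'
  end by the poly(A) capture is the one tagged in the wet protocol); every
  emitted read suffers independent per-base substitution error, and a
  configurable fraction of reads is replaced by random unique 21-mers that
  match nothing in the virtual index (sequencing noise exercising the
  singleton-removal and unmapped paths);
* flat term annotations with a few planted terms drawn mostly from DE
  genes, so enrichment recovery is testable;
* triplicate Ct tables in which each assayed gene's log2 fold change is
  the planted truth plus Gaussian noise.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .tag_library import ANCHOR, TAG_LENGTH, Transcript, build_index, write_fasta
from .tag_mapping import one_mismatch_neighbors

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic two-library experiment."""

    n_genes: int = 2000
    length_range: tuple[int, int] = (300, 1500)
    library_sizes: tuple[int, int] = (200_000, 200_000)
    de_fraction: float = 0.1
    de_log2fc_range: tuple[float, float] = (1.0, 5.0)
    abundance_sigma: float = 1.2
    error_rate: float = 0.005
    singleton_noise_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.length_range
        if lo < 25:
            raise ValueError("minimum transcript length must be >= 25 "
                             "(cannot place CATG with 17 nt downstream)")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must lie in [0, 1]")
        if not (0.0 <= self.singleton_noise_rate <= 1.0):
            raise ValueError("singleton_noise_rate must lie in [0, 1]")
        if min(self.library_sizes) < 1:
            raise ValueError("library sizes must be positive")
        if self.de_log2fc_range[0] <= 0 or self.de_log2fc_range[1] < self.de_log2fc_range[0]:
            raise ValueError("de_log2fc_range must be positive and ordered")
        if self.abundance_sigma <= 0:
            raise ValueError("abundance_sigma must be positive")
        n_de = int(round(self.de_fraction * self.n_genes))
        if self.de_fraction > 0 and n_de == 0:
            raise ValueError("de_fraction > 0 but n_genes too small to plant "
                             "at least one DE gene")


@dataclass
class SyntheticExperiment:
    """A paired two-library experiment with full ground truth."""

    config: SyntheticConfig
    transcripts: list[Transcript]
    reads_a: np.ndarray  # (n, 21) uint8 ASCII
    reads_b: np.ndarray
    truth: pd.DataFrame  # gene_id, abundance_a, abundance_b, is_de,
    #                      true_log2fc, n_emitted_a, n_emitted_b

    @property
    def gene_tags(self) -> dict[str, str]:
        """Each gene's emitted (3'-most) tag."""
        return {tr.id: tr.sequence[-TAG_LENGTH:] for tr in self.transcripts}


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_transcriptome(config: SyntheticConfig,
                           rng: np.random.Generator | None = None) -> list[Transcript]:
    """Random transcripts, each with a CATG planted 21 nt from the 3' end.

    The planted site is the 3'-most possible valid site, so it is always
    the emitted tag site; additional CATG sites arise by chance and enter
    the virtual index like any real internal site.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    width = len(str(config.n_genes))
    transcripts = []
    anchor = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        seq[length - TAG_LENGTH : length - TAG_LENGTH + 4] = anchor
        transcripts.append(Transcript(id=f"gene_{i + 1:0{width}d}",
                                      sequence=seq.tobytes().decode()))
    return transcripts


def _apply_errors(reads: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return reads
    base_idx = np.searchsorted(_BASES, reads)  # ACGT are sorted ASCII
    mask = rng.random(reads.shape) < error_rate
    shift = rng.integers(1, 4, size=reads.shape)
    mutated = (base_idx + shift) % 4
    return np.where(mask, _BASES[mutated], reads).astype(np.uint8)


def _noise_reads(n: int, forbidden: set[str], rng: np.random.Generator) -> np.ndarray:
    """Random unique 21-mers with no exact or 1-mismatch hit in the index."""
    out = np.empty((n, TAG_LENGTH), dtype=np.uint8)
    made: set[str] = set()
    i = 0
    while i < n:
        cand = _random_seq(rng, TAG_LENGTH)
        tag = cand.tobytes().decode()
        if tag in made or tag in forbidden:
            continue
        if any(nb in forbidden for nb in one_mismatch_neighbors(tag)):
            continue
        made.add(tag)
        out[i] = cand
        i += 1
    return out


def _sample_library(tag_matrix: np.ndarray, abundance: np.ndarray, size: int,
                    config: SyntheticConfig, indexed_tags: set[str],
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_noise = int(round(config.singleton_noise_rate * size))
    n_signal = size - n_noise
    counts = rng.multinomial(n_signal, abundance)
    gene_idx = np.repeat(np.arange(len(abundance)), counts)
    reads = _apply_errors(tag_matrix[gene_idx], config.error_rate, rng)
    if n_noise:
        reads = np.vstack([reads, _noise_reads(n_noise, indexed_tags, rng)])
    reads = reads[rng.permutation(reads.shape[0])]
    return reads, counts


def make_paired_experiment(config: SyntheticConfig) -> SyntheticExperiment:
    """Generate transcriptome, two raw libraries and the ground truth."""
    rng = np.random.default_rng(config.seed)
    transcripts = generate_transcriptome(config, rng)
    n = config.n_genes

    base = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    base /= base.sum()

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc = np.zeros(n)
    boost_a = np.zeros(n, dtype=bool)
    boost_b = np.zeros(n, dtype=bool)
    if n_de:
        lo, hi = config.de_log2fc_range
        magnitude = rng.uniform(lo, hi, size=n_de)
        # Greedy mass partition: each DE gene is boosted in exactly one
        # condition; sides are chosen so the total planted mass matches,
        # which keeps non-DE genes' relative abundances equal across
        # conditions after renormalization (the recorded truth stays exact).
        weight = base[de_idx] * (np.exp2(magnitude) - 1.0)
        mass_a = mass_b = 0.0
        for j in np.argsort(-weight, kind="stable"):
            g = de_idx[j]
            if mass_b <= mass_a:
                boost_b[g] = True
                lfc[g] = magnitude[j]
                mass_b += weight[j]
            else:
                boost_a[g] = True
                lfc[g] = -magnitude[j]
                mass_a += weight[j]
    abundance_a = base * np.where(boost_a, np.exp2(-lfc), 1.0)
    abundance_a /= abundance_a.sum()
    abundance_b = base * np.where(boost_b, np.exp2(lfc), 1.0)
    abundance_b /= abundance_b.sum()

    tag_matrix = np.vstack([
        np.frombuffer(tr.sequence[-TAG_LENGTH:].encode(), dtype=np.uint8)
        for tr in transcripts
    ])
    indexed_tags: set[str] = (set(build_index(transcripts))
                              if config.singleton_noise_rate > 0 else set())
    reads_a, emitted_a = _sample_library(tag_matrix, abundance_a,
                                         config.library_sizes[0], config,
                                         indexed_tags, rng)
    reads_b, emitted_b = _sample_library(tag_matrix, abundance_b,
                                         config.library_sizes[1], config,
                                         indexed_tags, rng)

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    truth = pd.DataFrame({
        "gene_id": [tr.id for tr in transcripts],
        "abundance_a": abundance_a,
        "abundance_b": abundance_b,
        "is_de": is_de,
        "true_log2fc": lfc,
        "n_emitted_a": emitted_a,
        "n_emitted_b": emitted_b,
    })
    return SyntheticExperiment(config=config, transcripts=transcripts,
                               reads_a=reads_a, reads_b=reads_b, truth=truth)


def generate_annotations(genes: list[str], truth: pd.DataFrame, n_terms: int,
                         planted_terms: int, seed: int,
                         term_size_range: tuple[int, int] = (10, 30),
                         planted_de_share: float = 0.8) -> AnnotationSet:
    """Random flat annotations with enrichment signal planted in a few terms.

    Planted terms draw at least ``planted_de_share`` of their genes from the
    truly DE genes; the remaining terms are uniform over all genes.  Planted
    terms are named ``planted_k``, background terms ``term_k``.
    """
    if planted_terms > n_terms:
        raise ValueError("planted_terms cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    de_genes = list(truth.loc[truth["is_de"], "gene_id"])
    ann = AnnotationSet(namespace="synthetic")
    lo, hi = term_size_range
    for k in range(n_terms):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        if k < planted_terms and de_genes:
            n_from_de = min(int(np.ceil(planted_de_share * size)), len(de_genes))
            members = list(rng.choice(de_genes, size=n_from_de, replace=False))
            others = [g for g in genes if g not in set(members)]
            n_rest = min(size - n_from_de, len(others))
            if n_rest > 0:
                members += list(rng.choice(others, size=n_rest, replace=False))
            term_id = f"planted_{k + 1:03d}"
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)),
                                      replace=False))
            term_id = f"term_{k + 1:03d}"
        for g in members:
            ann.add(g, term_id, term_id)
    return ann


def generate_qpcr_table(truth: pd.DataFrame, n_assayed: int, seed: int,
                        ref_gene: str = "actin", noise_sigma: float = 0.3,
                        replicate_sd: float = 0.05,
                        treatment_group: str = "treatment") -> pd.DataFrame:
    """Triplicate Ct table emulating assays of genes with known fold change.

    Each assayed gene's measured log2 fold change equals its planted
    true_log2fc plus N(0, noise_sigma) biological/technical noise; within a
    sample, replicate Cts scatter with sd ``replicate_sd`` cycles.  The
    reference gene is appended with a flat Ct in every group.
    """
    rng = np.random.default_rng(seed)
    prefer_de = truth.sort_values(["is_de", "gene_id"],
                                  ascending=[False, True])
    assayed = prefer_de.head(n_assayed)
    rows = []
    for _, g in assayed.iterrows():
        ct_ctrl = float(rng.uniform(18.0, 28.0))
        measured_lfc = float(g["true_log2fc"] + rng.normal(0.0, noise_sigma))
        ct_treat = ct_ctrl - measured_lfc  # perfect doubling: 1 cycle per log2
        for group, base in (("control", ct_ctrl), (treatment_group, ct_treat)):
            reps = base + rng.normal(0.0, replicate_sd, size=3)
            rows.append((group, g["gene_id"], *np.round(reps, 3)))
    for group in ("control", treatment_group):
        reps = 15.0 + rng.normal(0.0, replicate_sd, size=3)
        rows.append((group, ref_gene, *np.round(reps, 3)))
    return pd.DataFrame(rows, columns=["sample_group", "gene_id",
                                       "ct_rep1", "ct_rep2", "ct_rep3"])


# -- on-disk outputs -----------------------------------------------------

def reads_to_strings(reads: np.ndarray) -> list[str]:
    return [t.decode() for t in
            np.ascontiguousarray(reads).view(f"S{TAG_LENGTH}").ravel()]


def write_fastq(reads: np.ndarray, path: str | Path, quality_char: str = "I") -> None:
    qual = quality_char * TAG_LENGTH
    with open(path, "w") as fh:
        for i, tag in enumerate(reads_to_strings(reads), start=1):
            fh.write(f"@read_{i}\n{tag}\n+\n{qual}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene_id", "abundance_a", "abundance_b", "is_de", "true_log2fc"]
    out = truth[cols].rename(columns={"abundance_a": "abundance_A",
                                      "abundance_b": "abundance_B"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_experiment(exp: SyntheticExperiment, outdir: str | Path,
                     fastq: bool = True) -> dict[str, Path]:
    """Write FASTA transcriptome, raw libraries and truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"transcriptome": outdir / "transcriptome.fasta",
             "truth": outdir / "truth.tsv"}
    write_fasta(exp.transcripts, paths["transcriptome"])
    write_truth(exp.truth, paths["truth"])
    for label, reads in (("a", exp.reads_a), ("b", exp.reads_b)):
        if fastq:
            paths[f"library_{label}"] = outdir / f"library_{label}.fastq"
            write_fastq(reads, paths[f"library_{label}"])
        else:
            paths[f"library_{label}"] = outdir / f"library_{label}.tsv"
            tags, counts = np.unique(reads_to_strings(reads), return_counts=True)
            with open(paths[f"library_{label}"], "w") as fh:
                for tag, cnt in zip(tags, counts):
                    fh.write(f"{tag}\t{cnt}\n")
    return paths
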