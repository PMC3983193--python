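"""Tag-to-gene mapping (<=1 mismatch), TPM quantification and saturation.

A clean tag is assigned by exact hash lookup first; only when no exact hit
exists are the 63 single-substitution neighbours of the 21-mer consulted.
A perfect hit therefore cannot be outvoted by mismatch neighbours.  Tags
whose hits (at the decisive stage) span more than one gene are ambiguous
and discarded; only unambiguous tags contribute to per-gene counts.

TPM here is tags per million: count / library_total * 1e6, where the
denominator is by default the total number of clean tags in the library
(mapped or not); a mapped-only denominator is available.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tag_library import TAG_LENGTH, VirtualTagIndex
from .tag_processing import CleanTagSet

_BASES = "ACGT"


class MapStatus(enum.Enum):
    EXACT = "exact"
    ONE_MISMATCH = "one_mismatch"
    AMBIGUOUS = "ambiguous"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class MapResult:
    status: MapStatus
    gene_id: str | None  # set only for EXACT / ONE_MISMATCH

    @property
    def unambiguous(self) -> bool:
        return self.gene_id is not None


def one_mismatch_neighbors(tag: str) -> list[str]:
    """All 63 sequences at Hamming distance exactly 1 from a 21-mer."""
    out = []
    for i, base in enumerate(tag):
        for alt in _BASES:
            if alt != base:
                out.append(tag[:i] + alt + tag[i + 1 :])
    return out


def map_tag(tag: str, index: VirtualTagIndex) -> MapResult:
    """Assign one tag to a gene, or call it ambiguous/unmapped."""
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(tag)}")
    exact = index.genes(tag)
    if exact:
        if len(exact) == 1:
            return MapResult(MapStatus.EXACT, next(iter(exact)))
        return MapResult(MapStatus.AMBIGUOUS, None)
    hits: set[str] = set()
    for neighbor in one_mismatch_neighbors(tag):
        hits |= index.genes(neighbor)
    if not hits:
        return MapResult(MapStatus.UNMAPPED, None)
    if len(hits) == 1:
        return MapResult(MapStatus.ONE_MISMATCH, next(iter(hits)))
    return MapResult(MapStatus.AMBIGUOUS, None)


@dataclass
class MappingReport:
    """Distinct clean tags partitioned by mapping outcome."""

    n_exact: int = 0
    n_one_mismatch: int = 0
    n_ambiguous_discarded: int = 0
    n_unmapped: int = 0

    @property
    def n_distinct(self) -> int:
        return (self.n_exact + self.n_one_mismatch
                + self.n_ambiguous_discarded + self.n_unmapped)

    @property
    def unambiguous_fraction(self) -> float:
        n = self.n_distinct
        return (self.n_exact + self.n_one_mismatch) / n if n else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("n_exact\tn_one_mismatch\tn_ambiguous_discarded\tn_unmapped"
                     "\tunambiguous_fraction\n")
            fh.write(f"{self.n_exact}\t{self.n_one_mismatch}"
                     f"\t{self.n_ambiguous_discarded}\t{self.n_unmapped}"
                     f"\t{self.unambiguous_fraction:.6f}\n")


@dataclass
class ExpressionProfile:
    """Per-gene unambiguous clean-tag counts and TPM for one library."""

    library_id: str
    counts: dict[str, int]
    library_total: int  # TPM denominator (clean tags by default)

    @property
    def tpm(self) -> dict[str, float]:
        if self.library_total == 0:
            return {g: 0.0 for g in self.counts}
        return {g: c / self.library_total * 1e6 for g, c in self.counts.items()}

    @property
    def n_detected(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def to_tsv(self, path: str | Path) -> None:
        tpm = self.tpm
        with open(path, "w") as fh:
            fh.write(f"# library_id={self.library_id}\tlibrary_total={self.library_total}\n")
            fh.write("gene_id\traw_count\ttpm\n")
            for g in sorted(self.counts):
                fh.write(f"{g}\t{self.counts[g]}\t{tpm[g]:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionProfile":
        counts: dict[str, int] = {}
        library_id = Path(path).stem
        library_total = 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = dict(f.split("=", 1) for f in first[1:].strip().split("\t"))
                library_id = meta.get("library_id", library_id)
                library_total = int(meta.get("library_total", 0))
                fh.readline()  # header
            for line in fh:
                g, c, _tpm = line.split("\t")
                counts[g] = int(c)
        if library_total == 0:
            library_total = sum(counts.values())
        return cls(library_id=library_id, counts=counts, library_total=library_total)


def quantify(clean: CleanTagSet, index: VirtualTagIndex, library_id: str = "library",
             tpm_denominator: str = "clean") -> tuple[ExpressionProfile, MappingReport]:
    """Map every distinct clean tag and sum copy numbers per gene.

    Ambiguous and unmapped copies are excluded from gene counts but kept in
    the TPM denominator when ``tpm_denominator='clean'`` (the default);
    ``'mapped'`` restricts the denominator to unambiguously mapped copies.
    """
    if tpm_denominator not in ("clean", "mapped"):
        raise ValueError("tpm_denominator must be 'clean' or 'mapped'")
    counts: dict[str, int] = {}
    report = MappingReport()
    mapped_copies = 0
    for tag, n in clean.counts.items():
        res = map_tag(tag, index)
        if res.status is MapStatus.EXACT:
            report.n_exact += 1
        elif res.status is MapStatus.ONE_MISMATCH:
            report.n_one_mismatch += 1
        elif res.status is MapStatus.AMBIGUOUS:
            report.n_ambiguous_discarded += 1
        else:
            report.n_unmapped += 1
        if res.gene_id is not None:
            counts[res.gene_id] = counts.get(res.gene_id, 0) + n
            mapped_copies += n
    total = clean.total_clean if tpm_denominator == "clean" else mapped_copies
    profile = ExpressionProfile(library_id=library_id, counts=counts,
                                library_total=total)
    return profile, report


def saturation_curve(raw_tags: Sequence[str] | np.ndarray, index: VirtualTagIndex,
                     depth_grid: Iterable[int], seed: int = 0) -> list[tuple[int, int]]:
    """Detected-gene count as a function of sequencing depth.

    The stream is permuted once (reproducibly from ``seed``); each depth d
    reports the number of genes with >=1 unambiguously mapped tag among the
    first d tags of that permutation, so the curve is non-decreasing by
    construction.
    """
    if isinstance(raw_tags, np.ndarray):
        raw_tags = [t.decode() if isinstance(t, bytes) else str(t)
                    for t in np.asarray(raw_tags).view(f"S{TAG_LENGTH}").ravel()]
    n = len(raw_tags)
    grid = sorted(int(d) for d in depth_grid)
    if grid and grid[-1] > n:
        raise ValueError(f"depth {grid[-1]} exceeds stream size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assign_cache: dict[str, str | None] = {}
    first_seen: dict[str, int] = {}  # gene -> first stream position (1-based)
    for pos, idx in enumerate(order, start=1):
        tag = raw_tags[idx]
        if tag not in assign_cache:
            assign_cache[tag] = map_tag(tag, index).gene_id
        gene = assign_cache[tag]
        if gene is not None and gene not in first_seen:
            first_seen[gene] = pos
    firsts = np.sort(np.fromiter(first_seen.values(), dtype=np.int64,
                                 count=len(first_seen)))
    return [(d, int(np.searchsorted(firsts, d, side="right"))) for d in grid]
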