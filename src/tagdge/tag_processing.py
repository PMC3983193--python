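"""Raw tag cleaning: adaptor trimming, quality filtering, singleton removal.

A library's clean-tag set is the multiset of distinct 21-nt tags left after
(1) removing 3' adaptor sequence, (2) rejecting reads that are empty, too
short, contain N or fall below a base-quality threshold, and (3) dropping
tags observed exactly once in the library (singletons, dominated by
sequencing error).  Counting happens before singleton removal so retained
copy numbers reflect the full library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO

from .tag_library import TAG_LENGTH

DEFAULT_MIN_QUALITY = 10


@dataclass
class RawRead:
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length does not match sequence length")


@dataclass
class CleanTagSet:
    """Distinct clean tags of one library with copy numbers and statistics.

    ``total_clean`` counts retained copies; ``n_rejected`` counts reads
    removed at trim/quality stages and ``n_singleton_copies`` reads removed
    as copy-number-1 tags, so that
    ``total_clean + n_rejected + n_singleton_copies == total_raw``.
    """

    counts: dict[str, int]
    total_raw: int
    n_rejected: int = 0
    n_singleton_copies: int = 0

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.counts)

    @property
    def clean_ratio(self) -> float:
        return self.total_clean / self.total_raw if self.total_raw else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tcopy_number\n")
            for tag in sorted(self.counts):
                fh.write(f"{tag}\t{self.counts[tag]}\n")

    def stats_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("total_raw\ttotal_clean\tdistinct_clean\tclean_ratio\n")
            fh.write(f"{self.total_raw}\t{self.total_clean}\t{self.distinct_clean}"
                     f"\t{self.clean_ratio:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CleanTagSet":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag\t"):
                raise ValueError(f"{path}: not a clean-tag TSV")
            for line in fh:
                tag, n = line.split("\t")
                counts[tag] = int(n)
        total = sum(counts.values())
        return cls(counts=counts, total_raw=total)


def trim_adaptor(read: RawRead, adaptor: str) -> str | None:
    """Return the 21-nt insert of ``read``, or None when the read is rejected.

    Reads of exactly 21 nt pass through.  Longer reads are accepted when
    everything after the first 21 nt is consistent with the 3' adaptor
    (either a prefix of the adaptor or the adaptor followed by run-through).
    Shorter reads are adaptor-only/empty and rejected.
    """
    seq = read.sequence.upper()
    if len(seq) < TAG_LENGTH:
        return None
    if len(seq) == TAG_LENGTH:
        return seq
    if not adaptor:
        raise ValueError("adaptor sequence required to trim reads longer than 21 nt")
    tail = seq[TAG_LENGTH:]
    adaptor = adaptor.upper()
    if adaptor.startswith(tail) or tail.startswith(adaptor):
        return seq[:TAG_LENGTH]
    return None


def quality_filter(tag: str, quality: list[int] | None,
                   min_quality: int = DEFAULT_MIN_QUALITY) -> bool:
    """True when the tag is kept: no N and no base below ``min_quality``."""
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(tag)}")
    if quality is not None and len(quality) < TAG_LENGTH:
        raise ValueError("quality shorter than tag")
    if "N" in tag:
        return False
    if quality is not None and min(quality[:TAG_LENGTH]) < min_quality:
        return False
    return True


ReadsInput = Union[Iterable[Union[RawRead, str]], np.ndarray]


def build_clean_set(reads: ReadsInput, adaptor: str = "",
                    min_quality: int = DEFAULT_MIN_QUALITY) -> CleanTagSet:
    """Run trim -> quality filter -> count -> singleton removal over a library.

    ``reads`` may be an iterable of :class:`RawRead` or plain sequence
    strings, or a 2-D uint8 array of ASCII codes (one 21-nt read per row,
    the layout the synthetic generator emits) for which the per-read Python
    loop is bypassed.
    """
    counter: Counter[str] = Counter()
    if isinstance(reads, np.ndarray):
        if reads.ndim != 2 or reads.shape[1] != TAG_LENGTH:
            raise ValueError(f"read array must have shape (n, {TAG_LENGTH})")
        total_raw = reads.shape[0]
        n_rejected = 0
        tags, tag_counts = np.unique(
            np.ascontiguousarray(reads).view(f"S{TAG_LENGTH}").ravel(),
            return_counts=True,
        )
        for tag_b, n in zip(tags, tag_counts):
            tag = tag_b.decode()
            if "N" in tag:
                n_rejected += int(n)
            else:
                counter[tag] = int(n)
    else:
        total_raw = 0
        n_rejected = 0
        for read in reads:
            if isinstance(read, str):
                read = RawRead(sequence=read)
            total_raw += 1
            tag = trim_adaptor(read, adaptor)
            if tag is None or not quality_filter(tag, read.quality, min_quality):
                n_rejected += 1
                continue
            counter[tag] += 1

    singles = {t for t, n in counter.items() if n == 1}
    counts = {t: n for t, n in counter.items() if n >= 2}
    return CleanTagSet(
        counts=counts,
        total_raw=total_raw,
        n_rejected=n_rejected,
        n_singleton_copies=len(singles),
    )


def read_fastq(path: str | Path) -> list[RawRead]:
    """Load raw reads from a Phred+33 FASTQ file."""
    return [
        RawRead(sequence=str(rec.seq).upper(),
                quality=rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_tag_counts(path: str | Path) -> CleanTagSet:
    """Pre-counted mode: headerless 2-column tag/count TSV.

    Trim and quality stages are skipped but singleton removal still applies.
    """
    counter: Counter[str] = Counter()
    total_raw = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            tag, n_s = line.split()
            n = int(n_s)
            total_raw += n
            counter[tag.upper()] += n
    singles = {t for t, n in counter.items() if n == 1}
    counts = {t: n for t, n in counter.items() if n >= 2}
    return CleanTagSet(counts=counts, total_raw=total_raw,
                       n_singleton_copies=len(singles))
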