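"""Virtual CATG+17 tag reference construction.

NlaIII recognizes CATG; MmeI cuts 17 bp downstream of the recognition site,
so every expressed tag is a 21-nt sequence beginning with CATG.  The mapping
reference ("virtual tag library") is the set of all such 21-mers that can be
produced from a transcriptome: one candidate per CATG occurrence on the sense
strand with at least 17 nt downstream.  A tag seen at sites in more than one
gene is flagged ambiguous; ambiguity is a property of gene identity, so the
same tag at two sites of a single gene is a single unambiguous entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

TAG_LENGTH = 21
ANCHOR = "CATG"
DOWNSTREAM = TAG_LENGTH - len(ANCHOR)  # 17


@dataclass(frozen=True)
class Transcript:
    """A reference transcript: identifier plus sense-strand sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has empty sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"transcript {self.id!r} has non-ACGTN symbols {bad}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class VirtualTag:
    """One CATG+17 site of one transcript.

    ``offset`` is the 0-based position of the C of CATG on the sense strand;
    ``site_rank_from_3prime`` is 1 for the 3'-most valid site of the gene.
    """

    tag: str
    gene_id: str
    offset: int
    site_rank_from_3prime: int


def extract_tags(transcript: Transcript) -> list[VirtualTag]:
    """Enumerate all valid CATG+17 tags of one transcript.

    A site is valid when the CATG has >= 17 nt downstream and the resulting
    21-mer contains no N.  Tags are returned in 5'->3' order; ranks count
    from the 3' end (the 3'-most valid site has rank 1).
    """
    seq = transcript.sequence
    sites: list[tuple[int, str]] = []
    pos = seq.find(ANCHOR)
    while pos != -1:
        tag = seq[pos : pos + TAG_LENGTH]
        if len(tag) == TAG_LENGTH and "N" not in tag:
            sites.append((pos, tag))
        pos = seq.find(ANCHOR, pos + 1)
    n = len(sites)
    return [
        VirtualTag(tag=tag, gene_id=transcript.id, offset=off,
                   site_rank_from_3prime=n - i)
        for i, (off, tag) in enumerate(sites)
    ]


class VirtualTagIndex:
    """Lookup from 21-nt tag sequence to the genes and sites it occurs at.

    A tag is *ambiguous* when its sites span more than one gene; only
    unambiguous tags contribute to expression counts downstream.
    """

    def __init__(self) -> None:
        # tag -> gene_id -> sorted list of offsets
        self._entries: dict[str, dict[str, list[int]]] = {}

    # -- construction ----------------------------------------------------

    @classmethod
    def build(cls, transcripts: Iterable[Transcript]) -> "VirtualTagIndex":
        """Build the index as the union of ``extract_tags`` over all inputs."""
        index = cls()
        seen_ids: set[str] = set()
        for tr in transcripts:
            if tr.id in seen_ids:
                raise ValueError(f"duplicate transcript id {tr.id!r}")
            seen_ids.add(tr.id)
            for vt in extract_tags(tr):
                index._add(vt.tag, vt.gene_id, vt.offset)
        return index

    def _add(self, tag: str, gene_id: str, offset: int) -> None:
        genes = self._entries.setdefault(tag, {})
        offsets = genes.setdefault(gene_id, [])
        offsets.append(offset)
        offsets.sort()

    # -- queries ---------------------------------------------------------

    def __contains__(self, tag: str) -> bool:
        return tag in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def genes(self, tag: str) -> frozenset[str]:
        """The set of genes carrying ``tag``; empty if the tag is not indexed."""
        return frozenset(self._entries.get(tag, ()))

    def sites(self, tag: str) -> list[tuple[str, int]]:
        """All (gene_id, offset) sites of ``tag``, sorted."""
        return sorted(
            (g, off)
            for g, offs in self._entries.get(tag, {}).items()
            for off in offs
        )

    def is_ambiguous(self, tag: str) -> bool:
        return len(self._entries.get(tag, ())) > 1

    @property
    def ambiguous_tags(self) -> set[str]:
        return {t for t, genes in self._entries.items() if len(genes) > 1}

    @property
    def gene_ids(self) -> set[str]:
        return {g for genes in self._entries.values() for g in genes}

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write tag, comma-joined gene ids, comma-joined offsets, ambiguous flag."""
        with open(path, "w") as fh:
            fh.write("tag\tgene_ids\toffsets\tambiguous\n")
            for tag in sorted(self._entries):
                sites = self.sites(tag)
                genes = ",".join(g for g, _ in sites)
                offsets = ",".join(str(off) for _, off in sites)
                fh.write(f"{tag}\t{genes}\t{offsets}\t{int(self.is_ambiguous(tag))}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VirtualTagIndex":
        index = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag\t"):
                raise ValueError(f"{path}: not a tag index TSV")
            for line in fh:
                tag, genes, offsets, _amb = line.rstrip("\n").split("\t")
                for g, off in zip(genes.split(","), offsets.split(",")):
                    index._add(tag, g, int(off))
        return index


def read_fasta(path: str | Path) -> list[Transcript]:
    """Load transcripts from a (multi-line, case-insensitive) FASTA file."""
    return [Transcript(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(transcripts: Iterable[Transcript], path, width: int = 70) -> None:
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        for tr in transcripts:
            fh.write(f">{tr.id}\n")
            for i in range(0, len(tr.sequence), width):
                fh.write(tr.sequence[i : i + width] + "\n")
    finally:
        if fh is not path:
            fh.close()


def build_index(transcripts: Iterable[Transcript]) -> VirtualTagIndex:
    """Convenience alias for :meth:`VirtualTagIndex.build`."""
    return VirtualTagIndex.build(transcripts)
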