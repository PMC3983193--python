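"""Hypergeometric over-representation of annotation terms among DEGs.

For a term annotating M of N background genes, with n DEGs of which m carry
the term, the enrichment p-value is the upper tail P[X >= m] of the
hypergeometric distribution (sampling n genes without replacement from the
background).  Terms with raw p < alpha (default 0.05) are flagged enriched;
a BH-adjusted column is emitted alongside for reference but does not drive
the flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .differential_expression import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class AnnotationSet:
    """Flat gene -> term annotations (GO-like or pathway-like), pre-propagated."""

    terms: dict[str, set[str]] = field(default_factory=dict)  # term_id -> genes
    names: dict[str, str] = field(default_factory=dict)       # term_id -> label
    namespace: str = "term"

    def add(self, gene_id: str, term_id: str, term_name: str = "") -> None:
        self.terms.setdefault(term_id, set()).add(gene_id)
        if term_name or term_id not in self.names:
            self.names[term_id] = term_name or term_id

    @property
    def annotated_genes(self) -> set[str]:
        return {g for genes in self.terms.values() for g in genes}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.terms):
                for gene in sorted(self.terms[term]):
                    fh.write(f"{gene}\t{term}\t{self.names.get(term, term)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, namespace: str = "term") -> "AnnotationSet":
        """Read gene_id <TAB> term_id [<TAB> term_name], one pair per line."""
        ann = cls(namespace=namespace)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                gene, term = parts[0], parts[1]
                name = parts[2] if len(parts) > 2 else term
                ann.add(gene, term, name)
        return ann


def hypergeom_upper_tail(m: int, big_m: int, n: int, big_n: int) -> float:
    """P[X >= m] with X ~ Hypergeom(N=big_n, K=big_m, draws=n)."""
    if not (0 <= m <= min(big_m, n)):
        raise ValueError(f"m={m} outside [0, min(M={big_m}, n={n})]")
    if big_m > big_n or n > big_n:
        raise ValueError("term size and DEG count cannot exceed background size")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, big_n, big_m, n))


def enrich(annotations: AnnotationSet, degs: set[str], background: set[str],
           alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Test every term with >=1 background gene; rows sorted by p ascending.

    DEGs outside the background are dropped with a warning.  Term gene sets
    are intersected with the background before counting.
    """
    if not background:
        raise ValueError("background gene set must be non-empty")
    stray = degs - background
    if stray:
        logger.warning("%d DEGs not in background were dropped", len(stray))
        degs = degs & background
    big_n = len(background)
    n = len(degs)
    rows = []
    for term_id in sorted(annotations.terms):
        term_genes = annotations.terms[term_id] & background
        big_m = len(term_genes)
        if big_m == 0:
            continue
        m = len(term_genes & degs)
        p = hypergeom_upper_tail(m, big_m, n, big_n)
        rows.append((term_id, annotations.names.get(term_id, term_id),
                     big_n, big_m, n, m, p))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "N", "M", "n", "m",
                                     "p_value"])
    df["bh"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    df["enriched"] = df["p_value"] < alpha
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df


def write_enrichment_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
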