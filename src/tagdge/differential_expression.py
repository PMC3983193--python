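"""Replicate-free two-library differential expression.

With a single sequencing run per condition there are no replicates, so
per-gene significance is assessed with the Audic-Claverie exact test: given
x tags for a gene in a library of N1 total tags, the posterior predictive
probability of seeing y tags in a second library of N2 tags is

    P(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

The two-sided p-value doubles the smaller of the two inclusive tails at the
observed y, capped at 1.  All tail sums are computed in log space.

Fold changes are log2(TPM2/TPM1) with a positive TPM floor so zero counts
give finite ratios; multiplicity is handled with Benjamini-Hochberg step-up
FDR, and a gene is called differentially expressed when FDR < 0.05 and
|log2 ratio| >= 1 (both thresholds configurable).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .tag_mapping import ExpressionProfile

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_LFC_THRESHOLD = 1.0


def _log_pmf(y_values: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    # log P(y|x) for an array of y values; r = N2/N1
    y = y_values
    return (y * log_r + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * log_1pr)


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts (x, y) in totals (N1, N2)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be >= 1")
    log_r = np.log(n2) - np.log(n1)
    log_1pr = np.logaddexp(0.0, log_r)
    grid = np.arange(y + 1)
    log_terms = _log_pmf(grid, x, log_r, log_1pr)
    lower = float(np.exp(logsumexp(log_terms)))           # P(Y <= y)
    if y == 0:
        upper = 1.0
    else:
        below = float(np.exp(logsumexp(log_terms[:-1])))  # P(Y < y)
        upper = max(0.0, 1.0 - below)                     # P(Y >= y)
    return min(1.0, 2.0 * min(lower, upper))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def log2_ratio(tpm1: float, tpm2: float, floor: float) -> float:
    """log2 of the floored TPM ratio; finite for any zero count."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if tpm1 < 0 or tpm2 < 0:
        raise ValueError("TPM values must be non-negative")
    return float(np.log2(max(tpm2, floor) / max(tpm1, floor)))


def call_degs(profile_a: ExpressionProfile, profile_b: ExpressionProfile,
              fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
              lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
              floor: float | None = None) -> pd.DataFrame:
    """Per-gene two-library comparison over the union gene universe.

    Genes absent from both libraries are not tested; FDR is computed over
    all tested genes.  When ``floor`` is None each library uses half a tag's
    worth of TPM (0.5 / library_total * 1e6) as its own floor.

    Returns a DataFrame with columns gene_id, count_a, count_b, tpm_a,
    tpm_b, log2_ratio, p_value, fdr, call (up / down / ns), sorted by
    gene_id.
    """
    if profile_a.library_id == profile_b.library_id:
        raise ValueError("the two profiles must have distinct library ids")
    n1, n2 = profile_a.library_total, profile_b.library_total
    if n1 < 1 or n2 < 1:
        raise ValueError("both libraries must contain clean tags")
    floor_a = floor if floor is not None else 0.5 / n1 * 1e6
    floor_b = floor if floor is not None else 0.5 / n2 * 1e6
    genes = sorted(set(profile_a.counts) | set(profile_b.counts))
    rows = []
    for g in genes:
        x = profile_a.counts.get(g, 0)
        y = profile_b.counts.get(g, 0)
        if x + y == 0:
            continue
        tpm1 = x / n1 * 1e6
        tpm2 = y / n2 * 1e6
        lfc = float(np.log2(max(tpm2, floor_b) / max(tpm1, floor_a)))
        rows.append((g, x, y, tpm1, tpm2, lfc, ac_pvalue(x, y, n1, n2)))
    df = pd.DataFrame(rows, columns=["gene_id", "count_a", "count_b",
                                     "tpm_a", "tpm_b", "log2_ratio", "p_value"])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    sig = df["fdr"] < fdr_threshold
    df["call"] = "ns"
    df.loc[sig & (df["log2_ratio"] >= lfc_threshold), "call"] = "up"
    df.loc[sig & (df["log2_ratio"] <= -lfc_threshold), "call"] = "down"
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
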