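"""2^-ddCt relative quantification and qPCR/DGE concordance scoring.

Replicate Ct values are averaged per (group, gene) first; the target gene's
mean Ct is normalized against a reference gene within each group (dCt), and
each treatment group's dCt is referenced to the control group's (ddCt).
Relative quantity rq = 2^-ddCt assumes perfect doubling per cycle, so the
control condition has rq = 1 by construction and log2(rq) = -ddCt.

Concordance with DGE: a (gene, group) test agrees when the qPCR log2(rq)
and the DGE log2 ratio have the same nonzero sign, or when both magnitudes
fall below a no-change band (0.25 by default).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

NO_CHANGE_BAND = 0.25


def delta_delta_ct(ct_target_treat: float, ct_ref_treat: float,
                   ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """rq = 2^-[(Ct_tgt,t - Ct_ref,t) - (Ct_tgt,c - Ct_ref,c)] from mean Cts."""
    for v in (ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct TSV: sample_group, gene_id, ct_rep1..ct_repK (>=1 replicate)."""
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("ct_rep")]
    if not rep_cols or "sample_group" not in df.columns or "gene_id" not in df.columns:
        raise ValueError(f"{path}: expected sample_group, gene_id, ct_rep* columns")
    return df


def relative_expression(ct: pd.DataFrame, ref_gene: str,
                        control_group: str) -> pd.DataFrame:
    """Per (gene, treatment group) rq and log2_rq, control group as baseline."""
    rep_cols = [c for c in ct.columns if c.startswith("ct_rep")]
    means = ct.assign(mean_ct=ct[rep_cols].mean(axis=1))
    means = means.set_index(["sample_group", "gene_id"])["mean_ct"]
    groups = sorted(ct["sample_group"].unique())
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent from Ct table")
    rows = []
    for group in groups:
        if group == control_group:
            continue
        if (group, ref_gene) not in means.index or (control_group, ref_gene) not in means.index:
            raise ValueError(f"reference gene {ref_gene!r} missing in group "
                             f"{group!r} or {control_group!r}")
        for gene in sorted(ct.loc[ct["sample_group"] == group, "gene_id"].unique()):
            if gene == ref_gene:
                continue
            if (control_group, gene) not in means.index:
                continue
            rq = delta_delta_ct(means[(group, gene)], means[(group, ref_gene)],
                                means[(control_group, gene)],
                                means[(control_group, ref_gene)])
            rows.append((gene, group, rq, float(np.log2(rq))))
    return pd.DataFrame(rows, columns=["gene_id", "group", "rq", "log2_rq"])


def is_consistent(log2_rq: float, log2_ratio: float,
                  band: float = NO_CHANGE_BAND) -> bool:
    """Sign agreement, or joint no-change (both magnitudes below the band)."""
    if abs(log2_rq) < band and abs(log2_ratio) < band:
        return True
    return log2_rq * log2_ratio > 0


def concordance(qpcr: pd.DataFrame, de_by_group: dict[str, pd.DataFrame],
                band: float = NO_CHANGE_BAND) -> tuple[int, int, float]:
    """Count consistent (gene, group) tests between qPCR and DGE tables.

    ``qpcr`` is the output of :func:`relative_expression`; ``de_by_group``
    maps each treatment group to its DGE table (gene_id, log2_ratio, ...).
    """
    n_total = 0
    n_consistent = 0
    for group, de in de_by_group.items():
        lfc = de.set_index("gene_id")["log2_ratio"]
        sub = qpcr[qpcr["group"] == group]
        for _, row in sub.iterrows():
            if row["gene_id"] not in lfc.index:
                continue
            n_total += 1
            if is_consistent(row["log2_rq"], float(lfc[row["gene_id"]]), band):
                n_consistent += 1
    if n_total == 0:
        raise ValueError("no overlapping (gene, group) keys between qPCR and DGE")
    return n_consistent, n_total, n_consistent / n_total
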