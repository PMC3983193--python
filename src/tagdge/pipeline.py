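"""End-to-end orchestration: simulate/load -> index -> clean -> map -> DE ->
enrichment -> qPCR concordance, with a run manifest.

Every stage output is a pure function of the declared inputs plus the
configuration, so re-running with the same config and seed reproduces
byte-identical tables.  The manifest records input checksums, parameters,
per-stage row counts and wall times; a failing stage aborts the run with
the stage named and leaves a FAILED marker next to any partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import differential_expression as de_mod
from . import enrichment as enrich_mod
from . import qpcr as qpcr_mod
from . import simulate as sim_mod
from . import tag_mapping as map_mod
from . import tag_processing as proc_mod
from . import tag_library as lib_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    # thresholds (defaults are the standard tag-DGE choices)
    fdr: float = 0.05
    lfc: float = 1.0
    alpha: float = 0.05
    min_quality: int = 10
    tpm_denominator: str = "clean"
    floor: float | None = None
    adaptor: str = ""
    # either a simulate block ...
    simulate: dict[str, Any] | None = None
    n_terms: int = 50
    planted_terms: int = 3
    n_qpcr_genes: int = 20
    # ... or explicit input paths
    transcriptome: Path | None = None
    library_a: Path | None = None
    library_b: Path | None = None
    annotations: Path | None = None
    qpcr_table: Path | None = None
    ref_gene: str = "actin"
    control_group: str = "control"
    treatment_group: str = "treatment"

    def __post_init__(self) -> None:
        if not (0 < self.fdr <= 1) or not (0 < self.alpha <= 1):
            raise ValueError("fdr and alpha must lie in (0, 1]")
        if self.lfc < 0:
            raise ValueError("lfc threshold must be non-negative")
        if self.tpm_denominator not in ("clean", "mapped"):
            raise ValueError("tpm_denominator must be 'clean' or 'mapped'")
        if self.simulate is None and (self.transcriptome is None
                                      or self.library_a is None
                                      or self.library_b is None):
            raise ValueError("either a simulate block or transcriptome plus "
                             "two library paths must be provided")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.pop("thresholds", {})
        inputs = raw.pop("inputs", {})
        kwargs: dict[str, Any] = {}
        kwargs.update(thresholds)
        for key in ("transcriptome", "library_a", "library_b",
                    "annotations", "qpcr_table"):
            if key in inputs:
                kwargs[key] = Path(inputs[key])
        kwargs.update(raw)
        kwargs["outdir"] = Path(kwargs["outdir"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all configured stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "fdr": config.fdr, "lfc": config.lfc, "alpha": config.alpha,
            "min_quality": config.min_quality,
            "tpm_denominator": config.tpm_denominator, "floor": config.floor,
        },
        "stages": {},
        "inputs": {},
    }
    state: dict[str, Any] = {}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            rows = fn()
        except Exception as exc:
            failed_marker.write_text(f"stage '{name}' failed: {exc}\n")
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {
            "rows": rows,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s done (%s rows)", name, rows)

    # -- simulate or load ------------------------------------------------
    def _simulate() -> int:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", config.seed)
        for key in ("length_range", "library_sizes", "de_log2fc_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        cfg = sim_mod.SyntheticConfig(**sim_kwargs)
        exp = sim_mod.make_paired_experiment(cfg)
        paths = sim_mod.write_experiment(exp, outdir / "synthetic")
        ann = sim_mod.generate_annotations(
            [t.id for t in exp.transcripts], exp.truth,
            n_terms=config.n_terms, planted_terms=config.planted_terms,
            seed=cfg.seed + 1)
        ann_path = outdir / "synthetic" / "annotations.tsv"
        ann.to_tsv(ann_path)
        ct = sim_mod.generate_qpcr_table(exp.truth, n_assayed=config.n_qpcr_genes,
                                         seed=cfg.seed + 2,
                                         ref_gene=config.ref_gene,
                                         treatment_group=config.treatment_group)
        ct_path = outdir / "synthetic" / "qpcr_ct.tsv"
        ct.to_csv(ct_path, sep="\t", index=False)
        state["transcriptome"] = paths["transcriptome"]
        state["library_a"] = paths["library_a"]
        state["library_b"] = paths["library_b"]
        state["annotations"] = ann_path
        state["qpcr_table"] = ct_path
        return cfg.n_genes

    def _load() -> int:
        for key in ("transcriptome", "library_a", "library_b"):
            p = getattr(config, key)
            if not Path(p).exists():
                raise FileNotFoundError(p)
            state[key] = Path(p)
        # optional inputs are validated by the stages that consume them
        for key in ("annotations", "qpcr_table"):
            p = getattr(config, key)
            if p is not None:
                state[key] = Path(p)
        return 0

    if config.simulate is not None:
        stage("simulate", _simulate)
    else:
        stage("load_inputs", _load)

    for key, p in state.items():
        if isinstance(p, Path) and p.exists():
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    # -- index -----------------------------------------------------------
    def _index() -> int:
        transcripts = lib_mod.read_fasta(state["transcriptome"])
        state["index"] = lib_mod.build_index(transcripts)
        state["gene_ids"] = [t.id for t in transcripts]
        state["index"].to_tsv(outdir / "tag_index.tsv")
        return len(state["index"])

    stage("index", _index)

    # -- clean + map, per library ---------------------------------------
    def _clean(label: str):
        def fn() -> int:
            path = state[f"library_{label}"]
            if path.suffix in (".fastq", ".fq"):
                reads = proc_mod.read_fastq(path)
                clean = proc_mod.build_clean_set(reads, adaptor=config.adaptor,
                                                 min_quality=config.min_quality)
            else:
                clean = proc_mod.read_tag_counts(path)
            clean.to_tsv(outdir / f"clean_{label}.tsv")
            clean.stats_tsv(outdir / f"clean_{label}_stats.tsv")
            state[f"clean_{label}"] = clean
            return clean.distinct_clean
        return fn

    def _map(label: str):
        def fn() -> int:
            profile, report = map_mod.quantify(
                state[f"clean_{label}"], state["index"], library_id=label,
                tpm_denominator=config.tpm_denominator)
            profile.to_tsv(outdir / f"profile_{label}.tsv")
            report.to_tsv(outdir / f"mapping_{label}.tsv")
            state[f"profile_{label}"] = profile
            return len(profile.counts)
        return fn

    for label in ("a", "b"):
        stage(f"clean_{label}", _clean(label))
        stage(f"map_{label}", _map(label))

    # -- differential expression ----------------------------------------
    def _de() -> int:
        df = de_mod.call_degs(state["profile_a"], state["profile_b"],
                              fdr_threshold=config.fdr,
                              lfc_threshold=config.lfc, floor=config.floor)
        de_mod.write_de_table(df, outdir / "de_table.tsv")
        state["de"] = df
        return len(df)

    stage("de", _de)

    # -- enrichment ------------------------------------------------------
    if config.simulate is not None or config.annotations is not None:
        def _enrich() -> int:
            ann_path = state.get("annotations")
            if ann_path is None or not Path(ann_path).exists():
                raise FileNotFoundError("annotation file missing")
            ann = enrich_mod.AnnotationSet.from_tsv(ann_path)
            degs = set(state["de"].loc[state["de"]["call"] != "ns", "gene_id"])
            background = set(state["gene_ids"])
            df = enrich_mod.enrich(ann, degs, background, alpha=config.alpha)
            enrich_mod.write_enrichment_table(df, outdir / "enrichment.tsv")
            state["enrichment"] = df
            return len(df)

        stage("enrichment", _enrich)

    # -- qPCR concordance ------------------------------------------------
    if config.simulate is not None or config.qpcr_table is not None:
        def _qpcr() -> int:
            ct = qpcr_mod.read_ct_table(state["qpcr_table"])
            rq = qpcr_mod.relative_expression(ct, ref_gene=config.ref_gene,
                                              control_group=config.control_group)
            rq.to_csv(outdir / "qpcr_rq.tsv", sep="\t", index=False,
                      float_format="%.6g")
            n_ok, n_tot, frac = qpcr_mod.concordance(
                rq, {config.treatment_group: state["de"]})
            manifest["qpcr_concordance"] = {
                "n_consistent": n_ok, "n_total": n_tot, "fraction": frac}
            return n_tot

        stage("qpcr", _qpcr)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
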