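"""End-to-end orchestration: filter -> rank -> scan -> landscape -> SSSS ->
CPDV -> targets -> summary, with optional ORA and methylation branches.

The pipeline is a composition of the stage functions; running it end to
end on the same inputs yields exactly what invoking the stages one by one
would.  Every run writes a JSON manifest with all parameters and the seed
so it can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .expression import ExpressionMatrix, ProbeAnnotation, RankedList, collapse_and_rank, detection_filter
from .landscape import CutPoint, LandscapeCurve, SSSSCurve, cpdv_select, hypergeometric_landscape, ssss_integration
from .methylation import compare_groups, cumulative_methylation
from .seed_scan import MiRNA, OccurrenceIndex, SCRElementSet, UTRUniverse, derive_scr_elements, scan_occurrences
from .targets import AnnotationCollection, TargetSet, TargetSummary, ora, select_down_targets, summarize_targets

logger = logging.getLogger("mirscape")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_stages"]


@dataclass
class PipelineConfig:
    """File paths and thresholds for a full pipeline run."""

    utr_fasta: str
    expression_tsv: str
    design_yaml: str
    annotation_tsv: str
    mirna_tsv: str
    out_dir: str
    bin_width: int = 200
    cpdv_lookahead: int = 5
    detection_alpha: float = 0.01
    fdr_q: float = 0.1
    fc_threshold: float = 0.5
    min_probes: int = 5
    gmt: str | None = None
    pyro_tsv: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("utr_fasta", "expression_tsv", "design_yaml", "annotation_tsv", "mirna_tsv"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"configuration error: {name} not found at {path}")
        for opt in ("gmt", "pyro_tsv"):
            path = getattr(self, opt)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configuration error: {opt} not found at {path}")
        if not (0 < self.detection_alpha < 1 and 0 < self.fdr_q < 1):
            raise ValueError("configuration error: thresholds out of range")
        if self.bin_width < 1 or self.cpdv_lookahead < 1 or self.min_probes < 1:
            raise ValueError("configuration error: counts must be positive")


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    ranked: RankedList
    index: OccurrenceIndex
    landscape: LandscapeCurve
    ssss: dict[str, SSSSCurve]
    combined_cut: CutPoint
    per_mirna_cuts: dict[str, CutPoint]
    target_sets: dict[str, TargetSet]
    summary: TargetSummary | None
    ora_table: pd.DataFrame | None
    methylation_report: dict | None
    manifest: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_stages(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    universe: UTRUniverse,
    mirnas: Sequence[MiRNA],
    bin_width: int = 200,
    cpdv_lookahead: int = 5,
    detection_alpha: float = 0.01,
) -> PipelineResult:
    """Run the analysis stages on in-memory inputs.

    The CPDV cut is applied to the bin-wise sum of the per-miRNA SSSS
    curves (the combination-treatment default); per-miRNA cuts are also
    reported.  Down-target sets use each miRNA's canonical 2-7 SCR word.
    """
    filtered, _log = _stage("detection_filter")(detection_filter)(matrix, alpha=detection_alpha)
    ranked = _stage("collapse_and_rank")(collapse_and_rank)(filtered, annotation)
    in_universe = [g for g in ranked.genes if g in universe]
    if len(in_universe) < len(ranked):
        logger.info("dropping %d ranked genes absent from the 3'UTR universe",
                    len(ranked) - len(in_universe))
        sub = ranked.table[ranked.table["gene_id"].isin(set(in_universe))]
        ranked = RankedList(table=sub.drop(columns=["rank"]))

    element_sets: dict[str, SCRElementSet] = {
        m.name: derive_scr_elements(m) for m in mirnas
    }
    all_words = [w for es in element_sets.values() for w in es.words]
    index = _stage("scan_occurrences")(scan_occurrences)(universe, all_words)
    curve = _stage("hypergeometric_landscape")(hypergeometric_landscape)(
        ranked.genes, index, all_words, bin_width=bin_width
    )
    ssss = {
        name: ssss_integration(curve, es) for name, es in element_sets.items()
    }
    combined = sum(s.values for s in ssss.values())
    combined_cut = cpdv_select(combined.to_numpy(), lookahead=cpdv_lookahead, bin_width=bin_width)
    per_mirna_cuts = {
        name: cpdv_select(s, lookahead=cpdv_lookahead) for name, s in ssss.items()
    }
    target_sets = {
        name: select_down_targets(ranked, combined_cut, index, es.canonical_word, name)
        for name, es in element_sets.items()
    }
    summary = (
        summarize_targets(list(target_sets.values()), combined_cut.gene_count)
        if combined_cut.gene_count > 0 and target_sets
        else None
    )
    manifest = {
        "n_genes_ranked": len(ranked),
        "bin_width": bin_width,
        "cpdv_lookahead": cpdv_lookahead,
        "detection_alpha": detection_alpha,
        "mirnas": {name: list(es.words) for name, es in element_sets.items()},
        "cut_bin": combined_cut.bin_index,
        "cut_gene_count": combined_cut.gene_count,
        "target_sizes": {n: len(t) for n, t in target_sets.items()},
        "target_union": summary.union if summary else None,
        "target_union_pct": summary.union_pct if summary else None,
    }
    return PipelineResult(
        ranked=ranked,
        index=index,
        landscape=curve,
        ssss=ssss,
        combined_cut=combined_cut,
        per_mirna_cuts=per_mirna_cuts,
        target_sets=target_sets,
        summary=summary,
        ora_table=None,
        methylation_report=None,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline from files and write versioned outputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    universe = mio.read_fasta_universe(config.utr_fasta)
    matrix = mio.read_expression(config.expression_tsv, config.design_yaml)
    annotation = mio.read_annotation(config.annotation_tsv)
    mirnas = mio.read_mirna_table(config.mirna_tsv)

    result = run_stages(
        matrix,
        annotation,
        universe,
        mirnas,
        bin_width=config.bin_width,
        cpdv_lookahead=config.cpdv_lookahead,
        detection_alpha=config.detection_alpha,
    )

    if config.gmt:
        annotations = AnnotationCollection.from_gmt(config.gmt)
        union = set().union(*(t.genes for t in result.target_sets.values()))
        result.ora_table = _stage("ora")(ora)(
            union, annotations, universe_size=len(result.ranked), q=config.fdr_q
        )
        result.ora_table.to_csv(out_dir / "ora.tsv", sep="\t", index=False)

    if config.pyro_tsv:
        assays = mio.read_pyro_table(config.pyro_tsv)
        scores = [cumulative_methylation(a) for a in assays]
        groups = sorted({s.group for s in scores})
        report: dict = {
            "scores": {s.sample_id: s.cumulative for s in scores},
            "n_sites": scores[0].n_sites if scores else 0,
            "max_score": scores[0].max_score if scores else 0,
        }
        if len(groups) == 2:
            cmp = compare_groups(
                [s for s in scores if s.group == groups[0]],
                [s for s in scores if s.group == groups[1]],
            )
            report["comparison"] = {
                "groups": groups,
                "t": cmp.t_statistic,
                "p": cmp.p_value,
                "means": cmp.means,
                "sems": cmp.sems,
            }
        result.methylation_report = report
        (out_dir / "methylation.json").write_text(json.dumps(report, indent=2))

    mio.write_ranked_list(result.ranked, out_dir / "ranked.tsv")
    result.landscape.scores.to_csv(out_dir / "landscape.tsv", sep="\t")
    pd.DataFrame({n: s.values for n, s in result.ssss.items()}).to_csv(
        out_dir / "ssss.tsv", sep="\t"
    )
    cut_report = {
        "combined": {
            "bin_index": result.combined_cut.bin_index,
            "gene_count": result.combined_cut.gene_count,
            "cpdv": [None if not np.isfinite(v) else float(v) for v in result.combined_cut.cpdv],
        },
        "per_mirna": {
            n: {"bin_index": c.bin_index, "gene_count": c.gene_count}
            for n, c in result.per_mirna_cuts.items()
        },
    }
    (out_dir / "cutpoint.json").write_text(json.dumps(cut_report, indent=2))
    for name, tset in result.target_sets.items():
        safe = name.replace("/", "_")
        pd.DataFrame(
            {"gene_id": sorted(tset.matches), "words": ["|".join(tset.matches[g]) for g in sorted(tset.matches)]}
        ).to_csv(out_dir / f"targets_{safe}.tsv", sep="\t", index=False)

    manifest = dict(result.manifest)
    manifest.update({"config": asdict(config), "seed": config.seed})
    result.manifest = manifest
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
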