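"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA for 3'UTR universes (record id = first whitespace-delimited token),
TSV for expression matrices, annotations, ranked lists, landscapes and
methylation tables, BED for regions (0-based half-open), GMT for
annotation gene sets, and YAML for configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CtTable, ExpressionMatrix, ProbeAnnotation, RankedList
from .methylation import BetaProbeSet, PyroAssay, RegionSpec
from .seed_scan import MiRNA, UTRUniverse

__all__ = [
    "read_fasta_universe",
    "write_fasta_universe",
    "read_mirna_table",
    "read_expression",
    "read_annotation",
    "read_ranked_list",
    "write_ranked_list",
    "read_bed_regions",
    "read_pyro_table",
    "read_beta_table",
    "read_ct_table",
    "read_yaml",
    "write_yaml",
]


def read_fasta_universe(path) -> UTRUniverse:
    """Read a 3'UTR FASTA; sequences are uppercased, duplicate ids rejected."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id.split()[0]
        if gene_id in records:
            raise ValueError(f"{path}: duplicate record id {gene_id!r}")
        records[gene_id] = str(rec.seq).upper()
    return UTRUniverse(records=records)


def write_fasta_universe(universe: UTRUniverse, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in universe.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_mirna_table(path) -> list[MiRNA]:
    """TSV with columns name, mature_seq and optional seed_start, seed_end."""
    t = pd.read_csv(path, sep="\t")
    required = {"name", "mature_seq"}
    if not required <= set(t.columns):
        raise ValueError(f"{path}: miRNA table needs columns {sorted(required)}")
    out = []
    for row in t.itertuples(index=False):
        span = (
            (int(row.seed_start), int(row.seed_end))
            if {"seed_start", "seed_end"} <= set(t.columns)
            else (1, 8)
        )
        out.append(MiRNA(name=str(row.name), mature_seq=str(row.mature_seq), seed_span=span))
    return out


def read_expression(values_path, design_path) -> ExpressionMatrix:
    """Intensity TSV (probe_id index, sample columns) + YAML design.

    The design file maps ``conditions: {sample: treated|control}`` and
    lists ``negative_controls: [probe ids]``.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    design = read_yaml(design_path)
    return ExpressionMatrix(
        values=values,
        conditions=dict(design["conditions"]),
        negative_controls=set(design.get("negative_controls", [])),
    )


def write_expression(matrix: ExpressionMatrix, values_path, design_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="probe_id")
    write_yaml(
        {
            "conditions": dict(matrix.conditions),
            "negative_controls": sorted(matrix.negative_controls),
        },
        design_path,
    )


def read_annotation(path) -> ProbeAnnotation:
    t = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    return ProbeAnnotation(table=t)


def read_ranked_list(path) -> RankedList:
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return RankedList(table=t[[c for c in t.columns if c != "rank"]])


def write_ranked_list(ranked: RankedList, path) -> None:
    ranked.table.to_csv(path, sep="\t", index=False)


def read_bed_regions(path, min_probes: int = 5) -> list[RegionSpec]:
    """BED3 (0-based half-open) to region specs."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs chrom, start, end")
            regions.append(
                RegionSpec(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    min_probes=min_probes,
                )
            )
    return regions


def read_pyro_table(path) -> list[PyroAssay]:
    """TSV (sample, group, chrom, pos, replicate, pct_meth) -> assays."""
    t = pd.read_csv(path, sep="\t")
    assays = []
    for (sample, group), sub in t.groupby(["sample", "group"], sort=False):
        assays.append(
            PyroAssay(
                sample_id=str(sample),
                group=str(group),
                data=sub[["chrom", "pos", "replicate", "pct_meth"]].reset_index(drop=True),
            )
        )
    return assays


def write_pyro_table(assays: list[PyroAssay], path) -> None:
    frames = []
    for a in assays:
        d = a.data.copy()
        d.insert(0, "group", a.group)
        d.insert(0, "sample", a.sample_id)
        frames.append(d)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_beta_table(path) -> BetaProbeSet:
    return BetaProbeSet(table=pd.read_csv(path, sep="\t", dtype={"probe_id": str}))


def read_ct_table(path, reference_assays, reference_sample) -> CtTable:
    return CtTable(
        data=pd.read_csv(path, sep="\t"),
        reference_assays=list(reference_assays),
        reference_sample=reference_sample,
    )


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
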