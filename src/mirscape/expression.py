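"""Probe-level expression to ranked gene lists, plus qPCR utilities.

The landscape analysis consumes a ranked gene list: genes ordered from most
down- to most up-regulated after a perturbation, one entry per gene.  This
module provides the minimal path from probe-level array intensities to that
list — an empirical detection filter against negative-control probes,
log2 fold-change computation, one-probe-per-gene collapse — together with
Benjamini-Hochberg FDR adjustment and delta-delta-Ct relative
quantification for qPCR validation assays.

Normalisation here is deliberately plain: intensities are transformed as
log2(x + 1) and no array-internal (quantile/VSN) normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "RankedList",
    "CtTable",
    "detection_filter",
    "collapse_and_rank",
    "bh_adjust",
    "ddct_relative_expression",
]


@dataclass
class ExpressionMatrix:
    """Probe x sample intensities with condition labels and control flags.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative intensities, probes as index, samples as columns.
    conditions : mapping
        sample id -> ``"treated"`` or ``"control"``.
    negative_controls : set of str
        Probe ids of negative-control probes (required for detection
        filtering).
    """

    values: pd.DataFrame
    conditions: dict[str, str]
    negative_controls: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dupes[:3])}")
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing[:3]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        self.negative_controls = set(self.negative_controls) & set(self.values.index)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]


@dataclass
class ProbeAnnotation:
    """probe_id -> gene_id mapping with 3'UTR availability flags."""

    table: pd.DataFrame  # columns: probe_id, gene_id, has_full_utr

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "has_full_utr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in annotation")


@dataclass
class RankedList:
    """Genes ordered from most down- to most up-regulated.

    ``table`` has columns rank (1-based), gene_id, log2fc and optionally
    p_adjusted; exactly one row per gene, sorted ascending by log2fc.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["gene_id"].duplicated().any():
            raise ValueError("ranked list must have one entry per gene")
        fc = self.table["log2fc"].to_numpy()
        if np.any(np.diff(fc) < 0):
            raise ValueError("ranked list statistic must be non-decreasing")
        self.table = self.table.reset_index(drop=True)
        self.table["rank"] = np.arange(1, len(self.table) + 1)

    @property
    def genes(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_stats(cls, log2fc: Mapping[str, float]) -> "RankedList":
        """Build from a gene -> log2FC mapping (ascending, ties by gene id)."""
        table = (
            pd.DataFrame({"gene_id": list(log2fc), "log2fc": list(log2fc.values())})
            .sort_values(["log2fc", "gene_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(table=table)


def detection_filter(
    matrix: ExpressionMatrix, alpha: float = 0.01
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove probes not detected above the negative-control background.

    A probe's detection p-value is the fraction of negative-control
    intensities (pooled over control probes and samples) that are >= the
    probe's mean intensity across samples.  Probes with p > ``alpha`` are
    removed, as are the negative-control probes themselves.  Returns the
    filtered matrix and a per-probe log (probe_id, detection_p, retained).
    """
    if len(matrix.negative_controls) < 2:
        raise ValueError("detection filter needs >= 2 negative-control probes")
    nc_values = np.sort(
        matrix.values.loc[sorted(matrix.negative_controls)].to_numpy().ravel()
    )
    probe_means = matrix.values.mean(axis=1)
    # p = fraction of NC intensities >= probe mean
    below = np.searchsorted(nc_values, probe_means.to_numpy(), side="left")
    detection_p = 1.0 - below / len(nc_values)
    log = pd.DataFrame(
        {
            "probe_id": matrix.values.index,
            "detection_p": detection_p,
            "is_negative_control": [p in matrix.negative_controls for p in matrix.values.index],
        }
    )
    log["retained"] = (log["detection_p"] <= alpha) & ~log["is_negative_control"]
    kept = log.loc[log["retained"], "probe_id"]
    filtered = ExpressionMatrix(
        values=matrix.values.loc[kept],
        conditions=dict(matrix.conditions),
        negative_controls=set(),
    )
    return filtered, log


def collapse_and_rank(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation
) -> RankedList:
    """Collapse probes to genes and rank by log2 fold change, ascending.

    Per probe, log2FC = mean over treated samples of log2(x + 1) minus the
    same mean over control samples.  Per gene the probe with the largest
    |log2FC| represents it (ties by probe id); genes without full 3'UTR
    annotation are excluded.  Output is sorted ascending by log2FC with
    ties broken by gene id, so rank 1 is the most downregulated gene.
    """
    treated = matrix.samples_in("treated")
    control = matrix.samples_in("control")
    if not treated or not control:
        raise ValueError("need both treated and control samples")
    logged = np.log2(matrix.values + 1.0)
    lfc = logged[treated].mean(axis=1) - logged[control].mean(axis=1)
    ann = annotation.table.set_index("probe_id")
    rows = []
    for probe, fc in lfc.items():
        if probe not in ann.index:
            continue
        if not bool(ann.at[probe, "has_full_utr"]):
            continue
        rows.append((str(probe), str(ann.at[probe, "gene_id"]), float(fc)))
    if not rows:
        raise ValueError("no annotated genes remain after filtering")
    per_probe = pd.DataFrame(rows, columns=["probe_id", "gene_id", "log2fc"])
    per_probe["abs_fc"] = per_probe["log2fc"].abs()
    per_probe = per_probe.sort_values(
        ["gene_id", "abs_fc", "probe_id"], ascending=[True, False, True], kind="mergesort"
    )
    collapsed = per_probe.drop_duplicates("gene_id", keep="first")
    table = (
        collapsed[["gene_id", "log2fc"]]
        .sort_values(["log2fc", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return RankedList(table=table)


def bh_adjust(
    p_values: Sequence[float] | np.ndarray, q: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment with significance flags at ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted, adjusted <= q


@dataclass
class CtTable:
    """qPCR Ct values with reference-assay and reference-sample designation.

    ``data`` has columns sample, assay, replicate, ct.  ``reference_assays``
    are the normaliser assays (>= 1); all other assays are targets.
    ``reference_sample`` is the calibrator mapped to relative expression 1.
    """

    data: pd.DataFrame
    reference_assays: list[str]
    reference_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "assay", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if not np.isfinite(self.data["ct"]).all():
            raise ValueError("Ct values must be finite")
        assays = set(self.data["assay"])
        if not self.reference_assays or not set(self.reference_assays) <= assays:
            raise ValueError("reference assays missing from table")
        if self.reference_sample not in set(self.data["sample"]):
            raise ValueError(f"reference sample {self.reference_sample!r} not in table")

    @property
    def target_assays(self) -> list[str]:
        refs = set(self.reference_assays)
        return [a for a in dict.fromkeys(self.data["assay"]) if a not in refs]


def ddct_relative_expression(table: CtTable) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    Replicate Cts are averaged per (sample, assay); with several reference
    assays the arithmetic mean of their mean Cts is used (equivalent to a
    geometric mean of the linear quantities).  For each target assay,
    dCt = Ct_target - mean(Ct_references) per sample and relative
    expression = 2^-(dCt_sample - dCt_reference_sample), so the reference
    sample maps to 1.0 exactly.

    Returns a DataFrame indexed by sample with one column per target assay.
    """
    means = table.data.groupby(["sample", "assay"])["ct"].mean().unstack()
    if means.isna().any().any():
        missing = means.stack(dropna=False)
        missing = missing[missing.isna()]
        raise ValueError(f"missing Ct for {list(missing.index[:3])}")
    ref_ct = means[table.reference_assays].mean(axis=1)
    out = {}
    for assay in table.target_assays:
        dct = means[assay] - ref_ct
        ddct = dct - dct.loc[table.reference_sample]
        out[assay] = np.power(2.0, -ddct)
    return pd.DataFrame(out)
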