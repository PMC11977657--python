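"""SCR-containing target gene lists, set summaries, and over-representation.

Down-targets are genes among the CPDV-selected most-downregulated leading
edge whose 3'UTR carries the miRNA's canonical SCR word; up- (de-repressed)
targets are SCR carriers with log2 fold change strictly above a threshold
in clinical-style data where the miRNA is lost.  Per-miRNA sets are
combined by plain inclusion-exclusion, and candidate lists can be tested
against user-supplied annotation gene sets by hypergeometric
over-representation with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import RankedList, bh_adjust
from .landscape import CutPoint
from .seed_scan import OccurrenceIndex

__all__ = [
    "TargetSet",
    "TargetSummary",
    "AnnotationCollection",
    "select_down_targets",
    "select_up_targets",
    "summarize_targets",
    "ora",
]


@dataclass
class TargetSet:
    """SCR-containing target genes for one miRNA, one direction."""

    mirna_name: str
    direction: str  # "down" | "up"
    matches: dict[str, tuple[str, ...]]  # gene_id -> matching SCR word(s)

    def __post_init__(self) -> None:
        if self.direction not in ("down", "up"):
            raise ValueError(f"direction must be 'down' or 'up', got {self.direction!r}")

    @property
    def genes(self) -> set[str]:
        return set(self.matches)

    def __len__(self) -> int:
        return len(self.matches)

    @classmethod
    def from_genes(
        cls, mirna_name: str, direction: str, genes: Iterable[str], word: str = ""
    ) -> "TargetSet":
        return cls(mirna_name, direction, {g: (word,) if word else () for g in genes})


@dataclass
class TargetSummary:
    """Set algebra over per-miRNA target sets against a leading-edge list."""

    sizes: dict[str, int]
    overlap: int
    union: int
    list_length: int

    @property
    def union_pct(self) -> float:
        """Union as a percentage of the leading-edge list, one decimal."""
        return round(100.0 * self.union / self.list_length, 1)

    @classmethod
    def from_counts(
        cls, size_a: int, size_b: int, overlap: int, list_length: int, names: tuple[str, str] = ("A", "B")
    ) -> "TargetSummary":
        if not 0 <= overlap <= min(size_a, size_b):
            raise ValueError("overlap must be between 0 and min(|A|, |B|)")
        union = size_a + size_b - overlap
        return cls(dict(zip(names, (size_a, size_b))), overlap, union, list_length)


def select_down_targets(
    ranked: RankedList,
    cut: CutPoint | int,
    index: OccurrenceIndex,
    word: str,
    mirna_name: str,
) -> TargetSet:
    """Genes in the leading edge at the cut whose 3'UTR carries the SCR word.

    ``cut`` may be a :class:`~mirscape.landscape.CutPoint` or a plain gene
    count; a cut of 0 yields an empty set.
    """
    n = cut.gene_count if isinstance(cut, CutPoint) else int(cut)
    if n < 0 or n > len(ranked):
        raise ValueError(f"cut gene count {n} outside ranked list of {len(ranked)}")
    leading = ranked.genes[:n]
    carriers = index.carriers(word)
    matches = {g: (word,) for g in leading if g in carriers}
    return TargetSet(mirna_name=mirna_name, direction="down", matches=matches)


def select_up_targets(
    ranked: RankedList,
    index: OccurrenceIndex,
    word: str,
    mirna_name: str,
    fc_threshold: float = 0.5,
) -> TargetSet:
    """De-repressed targets: SCR carriers with log2FC strictly > threshold."""
    stats_ = ranked.table.set_index("gene_id")["log2fc"]
    carriers = index.carriers(word)
    up = stats_.index[stats_ > fc_threshold]  # strict inequality
    matches = {g: (word,) for g in up if g in carriers}
    return TargetSet(mirna_name=mirna_name, direction="up", matches=matches)


def summarize_targets(sets: Sequence[TargetSet], list_length: int) -> TargetSummary:
    """Inclusion-exclusion summary of per-miRNA target sets.

    Reports each set's size, the overlap of all sets, the union, and the
    union as a percentage of ``list_length`` (e.g. the leading-edge count
    for down-targets, or the full gene list for up-targets).
    """
    if not sets:
        raise ValueError("need at least one target set")
    directions = {s.direction for s in sets}
    if len(directions) != 1:
        raise ValueError(f"target sets mix directions {sorted(directions)}")
    if list_length <= 0:
        raise ValueError("list_length must be positive")
    gene_sets = [s.genes for s in sets]
    overlap = set.intersection(*gene_sets)
    union = set.union(*gene_sets)
    return TargetSummary(
        sizes={s.mirna_name: len(s) for s in sets},
        overlap=len(overlap),
        union=len(union),
        list_length=list_length,
    )


@dataclass
class AnnotationCollection:
    """Named gene sets (pathway label -> gene ids) over a stated universe."""

    sets: dict[str, set[str]]

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "AnnotationCollection":
        sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
                name, _desc, *genes = fields
                if name in sets:
                    raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
                sets[name] = {g for g in genes if g}
        return cls(sets=sets)


def ora(
    target_genes: Iterable[str],
    annotations: AnnotationCollection,
    universe_size: int,
    q: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a target list in each gene set.

    For each annotation set of size K within a universe of ``universe_size``
    genes, with ``n`` targets of which ``x`` fall in the set, the enrichment
    p-value is ``P(X >= x)`` for ``X ~ Hypergeometric(N, K, n)``.  Returns a
    table ranked by p ascending with BH-adjusted values and significance
    flags at FDR ``q``.
    """
    targets = set(target_genes)
    n = len(targets)
    if universe_size < n:
        raise ValueError("target list larger than universe")
    if len(annotations) == 0:
        return pd.DataFrame(
            columns=["set_name", "set_size", "overlap", "p_value", "p_adjusted", "significant"]
        )
    rows = []
    for name, members in annotations.sets.items():
        K = len(members)
        x = len(targets & members)
        p = stats.hypergeom.sf(x - 1, universe_size, K, n)
        rows.append((name, K, x, float(p)))
    table = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    adjusted, flags = bh_adjust(table["p_value"].to_numpy(), q=q)
    table["p_adjusted"] = adjusted
    table["significant"] = flags
    return table.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
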