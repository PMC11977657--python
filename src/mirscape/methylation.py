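"""Bisulphite-pyrosequencing methylation scoring and array beta/M values.

Pyrosequencing reports a percent methylation (0-100) per CpG site and
replicate.  A sample's *cumulative methylation abundance* sums the per-site
mean percentages over all assayed sites, so a panel of n sites has a
maximum score of 100*n (e.g. 2300 for 23 sites).  Array probes report a
beta value (methylated fraction) which is logit-transformed to an M value,
M = log2(beta / (1 - beta)), for statistics.  Genomic regions of interest
are only scored when they contain a minimum number of probes (default 5).
Coordinates are 0-based half-open internally; file interfaces are 1-based
inclusive where stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PyroAssay",
    "CumulativeScore",
    "BetaProbeSet",
    "RegionSpec",
    "GroupComparison",
    "LinearFit",
    "cumulative_methylation",
    "beta_to_m",
    "m_to_beta",
    "region_probe_filter",
    "compare_groups",
    "linear_fit",
]

BETA_EPS = 1e-6


@dataclass
class PyroAssay:
    """Replicate percent-methylation values per CpG site for one sample.

    ``data`` has columns chrom, pos (1-based), replicate, pct_meth; site
    order follows first appearance and must be shared across samples that
    are compared.
    """

    sample_id: str
    group: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "replicate", "pct_meth"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"pyro table missing columns {sorted(missing)}")
        vals = self.data["pct_meth"].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("percent methylation must lie in [0, 100]")
        if self.data.empty:
            raise ValueError("assay has no sites")

    @property
    def sites(self) -> list[tuple[str, int]]:
        seen = self.data[["chrom", "pos"]].drop_duplicates()
        return [(str(c), int(p)) for c, p in seen.itertuples(index=False)]


@dataclass
class CumulativeScore:
    """Cumulative methylation abundance for one sample."""

    sample_id: str
    group: str
    per_site_mean: pd.Series  # indexed by (chrom, pos)
    cumulative: float
    n_sites: int

    @property
    def max_score(self) -> float:
        return 100.0 * self.n_sites

    @property
    def overall_pct(self) -> float:
        """Mean per-site methylation, i.e. cumulative / n_sites."""
        return self.cumulative / self.n_sites


def cumulative_methylation(assay: PyroAssay) -> CumulativeScore:
    """Sum per-site mean percent methylation across all assayed sites.

    Replicates (all bisulphite preparations pooled) are averaged per site
    arithmetically; a site with no replicate values is an error upstream
    because the assay table carries one row per replicate.
    """
    per_site = assay.data.groupby(["chrom", "pos"], sort=False)["pct_meth"].mean()
    return CumulativeScore(
        sample_id=assay.sample_id,
        group=assay.group,
        per_site_mean=per_site,
        cumulative=float(per_site.sum()),
        n_sites=len(per_site),
    )


def beta_to_m(beta, eps: float = BETA_EPS):
    """M value of a methylation beta: M = log2(beta / (1 - beta)).

    Betas are clipped to [eps, 1 - eps] so boundary values stay finite;
    values outside [0, 1] are a domain error.  Accepts scalars or arrays.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (logistic in base 2)."""
    m_arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.power(2.0, -m_arr))
    return float(b) if np.isscalar(m) else b


@dataclass
class BetaProbeSet:
    """Array probes with genomic position and per-sample beta values.

    ``table`` has columns probe_id, chrom, pos (1-based) plus one column
    per sample holding betas in [0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"beta table missing columns {sorted(missing)}")

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("probe_id", "chrom", "pos")]

    def m_values(self) -> pd.DataFrame:
        out = self.table[["probe_id", "chrom", "pos"]].copy()
        for col in self.sample_columns:
            out[col] = beta_to_m(self.table[col].to_numpy())
        return out


@dataclass(frozen=True)
class RegionSpec:
    """Genomic region, 0-based half-open, with a minimum probe requirement."""

    chrom: str
    start: int
    end: int
    min_probes: int = 5

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region start {self.start} must precede end {self.end}")

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return chrom == self.chrom and self.start <= pos_1based - 1 < self.end


def region_probe_filter(
    probes: BetaProbeSet, region: RegionSpec
) -> tuple[bool, pd.DataFrame]:
    """Retain a region iff it contains at least ``min_probes`` unique probes.

    Probe positions (1-based) are tested against the 0-based half-open
    region; duplicated probe records count once per unique probe_id.
    """
    t = probes.table
    in_region = t.apply(
        lambda r: region.contains(str(r["chrom"]), int(r["pos"])), axis=1
    )
    sub = t.loc[in_region].drop_duplicates("probe_id")
    return len(sub) >= region.min_probes, sub.reset_index(drop=True)


@dataclass
class GroupComparison:
    """Two-group comparison of cumulative scores."""

    t_statistic: float
    p_value: float
    means: tuple[float, float]
    sems: tuple[float, float]
    n: tuple[int, int]
    degenerate: bool  # both groups constant -> p undefined


def compare_groups(
    group_a: Sequence[float] | Iterable[CumulativeScore],
    group_b: Sequence[float] | Iterable[CumulativeScore],
    equal_var: bool = True,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of scores.

    Student's (equal-variance) test by default, Welch with
    ``equal_var=False``.  Accepts plain value vectors or
    :class:`CumulativeScore` objects.  Groups with zero pooled variance are
    flagged degenerate: t and p are NaN unless the means are also equal, in
    which case t = 0 and p = 1.
    """
    a = np.array([s.cumulative if isinstance(s, CumulativeScore) else s for s in group_a], dtype=float)
    b = np.array([s.cumulative if isinstance(s, CumulativeScore) else s for s in group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    means = (float(a.mean()), float(b.mean()))
    sems = (float(stats.sem(a)), float(stats.sem(b)))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if means[0] == means[1]:
            return GroupComparison(0.0, 1.0, means, sems, (len(a), len(b)), degenerate=True)
        return GroupComparison(np.nan, np.nan, means, sems, (len(a), len(b)), degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(float(t), float(p), means, sems, (len(a), len(b)), degenerate=False)


@dataclass
class LinearFit:
    """Ordinary least-squares fit for co-expression-style scatter data."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS regression of y on x with R^2 and slope-significance p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired points")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )
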