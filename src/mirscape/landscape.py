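"""Hypergeometric SCR enrichment landscapes, SSSS integration, CPDV cuts.

The landscape statistic asks, at each cut ``k*B`` along a ranked gene list
(most downregulated first), whether genes carrying a given SCR word are
over- or under-represented among the leading ``k*B`` genes relative to the
whole list.  With ``N`` genes in total, ``K`` of them carriers, and ``x``
carriers among the leading ``n = k*B``, the enrichment tail is
``P(X >= x)`` and the depletion tail ``P(X <= x)`` for
``X ~ Hypergeometric(N, K, n)``.  The per-bin signed score is
``sign * (-log10 p)`` using the smaller tail, positive for enrichment in
the downregulated leading set.

Per-miRNA curves for several seed-element words are integrated into a
single summed significance score (SSSS), and the cut point for downstream
target lists is chosen by the change-point delta value (CPDV): a bin's
score minus the minimum score over the next five bins, maximised over bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seed_scan import OccurrenceIndex, SCRElementSet

__all__ = [
    "LandscapeCurve",
    "SSSSCurve",
    "CutPoint",
    "hypergeometric_landscape",
    "ssss_integration",
    "cpdv_select",
]

P_FLOOR = 1e-300


@dataclass
class LandscapeCurve:
    """Signed per-bin significance scores, one column per SCR word.

    ``scores`` is indexed by leading-edge gene count (k*B for k = 1..n_bins).
    """

    bin_width: int
    n_genes: int
    scores: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return len(self.scores)

    @property
    def bin_edges(self) -> np.ndarray:
        return self.scores.index.to_numpy()

    def word_curve(self, word: str) -> np.ndarray:
        if word not in self.scores.columns:
            raise KeyError(f"word {word!r} not in landscape")
        return self.scores[word].to_numpy()


@dataclass
class SSSSCurve:
    """Per-bin single summed significance score for one miRNA."""

    mirna_name: str
    bin_width: int
    values: pd.Series  # indexed by leading-edge gene count

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


@dataclass
class CutPoint:
    """CPDV values per bin and the selected cut."""

    cpdv: np.ndarray
    bin_index: int  # 1-based
    bin_width: int

    @property
    def gene_count(self) -> int:
        return self.bin_index * self.bin_width


def _signed_scores(x: np.ndarray, N: int, K: int, n: np.ndarray, p_floor: float) -> np.ndarray:
    """Signed -log10 of the smaller hypergeometric tail at each cut."""
    # enrichment: P(X >= x) = sf(x - 1); depletion: P(X <= x) = cdf(x)
    p_enr = stats.hypergeom.sf(x - 1, N, K, n)
    p_dep = stats.hypergeom.cdf(x, N, K, n)
    enriched = p_enr <= p_dep  # tie -> enrichment sign, score ~0 anyway
    p = np.where(enriched, p_enr, p_dep)
    logp = -np.log10(np.maximum(p, p_floor))
    return np.where(enriched, logp, -logp)


def hypergeometric_landscape(
    ranked_genes: Sequence[str],
    index: OccurrenceIndex,
    words: Iterable[str],
    bin_width: int = 200,
    p_floor: float = P_FLOOR,
) -> LandscapeCurve:
    """Compute the binned enrichment/depletion landscape over a ranked list.

    Parameters
    ----------
    ranked_genes : sequence of str
        Gene ids ordered from most down- to most up-regulated; every gene
        must be present in ``index``.  The ranked list itself is the
        universe (N = len(ranked_genes)).
    index : OccurrenceIndex
        Gene-level word presence from :func:`~mirscape.seed_scan.scan_occurrences`.
    words : iterable of str
        SCR words to score; a word carried by no gene scores 0 at all bins.
    bin_width : int
        Genes per bin (default 200); bins are the cuts k*bin_width for
        k = 1..floor(N / bin_width).
    """
    genes = list(ranked_genes)
    N = len(genes)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if bin_width > N:
        raise ValueError(f"bin_width {bin_width} exceeds list length {N}")
    missing = [g for g in genes if g not in index.counts.index]
    if missing:
        raise KeyError(f"{len(missing)} ranked genes missing from index, e.g. {missing[:3]}")
    n_bins = N // bin_width
    cuts = bin_width * np.arange(1, n_bins + 1)
    cols: dict[str, np.ndarray] = {}
    for word in dict.fromkeys(words):
        present = index.presence_vector(word, genes)
        K = int(present.sum())
        if K == 0:
            cols[word] = np.zeros(n_bins)
            continue
        x = np.cumsum(present)[cuts - 1]
        cols[word] = _signed_scores(x, N, K, cuts, p_floor)
    scores = pd.DataFrame(cols, index=pd.Index(cuts, name="leading_genes"))
    return LandscapeCurve(bin_width=bin_width, n_genes=N, scores=scores)


def ssss_integration(
    curve: LandscapeCurve,
    elements: SCRElementSet,
    method: str = "sum",
) -> SSSSCurve:
    """Integrate a miRNA's element curves into its SSSS.

    ``method="sum"`` (default) adds the signed scores of the miRNA's SCR
    elements bin-wise.  ``method="fisher"`` combines the per-element tail
    p-values by Fisher's method and signs the combined -log10 p by the sum
    of the signed scores.
    """
    missing = [w for w in elements.words if w not in curve.scores.columns]
    if missing:
        raise KeyError(f"element words missing from landscape: {missing}")
    sub = curve.scores[list(dict.fromkeys(elements.words))]
    if method == "sum":
        values = sub.sum(axis=1)
    elif method == "fisher":
        logp = np.abs(sub.to_numpy())  # -log10 of each element's smaller tail
        chi2 = 2 * np.log(10) * logp.sum(axis=1)
        p_comb = stats.chi2.sf(chi2, df=2 * sub.shape[1])
        sign = np.sign(sub.sum(axis=1).to_numpy())
        sign[sign == 0] = 1.0
        values = pd.Series(
            sign * -np.log10(np.maximum(p_comb, P_FLOOR)), index=sub.index
        )
    else:
        raise ValueError(f"unknown integration method {method!r}")
    values.name = elements.mirna_name
    return SSSSCurve(mirna_name=elements.mirna_name, bin_width=curve.bin_width, values=values)


def cpdv_select(
    curve: Sequence[float] | np.ndarray | pd.Series | SSSSCurve,
    lookahead: int = 5,
    bin_width: int = 200,
) -> CutPoint:
    """Select the landscape cut by the change-point delta value.

    For bin i (1-based, left to right), CPDV_i = L_i - min(L_{i+1}, ...,
    L_{i+lookahead}), the window truncated at the end of the curve; the
    final bin has an empty window and CPDV -inf, so it is never selected.
    The selected bin is the argmax of CPDV, first index on ties; its
    leading-edge gene count is ``bin_index * bin_width``.  An all-equal
    curve yields CPDV 0 everywhere and selects bin 1.
    """
    if isinstance(curve, SSSSCurve):
        bin_width = curve.bin_width
        values = curve.to_numpy()
    else:
        values = np.asarray(curve, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("curve must have at least 2 bins")
    if lookahead < 1:
        raise ValueError("lookahead must be >= 1")
    cpdv = np.full(n, -np.inf)
    for i in range(n - 1):
        window = values[i + 1 : i + 1 + lookahead]
        cpdv[i] = values[i] - window.min()
    best = int(np.argmax(cpdv))  # first occurrence on ties
    return CutPoint(cpdv=cpdv, bin_index=best + 1, bin_width=bin_width)
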