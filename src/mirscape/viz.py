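"""Optional plotting helpers (requires matplotlib, installed via the
``plot`` extra)."""

from __future__ import annotations

from .landscape import CutPoint, LandscapeCurve, SSSSCurve

__all__ = ["plot_landscape"]


def plot_landscape(
    curve: LandscapeCurve,
    ssss: dict[str, SSSSCurve] | None = None,
    cut: CutPoint | None = None,
    ax=None,
):
    """Landscape plot: signed -log10 p per bin against the ranked list.

    Thin grey lines show each word's curve; coloured lines show per-miRNA
    SSSS curves; a dashed vertical line marks the CPDV cut.  Positive
    deflection on the left means SCR enrichment in downregulated genes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = curve.bin_edges
    for word in curve.scores.columns:
        ax.plot(x, curve.word_curve(word), color="0.75", lw=0.8, zorder=1)
    if ssss:
        for name, s in ssss.items():
            ax.plot(x, s.to_numpy(), lw=1.8, label=name, zorder=2)
        ax.legend(frameon=False, fontsize=8)
    if cut is not None:
        ax.axvline(cut.gene_count, ls="--", color="k", lw=1)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("ranked genes (most downregulated first)")
    ax.set_ylabel(r"signed $-\log_{10} P$")
    return ax
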