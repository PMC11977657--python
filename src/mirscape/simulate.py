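"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate a miRNA replenishment experiment read out on an
expression array: a universe of random 3'UTR sequences in which a known
subset of *responder* genes is enriched for the miRNA's seed-complementary
word, a differential-expression readout in which responders are shifted
down by a fixed log2 fold change plus Gaussian noise, two-group
pyrosequencing methylation tables, and qPCR Ct panels with known fold
changes.  Every generator draws from an independent substream of a single
root seed, so each can be regenerated on its own and a full run is
reproducible bit for bit.

Defaults mirror the scale of the analysis this package implements: 4000
genes with ~1 kb UTRs, 1400 responders carrying the spiked word at 60%
versus a 10% background, a -1.5 log2FC shift with SD 0.5 noise, and bins
of 200 genes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CtTable, ExpressionMatrix, ProbeAnnotation
from .methylation import PyroAssay
from .seed_scan import UTRUniverse

__all__ = [
    "SynthConfig",
    "simulate_utr_universe",
    "simulate_ranked_experiment",
    "simulate_methylation",
    "simulate_ct_table",
]

_STREAMS = ("universe", "expression", "methylation", "ct")


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; all randomness flows from ``seed``."""

    seed: int = 0
    # 3'UTR universe
    n_genes: int = 4000
    utr_len_median: float = 1000.0  # log-normal median (nt)
    utr_len_sigma: float = 0.5  # log-normal shape
    utr_len_min: int = 50
    gc_content: float = 0.40
    spike_words: tuple[str, ...] = ()  # words inserted into carriers
    # differential-expression experiment
    n_responders: int = 1400
    carrier_p_responder: float = 0.6
    carrier_p_background: float = 0.1
    effect_size: float = -1.5  # log2FC shift of responders
    noise_sd: float = 0.5
    n_treated: int = 3
    n_control: int = 3
    n_negative_controls: int = 200
    signal_log2_mean: float = 8.0
    signal_log2_sd: float = 0.5
    nc_log2_mean: float = 3.0
    nc_log2_sd: float = 0.3
    # methylation
    meth_sites: int = 23
    meth_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"malignant": 70.0, "control": 20.0}
    )
    meth_sd: float = 5.0
    meth_n_per_group: int = 5
    meth_replicates: int = 3
    # qPCR panel
    ct_baseline: float = 25.0
    ct_sd: float = 0.1
    ct_replicates: int = 3

    def __post_init__(self) -> None:
        for p in (self.carrier_p_responder, self.carrier_p_background, self.gc_content):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_responders > self.n_genes:
            raise ValueError("responder count exceeds gene count")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator, derived from the root seed."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}; choose from {_STREAMS}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def simulate_utr_universe(config: SynthConfig) -> tuple[UTRUniverse, pd.DataFrame]:
    """Random 3'UTRs with spiked words in designated carrier genes.

    Responder genes (the first ``n_responders`` in a random designation)
    carry each spike word with probability ``carrier_p_responder``, the
    rest with ``carrier_p_background``.  A carried word replaces bases at a
    uniform random position, keeping the length distribution exact; several
    words in one gene are placed without overlap.  Returns the universe and
    a truth table with columns gene_id, is_responder, and carrier_<word>.
    """
    rng = config.rng("universe")
    n = config.n_genes
    mu = np.log(config.utr_len_median)
    lengths = np.maximum(
        config.utr_len_min,
        np.round(rng.lognormal(mean=mu, sigma=config.utr_len_sigma, size=n)).astype(int),
    )
    for w in config.spike_words:
        if len(w) > lengths.min():
            raise ValueError(f"spike word {w!r} longer than shortest UTR")
    width = len(str(n))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    responder_flags = np.zeros(n, dtype=bool)
    responder_flags[rng.choice(n, size=config.n_responders, replace=False)] = True

    carrier: dict[str, np.ndarray] = {}
    for w in config.spike_words:
        p = np.where(responder_flags, config.carrier_p_responder, config.carrier_p_background)
        carrier[w] = rng.random(n) < p

    records: dict[str, str] = {}
    for i, gid in enumerate(gene_ids):
        seq = list(_random_sequence(rng, int(lengths[i]), config.gc_content))
        occupied: list[tuple[int, int]] = []
        for w in config.spike_words:
            if not carrier[w][i]:
                continue
            # place without overlapping a previously spiked word
            for _ in range(100):
                pos = int(rng.integers(0, len(seq) - len(w) + 1))
                span = (pos, pos + len(w))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError(f"could not place word {w!r} in {gid}")
            seq[span[0] : span[1]] = list(w)
            occupied.append(span)
        records[gid] = "".join(seq)

    truth = pd.DataFrame({"gene_id": gene_ids, "is_responder": responder_flags})
    for w in config.spike_words:
        truth[f"carrier_{w}"] = carrier[w]
    return UTRUniverse(records=records), truth


def simulate_ranked_experiment(
    config: SynthConfig, truth: pd.DataFrame
) -> tuple[ExpressionMatrix, ProbeAnnotation, pd.DataFrame]:
    """Probe intensities realising a known differential-expression signal.

    Responders get a true log2FC of ``effect_size``, others 0; the observed
    log2FC adds Normal(0, ``noise_sd``) noise.  One probe per gene is
    built so that mean(log2 treated) - mean(log2 control) on
    log2(intensity + 1) recovers the observed log2FC exactly, plus
    negative-control probes drawn from a low null intensity distribution.
    Returns the matrix, the probe annotation, and the truth table extended
    with true_log2fc and observed_log2fc.
    """
    rng = config.rng("expression")
    genes = truth["gene_id"].tolist()
    n = len(genes)
    true_lfc = np.where(truth["is_responder"].to_numpy(), config.effect_size, 0.0)
    observed_lfc = true_lfc + rng.normal(0.0, config.noise_sd, size=n)
    baseline = rng.normal(config.signal_log2_mean, config.signal_log2_sd, size=n)

    treated_names = [f"treated_{j+1}" for j in range(config.n_treated)]
    control_names = [f"control_{j+1}" for j in range(config.n_control)]
    # identical replicates within condition: exact log2FC recovery by design
    control_int = np.power(2.0, baseline) - 1.0
    treated_int = np.power(2.0, baseline + observed_lfc) - 1.0
    values = pd.DataFrame(
        {**{s: treated_int for s in treated_names}, **{s: control_int for s in control_names}},
        index=[f"probe_{g}" for g in genes],
    )
    nc_ids = [f"NC_{j+1}" for j in range(config.n_negative_controls)]
    nc_log2 = rng.normal(config.nc_log2_mean, config.nc_log2_sd,
                         size=(config.n_negative_controls, len(values.columns)))
    nc_values = pd.DataFrame(np.power(2.0, nc_log2) - 1.0, index=nc_ids, columns=values.columns)
    matrix = ExpressionMatrix(
        values=pd.concat([values, nc_values]),
        conditions={**{s: "treated" for s in treated_names}, **{s: "control" for s in control_names}},
        negative_controls=set(nc_ids),
    )
    annotation = ProbeAnnotation(
        table=pd.DataFrame(
            {"probe_id": [f"probe_{g}" for g in genes], "gene_id": genes, "has_full_utr": True}
        )
    )
    out_truth = truth.copy()
    out_truth["true_log2fc"] = true_lfc
    out_truth["observed_log2fc"] = observed_lfc
    return matrix, annotation, out_truth


def simulate_methylation(config: SynthConfig) -> list[PyroAssay]:
    """Two-group pyrosequencing tables with group-specific per-site means.

    Replicate percent-methylation values are Normal(group mean, SD)
    truncated to [0, 100]; each group has ``meth_n_per_group`` samples of
    ``meth_sites`` sites with ``meth_replicates`` replicates.
    """
    rng = config.rng("methylation")
    sites = [("chr11", 100_000 + 50 * k) for k in range(config.meth_sites)]
    assays: list[PyroAssay] = []
    for group, mean in config.meth_mean_by_group.items():
        for s in range(config.meth_n_per_group):
            rows = []
            for chrom, pos in sites:
                vals = np.clip(
                    rng.normal(mean, config.meth_sd, size=config.meth_replicates), 0.0, 100.0
                )
                rows.extend(
                    (chrom, pos, r + 1, float(v)) for r, v in enumerate(vals)
                )
            assays.append(
                PyroAssay(
                    sample_id=f"{group}_{s+1}",
                    group=group,
                    data=pd.DataFrame(rows, columns=["chrom", "pos", "replicate", "pct_meth"]),
                )
            )
    return assays


def simulate_ct_table(
    config: SynthConfig,
    fold_changes: dict[str, float] | None = None,
    reference_assays: Sequence[str] = ("REF1", "REF2", "REF3"),
    target_assay: str = "TARGET",
) -> tuple[CtTable, dict[str, float]]:
    """Ct panel realising known relative quantities per sample.

    Ct = baseline - log2(relative quantity) + Normal(0, ``ct_sd``) per
    replicate; reference assays have relative quantity 1 in every sample
    and the sample named ``"reference"`` (fold change 1) is the calibrator.
    Returns the table and the true fold-change map.
    """
    rng = config.rng("ct")
    if fold_changes is None:
        fold_changes = {"reference": 1.0, "sample_A": 2.0, "sample_B": 0.25}
    if "reference" not in fold_changes:
        raise ValueError("fold_changes must include the 'reference' calibrator sample")
    rows = []
    for sample, fc in fold_changes.items():
        for assay in list(reference_assays) + [target_assay]:
            qty = fc if assay == target_assay else 1.0
            for rep in range(1, config.ct_replicates + 1):
                ct = config.ct_baseline - np.log2(qty) + rng.normal(0.0, config.ct_sd)
                rows.append((sample, assay, rep, float(ct)))
    table = CtTable(
        data=pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct"]),
        reference_assays=list(reference_assays),
        reference_sample="reference",
    )
    return table, dict(fold_changes)
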