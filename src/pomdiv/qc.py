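"""Genotype-panel quality control and per-locus diversity statistics.

Cleaning rules follow the genotyping-panel workflow: samples with more
than 10% no-calls are dropped first, then assays (loci) with more than
30% no-calls among the surviving samples; afterwards uninformative loci
(minor allele frequency below 0.05, or heterozygous in every called
sample) are removed before diversity analysis.

Per-locus statistics: allele frequency over called alleles, MAF, observed
and expected (Hardy–Weinberg, 2pq) heterozygosity, and the polymorphism
information content

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

which for a biallelic locus reduces to 1 - (p^2 + q^2) - 2 p^2 q^2 with a
maximum of 0.375 at p = q = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class QCLog:
    """Record of removals performed by the panel filters."""

    removed_samples: dict[str, str] = field(default_factory=dict)
    removed_loci: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", k, v) for k, v in self.removed_samples.items()]
        rows += [("locus", k, v) for k, v in self.removed_loci.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


class EmptyPanelError(ValueError):
    """Raised when filtering removes every sample or locus; carries the log."""

    def __init__(self, message: str, log: QCLog):
        super().__init__(message)
        self.log = log


def filter_nocall(
    panel: GenotypePanel,
    max_sample_nocall: float = 0.10,
    max_assay_nocall: float = 0.30,
) -> tuple[GenotypePanel, QCLog]:
    """Drop bad samples, then failed assays, by no-call fraction.

    Samples with a no-call fraction strictly greater than
    `max_sample_nocall` are removed first; assays are then re-evaluated on
    the surviving samples and removed when their no-call fraction strictly
    exceeds `max_assay_nocall`.  Returns the filtered panel and a removal
    log; raises :class:`EmptyPanelError` (log attached) if nothing survives.
    """
    if not 0.0 <= max_sample_nocall <= 1.0 or not 0.0 <= max_assay_nocall <= 1.0:
        raise ValueError("no-call thresholds must lie in [0, 1]")
    log = QCLog()
    nn = panel.calls < 0
    sample_frac = nn.mean(axis=1)
    keep_s = sample_frac <= max_sample_nocall
    for i in np.flatnonzero(~keep_s):
        log.removed_samples[panel.sample_ids[i]] = (
            f"no-call fraction {sample_frac[i]:.3f} > {max_sample_nocall}"
        )
    if not keep_s.any():
        raise EmptyPanelError("all samples removed by the no-call filter", log)

    nn_surv = nn[keep_s]
    locus_frac = nn_surv.mean(axis=0)
    keep_l = locus_frac <= max_assay_nocall
    for j in np.flatnonzero(~keep_l):
        log.removed_loci[panel.locus_ids[j]] = (
            f"no-call fraction {locus_frac[j]:.3f} > {max_assay_nocall}"
        )
    if not keep_l.any():
        raise EmptyPanelError("all loci removed by the no-call filter", log)

    out = panel.subset(
        samples=list(np.flatnonzero(keep_s)), loci=list(np.flatnonzero(keep_l))
    )
    return out, log


def pic(freqs) -> float:
    """Polymorphism information content from a vector of allele frequencies."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    sq = p**2
    cross = np.outer(sq, sq)
    return float(1.0 - sq.sum() - 2.0 * (np.triu(cross, k=1).sum()))


def pic_biallelic(p) -> float | np.ndarray:
    """PIC of a biallelic locus with allele frequency p: 1-(p²+q²)-2p²q²."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def locus_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-locus allele frequency, MAF, PIC and heterozygosities.

    Frequencies are computed over called alleles only (no-calls excluded
    from numerator and denominator).  Loci with no calls at all are
    flagged `undefined` with NaN statistics.

    Returns a DataFrame indexed by locus id with columns
    p (frequency of the A allele), maf, pic, h_obs, h_exp, n_called,
    undefined.
    """
    G = panel.calls
    called = G >= 0
    n_called = called.sum(axis=0)
    b_count = np.where(called, G, 0).sum(axis=0)  # B-allele copies
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = b_count / (2.0 * n_called)
    p_a = 1.0 - p_b
    maf = np.minimum(p_a, p_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = np.where(called, G == 1, False).sum(axis=0) / n_called
    h_exp = 2.0 * p_a * p_b
    pic_v = pic_biallelic(p_a)
    undefined = n_called == 0
    for arr in (p_a, maf, h_obs, h_exp, pic_v):
        arr[undefined] = np.nan
    return pd.DataFrame(
        {
            "p": p_a,
            "maf": maf,
            "pic": pic_v,
            "h_obs": h_obs,
            "h_exp": h_exp,
            "n_called": n_called,
            "undefined": undefined,
        },
        index=pd.Index(panel.locus_ids, name="locus"),
    )


def filter_informative(
    panel: GenotypePanel, maf_min: float = 0.05
) -> tuple[GenotypePanel, QCLog]:
    """Remove uninformative loci: MAF below `maf_min`, all-heterozygous
    loci (every called genotype AB), and loci with no calls at all.

    Returns the filtered panel and a removal log with per-rule reasons.
    Idempotent: a second application removes nothing further.
    """
    stats = locus_stats(panel)
    log = QCLog()
    keep = np.ones(panel.n_loci, dtype=bool)
    all_het = (stats["h_obs"].to_numpy() == 1.0) & ~stats["undefined"].to_numpy()
    low_maf = (stats["maf"].to_numpy() < maf_min) & ~all_het
    none_called = stats["undefined"].to_numpy()
    for j in np.flatnonzero(all_het):
        log.removed_loci[panel.locus_ids[j]] = "heterozygous in every called sample"
        keep[j] = False
    for j in np.flatnonzero(low_maf & ~none_called):
        log.removed_loci[panel.locus_ids[j]] = (
            f"maf {stats['maf'].iloc[j]:.4f} < {maf_min}"
        )
        keep[j] = False
    for j in np.flatnonzero(none_called):
        log.removed_loci[panel.locus_ids[j]] = "no called genotypes"
        keep[j] = False
    if not keep.any():
        raise EmptyPanelError("no informative loci left", log)
    return panel.subset(loci=list(np.flatnonzero(keep))), log
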