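"""Wright's fixation indices for labeled subgroups of a genotype panel.

Within-group fixation (heterozygote deficit) per locus:

    F_S = 1 − H_obs / H_exp,

with H_obs the observed heterozygote fraction among the group's called
samples and H_exp = 2 p (1 − p) from the group's allele frequency.
Positive values indicate fewer heterozygotes than the Hardy–Weinberg
expectation.

Differentiation among groups per locus:

    F_ST = (H_T − H_S) / H_T,

with H_S the weighted average of the groups' expected heterozygosities
(weights proportional to called-sample counts) and H_T = 2 p̄ (1 − p̄)
from the pooled frequency.  H_S ≤ H_T by concavity, so F_ST ≥ 0.

Medians are taken over the loci where the statistic is defined
(H_exp > 0 within the group for F_S; H_T > 0 for F_ST).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel


def _group_freqs(panel: GenotypePanel, samples: Sequence[str]) -> pd.DataFrame:
    sub = panel.subset(samples=list(samples))
    G = sub.calls
    called = G >= 0
    n_called = called.sum(axis=0)
    b = np.where(called, G, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = b / (2.0 * n_called)
        h_obs = np.where(called, G == 1, False).sum(axis=0) / n_called
    return pd.DataFrame(
        {"p": p, "h_obs": h_obs, "n_called": n_called},
        index=pd.Index(panel.locus_ids, name="locus"),
    )


def fixation_index_fs(
    panel: GenotypePanel, samples: Sequence[str], min_called: int = 2
) -> tuple[pd.DataFrame, float]:
    """Per-locus F_S = 1 − H_obs/H_exp for one group, and its median.

    A locus contributes when the group has at least `min_called` called
    samples there and is polymorphic within the group (H_exp > 0);
    monomorphic loci are excluded from the median.  Raises for groups of
    fewer than 2 samples.
    """
    if len(samples) < 2:
        raise ValueError("a group needs at least 2 samples for heterozygosity")
    stats = _group_freqs(panel, samples)
    h_exp = 2.0 * stats["p"] * (1.0 - stats["p"])
    usable = (stats["n_called"] >= min_called) & (h_exp > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fs = 1.0 - stats["h_obs"] / h_exp
    fs[~usable] = np.nan
    out = pd.DataFrame(
        {
            "p": stats["p"],
            "h_obs": stats["h_obs"],
            "h_exp": h_exp,
            "n_called": stats["n_called"],
            "f_s": fs,
        }
    )
    median = float(np.nanmedian(fs)) if usable.any() else float("nan")
    return out, median


def fixation_index_fst(
    panel: GenotypePanel,
    groups: Mapping[str, Sequence[str]],
    deviation_bound: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-locus F_ST = (H_T − H_S)/H_T over labeled groups, with summary.

    H_S weights each group's expected heterozygosity by its called-sample
    count at the locus; H_T uses the frequency pooled over all grouped
    samples.  Loci with H_T = 0 (monomorphic overall) are excluded.  The
    summary reports the median F_ST and the fraction of contributing loci
    with F_ST below `deviation_bound`.
    """
    labels = [g for g, s in groups.items() if len(s) > 0]
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups for F_ST")
    per_group = {g: _group_freqs(panel, groups[g]) for g in labels}

    n_mat = np.stack([per_group[g]["n_called"].to_numpy() for g in labels])
    p_mat = np.stack([per_group[g]["p"].to_numpy() for g in labels])
    p_mat = np.where(n_mat > 0, p_mat, 0.0)
    n_tot = n_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n_mat * p_mat).sum(axis=0) / n_tot
        h_s = (n_mat * 2.0 * p_mat * (1.0 - p_mat)).sum(axis=0) / n_tot
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (h_t - h_s) / h_t
    usable = (h_t > 0) & (n_tot > 0)
    fst[~usable] = np.nan

    table = pd.DataFrame(
        {"p_pooled": p_bar, "h_s": h_s, "h_t": h_t, "f_st": fst},
        index=pd.Index(panel.locus_ids, name="locus"),
    )
    contributing = fst[usable]
    summary = {
        "n_loci": int(usable.sum()),
        "median_fst": float(np.median(contributing)) if usable.any() else float("nan"),
        "frac_below_bound": (
            float((contributing < deviation_bound).mean()) if usable.any() else float("nan")
        ),
        "deviation_bound": deviation_bound,
    }
    return table, summary


def groups_from_labels(labels: Mapping[str, str]) -> dict[str, list[str]]:
    """Invert a sample -> group-label mapping into group -> samples."""
    out: dict[str, list[str]] = {}
    for sample, label in labels.items():
        out.setdefault(label, []).append(sample)
    return out
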