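"""Allele-sharing genetic distance between diploid individuals.

For two diploid genotypes at one locus, PS is the proportion of shared
alleles counting multiplicity (Bowcock convention): the size of the
multiset intersection of the two allele pairs divided by 2, so
PS ∈ {0, 1/2, 1}.  PSA averages PS over the loci where both samples are
called, and the genetic distance is D = 1 − PSA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class DistanceMatrix:
    """Symmetric 1−PSA dissimilarity with zero diagonal, entries in [0, 1]."""

    sample_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.D.min() < -1e-12 or self.D.max() > 1 + 1e-12:
            raise ValueError("1-PSA distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.sample_ids, columns=self.sample_ids)


def shared_alleles(g1: int, g2: int) -> int:
    """Multiset-shared allele count between two diploid genotype codes."""
    if g1 < 0 or g2 < 0:
        raise ValueError("shared alleles undefined for no-calls")
    return 2 - abs(g1 - g2) if g1 != g2 else 2


def psa_distance(panel: GenotypePanel) -> DistanceMatrix:
    """Pairwise 1−PSA distance matrix over a genotype panel.

    PS per locus is computed from the B-allele dosage codes: genotypes
    sharing both alleles give PS = 1, one allele 1/2, none 0.  The average
    runs over pairwise-complete loci (both samples called), so each pair
    has its own effective locus count.  A pair with no co-called loci is
    an error — its distance is undefined.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    G = panel.calls.astype(np.int16)
    called = G >= 0
    n = panel.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        n_loci = both.sum(axis=1)
        if (n_loci == 0).any():
            j = int(np.flatnonzero(n_loci == 0)[0]) + i + 1
            raise ValueError(
                f"samples {panel.sample_ids[i]!r} and {panel.sample_ids[j]!r} "
                "share no co-called loci; distance undefined"
            )
        diff = np.abs(G[i] - G[i + 1 :])
        shared = np.where(diff == 0, 2, 2 - diff)  # AB vs AB shares both
        ps = np.where(both, shared, 0).sum(axis=1) / (2.0 * n_loci)
        D[i, i + 1 :] = 1.0 - ps
    D = D + D.T
    return DistanceMatrix(list(panel.sample_ids), D)
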