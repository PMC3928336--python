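"""Diploid biallelic genotype panel: the central container of the pipeline.

Genotypes are abstract biallelic calls — ``AA`` (homozygous reference-like
allele), ``AB`` (heterozygous), ``BB`` (homozygous alternate-like allele) and
``NN`` (no call).  Internally calls are stored as the count of the B allele
(0, 1, 2) with ``-1`` for no-calls, in an ``int8`` samples x loci matrix.
Nucleotide identity, when known, is carried separately per locus and never
affects panel arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: string call -> internal code (count of B alleles; -1 = no call)
CALL_TO_CODE = {"AA": 0, "AB": 1, "BB": 2, "NN": -1}
CODE_TO_CALL = {v: k for k, v in CALL_TO_CODE.items()}

NOCALL = -1


@dataclass
class GenotypePanel:
    """Samples x biallelic loci matrix of diploid calls with no-call support.

    Parameters
    ----------
    sample_ids
        Unique sample (accession) identifiers, one per row of `calls`.
    locus_ids
        Unique locus identifiers, one per column of `calls`.
    calls
        ``int8`` matrix with entries in {-1, 0, 1, 2} (NN, AA, AB, BB).
    locus_alleles
        Optional per-locus (ref, alt) nucleotide labels for loci whose
        sequence context is known; ``None`` for purely abstract panels.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    locus_alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x loci matrix")
        n, m = self.calls.shape
        if n != len(self.sample_ids) or m != len(self.locus_ids):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be coded -1 (NN), 0 (AA), 1 (AB) or 2 (BB)")
        if self.locus_alleles is not None:
            self.locus_alleles = [tuple(a) for a in self.locus_alleles]
            if len(self.locus_alleles) != m:
                raise ValueError("locus_alleles length must equal number of loci")
            for ref, alt in self.locus_alleles:
                if ref == alt:
                    raise ValueError(f"locus alleles must differ, got ({ref}, {alt})")

    # ------------------------------------------------------------------ basics
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def called_mask(self) -> np.ndarray:
        """Boolean matrix, True where a genotype call is present."""
        return self.calls >= 0

    def call_strings(self) -> np.ndarray:
        """Calls as an array of {AA, AB, BB, NN} strings."""
        lut = np.array([CODE_TO_CALL[-1], "AA", "AB", "BB"], dtype="U2")
        return lut[self.calls + 1]

    # -------------------------------------------------------------- construction
    @classmethod
    def from_strings(
        cls,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: Sequence[Sequence[str]],
        locus_alleles: list[tuple[str, str]] | None = None,
    ) -> "GenotypePanel":
        codes = np.empty((len(sample_ids), len(locus_ids)), dtype=np.int8)
        for i, row in enumerate(calls):
            if len(row) != len(locus_ids):
                raise ValueError(f"row {i} has {len(row)} calls, expected {len(locus_ids)}")
            for j, call in enumerate(row):
                try:
                    codes[i, j] = CALL_TO_CODE[call]
                except KeyError:
                    raise ValueError(
                        f"invalid call {call!r} at sample {sample_ids[i]!r}, "
                        f"locus {locus_ids[j]!r}; expected one of AA/AB/BB/NN"
                    ) from None
        return cls(list(sample_ids), list(locus_ids), codes, locus_alleles)

    # ------------------------------------------------------------------ slicing
    def subset(
        self,
        samples: Sequence[str] | Sequence[int] | None = None,
        loci: Sequence[str] | Sequence[int] | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given samples and/or loci.

        Accepts ids or positional indices; order of the arguments is preserved
        in the result.
        """
        si = self._resolve(samples, self.sample_ids) if samples is not None else np.arange(self.n_samples)
        li = self._resolve(loci, self.locus_ids) if loci is not None else np.arange(self.n_loci)
        alleles = None
        if self.locus_alleles is not None:
            alleles = [self.locus_alleles[j] for j in li]
        return GenotypePanel(
            [self.sample_ids[i] for i in si],
            [self.locus_ids[j] for j in li],
            self.calls[np.ix_(si, li)].copy(),
            alleles,
        )

    @staticmethod
    def _resolve(keys: Sequence, ids: list[str]) -> np.ndarray:
        keys = list(keys)
        if all(isinstance(k, (int, np.integer)) for k in keys):
            return np.asarray(keys, dtype=int)
        index = {s: i for i, s in enumerate(ids)}
        try:
            return np.asarray([index[k] for k in keys], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown id {e.args[0]!r}") from None

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
            and self.locus_alleles == other.locus_alleles
        )
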