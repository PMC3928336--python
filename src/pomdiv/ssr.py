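"""Perfect microsatellite (SSR) scanning and motif bookkeeping.

Finds all maximal perfect tandem repeats of primitive 1–6 nt units meeting
per-unit-length copy-number thresholds (MISA-convention defaults), reports
motifs in canonical form — the lexicographically minimal rotation over the
observed unit and its reverse complement — and resolves nested/overlapping
calls to the longest repeat, ties to the smaller unit.

Coordinates are 0-based half-open internally; TSV reports are 1-based and
say so in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

#: MISA-convention minimum copy numbers per unit length (mono..hexa)
MISA_DEFAULT_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(unit: str) -> bool:
    """True if `unit` is not itself a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def canonical_motif(unit: str) -> tuple[str, str]:
    """Canonical form of a repeat unit and its strand class.

    The canonical motif is the lexicographically minimal rotation over the
    unit and its reverse complement.  Strand class is ``"+"`` when the
    observed unit's own rotations attain the canonical form (including the
    self-reverse-complementary case), ``"-"`` when only the reverse
    complement does.
    """
    fwd = min(_rotations(unit))
    rev = min(_rotations(reverse_complement(unit)))
    if fwd <= rev:
        return fwd, "+"
    return rev, "-"


@dataclass(frozen=True, order=True)
class SSRLocus:
    """One detected perfect microsatellite.

    ``start`` is the 0-based offset of the first repeat base;
    ``motif`` is canonical (see :func:`canonical_motif`); ``strand_class``
    records which of the reverse-complement pair the observed unit belongs
    to; ``unit_length`` is the length of the repeat unit, so the repeat
    spans ``copies * unit_length`` bases.
    """

    contig_id: str
    start: int
    motif: str
    strand_class: str
    copies: int
    unit_length: int

    @property
    def length(self) -> int:
        return self.copies * self.unit_length

    @property
    def end(self) -> int:
        return self.start + self.length

    def key(self) -> tuple[str, str, int]:
        """(contig, canonical motif, start) — the list-crossing identity."""
        return (self.contig_id, self.motif, self.start)


def _maximal_runs(seq: str, unit_len: int) -> list[tuple[int, int]]:
    """Maximal (start, total_length) stretches with period `unit_len`.

    A stretch is a maximal run of positions j with seq[j] == seq[j + unit_len]
    over A/C/G/T only (N never matches), extended by one unit.
    """
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = a.size
    if n <= unit_len:
        return []
    valid = (a == ord("A")) | (a == ord("C")) | (a == ord("G")) | (a == ord("T"))
    match = (a[:-unit_len] == a[unit_len:]) & valid[:-unit_len] & valid[unit_len:]
    if not match.any():
        return []
    m = match.astype(np.int8)
    boundaries = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(boundaries == 1)
    ends = np.flatnonzero(boundaries == -1)  # exclusive, in match coordinates
    return [(int(s), int(e - s + unit_len)) for s, e in zip(starts, ends)]


def scan_sequence(
    contig_id: str, seq: str, min_copies: dict[int, int] | None = None
) -> list[SSRLocus]:
    """Scan one sequence for perfect SSRs.  See :func:`scan_ssrs`."""
    thresholds = MISA_DEFAULT_MIN_COPIES if min_copies is None else min_copies
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"contig {contig_id!r} contains non-ACGTN characters: {bad}")

    candidates: list[tuple[int, int, int, str]] = []  # (start, length, unit_len, unit)
    for unit_len in sorted(thresholds):
        if not 1 <= unit_len <= 6:
            raise ValueError("repeat unit lengths must be 1..6")
        for start, total in _maximal_runs(seq, unit_len):
            copies = total // unit_len
            if copies < thresholds[unit_len]:
                continue
            unit = seq[start : start + unit_len]
            if not is_primitive(unit):
                continue  # covered by the shorter period
            candidates.append((start, copies * unit_len, unit_len, unit))

    # longest repeat wins overlaps; ties go to the smaller unit, then leftmost
    candidates.sort(key=lambda c: (-c[1], c[2], c[0]))
    kept: list[tuple[int, int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        s, length = cand[0], cand[1]
        e = s + length
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        kept.append(cand)
        occupied.append((s, e))

    loci = []
    for start, length, unit_len, unit in kept:
        motif, strand = canonical_motif(unit)
        loci.append(
            SSRLocus(contig_id, start, motif, strand, length // unit_len, unit_len)
        )
    loci.sort(key=lambda l: l.start)
    return loci


def scan_ssrs(
    contigs: dict[str, str], min_copies: dict[int, int] | None = None
) -> list[SSRLocus]:
    """Find all maximal perfect SSRs in a contig set.

    Parameters
    ----------
    contigs
        Mapping contig id -> sequence (A/C/G/T/N; case-insensitive).
    min_copies
        Minimum copy number per unit length 1..6; defaults to the MISA
        convention (mono 10, di 6, tri–hexa 5).

    Returns loci ordered by contig id then start.
    """
    loci: list[SSRLocus] = []
    for contig_id in sorted(contigs):
        loci.extend(scan_sequence(contig_id, contigs[contig_id], min_copies))
    return loci


def intersect_ssrs(list_a: list[SSRLocus], list_b: list[SSRLocus]) -> list[SSRLocus]:
    """Cross two SSR lists on the (contig, canonical motif, start) key.

    Emulates dual-scanner confirmation: a locus is retained iff its key
    appears in both lists.  Output is taken from `list_a` and ordered by
    contig then start.
    """
    keys_b = {l.key() for l in list_b}
    out = [l for l in list_a if l.key() in keys_b]
    out.sort(key=lambda l: (l.contig_id, l.start))
    return out


def motif_spectrum(ssrs: list[SSRLocus]) -> pd.DataFrame:
    """Count SSRs by (unit length, canonical motif, strand class).

    Returns a DataFrame with columns unit_length, motif, strand_class,
    count, percent (exact, of the total) and percent_int (half-up rounded
    integer percent for report parity).  Empty input gives an empty table.
    """
    counts = Counter((l.unit_length, l.motif, l.strand_class) for l in ssrs)
    total = sum(counts.values())
    rows = [
        (ul, motif, strand, c, 100.0 * c / total, int(100.0 * c / total + 0.5))
        for (ul, motif, strand), c in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["unit_length", "motif", "strand_class", "count", "percent", "percent_int"],
    )


def unit_length_spectrum(ssrs: list[SSRLocus]) -> pd.DataFrame:
    """Aggregate :func:`motif_spectrum` by unit length (mono..hexa)."""
    counts = Counter(l.unit_length for l in ssrs)
    total = sum(counts.values())
    rows = [
        (ul, c, 100.0 * c / total, int(100.0 * c / total + 0.5))
        for ul, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["unit_length", "count", "percent", "percent_int"])


def ssrs_to_frame(ssrs: list[SSRLocus]) -> pd.DataFrame:
    """SSR list as a report table (1-based start column, stated in the name)."""
    return pd.DataFrame(
        [
            (l.contig_id, l.start + 1, l.motif, l.strand_class, l.copies, l.length)
            for l in ssrs
        ],
        columns=["contig", "start_1based", "motif", "strand", "copies", "length"],
    )
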