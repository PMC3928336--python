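"""Coverage-based SNP calling from quality-filtered pileup tables.

An allele-coverage table records, per contig position and accession, the
number of high-quality base calls supporting each nucleotide.  A position
is a within-accession SNP when at least two distinct alleles each reach
the coverage cutoff (default 3x); a between-accession SNP when each of
two accessions is homozygous (exactly one allele at or above the cutoff)
for a different allele.

Substitutions are classified as transitions (A<->G, C<->T) or
transversions; the t/v ratio of a call set is the count ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

COVERAGE_COLUMNS = ["contig", "pos", "accession", "A", "C", "G", "T"]


@dataclass(frozen=True)
class SNPCall:
    """One called SNP position.

    `alleles` are ordered by descending coverage (within-accession) or as
    (accession_a allele, accession_b allele) for between-accession calls;
    `coverages` aligns with `alleles`.  Positions with more than two
    qualifying alleles are flagged `multiallelic`, not dropped.
    """

    contig_id: str
    position: int
    scope: str  # "within" or "between"
    accession: str | tuple[str, str]
    alleles: tuple[str, ...]
    coverages: tuple[int, ...]
    multiallelic: bool = False

    @property
    def substitution_class(self) -> str:
        return classify_substitution(self.alleles[:2])


def classify_substitution(allele_pair) -> str:
    """'transition' for A<->G / C<->T, 'transversion' otherwise."""
    a, b = allele_pair
    if a == b:
        raise ValueError("substitution requires two distinct alleles")
    for n in (a, b):
        if n not in NUCLEOTIDES:
            raise ValueError(f"not a nucleotide: {n!r}")
    both_purine = a in _PURINES and b in _PURINES
    both_pyrimidine = a in _PYRIMIDINES and b in _PYRIMIDINES
    return "transition" if (both_purine or both_pyrimidine) else "transversion"


def tv_ratio(calls: list[SNPCall]) -> float:
    """Transition/transversion count ratio; inf when no transversions."""
    ts = sum(c.substitution_class == "transition" for c in calls)
    tv = len(calls) - ts
    if tv == 0:
        return math.inf
    return ts / tv


def _validate_coverage(coverage: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVERAGE_COLUMNS if c not in coverage.columns]
    if missing:
        raise ValueError(f"coverage table lacks columns {missing}")
    if (coverage[list(NUCLEOTIDES)] < 0).any().any():
        raise ValueError("coverage counts must be non-negative")
    return coverage


def call_snps_within(
    coverage: pd.DataFrame, accession: str, min_allele_cov: int = 3
) -> list[SNPCall]:
    """Within-accession (heterozygous-site) SNP calls.

    A position qualifies when >= 2 distinct alleles each have coverage of
    at least `min_allele_cov`.  The two best-covered alleles are reported
    (ties broken alphabetically); positions with more than two qualifying
    alleles carry the multiallelic flag.
    """
    _validate_coverage(coverage)
    sub = coverage[coverage["accession"] == accession]
    calls = []
    for row in sub.itertuples(index=False):
        counts = {n: int(getattr(row, n)) for n in NUCLEOTIDES}
        qualified = sorted(
            (n for n, c in counts.items() if c >= min_allele_cov),
            key=lambda n: (-counts[n], n),
        )
        if len(qualified) < 2:
            continue
        top = tuple(qualified[:2])
        calls.append(
            SNPCall(
                contig_id=row.contig,
                position=int(row.pos),
                scope="within",
                accession=accession,
                alleles=top,
                coverages=tuple(counts[n] for n in top),
                multiallelic=len(qualified) > 2,
            )
        )
    return calls


def call_snps_between(
    coverage: pd.DataFrame,
    accession_a: str,
    accession_b: str,
    min_allele_cov: int = 3,
    max_minor_cov: int | None = None,
) -> list[SNPCall]:
    """Between-accession SNP calls: opposite homozygotes at one position.

    Each accession must have exactly one allele with coverage at or above
    `min_allele_cov`, and the two alleles must differ.  With
    `max_minor_cov` set (e.g. 0 for zero tolerance), any other allele
    covered above that bound disqualifies the position.
    """
    _validate_coverage(coverage)
    frames = {}
    for acc in (accession_a, accession_b):
        sub = coverage[coverage["accession"] == acc]
        if sub.empty:
            raise ValueError(f"accession {acc!r} absent from the coverage table")
        frames[acc] = sub.set_index(["contig", "pos"])

    def homozygous_allele(row) -> str | None:
        counts = {n: int(row[n]) for n in NUCLEOTIDES}
        qualified = [n for n, c in counts.items() if c >= min_allele_cov]
        if len(qualified) != 1:
            return None
        if max_minor_cov is not None:
            minor = max(c for n, c in counts.items() if n != qualified[0])
            if minor > max_minor_cov:
                return None
        return qualified[0]

    common = frames[accession_a].index.intersection(frames[accession_b].index)
    calls = []
    for contig, pos in common:
        row_a = frames[accession_a].loc[(contig, pos)]
        row_b = frames[accession_b].loc[(contig, pos)]
        allele_a = homozygous_allele(row_a)
        allele_b = homozygous_allele(row_b)
        if allele_a is None or allele_b is None or allele_a == allele_b:
            continue
        calls.append(
            SNPCall(
                contig_id=contig,
                position=int(pos),
                scope="between",
                accession=(accession_a, accession_b),
                alleles=(allele_a, allele_b),
                coverages=(int(row_a[allele_a]), int(row_b[allele_b])),
            )
        )
    return calls


def cover_index(hsp_length: float, query_length: float, hit_length: float) -> float:
    """Mutual-coverage index CI = 2*HSP/(QL+HL), capped at 1.

    HSP is the aligned-segment length; QL and HL the query and hit
    lengths.  Gapped alignments can exceed either sequence length, hence
    the cap.  All lengths must be positive.
    """
    if hsp_length <= 0 or query_length <= 0 or hit_length <= 0:
        raise ValueError("all lengths must be positive")
    return min(1.0, 2.0 * hsp_length / (query_length + hit_length))


def snp_calls_to_frame(calls: list[SNPCall]) -> pd.DataFrame:
    """Call list as a report table (1-based positions, stated in the name)."""
    rows = []
    for c in calls:
        acc = c.accession if isinstance(c.accession, str) else "|".join(c.accession)
        rows.append(
            (
                c.contig_id,
                c.position + 1,
                c.scope,
                acc,
                "/".join(c.alleles),
                "/".join(str(x) for x in c.coverages),
                c.substitution_class,
                c.multiallelic,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos_1based",
            "scope",
            "accession",
            "alleles",
            "coverages",
            "substitution",
            "multiallelic",
        ],
    )
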