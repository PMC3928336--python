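"""Shared fixtures and independent oracle implementations.

The oracles deliberately take different algorithmic routes from the
library code they check: the SSR oracle is regex-based, the Ward oracle
recomputes the variance objective from cluster members at every step, and
the PSA oracle counts shared alleles with explicit multisets.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter

import numpy as np
import pytest

from pomdiv.panel import GenotypePanel
from pomdiv.ssr import MISA_DEFAULT_MIN_COPIES, canonical_motif, is_primitive

# --------------------------------------------------------------- SSR oracle


def regex_ssr_oracle(contig_id: str, seq: str, min_copies=None):
    """All maximal perfect SSRs via regex backreferences.

    For each unit length a greedy backreference pattern finds maximal
    repeat runs; primitivity, thresholds and the longest-wins overlap
    resolution are applied exactly as specified, but through independent
    code.  Returns (contig, start, canonical motif, strand, copies,
    unit_len) tuples.
    """
    thresholds = MISA_DEFAULT_MIN_COPIES if min_copies is None else min_copies
    seq = seq.upper()
    candidates = []
    for u in range(1, 7):
        if thresholds.get(u) is None:
            continue
        pattern = re.compile(r"(?=(([ACGT]{%d})\2+))" % u)
        for m in pattern.finditer(seq):
            run, unit = m.group(1), m.group(2)
            if not is_primitive(unit):
                continue
            copies = len(run) // u
            if copies < thresholds[u]:
                continue
            candidates.append((m.start(), copies * u, u, unit))
    # de-duplicate shifted reports of one run: keep the leftmost start for
    # identical (end, unit length)
    best = {}
    for start, length, u, unit in candidates:
        key = (start + length, u)
        if key not in best or start < best[key][0]:
            best[key] = (start, length, u, unit)
    candidates = sorted(best.values(), key=lambda c: (-c[1], c[2], c[0]))
    kept, occupied = [], []
    for cand in candidates:
        s, length = cand[0], cand[1]
        if any(s < oe and os_ < s + length for os_, oe in occupied):
            continue
        kept.append(cand)
        occupied.append((s, s + length))
    out = []
    for start, length, u, unit in kept:
        motif, strand = canonical_motif(unit)
        out.append((contig_id, start, motif, strand, length // u, u))
    return sorted(out, key=lambda t: t[1])


# -------------------------------------------------------------- Ward oracle


def exhaustive_ward(D: np.ndarray):
    """Ward clustering by recomputing the variance objective each step.

    The merge cost of clusters A, B is ΔESS = nA·nB/(nA+nB)·‖cA−cB‖²,
    with the centroid gap recovered from pairwise squared distances:
    ‖cA−cB‖² = mean cross d² − σA² − σB², σX² = Σ_{x<x'} d²/nX².
    Heights are sqrt(2·ΔESS) (the original-distance scale); ties break on
    the smallest pair of cluster ids.  Returns (merges, heights).
    """
    n = D.shape[0]
    D2 = D.astype(float) ** 2
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges, heights = [], []

    def sigma2(members):
        if len(members) == 1:
            return 0.0
        s = sum(D2[a, b] for a, b in itertools.combinations(members, 2))
        return s / len(members) ** 2

    while len(clusters) > 1:
        best = None
        for ca, cb in itertools.combinations(sorted(clusters), 2):
            A, B = clusters[ca], clusters[cb]
            cross = np.mean([D2[a, b] for a in A for b in B])
            gap2 = cross - sigma2(A) - sigma2(B)
            cost = len(A) * len(B) / (len(A) + len(B)) * gap2
            key = (cost, ca, cb)
            if best is None or key < best:
                best = key
        cost, ca, cb = best
        merges.append((ca, cb))
        heights.append(np.sqrt(max(2.0 * cost, 0.0)))
        clusters[next_id] = clusters.pop(ca) + clusters.pop(cb)
        next_id += 1
    return np.array(merges), np.array(heights)


# --------------------------------------------------------------- PSA oracle


_CODE_TO_PAIR = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}


def multiset_psa_oracle(panel: GenotypePanel) -> np.ndarray:
    """1−PSA distances by explicit multiset intersection of allele pairs."""
    n = panel.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ps_vals = []
            for l in range(panel.n_loci):
                gi, gj = panel.calls[i, l], panel.calls[j, l]
                if gi < 0 or gj < 0:
                    continue
                a = Counter(_CODE_TO_PAIR[gi])
                b = Counter(_CODE_TO_PAIR[gj])
                shared = sum((a & b).values())
                ps_vals.append(shared / 2.0)
            D[i, j] = D[j, i] = 1.0 - float(np.mean(ps_vals))
    return D


# ------------------------------------------------------------------ fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel():
    """4 samples x 3 loci with one no-call, hand-checkable."""
    return GenotypePanel.from_strings(
        ["s1", "s2", "s3", "s4"],
        ["l1", "l2", "l3"],
        [
            ["AA", "AB", "BB"],
            ["AA", "AA", "BB"],
            ["AB", "NN", "AA"],
            ["BB", "AB", "AA"],
        ],
    )


def random_panel(rng, n=12, L=20, nocall=0.1) -> GenotypePanel:
    calls = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    calls[rng.random((n, L)) < nocall] = -1
    return GenotypePanel(
        [f"s{i}" for i in range(n)], [f"l{j}" for j in range(L)], calls
    )
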