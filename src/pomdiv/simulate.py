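"""Synthetic data generation for the diversity pipeline.

Three generators produce every input the analysis consumes:

* :func:`generate_panel` — diploid genotype panels drawn from the
  Balding–Nichols model with ``K`` latent ancestral populations, optional
  Dirichlet admixture and independent no-call dropout.  This is the
  generative model underlying the admixture (STRUCTURE-style) analysis, so
  parameter-recovery tests against it are well posed.
* :func:`generate_contigs` — contig sequences with planted perfect
  microsatellites (SSRs) on a repeat-free random background.
* :func:`generate_coverage` — per-position, per-accession allele-coverage
  tables with Poisson depth and uniform substitution sequencing error,
  emulating quality-filtered pileups over known genotypes.

All generators are pure functions of their arguments including ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .ssr import MISA_DEFAULT_MIN_COPIES, SSRLocus, canonical_motif, is_primitive, scan_sequence

NUCLEOTIDES = np.array(["A", "C", "G", "T"])


@dataclass
class PanelTruth:
    """Latent structure behind a simulated genotype panel.

    Attributes
    ----------
    n_pops
        Number of ancestral populations (the K of the admixture model).
    ancestral_freqs
        Per-locus B-allele frequency in the common ancestor, each in (0, 1).
    pop_freqs
        (n_pops, n_loci) derived per-population frequencies.
    q_true
        (n_samples, n_pops) admixture proportions; rows sum to 1.
    differentiation
        Balding–Nichols drift parameter F in [0, 1).
    pop_of_origin
        For unadmixed panels, the index of each sample's source population;
        None when admixture proportions were drawn from a Dirichlet.
    """

    n_pops: int
    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray
    q_true: np.ndarray
    differentiation: float
    pop_of_origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.differentiation < 1.0:
            raise ValueError("differentiation F must lie in [0, 1)")
        if np.any(self.pop_freqs < 0) or np.any(self.pop_freqs > 1):
            raise ValueError("pop_freqs must lie in [0, 1]")
        if not np.allclose(self.q_true.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("q_true rows must sum to 1")


def generate_panel(
    n_pops: int,
    n_per_pop: int,
    n_loci: int,
    differentiation: float = 0.15,
    admixture_alpha: float | None = None,
    nocall_rate: float = 0.0,
    seed: int = 0,
    ancestral_maf_floor: float = 0.1,
) -> tuple[GenotypePanel, PanelTruth]:
    """Simulate a diploid biallelic genotype panel with latent structure.

    Ancestral B-allele frequencies are drawn Uniform(floor, 1-floor); each
    population's frequencies drift from the ancestor under the
    Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) model (equal to the
    ancestor when F = 0).  Each sample's two allele copies draw their
    population of origin independently from that sample's admixture
    proportions, matching the admixture model's per-gamete assumption.
    No-calls are placed independently per genotype.

    Parameters
    ----------
    n_pops, n_per_pop, n_loci
        Panel dimensions; all must be >= 1.  Total samples = n_pops * n_per_pop.
    differentiation
        Drift parameter F in [0, 1).  F = 1 is rejected (degenerate Beta).
    admixture_alpha
        If None, samples are unadmixed (one-hot ancestry in blocks of
        n_per_pop); otherwise admixture proportions are Dirichlet(alpha)
        draws.  Must be > 0 when given.
    nocall_rate
        Independent probability of an NN call, in [0, 1).
    seed
        Seed for all randomness; identical arguments give identical panels.
    ancestral_maf_floor
        Lower bound of the ancestral frequency distribution, keeping
        simulated panels away from the uninformative low-MAF regime that the
        analysis filters out.

    Returns
    -------
    (GenotypePanel, PanelTruth)
        The panel carries random distinct ref/alt nucleotide labels per
        locus so that coverage simulation can operate on it.
    """
    if min(n_pops, n_per_pop, n_loci) < 1:
        raise ValueError("n_pops, n_per_pop and n_loci must all be >= 1")
    if not 0.0 <= differentiation < 1.0:
        raise ValueError("differentiation F must lie in [0, 1); F = 1 is degenerate")
    if admixture_alpha is not None and admixture_alpha <= 0:
        raise ValueError("admixture_alpha must be > 0")
    if not 0.0 <= nocall_rate < 1.0:
        raise ValueError("nocall_rate must lie in [0, 1)")
    if not 0.0 <= ancestral_maf_floor < 0.5:
        raise ValueError("ancestral_maf_floor must lie in [0, 0.5)")

    rng = np.random.default_rng(seed)
    n = n_pops * n_per_pop
    F = differentiation

    p_anc = rng.uniform(ancestral_maf_floor, 1.0 - ancestral_maf_floor, size=n_loci)
    if F > 0:
        shape = (1.0 - F) / F
        pop_freqs = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(n_pops, n_loci))
    else:
        pop_freqs = np.tile(p_anc, (n_pops, 1))

    pop_of_origin: np.ndarray | None
    if admixture_alpha is None:
        pop_of_origin = np.repeat(np.arange(n_pops), n_per_pop)
        q_true = np.zeros((n, n_pops))
        q_true[np.arange(n), pop_of_origin] = 1.0
    else:
        pop_of_origin = None
        q_true = rng.dirichlet(np.full(n_pops, float(admixture_alpha)), size=n)

    # two allele copies, each with its own population of origin
    cum_q = np.cumsum(q_true, axis=1)
    genotype = np.zeros((n, n_loci), dtype=np.int8)
    locus_idx = np.arange(n_loci)
    for _copy in range(2):
        u = rng.random((n, n_loci))
        z = (u[:, :, None] > cum_q[:, None, :]).sum(axis=2)
        genotype += (rng.random((n, n_loci)) < pop_freqs[z, locus_idx]).astype(np.int8)

    if nocall_rate > 0:
        genotype[rng.random((n, n_loci)) < nocall_rate] = -1

    sample_ids = [f"S{i:04d}" for i in range(n)]
    locus_ids = [f"L{j:04d}" for j in range(n_loci)]
    ref = rng.integers(0, 4, size=n_loci)
    alt = (ref + rng.integers(1, 4, size=n_loci)) % 4
    locus_alleles = list(zip(NUCLEOTIDES[ref], NUCLEOTIDES[alt]))

    panel = GenotypePanel(sample_ids, locus_ids, genotype, locus_alleles)
    truth = PanelTruth(n_pops, p_anc, pop_freqs, q_true, F, pop_of_origin)
    return panel, truth


# --------------------------------------------------------------------- contigs

@dataclass(frozen=True)
class PlantedContigSpec:
    """One perfect microsatellite planted into a synthetic contig.

    ``background_length`` is the total contig length; the repeat
    (``copies`` x ``motif``) overwrites the random background starting at
    0-based ``start`` and must fit within the contig.  Several specs may
    share a ``contig_id`` provided their repeat intervals do not touch.
    """

    contig_id: str
    motif: str
    copies: int
    start: int
    background_length: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.motif) <= 6:
            raise ValueError("motif length must be 1..6")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over {A,C,G,T}")
        if not is_primitive(self.motif):
            raise ValueError(f"motif {self.motif!r} is not primitive")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.start < 0 or self.end > self.background_length:
            raise ValueError("planted repeat must fit within the contig")

    @property
    def repeat_length(self) -> int:
        return self.copies * len(self.motif)

    @property
    def end(self) -> int:
        return self.start + self.repeat_length

    def expected_locus(self) -> SSRLocus:
        """The SSRLocus a scanner should report for this planted repeat."""
        motif, strand = canonical_motif(self.motif)
        return SSRLocus(
            contig_id=self.contig_id,
            motif=motif,
            strand_class=strand,
            copies=self.copies,
            start=self.start,
            unit_length=len(self.motif),
        )


def generate_contigs(
    specs: list[PlantedContigSpec],
    gc_fraction: float = 0.5,
    seed: int = 0,
    min_copies: dict[int, int] | None = None,
    max_attempts: int = 100,
) -> dict[str, str]:
    """Build contig sequences containing exactly the planted perfect repeats.

    The non-repeat background is drawn with the requested GC fraction and is
    rejection-checked with the SSR scanner itself: a contig is regenerated
    until the scanner (at `min_copies` thresholds, MISA defaults) reports
    exactly the planted repeats that meet those thresholds — no accidental
    background SSRs, no accidental extension of a planted repeat into its
    flanks.

    Returns a mapping contig_id -> sequence.  Raises if two planted repeats
    on the same contig collide (overlap or touch), or if a conforming
    background cannot be found in `max_attempts` tries.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie in (0, 1)")
    thresholds = dict(MISA_DEFAULT_MIN_COPIES if min_copies is None else min_copies)
    rng = np.random.default_rng(seed)

    by_contig: dict[str, list[PlantedContigSpec]] = {}
    for spec in specs:
        by_contig.setdefault(spec.contig_id, []).append(spec)

    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    contigs: dict[str, str] = {}
    for contig_id, contig_specs in by_contig.items():
        lengths = {s.background_length for s in contig_specs}
        if len(lengths) > 1:
            raise ValueError(
                f"specs for contig {contig_id!r} disagree on background_length"
            )
        length = lengths.pop()
        ordered = sorted(contig_specs, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:  # touching repeats can merge into one run
                raise ValueError(
                    f"planted repeats collide on contig {contig_id!r}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        expected = sorted(
            (
                s.expected_locus()
                for s in ordered
                if s.copies >= thresholds.get(len(s.motif), np.inf)
            ),
            key=lambda l: l.start,
        )
        for _attempt in range(max_attempts):
            seq = NUCLEOTIDES[rng.choice(4, size=length, p=probs)]
            for s in ordered:
                seq[s.start : s.end] = list(s.motif * s.copies)
            candidate = "".join(seq)
            found = sorted(
                scan_sequence(contig_id, candidate, thresholds), key=lambda l: l.start
            )
            if found == expected:
                contigs[contig_id] = candidate
                break
        else:
            raise RuntimeError(
                f"could not generate an SSR-clean background for contig "
                f"{contig_id!r} in {max_attempts} attempts"
            )
    return contigs


# -------------------------------------------------------------------- coverage

def generate_coverage(
    panel: GenotypePanel,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
    position: int = 0,
) -> pd.DataFrame:
    """Simulate a per-position, per-accession allele-coverage table.

    Each called genotype of `panel` becomes one pileup position (contig id =
    locus id, at `position`).  Read depth is Poisson(mean_depth); each read
    draws one of the genotype's two alleles uniformly and is corrupted with
    probability `error_rate` into one of the three other nucleotides,
    uniformly.  Rows with zero depth are dropped, so ``mean_depth = 0``
    yields an empty table.

    Returns a DataFrame with columns contig, pos, accession, A, C, G, T.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0.0 <= error_rate < 0.05:
        raise ValueError("error_rate must lie in [0, 0.05)")
    if panel.locus_alleles is None:
        raise ValueError("panel has no per-locus nucleotide labels")

    rng = np.random.default_rng(seed)
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    rows = []
    for j, locus in enumerate(panel.locus_ids):
        ref, alt = panel.locus_alleles[j]
        ri, ai = nuc_index[ref], nuc_index[alt]
        for i, accession in enumerate(panel.sample_ids):
            g = panel.calls[i, j]
            if g < 0:
                continue
            depth = rng.poisson(mean_depth)
            if depth == 0:
                continue
            n_alt = rng.binomial(depth, 0.5) if g == 1 else (depth if g == 2 else 0)
            counts = np.zeros(4, dtype=np.int64)
            counts[ai] += n_alt
            counts[ri] += depth - n_alt
            if error_rate > 0:
                n_err = rng.binomial(depth, error_rate)
                for _ in range(n_err):
                    src = rng.choice(4, p=counts / counts.sum())
                    counts[src] -= 1
                    counts[(src + rng.integers(1, 4)) % 4] += 1
            rows.append((locus, position, accession, *counts))
    return pd.DataFrame(rows, columns=["contig", "pos", "accession", "A", "C", "G", "T"])
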