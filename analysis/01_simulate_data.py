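#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces, under results/data/:
  * a diploid genotype panel with two latent ancestral populations
    (2 x 60 accessions, 300 biallelic loci, Balding–Nichols F = 0.15,
    2% no-calls) plus its latent-truth sidecars — the stand-in for a
    germplasm collection genotyped on a fixed SNP panel;
  * 60 contigs with planted perfect microsatellites on repeat-free
    background — the stand-in for assembled transcriptome contigs;
  * an allele-coverage table (Poisson depth 30, 0.5% base error) over a
    6-accession slice — the stand-in for quality-filtered pileups.

All downstream analysis scripts read these files.
"""

import json
from pathlib import Path

import numpy as np

from pomdiv import io as pio
from pomdiv.simulate import (
    PlantedContigSpec,
    generate_contigs,
    generate_coverage,
    generate_panel,
)
from pomdiv.ssr import MISA_DEFAULT_MIN_COPIES

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # ------------------------------------------------------------- panel
    panel, truth = generate_panel(
        n_pops=2, n_per_pop=60, n_loci=300,
        differentiation=0.15, nocall_rate=0.02, seed=SEED,
    )
    pio.write_panel_tsv(panel, OUT / "panel.tsv", header_comment=f"simulated panel seed={SEED}")
    pio.write_panel_vcf(panel, OUT / "panel.vcf", source="pomdiv simulate")
    pio.write_truth_sidecar(truth, OUT / "panel")
    print(f"panel: {panel.n_samples} accessions x {panel.n_loci} loci, "
          f"{(panel.calls < 0).mean():.1%} no-calls")

    # ----------------------------------------------------------- contigs
    motifs = ["A", "AG", "GA", "CT", "AAG", "GAA", "AGG", "AT", "AC", "AAAG", "AGAGG", "AACGTC"]
    specs = []
    for i in range(60):
        motif = motifs[int(rng.integers(len(motifs)))]
        copies = int(MISA_DEFAULT_MIN_COPIES[len(motif)] + rng.integers(0, 5))
        start = int(rng.integers(80, 500))
        specs.append(PlantedContigSpec(f"contig{i:03d}", motif, copies, start, 800))
    contigs = generate_contigs(specs, gc_fraction=0.47, seed=SEED + 1)
    pio.write_fasta(contigs, OUT / "contigs.fasta")
    planted = [
        {"contig": s.contig_id, "motif": s.motif, "copies": s.copies, "start": s.start}
        for s in specs
    ]
    (OUT / "planted_ssrs.json").write_text(json.dumps(planted, indent=2) + "\n")
    print(f"contigs: {len(contigs)} sequences with {len(specs)} planted SSRs")

    # ---------------------------------------------------------- coverage
    slice_panel = panel.subset(samples=panel.sample_ids[:6])
    coverage = generate_coverage(slice_panel, mean_depth=30, error_rate=0.005, seed=SEED + 2)
    pio.write_coverage_tsv(coverage, OUT / "coverage.tsv",
                           header_comment="pos is 0-based; counts are quality-filtered reads")
    print(f"coverage: {len(coverage)} accession-position rows over "
          f"{coverage['contig'].nunique()} loci")

    pio.write_manifest(
        {
            "seed": SEED,
            "panel": {"n_pops": 2, "n_per_pop": 60, "n_loci": 300,
                      "differentiation": 0.15, "nocall_rate": 0.02},
            "contigs": {"n": len(contigs), "gc_fraction": 0.47},
            "coverage": {"accessions": 6, "mean_depth": 30, "error_rate": 0.005},
        },
        OUT / "manifest.json",
    )


if __name__ == "__main__":
    main()
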