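#!/usr/bin/env python
"""SSR and SNP marker discovery on the simulated inputs.

SSRs: the contigs are scanned twice — once with the MISA-convention copy
thresholds and once with a more permissive profile standing in for a
second scanner — and the two lists are crossed on (contig, motif, start),
keeping only dual-confirmed loci.  The motif spectrum of the intersection
is tabulated by unit length and by motif/strand.

SNPs: within-accession (heterozygous-site) calls at the 3x allele-coverage
cutoff for every accession in the coverage table, between-accession calls
for the first pair, and transition/transversion summaries.

Writes results/markers/: ssr tables, spectrum tables, snp tables and a
summary JSON.
"""

import json
from pathlib import Path

from pomdiv import io as pio
from pomdiv.snp import call_snps_between, call_snps_within, snp_calls_to_frame, tv_ratio
from pomdiv.ssr import (
    MISA_DEFAULT_MIN_COPIES,
    intersect_ssrs,
    motif_spectrum,
    scan_ssrs,
    ssrs_to_frame,
    unit_length_spectrum,
)

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results" / "markers"

PERMISSIVE_MIN_COPIES = {1: 9, 2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    contigs = pio.read_fasta(DATA / "contigs.fasta")

    strict = scan_ssrs(contigs, MISA_DEFAULT_MIN_COPIES)
    permissive = scan_ssrs(contigs, PERMISSIVE_MIN_COPIES)
    crossed = intersect_ssrs(strict, permissive)
    print(f"SSRs: {len(strict)} (strict) / {len(permissive)} (permissive) "
          f"-> {len(crossed)} dual-confirmed")

    ssrs_to_frame(crossed).to_csv(OUT / "ssr_confirmed.tsv", sep="\t", index=False)
    motif_spectrum(crossed).to_csv(OUT / "ssr_motif_spectrum.tsv", sep="\t", index=False)
    by_len = unit_length_spectrum(crossed)
    by_len.to_csv(OUT / "ssr_unit_length_spectrum.tsv", sep="\t", index=False)
    print(by_len.to_string(index=False))

    coverage = pio.read_coverage_tsv(DATA / "coverage.tsv")
    accessions = sorted(coverage["accession"].unique())
    within = []
    for acc in accessions:
        within += call_snps_within(coverage, acc, min_allele_cov=3)
    between = call_snps_between(coverage, accessions[0], accessions[1], min_allele_cov=3)
    snp_calls_to_frame(within).to_csv(OUT / "snp_within.tsv", sep="\t", index=False)
    snp_calls_to_frame(between).to_csv(OUT / "snp_between.tsv", sep="\t", index=False)

    summary = {
        "ssr": {
            "strict": len(strict),
            "permissive": len(permissive),
            "dual_confirmed": len(crossed),
        },
        "snp": {
            "within_calls": len(within),
            "between_calls": len(between),
            "tv_ratio_within": tv_ratio(within) if within else None,
            "tv_ratio_between": tv_ratio(between) if between else None,
        },
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    print(f"SNPs: {len(within)} within-accession "
          f"(t/v {summary['snp']['tv_ratio_within']:.2f}), "
          f"{len(between)} between the first two accessions")


if __name__ == "__main__":
    main()
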