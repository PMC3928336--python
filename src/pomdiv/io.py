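"""File-format adapters: FASTA contigs, genotype panels (TSV and minimal
VCF), allele-coverage tables and group assignments.

The panel layer is abstract biallelic (calls AA/AB/BB/NN); nucleotide
identity appears only where sequence context exists (marker discovery,
VCF REF/ALT).  TSV panels have samples as rows and loci as columns.  The
VCF dialect is minimal: one biallelic record per locus, GT as the only
FORMAT field, ``./.`` for no-calls; CHROM is the contig (or locus) id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import CALL_TO_CODE, GenotypePanel
from .snp import COVERAGE_COLUMNS

_VALID_CHARS = set("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """Read contigs from FASTA: uppercase-normalized, duplicate ids and
    non-ACGTN characters rejected.  An empty file gives an empty dict."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for contig {record.id!r} in {path}")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"contig {record.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        contigs[record.id] = seq
    return contigs


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------- panels

def read_panel(path, dialect: str = "tsv") -> GenotypePanel:
    """Read a genotype panel from TSV or minimal VCF.

    Equivalent content in either dialect produces an identical panel
    (sample order, locus order, calls).  The TSV dialect uses abstract
    A/B labels: calls must be AA/AB/BB/NN.
    """
    if dialect == "tsv":
        return _read_panel_tsv(path)
    if dialect == "vcf":
        return _read_panel_vcf(path)
    raise ValueError(f"unsupported panel dialect {dialect!r}")


def _read_panel_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    sample_ids = [str(s) for s in df.index]
    locus_ids = [str(c) for c in df.columns]
    return GenotypePanel.from_strings(sample_ids, locus_ids, df.to_numpy())


def write_panel_tsv(panel: GenotypePanel, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        panel.call_strings(), index=panel.sample_ids, columns=panel.locus_ids
    )
    df.index.name = "sample"
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


def _read_panel_vcf(path) -> GenotypePanel:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        locus_ids: list[str] = []
        alleles: list[tuple[str, str]] = []
        rows: list[list[int]] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic; "
                    "the panel layer requires biallelic loci"
                )
            locus_ids.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}")
            alleles.append((rec.ref, rec.alts[0]))
            col = []
            for s in sample_ids:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(-1)
                    continue
                if len(gt) != 2:
                    raise ValueError(
                        f"non-diploid genotype at {rec.chrom}:{rec.pos} sample {s}"
                    )
                col.append(int(gt[0]) + int(gt[1]))
            rows.append(col)
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(sample_ids), 0), np.int8)
    return GenotypePanel(sample_ids, locus_ids, calls, alleles or None)


def write_panel_vcf(panel: GenotypePanel, path, source: str | None = None) -> None:
    """Minimal VCF export: GT only, one biallelic record per locus.

    Without sequence context, CHROM is the locus id and POS is 1; REF/ALT
    fall back to symbolic A/B when the panel carries no nucleotide labels.
    """
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if source:
            fh.write(f"##source={source}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for j, locus in enumerate(panel.locus_ids):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, locus in enumerate(panel.locus_ids):
            ref, alt = (
                panel.locus_alleles[j] if panel.locus_alleles is not None else ("A", "T")
            )
            gts = "\t".join(gt_map[int(g)] for g in panel.calls[:, j])
            fh.write(f"{locus}\t1\t{locus}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# -------------------------------------------------------------------- sidecars

def write_truth_sidecar(truth, prefix) -> None:
    """Write a simulation's latent structure next to its panel: admixture
    proportions (``<prefix>.q_true.tsv``), per-population frequencies
    (``<prefix>.pop_freqs.tsv``)."""
    prefix = Path(prefix)
    q = pd.DataFrame(
        truth.q_true, columns=[f"pop{k}" for k in range(truth.n_pops)]
    )
    q.index.name = "sample_index"
    q.to_csv(f"{prefix}.q_true.tsv", sep="\t")
    pf = pd.DataFrame(
        truth.pop_freqs.T, columns=[f"pop{k}" for k in range(truth.n_pops)]
    )
    pf.index.name = "locus_index"
    pf.insert(0, "ancestral", truth.ancestral_freqs)
    pf.to_csv(f"{prefix}.pop_freqs.tsv", sep="\t")


def write_manifest(params: dict, path) -> None:
    """JSON manifest of generator parameters and seed."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# -------------------------------------------------------------------- coverage

def read_coverage_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table {path} lacks columns {missing}")
    return df


def write_coverage_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------- groups

def read_groups_tsv(path) -> dict[str, str]:
    """Sample -> group label mapping from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("groups TSV needs columns: sample, label")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_groups_tsv(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)
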