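#!/usr/bin/env python
"""Genetic diversity of the dendrogram groups: Wright's F_S and F_ST.

For each group from the kinship cut, computes per-locus F_S
(1 − H_obs/H_exp) and its median — positive medians indicate a
heterozygote deficit relative to Hardy–Weinberg.  Across groups,
computes per-locus F_ST = (H_T − H_S)/H_T, its median, and the fraction
of loci deviating less than 5%.

Writes results/fstats/: per-group F_S tables, F_ST table, summary JSON.
"""

import json
from pathlib import Path

from pomdiv import io as pio
from pomdiv.fstats import fixation_index_fs, fixation_index_fst, groups_from_labels

QC = Path(__file__).resolve().parents[1] / "results" / "qc"
KIN = Path(__file__).resolve().parents[1] / "results" / "kinship"
OUT = Path(__file__).resolve().parents[1] / "results" / "fstats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = pio.read_panel(QC / "panel_informative.tsv")
    groups = groups_from_labels(pio.read_groups_tsv(KIN / "groups.tsv"))

    medians = {}
    for name, members in sorted(groups.items()):
        table, median = fixation_index_fs(panel, members)
        table.to_csv(OUT / f"fs_{name}.tsv", sep="\t")
        medians[name] = median
        print(f"{name} ({len(members)} accessions): median F_S = {median:+.3f}")

    fst_table, fst_summary = fixation_index_fst(panel, groups, deviation_bound=0.05)
    fst_table.to_csv(OUT / "fst.tsv", sep="\t")
    print(f"among-group differentiation: median F_ST = {fst_summary['median_fst']:.3f}; "
          f"{fst_summary['frac_below_bound']:.0%} of loci deviate less than 5%")

    summary = {"median_fs": medians, "fst": fst_summary}
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
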