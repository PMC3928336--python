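"""End-to-end pipeline: QC → diversity → clustering → admixture → F-statistics.

A :class:`RunConfig` (round-trippable through a single JSON document,
unknown keys rejected) drives the stages in order, writing every
intermediate artifact into the output directory and a single
``summary.json`` at the end.  Every stochastic stage is seeded from the
master seed, so two runs of the same config produce identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import io as pio
from .admixture import evanno_delta_k, run_k_scan
from .cluster import bootstrap_support, write_newick
from .distance import psa_distance
from .fstats import fixation_index_fs, fixation_index_fst
from .panel import GenotypePanel
from .qc import filter_informative, filter_nocall, locus_stats
from .simulate import generate_panel

logger = logging.getLogger(__name__)


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateBlock:
    """Synthetic-panel parameters (used when no input panel is given)."""

    n_pops: int = 2
    n_per_pop: int = 60
    n_loci: int = 300
    differentiation: float = 0.15
    admixture_alpha: float | None = None
    nocall_rate: float = 0.02


@dataclass
class QCBlock:
    max_sample_nocall: float = 0.10
    max_assay_nocall: float = 0.30
    maf_min: float = 0.05


@dataclass
class DiversityBlock:
    n_boot: int = 200
    ward_variant: str = "d2"
    n_groups: int = 3  # dendrogram cut used for the F-statistics stage
    min_support_label: float = 85.0


@dataclass
class StructureBlock:
    k_min: int = 1
    k_max: int = 5
    runs_per_k: int = 5
    burnin: int = 1000
    reps: int = 5000
    alpha: float = 1.0


@dataclass
class RunConfig:
    """Master configuration; serializable to/from one JSON document."""

    seed: int = 0
    out_dir: str = "results/run"
    panel_path: str | None = None  # TSV panel; None -> simulate
    log_level: str = "INFO"
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    qc: QCBlock = field(default_factory=QCBlock)
    diversity: DiversityBlock = field(default_factory=DiversityBlock)
    structure: StructureBlock = field(default_factory=StructureBlock)

    def validate(self) -> None:
        if self.diversity.n_boot < 1:
            raise ValueError("diversity.n_boot must be >= 1")
        if self.diversity.ward_variant not in ("d", "d2"):
            raise ValueError("diversity.ward_variant must be 'd' or 'd2'")
        if self.structure.k_max - self.structure.k_min < 2:
            raise ValueError("structure needs at least 3 K values for ΔK")
        if self.structure.runs_per_k < 2:
            raise ValueError("structure.runs_per_k must be >= 2 for ΔK")
        if self.diversity.n_groups < 2:
            raise ValueError("diversity.n_groups must be >= 2")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        blocks = {
            "simulate": SimulateBlock,
            "qc": QCBlock,
            "diversity": DiversityBlock,
            "structure": StructureBlock,
        }
        parsed = {}
        for key, value in data.items():
            if key in blocks:
                parsed[key] = _from_dict(blocks[key], value)
            else:
                parsed[key] = value
        cfg = _from_dict(cls, parsed)
        cfg.validate()
        return cfg


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the summary dictionary.

    Artifacts written under ``config.out_dir``: the input or simulated
    panel, QC'd panel, removal logs, per-locus stats, distance matrix,
    bootstrap-annotated Newick tree, evidence and ΔK tables, Q matrix of
    the selected K, per-group F_S and F_ST tables, and ``summary.json``.
    A stage failure halts the run, leaving earlier artifacts in place.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed}

    # ---------------------------------------------------------------- input
    if config.panel_path is not None:
        panel = pio.read_panel(config.panel_path, dialect="tsv")
        logger.info("loaded panel %s", config.panel_path)
    else:
        sim = config.simulate
        panel, truth = generate_panel(
            sim.n_pops,
            sim.n_per_pop,
            sim.n_loci,
            differentiation=sim.differentiation,
            admixture_alpha=sim.admixture_alpha,
            nocall_rate=sim.nocall_rate,
            seed=seeds[0],
        )
        pio.write_truth_sidecar(truth, out / "panel")
        logger.info("simulated panel %dx%d", panel.n_samples, panel.n_loci)
    pio.write_panel_tsv(panel, out / "panel.tsv", header_comment=f"stage=input seed={config.seed}")
    summary["panel_before_qc"] = {"samples": panel.n_samples, "loci": panel.n_loci}

    # ------------------------------------------------------------------- QC
    panel_qc, log1 = filter_nocall(
        panel, config.qc.max_sample_nocall, config.qc.max_assay_nocall
    )
    panel_qc, log2 = filter_informative(panel_qc, config.qc.maf_min)
    qc_report = {
        "removed_samples": log1.removed_samples,
        "removed_loci_nocall": log1.removed_loci,
        "removed_loci_uninformative": log2.removed_loci,
    }
    (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2) + "\n")
    pio.write_panel_tsv(panel_qc, out / "panel_qc.tsv", header_comment="stage=qc")
    summary["panel_after_qc"] = {"samples": panel_qc.n_samples, "loci": panel_qc.n_loci}

    # ------------------------------------------------------------ diversity
    stats = locus_stats(panel_qc)
    stats.to_csv(out / "locus_stats.tsv", sep="\t")
    summary["median_pic"] = float(np.nanmedian(stats["pic"]))

    dm = psa_distance(panel_qc)
    dm.to_frame().to_csv(out / "distance.tsv", sep="\t")
    tree = bootstrap_support(
        panel_qc,
        n_boot=config.diversity.n_boot,
        seed=seeds[1],
        variant=config.diversity.ward_variant,
    )
    write_newick(tree, out / "dendrogram.nwk")
    summary["n_boot"] = config.diversity.n_boot

    # ------------------------------------------------------------ admixture
    st = config.structure
    evidences, fits = run_k_scan(
        panel_qc,
        st.k_min,
        st.k_max,
        runs_per_k=st.runs_per_k,
        burnin=st.burnin,
        reps=st.reps,
        alpha=st.alpha,
        seed=seeds[2],
    )
    res = evanno_delta_k(evidences)
    res.table.to_csv(out / "delta_k.tsv", sep="\t", index=False)
    summary["selected_k"] = res.selected_k
    summary["delta_k_ambiguous"] = res.ambiguous
    if res.selected_k is not None:
        best = fits[res.selected_k][
            int(np.argmax(evidences[res.selected_k]))
        ]
        best.q_frame().to_csv(out / "q_matrix.tsv", sep="\t")

    # ------------------------------------------------------------- F-stats
    labels = tree.cut(config.diversity.n_groups)
    groups = {
        f"G{g + 1}": [panel_qc.sample_ids[i] for i in np.flatnonzero(labels == g)]
        for g in range(config.diversity.n_groups)
    }
    pio.write_groups_tsv(
        {s: g for g, ss in groups.items() for s in ss}, out / "groups.tsv"
    )
    fs_medians = {}
    for g, members in groups.items():
        if len(members) < 2:
            logger.warning("group %s has <2 samples; F_S skipped", g)
            continue
        table, median = fixation_index_fs(panel_qc, members)
        table.to_csv(out / f"fs_{g}.tsv", sep="\t")
        fs_medians[g] = median
    summary["median_fs"] = fs_medians
    fst_table, fst_summary = fixation_index_fst(panel_qc, groups)
    fst_table.to_csv(out / "fst.tsv", sep="\t")
    summary["fst"] = fst_summary

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return summary
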