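"""End-to-end orchestration: simulate -> QC -> mixed model -> DE -> reports.

A single :class:`PipelineConfig` drives every stage; the top-level seed fans
out to per-stage seeds by fixed offsets so each stage is independently
reproducible.  Every stage writes a delimited table under the output
directory and the run ends with a manifest (file, sha256, stage) plus a
structured log of the per-stage counts.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .annotation import annotate_probes, summarise_annotation
from .mixed_model import DyeSwapMixedModel, build_design
from .mixture import (call_de, compute_contrasts, fit_two_component_mixture,
                      summarise_de)
from .qc import apply_qc, channel_summary
from .qpcr import ddct_report
from .simulate import (CONTRAST_PAIRS, SimulationConfig,
                       generate_annotation_fixtures, generate_design,
                       simulate_qpcr, simulate_spots)

logger = logging.getLogger(__name__)

# per-stage seed offsets from the top-level seed
STAGE_SEEDS = {"spots": 1, "annotation": 2, "qpcr": 3, "chromosomes": 4}


@dataclass
class PipelineConfig:
    outdir: str = "mixde_run"
    simulation: dict = field(default_factory=dict)
    snr_threshold: float = 1.0
    r_threshold: float = 0.85
    r_strict: bool = False
    reml_tol: float = 1e-6
    reml_max_iter: int = 200
    em_tol: float = 1e-8
    em_n_starts: int = 5
    fdr_target: float = 0.01
    seed: int = 0
    n_annotation_probes: int = 12
    qpcr_targets: tuple = ("DSC1",)
    qpcr_ddct_truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.fdr_target < 0.5:
            raise ValueError("fdr_target must be in (0, 0.5)")
        SimulationConfig(**self.simulation).validate()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls(**mio.load_config(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    stats = {}

    def record(stage, path):
        manifest.append({"stage": stage, "file": str(path),
                         "sha256": _sha256(path)})

    t0 = time.time()
    sim_cfg = SimulationConfig(**{**config.simulation,
                                  "seed": config.seed + STAGE_SEEDS["spots"]})
    design = generate_design(sim_cfg)
    spots, truth = simulate_spots(design, sim_cfg)
    record("simulate", mio.write_table(design, out / "design.tsv"))
    record("simulate", mio.write_table(spots, out / "spots.tsv"))
    record("simulate", mio.write_table(truth, out / "truth.tsv"))
    logger.info("simulate: %d channels, %d spots", len(design), len(spots))

    qc = apply_qc(spots, config.snr_threshold, config.r_threshold,
                  config.r_strict)
    record("qc", mio.write_qc_table(qc, out / "qc.tsv"))
    record("qc", mio.write_table(channel_summary(qc), out / "qc_summary.tsv"))
    stats["spots_passing_qc"] = int(qc["passed"].sum())
    logger.info("qc: %d/%d spots passed", stats["spots_passing_qc"], len(qc))

    md = build_design(qc, design)
    model = DyeSwapMixedModel(tol=config.reml_tol,
                              max_iter=config.reml_max_iter).fit_model_data(md)
    stats["genes_fitted"] = model.hg_solutions_.shape[0]
    record("fit", mio.write_table(model.fit_report(), out / "fit_report.tsv"))
    profiles = model.hg_solutions_.rename_axis("gene_id").reset_index()
    record("fit", mio.write_table(profiles, out / "normalized_expression.tsv"))
    logger.info("fit: %d genes, converged=%s in %d iterations",
                stats["genes_fitted"], model.converged_, model.n_iter_)

    contrasts = compute_contrasts(model.hg_solutions_, model.hg_pev_)
    results = []
    for i, contrast in enumerate(CONTRAST_PAIRS):
        sub = contrasts[contrasts["contrast"] == contrast]
        mix = fit_two_component_mixture(
            sub["statistic"].to_numpy(), tol=config.em_tol,
            n_starts=config.em_n_starts, random_state=config.seed + 10 + i)
        results.append(call_de(sub, mix, config.fdr_target))
    results = pd.concat(results, ignore_index=True)
    record("de", mio.write_table(results, out / "de_results.tsv"))
    stats["de_per_contrast"] = {
        c: int(results[(results["contrast"] == c)
                       & results["de_flag"]].shape[0])
        for c in CONTRAST_PAIRS}
    logger.info("de: %s", stats["de_per_contrast"])

    fixtures = generate_annotation_fixtures(
        config.n_annotation_probes, seed=config.seed + STAGE_SEEDS["annotation"])
    ann = annotate_probes(fixtures["probes"], fixtures["bovine_genes"],
                          fixtures["human_genes"], fixtures["blast_hits"])
    record("annotate", mio.write_table(ann, out / "annotation.tsv"))
    stats["annotation_categories"] = summarise_annotation(ann)
    logger.info("annotate: %s", stats["annotation_categories"])

    qpcr = simulate_qpcr(delta_ddct_truth=config.qpcr_ddct_truth or None,
                         target=config.qpcr_targets[0],
                         seed=config.seed + STAGE_SEEDS["qpcr"])
    record("qpcr", mio.write_table(qpcr, out / "qpcr_ct.tsv"))
    ddct = ddct_report(qpcr, targets=list(config.qpcr_targets))
    record("qpcr", mio.write_table(ddct, out / "qpcr_ddct.tsv"))

    cmap = synthetic_chromosome_map(
        results["gene_id"].unique(), seed=config.seed + STAGE_SEEDS["chromosomes"])
    venn = report_venn(results)
    chrom = report_chromosome_distribution(results, cmap)
    record("report", mio.write_json(venn, out / "venn.json"))
    record("report", mio.write_table(chrom, out / "chromosome_counts.tsv"))
    record("report", mio.write_json(stats, out / "stage_counts.json"))
    mio.write_json(manifest, out / "manifest.json")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return {"manifest": manifest, "stats": stats}


def synthetic_chromosome_map(gene_ids, n_chromosomes: int = 30,
                             seed: int = 0) -> pd.Series:
    """Random gene->chromosome assignment (chromosome 30 stands for X)."""
    rng = np.random.default_rng(seed)
    gene_ids = np.sort(np.asarray(gene_ids))
    return pd.Series(rng.integers(1, n_chromosomes + 1, len(gene_ids)),
                     index=gene_ids)


def report_venn(results: pd.DataFrame) -> dict:
    """Per-contrast DE counts and all pairwise/triple intersections."""
    summary = summarise_de(results)
    return {"counts": summary["counts"], "overlaps": summary["overlaps"],
            "total_genes": summary["total_genes"]}


def report_chromosome_distribution(results: pd.DataFrame,
                                   chromosome_map: pd.Series) -> pd.DataFrame:
    """Per-chromosome DE counts per contrast; unmapped genes go to 'unplaced'."""
    summary = summarise_de(results, chromosome_map)
    return summary["per_chromosome"]
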