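"""End-to-end orchestration: config in, result bundle out.

``run_discovery`` wires the whole chain — read coverage files, QC,
optional adjustment, site tests, regions, episignature — writes every
table plus run metadata, and returns the fitted results object.
``run_calibration`` runs the control-subsampling null on the configured
control group.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import NullCalibration, subsample_null
from .cohort import PipelineConfig, summarize_cohort
from .confounds import CellTypeReference
from .io import (
    SampleSheet,
    assemble_beta_matrix,
    read_bismark_cov,
    read_region_bed,
    read_sample_sheet,
)
from .model import EpisignatureModel, EpisignatureResults
from .qc import run_qc

logger = logging.getLogger(__name__)


def _load_model(config: PipelineConfig) -> EpisignatureModel:
    sheet = read_sample_sheet(config.sample_sheet)
    cov_dir = Path(config.coverage_dir)
    tables = {}
    for sid in sheet.ids:
        path = cov_dir / f"{sid}.cov"
        if not path.exists():
            raise FileNotFoundError(f"[load] coverage file missing: {path}")
        tables[sid] = read_bismark_cov(path)
    matrix = assemble_beta_matrix(tables, sheet)
    islands = read_region_bed(config.islands_bed, "cpg_island") if config.islands_bed else None
    targets = read_region_bed(config.targets_bed, "target_region") if config.targets_bed else None
    genes = read_region_bed(config.genes_bed, "gene") if config.genes_bed else None
    snp_mask = read_region_bed(config.snp_mask_bed, "snp_mask") if config.snp_mask_bed else None
    reference = None
    if config.celltype_reference:
        ref_table = pd.read_csv(config.celltype_reference, sep="\t")
        reference = CellTypeReference.from_table(ref_table)
    return EpisignatureModel(
        matrix, sheet, islands, targets, genes, snp_mask, reference, config.qc
    )


def _write_metadata(config: PipelineConfig, outdir: Path, extra: dict) -> None:
    meta = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    meta.update(extra)
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1))


def run_discovery(
    config: PipelineConfig, case_group: str, write_figures: bool = True
) -> EpisignatureResults:
    """Execute the discovery pipeline for one contrast and write outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        model = _load_model(config)
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc
    try:
        results = model.fit(
            case_group,
            control_group=config.control_group,
            sig_params=config.significance,
            region_params=config.region,
            adjust_celltype=config.adjust_celltype,
            adjust_sva=config.adjust_sva,
            covariates=config.covariates,
            nonredundant_cutoff=config.nonredundant_cutoff,
            gomlom_threshold=config.gomlom_threshold,
            seed=config.seed,
        )
    except Exception as exc:
        raise RuntimeError(f"[fit] {exc}") from exc
    prefix = outdir / f"{case_group}_vs_{config.control_group}"
    results.save(prefix)
    results.qc_report.as_frame().to_csv(
        outdir / "qc_report.tsv", sep="\t", index=False
    )
    summary = summarize_cohort(model.sheet)
    summary.per_group.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    if write_figures and results.z_matrix is not None:
        try:
            results.plot_heatmap(prefix.with_suffix(".heatmap.png"))
            results.plot_scatter(prefix.with_suffix(".scatter.png"))
            if results.pca is not None:
                results.plot_pca(prefix.with_suffix(".pca.png"))
        except Exception as exc:  # plots must never sink a run
            logger.warning("[plot] figure generation failed: %s", exc)
    _write_metadata(
        config,
        outdir,
        {
            "stage_counts": {
                "sites_tested": results.qc_report.n_retained_sites,
                "dmps": results.n_dmps,
                "islands": results.n_islands,
                "dmbs": results.n_dmbs,
            }
        },
    )
    return results


def run_calibration(config: PipelineConfig) -> NullCalibration:
    """Run the control-subsampling null calibration and write its tables."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        model = _load_model(config)
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc
    clean, _ = run_qc(model.matrix, model.snp_mask, model.qc_params)
    control_ids = model.sheet.samples_in_group(config.control_group)
    calib = subsample_null(
        clean.beta[control_ids],
        k_range=range(1, config.calibration_k_max + 1),
        reps=config.calibration_reps,
        seed=config.seed,
        params=config.significance,
    )
    calib.counts.to_csv(outdir / "calibration_counts.tsv", sep="\t", index=False)
    (outdir / "calibration_summary.json").write_text(
        json.dumps(calib.summary(), indent=1)
    )
    _write_metadata(config, outdir, {"calibration": calib.summary()})
    return calib
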