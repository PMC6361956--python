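"""End-to-end pipeline driver: simulate -> stage 1 -> stage 2 -> summarize.

Each region is analysed in isolation; per-protein fits are seeded
independently of processing order, so outputs are identical however the
work is scheduled.  A run manifest records input hashes, seeds, versions
and per-stage timings for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .errors import ConfigError, DesignError
from .mcmc import McmcConfig
from .quantdata import (
    SpectrumTable,
    StudyDesign,
    filter_min_spectra,
    read_design,
    read_spectrum_table,
    validate_design,
    write_spectrum_table,
)
from .stage1 import NormalizationFactors, fit_stage1_protein, infer_normalization
from .stage2 import (
    fit_stage2_protein,
    results_table,
    select_global_fdr,
    test_fold_change,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and chain regime for one region's analysis."""

    min_spectra: int = 3
    fc_threshold: float = 1.05
    alpha: float = 0.05
    mcmc_preset: str = "desk"
    seed: int = 0
    threads: int = 1
    check_convergence: bool = True
    normalization_mode: str = "drawwise"

    def __post_init__(self):
        if self.min_spectra < 1 or self.fc_threshold <= 1.0 or not 0 < self.alpha < 1:
            raise ConfigError("thresholds must be positive (fc_threshold > 1)")
        cfg = self.mcmc(stage=2)
        if cfg.n_chains * cfg.n_iterations < 1000:
            raise ConfigError("stage-2 regime must yield >= 1000 posterior draws")

    def mcmc(self, stage: int) -> McmcConfig:
        return McmcConfig.preset(self.mcmc_preset, stage=stage, seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fit1(args):
    table, design, pid, cfg, check = args
    return fit_stage1_protein(table, design, pid, cfg, check_convergence=check)


def _fit2(args):
    table, design, norm, pid, cfg, check = args
    return fit_stage2_protein(table, design, norm, pid, cfg, check_convergence=check)


def _map(fn, jobs, threads: int):
    if threads <= 1 or len(jobs) <= 1:
        return [fn(j) for j in jobs]
    with ProcessPoolExecutor(max_workers=threads) as pool:
        return list(pool.map(fn, jobs, chunksize=max(1, len(jobs) // (4 * threads))))


def analyze_region(
    table: SpectrumTable,
    design: StudyDesign,
    config: PipelineConfig,
):
    """Run the full inference for one region on in-memory inputs.

    Returns (results DataFrame, NormalizationFactors, filter report,
    sample-quantification DataFrame, significant-id set).
    """
    report = validate_design(design, table)
    if not report.ok:
        raise DesignError("; ".join(report.fatal))
    for w in report.warnings:
        logger.info("design: %s", w)

    filtered, filt_report = filter_min_spectra(table, config.min_spectra)
    proteins = filtered.proteins
    if not proteins:
        raise ConfigError("no proteins pass the minimum-spectra filter")

    cfg1 = config.mcmc(stage=1)
    posteriors = _map(
        _fit1,
        [(filtered, design, p, cfg1, config.check_convergence) for p in proteins],
        config.threads,
    )
    norm = infer_normalization(posteriors, design, mode=config.normalization_mode)

    cfg2 = config.mcmc(stage=2)
    fits = _map(
        _fit2,
        [(filtered, design, norm, p, cfg2, config.check_convergence) for p in proteins],
        config.threads,
    )
    calls = [test_fold_change(f, config.fc_threshold) for f in fits]
    significant = select_global_fdr(calls, config.alpha)
    results = results_table(calls, fits)

    quant_rows = []
    for f in fits:
        q = f.sample_quant.copy()
        q.insert(0, "protein", f.protein_id)
        quant_rows.append(q)
    import pandas as pd

    sample_quant = pd.concat(quant_rows, ignore_index=True)
    return results, norm, filt_report, sample_quant, significant


def run_pipeline(
    records_path,
    design_path,
    out_dir,
    config: PipelineConfig,
) -> dict:
    """File-to-file pipeline for one region; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "records": {"path": str(records_path), "sha256": _sha256(records_path)},
            "design": {"path": str(design_path), "sha256": _sha256(design_path)},
        },
        "stages": [],
    }

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )

        return done

    done = stage("load")
    table, load_report = read_spectrum_table(records_path)
    design = read_design(design_path)
    report = validate_design(design, table)
    if not report.ok:
        raise DesignError("; ".join(report.fatal))
    done()

    done = stage("filter")
    filtered, filt_report = filter_min_spectra(table, config.min_spectra)
    write_spectrum_table(filtered, out / "filtered_records.tsv")
    filt_report.to_json(out / "filter_report.json")
    done()

    done = stage("stage1_normalization")
    cfg1 = config.mcmc(stage=1)
    posteriors = _map(
        _fit1,
        [
            (filtered, design, p, cfg1, config.check_convergence)
            for p in filtered.proteins
        ],
        config.threads,
    )
    norm = infer_normalization(posteriors, design, mode=config.normalization_mode)
    norm.to_json(out / "normalization.json")
    done()

    done = stage("stage2_differential")
    cfg2 = config.mcmc(stage=2)
    fits = _map(
        _fit2,
        [
            (filtered, design, norm, p, cfg2, config.check_convergence)
            for p in filtered.proteins
        ],
        config.threads,
    )
    calls = [test_fold_change(f, config.fc_threshold) for f in fits]
    select_global_fdr(calls, config.alpha)
    results = results_table(calls, fits)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    import pandas as pd

    quant = pd.concat(
        [f.sample_quant.assign(protein=f.protein_id) for f in fits], ignore_index=True
    )
    quant.to_csv(out / "sample_quant.tsv", sep="\t", index=False)
    done()

    manifest["n_proteins"] = len(filtered.proteins)
    manifest["n_significant"] = int(results["significant"].sum())
    manifest["load_report"] = load_report.to_dict()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
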