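"""End-to-end orchestration: simulate/load -> normalize -> intersect ->
screen -> search -> assess -> report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .anova_screen import common_proteins, screen_candidates
from .ffnn import TrainingConfig
from .io_model import (
    IntensityMatrix,
    StudyDesign,
    ValidationError,
    read_intensity_table,
    read_sample_metadata,
    write_report,
)
from .panel_search import SplitSpec, SearchResult, assess_on_test, search_panels
from .preprocess import quantile_normalize
from .synthetic_data import SimulationConfig, simulate_three_studies

log = logging.getLogger("panelforge")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure; message names the stage."""


@dataclass
class PipelineConfig:
    # either a simulation config, or three (intensity, metadata) path pairs
    simulation: SimulationConfig | None = None
    overlap_fraction: float = 1.0
    study_paths: dict[str, tuple[str, str]] | None = None  # study -> (matrix, metadata)
    split: SplitSpec = field(default_factory=SplitSpec)
    panel_size: int = 5
    alpha: float = 0.01
    pool_cap: int | None = 10
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0
    normalize: bool = True
    cv_folds: int = 5
    n_jobs: int = 1
    output_dir: str | Path = "panelforge_out"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.study_paths is None):
            raise ValidationError("provide exactly one of simulation or study_paths")
        if self.study_paths is not None and set(self.study_paths) != {"A", "B", "C"}:
            raise ValidationError("study_paths must name studies A, B and C")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("load")
def _load_studies(config: PipelineConfig) -> dict[str, tuple[IntensityMatrix, StudyDesign]]:
    if config.simulation is not None:
        studies, _truth = simulate_three_studies(config.simulation, config.overlap_fraction)
        return dict(zip("ABC", studies))
    out = {}
    for study, (mpath, dpath) in config.study_paths.items():
        out[study] = (read_intensity_table(mpath), read_sample_metadata(dpath))
    return out


@_stage("normalize")
def _normalize(studies):
    return {s: (quantile_normalize(m), d) for s, (m, d) in studies.items()}


@_stage("intersect")
def _intersect(studies):
    shared = common_proteins([m for m, _ in studies.values()])
    log.info("%d proteins in common across the three studies", len(shared))
    return {s: (m.subset_proteins(shared), d) for s, (m, d) in studies.items()}


def run_pipeline(config: PipelineConfig) -> SearchResult:
    """Run every stage in order and write the report plus a manifest.

    The testing study is read only by the final assessment; screening uses
    the training study alone and selection uses the validation study alone.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    studies = _load_studies(config)
    if config.normalize:
        studies = _normalize(studies)
    studies = _intersect(studies)

    train = studies[config.split.training]
    validation = studies[config.split.validation]
    test = studies[config.split.testing]

    t0 = time.perf_counter()
    try:
        candidates = screen_candidates(train[0], train[1], alpha=config.alpha)
    except Exception as exc:
        raise PipelineError(f"stage 'screen' failed: {exc}") from exc
    log.info("stage screen done in %.2fs: %d candidates at alpha=%g",
             time.perf_counter() - t0, len(candidates), config.alpha)

    t0 = time.perf_counter()
    try:
        result = search_panels(
            candidates.protein_ids, train, validation,
            panel_size=config.panel_size, config=config.training,
            global_seed=config.seed, pool_cap=config.pool_cap,
            cv_folds=config.cv_folds, n_jobs=config.n_jobs,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'search' failed: {exc}") from exc
    log.info("stage search done in %.2fs: %d panels evaluated",
             time.perf_counter() - t0, len(result.panels))

    if result.cstar is not None:
        try:
            assess_on_test(result.cstar, test, train[1], validation[1])
        except Exception as exc:
            raise PipelineError(f"stage 'assess' failed: {exc}") from exc

    write_report(result, outdir / "report.json", outdir / "ranking.tsv")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "panel_size": config.panel_size,
        "alpha": config.alpha,
        "pool_cap": config.pool_cap,
        "cv_folds": config.cv_folds,
        "normalize": config.normalize,
        "split": {"training": config.split.training,
                  "validation": config.split.validation,
                  "testing": config.split.testing},
        "training": asdict(config.training),
        "simulation": None if config.simulation is None else asdict(config.simulation),
        "overlap_fraction": config.overlap_fraction,
        "study_paths": config.study_paths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result
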