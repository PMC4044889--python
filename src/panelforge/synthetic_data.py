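"""Case/control study simulator with a nested random-effects structure.

Each log2 intensity is drawn as

    y = mu + T (group shift) + S (sample effect) + I (injection effect)
        + eps (residual)

with independent normal random effects per protein.  The injection effect
and the residual are generated separately even though a single measurement
per injection cannot distinguish them; downstream fitting pools the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import IntensityMatrix, StudyDesign, ValidationError

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_study", "simulate_three_studies"]

STUDY_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 100
    n_informative: int = 5
    effect_size: float = 1.0
    baseline_mu: float = 20.0
    # defaults are package choices; no magnitudes exist for the real data
    sigma_sample: float = 1.0
    sigma_replicate: float = 0.5
    sigma_error: float = 0.5
    n_cancer: int = 40
    n_control: int = 40
    n_replicates: int = 2
    seed: int = 0
    effect_overrides: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        if not (0 <= self.n_informative <= self.n_proteins):
            raise ValidationError("need 0 <= n_informative <= n_proteins")
        for name in ("sigma_sample", "sigma_replicate", "sigma_error"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("n_cancer", "n_control", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")

    @property
    def sigma_total(self) -> float:
        """Std dev of one observation around its group mean."""
        return float(np.sqrt(self.sigma_sample**2 + self.sigma_replicate**2 + self.sigma_error**2))


@dataclass
class SimulationTruth:
    """Ground truth: which proteins carry a group effect, and how large."""

    informative_protein_ids: list[str]
    effect_sizes: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.informative_protein_ids) != set(self.effect_sizes):
            raise ValidationError("effect_sizes keys must equal informative ids")


def _protein_ids(n: int, prefix: str = "P") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _build_truth(config: SimulationConfig, protein_ids: Sequence[str]) -> SimulationTruth:
    informative = list(protein_ids[: config.n_informative])
    effects = {p: config.effect_size for p in informative}
    if config.effect_overrides:
        for p, e in config.effect_overrides.items():
            if p not in effects:
                raise ValidationError(f"effect override for non-informative protein {p!r}")
            effects[p] = float(e)
    return SimulationTruth(informative, effects)


def _study_rng(seed: int, study_label: str) -> np.random.Generator:
    label_index = STUDY_LABELS.index(study_label)
    return np.random.default_rng(np.random.SeedSequence([seed, label_index]))


def _simulate(
    config: SimulationConfig,
    study_label: str,
    protein_ids: Sequence[str],
    truth: SimulationTruth,
    n_cancer: int,
    n_control: int,
) -> tuple[IntensityMatrix, StudyDesign]:
    rng = _study_rng(config.seed, study_label)
    r = config.n_replicates
    n_samples = n_cancer + n_control
    n_inj = n_samples * r
    p = len(protein_ids)

    sample_ids = [f"{study_label}_s{k + 1:03d}" for k in range(n_samples)]
    groups = ["cancer"] * n_cancer + ["control"] * n_control
    injection_ids, inj_sample_idx, replicates = [], [], []
    for k, sid in enumerate(sample_ids):
        for rep in range(1, r + 1):
            injection_ids.append(f"{sid}_r{rep}")
            inj_sample_idx.append(k)
            replicates.append(rep)
    inj_sample_idx = np.asarray(inj_sample_idx)

    shift = np.zeros((p, n_inj))
    is_cancer = np.array([groups[k] == "cancer" for k in inj_sample_idx])
    for i, pid in enumerate(protein_ids):
        if pid in truth.effect_sizes:
            shift[i, is_cancer] = truth.effect_sizes[pid]

    sample_eff = rng.normal(0.0, config.sigma_sample, size=(p, n_samples))
    inj_eff = rng.normal(0.0, config.sigma_replicate, size=(p, n_inj))
    resid = rng.normal(0.0, config.sigma_error, size=(p, n_inj))
    values = config.baseline_mu + shift + sample_eff[:, inj_sample_idx] + inj_eff + resid

    matrix = IntensityMatrix(list(protein_ids), injection_ids, values)
    design = StudyDesign(
        injection_ids,
        [sample_ids[k] for k in inj_sample_idx],
        [groups[k] for k in inj_sample_idx],
        [study_label] * n_inj,
        replicates,
    )
    return matrix, design


def simulate_study(
    config: SimulationConfig, study_label: str = "A"
) -> tuple[IntensityMatrix, StudyDesign, SimulationTruth]:
    """Simulate one study.  Deterministic given (config.seed, study_label)."""
    if study_label not in STUDY_LABELS:
        raise ValidationError(f"study_label must be one of {STUDY_LABELS}")
    protein_ids = _protein_ids(config.n_proteins)
    truth = _build_truth(config, protein_ids)
    matrix, design = _simulate(
        config, study_label, protein_ids, truth, config.n_cancer, config.n_control
    )
    return matrix, design, truth


def simulate_three_studies(
    config: SimulationConfig,
    overlap_fraction: float = 1.0,
    study_sizes: Sequence[tuple[int, int]] | None = None,
) -> tuple[list[tuple[IntensityMatrix, StudyDesign]], SimulationTruth]:
    """Simulate studies A, B and C sharing a designated core protein set.

    ``overlap_fraction`` of each study's proteins form the shared core (the
    cross-study intersection is exactly the core); the remainder are
    study-specific ids.  Informative proteins always live inside the core.
    The third study defaults to half the sample size of the first two.
    """
    if not (0 < overlap_fraction <= 1.0):
        raise ValidationError("overlap_fraction must be in (0, 1]")
    n_core = int(round(config.n_proteins * overlap_fraction))
    if n_core < config.n_informative:
        raise ValidationError(
            f"core of {n_core} proteins cannot hold {config.n_informative} informative proteins"
        )
    core_ids = _protein_ids(n_core)
    truth = _build_truth(config, core_ids)
    if study_sizes is None:
        study_sizes = [
            (config.n_cancer, config.n_control),
            (config.n_cancer, config.n_control),
            (max(1, config.n_cancer // 2), max(1, config.n_control // 2)),
        ]
    if len(study_sizes) != 3:
        raise ValidationError("study_sizes must list three (n_cancer, n_control) pairs")

    n_extra = config.n_proteins - n_core
    studies = []
    for label, (nc, nk) in zip(STUDY_LABELS, study_sizes):
        extra = _protein_ids(n_extra, prefix=f"{label}_X") if n_extra else []
        studies.append(_simulate(config, label, core_ids + extra, truth, nc, nk))
    return studies, truth
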