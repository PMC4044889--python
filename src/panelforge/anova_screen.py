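"""Per-protein nested ANOVA and candidate-marker screening.

The model for one protein is a fixed group effect with random samples
nested in groups and random replicate injections within samples.  With a
single measurement per injection the injection effect and the residual are
confounded, so the fitter estimates their pooled variance, and the group
effect is tested against the sample-within-group stratum:

    F = MS(group) / MS(sample within group),  df = (g - 1, n_samples - g)

computed on per-sample means (exact for balanced replicate counts, a
standard approximation otherwise).  Variance components come from the
expected mean squares, truncated at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_model import IntensityMatrix, StudyDesign, ValidationError

__all__ = [
    "ANOVAResult",
    "CandidateSet",
    "DegreesOfFreedomError",
    "common_proteins",
    "fit_protein_anova",
    "screen_candidates",
]


class DegreesOfFreedomError(ValueError):
    """Layout too small to test the group effect."""


@dataclass
class ANOVAResult:
    protein_id: str
    f_statistic: float
    p_value: float
    df_num: float
    df_den: float
    var_sample: float          # estimate of the between-sample variance
    var_residual: float        # pooled replicate + residual variance (NaN if r == 1)
    group_means: dict[str, float]
    degenerate: bool = False   # zero denominator MS with positive numerator

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def mean_difference(self) -> float:
        means = self.group_means
        if "cancer" in means and "control" in means:
            return means["cancer"] - means["control"]
        return 0.0


@dataclass
class CandidateSet:
    protein_ids: list[str]
    alpha: float
    results: dict[str, ANOVAResult]

    def __post_init__(self) -> None:
        for pid in self.protein_ids:
            if not self.results[pid].p_value < self.alpha:
                raise ValidationError(f"candidate {pid!r} does not pass alpha={self.alpha}")

    def __len__(self) -> int:
        return len(self.protein_ids)


def common_proteins(matrices: Sequence[IntensityMatrix]) -> list[str]:
    """Protein ids present in every matrix, in the first matrix's order."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].protein_ids)
    for m in matrices[1:]:
        common &= set(m.protein_ids)
    return [p for p in matrices[0].protein_ids if p in common]


def fit_protein_anova(
    values: np.ndarray | Sequence[float],
    design: StudyDesign,
    protein_id: str = "",
) -> ANOVAResult:
    """Fit the nested ANOVA for one protein.

    ``values`` is aligned with ``design.injection_ids``; NaN entries are
    treated as missing.  Samples with no non-missing replicate are dropped;
    each group must retain at least two samples.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (design.n_injections,):
        raise ValidationError("values length must match the design's injections")

    # per-sample means and replicate counts
    sample_vals: dict[str, list[float]] = {}
    for v, sid in zip(values, design.sample_ids):
        if np.isnan(v):
            continue
        sample_vals.setdefault(sid, []).append(v)
    by_group: dict[str, list[tuple[float, int]]] = {}
    ss_resid = 0.0
    n_obs = 0
    for sid, vals in sample_vals.items():
        arr = np.asarray(vals)
        m = float(arr.mean())
        by_group.setdefault(design.group_of_sample(sid), []).append((m, arr.size))
        ss_resid += float(((arr - m) ** 2).sum())
        n_obs += arr.size

    groups = sorted(by_group)
    g = len(groups)
    if g < 2:
        raise DegreesOfFreedomError("need at least two groups with data")
    for grp in groups:
        if len(by_group[grp]) < 2:
            raise DegreesOfFreedomError(f"group {grp!r} has fewer than two samples")

    n_samples = sum(len(v) for v in by_group.values())
    means = {grp: np.array([m for m, _ in by_group[grp]]) for grp in groups}
    counts = np.array([c for grp in groups for _, c in by_group[grp]], dtype=float)
    all_means = np.concatenate([means[grp] for grp in groups])
    grand = float(all_means.mean())

    ss_group = sum(len(means[grp]) * (means[grp].mean() - grand) ** 2 for grp in groups)
    ss_sample = sum(float(((means[grp] - means[grp].mean()) ** 2).sum()) for grp in groups)
    df_num = g - 1
    df_den = n_samples - g
    ms_group = ss_group / df_num
    ms_sample = ss_sample / df_den

    degenerate = False
    if ms_sample == 0.0:
        if ms_group == 0.0:
            f_stat, p_value = 0.0, 1.0
        else:
            f_stat, p_value, degenerate = float("inf"), 0.0, True
    else:
        f_stat = ms_group / ms_sample
        p_value = float(stats.f.sf(f_stat, df_num, df_den))

    # variance components by expected mean squares on sample means:
    # E[MS_sample] = sigma_sample^2 + sigma_within^2 / r_h  (harmonic mean r)
    df_resid = n_obs - n_samples
    if df_resid > 0:
        var_residual = ss_resid / df_resid
        r_h = counts.size / float((1.0 / counts).sum())
        var_sample = max(0.0, ms_sample - var_residual / r_h)
    else:
        var_residual = float("nan")
        var_sample = max(0.0, ms_sample)  # confounded with within-sample variance

    group_means = {grp: float(means[grp].mean()) for grp in groups}
    return ANOVAResult(
        protein_id=protein_id,
        f_statistic=float(f_stat),
        p_value=p_value,
        df_num=float(df_num),
        df_den=float(df_den),
        var_sample=float(var_sample),
        var_residual=float(var_residual),
        group_means=group_means,
        degenerate=degenerate,
    )


def screen_candidates(
    matrix: IntensityMatrix, design: StudyDesign, alpha: float = 0.01
) -> CandidateSet:
    """ANOVA every protein and keep those with raw p < ``alpha``.

    Candidates are ordered by ascending p-value, ties broken by descending
    absolute group-mean difference, then protein id.  Proteins whose fit
    fails are skipped with a warning.  No multiple-testing correction.
    """
    # align design rows to matrix column order
    pos = {inj: k for k, inj in enumerate(design.injection_ids)}
    keep = [pos[i] for i in matrix.injection_ids]
    aligned = StudyDesign(
        [design.injection_ids[k] for k in keep],
        [design.sample_ids[k] for k in keep],
        [design.groups[k] for k in keep],
        [design.studies[k] for k in keep],
        [design.replicates[k] for k in keep],
    )

    results: dict[str, ANOVAResult] = {}
    for i, pid in enumerate(matrix.protein_ids):
        try:
            results[pid] = fit_protein_anova(matrix.values[i], aligned, pid)
        except (DegreesOfFreedomError, ValidationError) as exc:
            warnings.warn(f"skipping protein {pid!r}: {exc}", stacklevel=2)

    passing = [pid for pid, r in results.items() if r.p_value < alpha]
    passing.sort(key=lambda pid: (results[pid].p_value,
                                  -abs(results[pid].mean_difference), pid))
    return CandidateSet(passing, alpha, results)
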