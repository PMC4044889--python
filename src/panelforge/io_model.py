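"""Core data model and tabular I/O.

Two tables drive everything downstream: a proteins-by-injections intensity
matrix and a per-injection sample-metadata table.  Both are plain TSV/CSV so
fixtures can be written by hand and round-tripped exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "IntensityMatrix",
    "StudyDesign",
    "read_intensity_table",
    "write_intensity_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "write_report",
    "read_report",
]

#: tokens recognised as a missing cell in intensity tables
MISSING_TOKENS = ("NA", "")

GROUPS = ("cancer", "control")


class FormatError(ValueError):
    """Malformed input table (duplicates, bad cells, wrong columns)."""


class ValidationError(ValueError):
    """Structurally valid table that violates a domain invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class IntensityMatrix:
    """Proteins-by-injections matrix of (log2) intensities.

    Missing entries are stored as NaN and exposed through
    :attr:`missing_mask`.
    """

    protein_ids: list[str]
    injection_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.injection_ids = [str(i) for i in self.injection_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.protein_ids), len(self.injection_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.injection_ids)} injections"
            )
        _check_unique(self.protein_ids, "protein")
        _check_unique(self.injection_ids, "injection")

    # -- convenience ----------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_injections(self) -> int:
        return len(self.injection_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]

    def subset_proteins(self, keep: Sequence[str]) -> "IntensityMatrix":
        """Restrict to ``keep`` (in the given order)."""
        index = {p: i for i, p in enumerate(self.protein_ids)}
        rows = [index[p] for p in keep]
        return IntensityMatrix(list(keep), list(self.injection_ids), self.values[rows].copy())

    def subset_injections(self, keep: Sequence[str]) -> "IntensityMatrix":
        index = {c: j for j, c in enumerate(self.injection_ids)}
        cols = [index[c] for c in keep]
        return IntensityMatrix(list(self.protein_ids), list(keep), self.values[:, cols].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.injection_ids)

    def equals(self, other: "IntensityMatrix") -> bool:
        return (
            self.protein_ids == other.protein_ids
            and self.injection_ids == other.injection_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class StudyDesign:
    """Per-injection metadata: sample, group, study and replicate index."""

    injection_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    studies: list[str]
    replicates: list[int]

    def __post_init__(self) -> None:
        n = len(self.injection_ids)
        for name in ("sample_ids", "groups", "studies", "replicates"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column {name} has wrong length")
        _check_unique(self.injection_ids, "injection")
        self.groups = [g.strip().lower() for g in self.groups]
        self.studies = [s.strip().upper() for s in self.studies]
        for g in self.groups:
            if g not in GROUPS:
                raise ValidationError(f"unknown group label {g!r} (expected one of {GROUPS})")
        self.replicates = [int(r) for r in self.replicates]
        if any(r < 1 for r in self.replicates):
            raise ValidationError("replicate indices must be positive")
        # each sample belongs to exactly one group and one study
        sample_group: dict[str, str] = {}
        sample_study: dict[str, str] = {}
        for s, g, st in zip(self.sample_ids, self.groups, self.studies):
            if sample_group.setdefault(s, g) != g:
                raise ValidationError(f"sample {s!r} assigned to two groups")
            if sample_study.setdefault(s, st) != st:
                raise ValidationError(f"sample {s!r} assigned to two studies")
        self._sample_group = sample_group
        self._sample_study = sample_study

    # -- accessors ------------------------------------------------------

    @property
    def n_injections(self) -> int:
        return len(self.injection_ids)

    @property
    def sample_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(s)
        return list(seen)

    def group_of_sample(self, sample_id: str) -> str:
        return self._sample_group[sample_id]

    def study_of_sample(self, sample_id: str) -> str:
        return self._sample_study[sample_id]

    def injection_group(self, injection_id: str) -> str:
        return self.groups[self.injection_ids.index(injection_id)]

    def labels_for(self, injection_ids: Sequence[str]) -> np.ndarray:
        """1 for cancer, 0 for control, aligned with ``injection_ids``."""
        lookup = dict(zip(self.injection_ids, self.groups))
        return np.array([1 if lookup[i] == "cancer" else 0 for i in injection_ids])

    def restrict_to_study(self, study: str) -> "StudyDesign":
        keep = [k for k, s in enumerate(self.studies) if s == study.upper()]
        return StudyDesign(
            [self.injection_ids[k] for k in keep],
            [self.sample_ids[k] for k in keep],
            [self.groups[k] for k in keep],
            [self.studies[k] for k in keep],
            [self.replicates[k] for k in keep],
        )

    def matches_matrix(self, matrix: IntensityMatrix) -> bool:
        return set(matrix.injection_ids) <= set(self.injection_ids)

    def is_balanced(self) -> bool:
        """True when every sample has the same replicate count and the two
        groups contain equally many samples."""
        counts: dict[str, int] = {}
        for s in self.sample_ids:
            counts[s] = counts.get(s, 0) + 1
        if len(set(counts.values())) > 1:
            return False
        per_group: dict[str, int] = {g: 0 for g in GROUPS}
        for s in counts:
            per_group[self._sample_group[s]] += 1
        return len({v for v in per_group.values() if True}) == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_id": self.injection_ids,
                "sample_id": self.sample_ids,
                "group": self.groups,
                "study": self.studies,
                "replicate": self.replicates,
            }
        )


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_intensity_table(
    path: str | Path, dialect: str = "tsv", transpose: bool = False
) -> IntensityMatrix:
    """Read a proteins-by-injections table.

    First column holds protein ids, header row holds injection ids.  Cells
    must be numeric or one of the missing tokens ("NA" or empty).  Set
    ``transpose`` if the file is injections-by-proteins; orientation is
    never autodetected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(dialect))
    # pandas silently renames duplicate header fields, so check the raw line
    _check_unique(header[1:], "protein" if transpose else "injection")
    df = pd.read_csv(
        path, sep=_sep(dialect), index_col=0, dtype=str,
        keep_default_na=False,
    )
    if transpose:
        df = df.T
    protein_ids = [str(p) for p in df.index]
    injection_ids = [str(c) for c in df.columns]
    _check_unique(protein_ids, "protein")
    _check_unique(injection_ids, "injection")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip() if isinstance(raw[i, j], str) else raw[i, j]
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell {cell!r} at protein {protein_ids[i]!r}, "
                    f"injection {injection_ids[j]!r} in {path}"
                ) from None
    return IntensityMatrix(protein_ids, injection_ids, values)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path, dialect: str = "tsv") -> None:
    df = matrix.to_frame()
    df.index.name = "protein_id"
    df.to_csv(Path(path), sep=_sep(dialect), na_rep="NA")


METADATA_COLUMNS = ("injection_id", "sample_id", "group", "study", "replicate")


def read_sample_metadata(path: str | Path, dialect: str = "tsv") -> StudyDesign:
    """Read the five-column per-injection metadata table."""
    df = pd.read_csv(Path(path), sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table missing columns: {missing}")
    try:
        replicates = [int(r) for r in df["replicate"]]
    except ValueError as exc:
        raise FormatError(f"non-integer replicate index: {exc}") from None
    return StudyDesign(
        list(df["injection_id"]),
        list(df["sample_id"]),
        list(df["group"]),
        list(df["study"]),
        replicates,
    )


def write_sample_metadata(design: StudyDesign, path: str | Path, dialect: str = "tsv") -> None:
    design.to_frame().to_csv(Path(path), sep=_sep(dialect), index=False)


# ----------------------------------------------------------------------
# Search report
# ----------------------------------------------------------------------

def _panel_record(pc) -> dict:
    rec = {
        "panel": list(pc.panel),
        "rank": pc.rank,
        "training_sse": pc.training_sse,
        "cv_mean_auc": pc.cv_mean_auc,
        "cv_epoch_budget": pc.cv_epoch_budget,
        "training_accuracy": pc.training_accuracy,
        "validation_auc": pc.validation_auc,
        "validation_accuracy": pc.validation_accuracy,
    }
    if pc.test_metrics is not None:
        rec["test_metrics"] = dict(pc.test_metrics)
    if pc.test_confusion is not None:
        rec["test_confusion"] = {
            "tp": pc.test_confusion.tp,
            "fp": pc.test_confusion.fp,
            "fn": pc.test_confusion.fn,
            "tn": pc.test_confusion.tn,
        }
    return rec


def write_report(result, path: str | Path, ranking_path: str | Path | None = None) -> None:
    """Write a machine-readable JSON report plus a flat TSV ranking table.

    Panels appear in rank order (descending validation AUC).  The TSV goes
    to ``ranking_path`` or ``<path>.ranking.tsv``.
    """
    path = Path(path)
    ranked = sorted(result.panels, key=lambda p: p.rank)
    payload = {
        "config": dict(result.config),
        "n_panels": len(ranked),
        "panels": [_panel_record(p) for p in ranked],
        "optimal_panel": list(result.cstar.panel) if result.cstar is not None else None,
    }
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    except OSError as exc:
        raise IOError(f"cannot write report to {path}: {exc}") from exc

    if ranking_path is None:
        ranking_path = path.with_suffix(path.suffix + ".ranking.tsv")
    rows = []
    for p in ranked:
        rows.append(
            {
                "rank": p.rank,
                "panel": ";".join(p.panel),
                "training_sse": p.training_sse,
                "training_accuracy": p.training_accuracy,
                "validation_accuracy": p.validation_accuracy,
                "validation_auc": p.validation_auc,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "rank", "panel", "training_sse", "training_accuracy",
            "validation_accuracy", "validation_auc",
        ],
    ).to_csv(Path(ranking_path), sep="\t", index=False)


def read_report(path: str | Path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)
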