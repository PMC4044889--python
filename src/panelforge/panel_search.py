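"""Exhaustive N-marker panel enumeration and selection by validation AUC.

Every combination of N proteins from the screened candidate pool is scored:
5-fold cross-validation on the training study picks an epoch budget, the
network is retrained on the full training study, and the panel's figure of
merit is the AUC of its scores on the validation study.  The winner is
assessed once, at the very end, on the untouched testing study.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from joblib import Parallel, delayed

from . import ffnn
from .io_model import IntensityMatrix, StudyDesign, ValidationError
from .metrics import (
    ConfusionMatrix,
    auc_score,
    confusion_from_scores,
    confusion_metrics,
)

__all__ = [
    "SplitSpec",
    "PanelCandidate",
    "SearchResult",
    "EvaluationError",
    "LeakageError",
    "enumerate_panels",
    "panel_features",
    "panel_seed",
    "evaluate_panel",
    "search_panels",
    "select_optimal",
    "assess_on_test",
]

ROLES = ("training", "validation", "testing")


class EvaluationError(ValueError):
    pass


class LeakageError(RuntimeError):
    """Test data touched a stage it must not touch."""


@dataclass(frozen=True)
class SplitSpec:
    """Bijection from roles to study labels, e.g. training=A, validation=C,
    testing=B."""

    training: str = "A"
    validation: str = "C"
    testing: str = "B"

    def __post_init__(self) -> None:
        studies = {self.training, self.validation, self.testing}
        if len(studies) != 3:
            raise ValidationError("split roles must map to three distinct studies")

    def study_for(self, role: str) -> str:
        return getattr(self, role)


@dataclass
class PanelCandidate:
    panel: tuple[str, ...]
    training_sse: float
    cv_mean_auc: float
    cv_epoch_budget: int
    validation_auc: float
    training_accuracy: float
    validation_accuracy: float
    rank: int = 0
    test_metrics: dict | None = None
    test_confusion: ConfusionMatrix | None = None
    model: ffnn.FFNNModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.validation_auc <= 1.0):
            raise ValidationError("validation_auc must lie in [0, 1]")


@dataclass
class SearchResult:
    panels: list[PanelCandidate]
    cstar: PanelCandidate | None
    config: dict


def enumerate_panels(candidates: Sequence[str], n: int) -> Iterator[tuple[str, ...]]:
    """All C(len(candidates), n) combinations, lexicographic in pool order."""
    if not (1 <= n <= len(candidates)):
        raise ValueError(f"panel size {n} out of range for pool of {len(candidates)}")
    return itertools.combinations(candidates, n)


def panel_seed(global_seed: int, panel: Sequence[str]) -> int:
    """Deterministic per-panel seed so parallel and serial runs agree."""
    digest = hashlib.sha256(
        (str(int(global_seed)) + "|" + "|".join(panel)).encode()
    ).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def panel_features(
    panel: Sequence[str], matrix: IntensityMatrix, design: StudyDesign
) -> tuple[np.ndarray, np.ndarray]:
    """(injections x panel) feature matrix and 0/1 labels (1 = cancer)."""
    index = {p: i for i, p in enumerate(matrix.protein_ids)}
    rows = []
    for pid in panel:
        if pid not in index:
            raise EvaluationError(f"panel protein {pid!r} absent from matrix")
        rows.append(index[pid])
    x = matrix.values[rows].T
    if np.isnan(x).any():
        bad = int(np.argwhere(np.isnan(x))[0][1])
        raise EvaluationError(f"missing values for panel protein {panel[bad]!r}")
    labels = design.labels_for(matrix.injection_ids)
    return x, labels


def evaluate_panel(
    panel: Sequence[str],
    train_data: tuple[IntensityMatrix, StudyDesign],
    validation_data: tuple[IntensityMatrix, StudyDesign],
    config: ffnn.TrainingConfig,
    global_seed: int = 0,
    cv_folds: int = 5,
) -> PanelCandidate:
    """Train, cross-validate and validation-score one panel.

    The per-panel seed is derived from (global_seed, panel ids), so results
    do not depend on evaluation order.
    """
    panel = tuple(panel)
    x_tr, y_tr = panel_features(panel, *train_data)
    x_va, y_va = panel_features(panel, *validation_data)

    cfg = replace(config, seed=panel_seed(global_seed, panel))
    cv = ffnn.cross_validate(x_tr, y_tr, ffnn.NetworkArchitecture.for_panel(len(panel)),
                             cfg, k=cv_folds)
    model = ffnn.train(
        x_tr, y_tr, ffnn.NetworkArchitecture.for_panel(len(panel)), cfg,
        epochs=cv.best_epoch,
    )
    tr_scores = ffnn.predict_scores(model, x_tr)
    va_scores = ffnn.predict_scores(model, x_va)
    tr_cm = confusion_from_scores(tr_scores, y_tr)
    va_cm = confusion_from_scores(va_scores, y_va)
    return PanelCandidate(
        panel=panel,
        training_sse=model.final_sse,
        cv_mean_auc=cv.best_mean_auc,
        cv_epoch_budget=cv.best_epoch,
        validation_auc=auc_score(va_scores, y_va),
        training_accuracy=confusion_metrics(tr_cm)["accuracy"],
        validation_accuracy=confusion_metrics(va_cm)["accuracy"],
        model=model,
    )


def select_optimal(candidates: Sequence[PanelCandidate]) -> PanelCandidate:
    """Argmax of validation AUC; ties broken by lower training SSE, then
    lexicographic panel ids.  Input order never matters."""
    if not candidates:
        raise ValueError("no panel candidates to select from")
    return min(candidates, key=lambda c: (-c.validation_auc, c.training_sse, c.panel))


def _rank(candidates: list[PanelCandidate]) -> list[PanelCandidate]:
    ranked = sorted(candidates, key=lambda c: (-c.validation_auc, c.training_sse, c.panel))
    for i, c in enumerate(ranked):
        c.rank = i + 1
    return ranked


def search_panels(
    candidates: Sequence[str],
    train_data: tuple[IntensityMatrix, StudyDesign],
    validation_data: tuple[IntensityMatrix, StudyDesign],
    panel_size: int,
    config: ffnn.TrainingConfig,
    global_seed: int = 0,
    pool_cap: int | None = None,
    cv_folds: int = 5,
    n_jobs: int = 1,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 1000,
) -> SearchResult:
    """Exhaustively evaluate panels from the candidate pool and rank them.

    ``pool_cap`` keeps only the first ``pool_cap`` candidates (the screen
    orders them by p-value, so this is a top-p cut).  With ``n_jobs`` > 1
    panels are evaluated in parallel; per-panel seeding keeps the outcome
    identical to the serial run.
    """
    pool = list(candidates)
    if pool_cap is not None:
        pool = pool[:pool_cap]
    panels = list(enumerate_panels(pool, panel_size))

    def _one(panel: tuple[str, ...]) -> PanelCandidate:
        return evaluate_panel(panel, train_data, validation_data, config,
                              global_seed=global_seed, cv_folds=cv_folds)

    results: list[PanelCandidate] = []
    if n_jobs == 1:
        for i, panel in enumerate(panels):
            results.append(_one(panel))
            if checkpoint_path and (i + 1) % checkpoint_every == 0:
                _write_checkpoint(results, checkpoint_path)
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(_one)(p) for p in panels)

    ranked = _rank(results)
    cstar = ranked[0] if ranked else None
    return SearchResult(
        panels=ranked,
        cstar=cstar,
        config={
            "panel_size": panel_size,
            "pool": pool,
            "global_seed": global_seed,
            "cv_folds": cv_folds,
        },
    )


def _write_checkpoint(results: list[PanelCandidate], path: str | Path) -> None:
    payload = [
        {"panel": list(c.panel), "validation_auc": c.validation_auc,
         "training_sse": c.training_sse}
        for c in results
    ]
    Path(path).write_text(json.dumps(payload))


def assess_on_test(
    cstar: PanelCandidate,
    test_data: tuple[IntensityMatrix, StudyDesign],
    train_design: StudyDesign | None = None,
    validation_design: StudyDesign | None = None,
) -> tuple[ConfusionMatrix, dict]:
    """One-shot assessment of the selected panel on the testing study.

    Scores are thresholded at 0 for the confusion matrix; the five metrics
    (sensitivity, specificity, precision, accuracy, AUC) come back as
    proportions.  Raises :class:`LeakageError` if any test injection also
    appears in the training or validation design.
    """
    if cstar.model is None:
        raise EvaluationError("selected panel carries no trained model")
    test_matrix, test_design = test_data
    test_injections = set(test_matrix.injection_ids)
    for other, name in ((train_design, "training"), (validation_design, "validation")):
        if other is not None and test_injections & set(other.injection_ids):
            shared = sorted(test_injections & set(other.injection_ids))[0]
            raise LeakageError(
                f"injection {shared!r} appears in both the testing and {name} sets"
            )

    x_te, y_te = panel_features(cstar.panel, test_matrix, test_design)
    scores = ffnn.predict_scores(cstar.model, x_te)
    cm = confusion_from_scores(scores, y_te)
    metrics = dict(confusion_metrics(cm))
    metrics["auc"] = auc_score(scores, y_te)
    cstar.test_confusion = cm
    cstar.test_metrics = metrics
    return cm, metrics
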