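"""Pearson-correlation evaluation of predicted flexibility profiles.

The accuracy metric throughout is the Pearson product-moment correlation
between the predicted and actual B profile of a protein, computed over all
of its residues; a dataset is summarized by the unweighted mean of the
per-protein coefficients.  Because Pearson correlation is invariant under
positive affine maps, the metric is directly comparable between the
normalized (Z-scored) and raw-Å² prediction modes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .features import FeatureMatrix

__all__ = ["EvalReport", "pearson_cc", "evaluate_dataset", "write_report", "ConstantInputError"]


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclasses.dataclass
class EvalReport:
    per_protein: list[tuple[str, float, int]]  # (protein_id, PCC, N)
    average_pcc: float
    failed: list[tuple[str, str]]  # (protein_id, reason)


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Standard Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a meaningful PCC")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def evaluate_dataset(
    model,
    dataset: Sequence[tuple[FeatureMatrix, np.ndarray]],
    b_mode: str = "normalized",
) -> EvalReport:
    """One PCC per protein over its full sequence, then the unweighted mean.

    ``dataset`` pairs each protein's feature matrix with its target
    profile.  A protein on which the model emits a constant profile (or
    whose target is constant) is recorded under ``failed`` with the reason
    and excluded from the mean.  ``b_mode`` is carried for reporting only:
    PCC is affine-invariant, so normalized and raw targets score
    identically.
    """
    matrices = [f.values if isinstance(f, FeatureMatrix) else np.asarray(f) for f, _ in dataset]
    ids = [
        f.protein_id if isinstance(f, FeatureMatrix) else f"protein_{i}"
        for i, (f, _) in enumerate(dataset)
    ]
    preds = model.predict_many(matrices)
    rows: list[tuple[str, float, int]] = []
    failed: list[tuple[str, str]] = []
    for pid, pred, (_, target) in zip(ids, preds, dataset):
        target = np.asarray(target, dtype=float)
        try:
            rows.append((pid, pearson_cc(pred, target), len(target)))
        except (ConstantInputError, ValueError) as err:
            failed.append((pid, str(err)))
    if not rows:
        raise ValueError("no protein yielded a defined PCC")
    avg = float(np.mean([r[1] for r in rows]))
    return EvalReport(per_protein=rows, average_pcc=avg, failed=failed)


def write_report(report: EvalReport, path: str | Path) -> None:
    """Delimited text: protein_id, N, PCC; footer with mean and failures."""
    with open(path, "w") as fh:
        fh.write("protein_id\tN\tPCC\n")
        for pid, pcc, n in report.per_protein:
            fh.write(f"{pid}\t{n}\t{pcc:.6f}\n")
        fh.write(f"# average_pcc\t{report.average_pcc:.6f}\tfailed={len(report.failed)}\n")
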