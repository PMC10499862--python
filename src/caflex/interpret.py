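"""Interpretability analyses: what information the regressor actually uses.

Two complementary probes quantify how far, in sequence and in space, one
residue influences another's predicted flexibility:

* **Window sweep** — predictions are recomputed from a contiguous sequence
  window of span ``ws`` centered on each residue; the PCC against the true
  profile rises with ``ws`` and plateaus at a protein-specific critical
  span ``wsc``.
* **Cutoff-radius masking** — predictions are recomputed after zeroing the
  feature rows of every residue farther than ``rcut`` Å (Euclidean, raw
  coordinates) from the probed site, leaving sequence positions intact.
  The pooled PCC relative to the unmasked PCC, and its per-atom marginal
  gain ΔPCC/ΔAtoms, delineate the spatial zone that matters.

The neighbor statistic n̂ (mean number of other Cα atoms within ``rcut``,
normalized by N−1) links the two: correlating the n̂-versus-window curve
with the PCC-versus-window curve, and scanning that correlation over
``rcut``, recovers the radius within which caging neighbors set the B
factor.  On synthetic data that radius is the generative ``r_star``.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .evaluation import ConstantInputError, pearson_cc
from .features import FeatureMatrix
from .model import Predictor
from .structures_io import ProteinRecord

__all__ = [
    "WindowSweep",
    "RcutSweep",
    "NhatCurve",
    "PccnResult",
    "GroupSummary",
    "window_predict",
    "window_predict_all",
    "window_sweep",
    "masked_predict_rcut",
    "masked_predict_all",
    "rcut_sweep",
    "delta_pcc_per_atom",
    "nhat",
    "nhat_curve",
    "pccn_vs_rcut",
    "group_summary",
    "write_sweep_table",
]


@dataclasses.dataclass
class WindowSweep:
    ws_values: list[int]
    pcc_at_ws: list[float]  # NaN where the PCC was undefined
    wsc_estimate: int
    flagged: list[int]  # ws values with undefined PCC


@dataclasses.dataclass
class RcutSweep:
    rcut_values: list[float]
    pcc: list[float]  # pooled PCC at each cutoff
    pcc_ratio: list[float]  # pcc / pcc_all
    atoms_considered: list[int]
    pcc_all: float


@dataclasses.dataclass
class NhatCurve:
    rcut: float
    n_bar: float
    n_hat: float


@dataclasses.dataclass
class PccnResult:
    rcut_values: list[float]
    pccn_values: list[float]  # mean over proteins of PCC_n
    argmax_rcut: float
    n_excluded: list[int]  # proteins excluded per rcut (constant n̂ curve)


@dataclasses.dataclass
class GroupSummary:
    group: str
    mean_actual: float
    sd_actual: float
    mean_predicted: float
    sd_predicted: float
    count: int


# ---- sequence-window probes ----------------------------------------------------


def _window_bounds(i: int, ws: int, n: int) -> tuple[int, int]:
    """Rows [lo, hi] of the span-ws window centered (left-biased) on i.

    The window holds min(ws+1, n) rows; near a terminus it shifts inward
    so it never crosses the chain ends but keeps its full span — hence a
    span of n−1 or more always covers the whole protein.
    """
    lo = i - math.ceil(ws / 2)
    hi = i + ws // 2
    if lo < 0:
        hi = min(n - 1, hi - lo)
        lo = 0
    elif hi > n - 1:
        lo = max(0, lo - (hi - (n - 1)))
        hi = n - 1
    return lo, hi


def window_predict(model: Predictor, features: FeatureMatrix, i: int, ws: int) -> float:
    """Prediction at residue i from its sequence window of span ``ws``.

    The window holds the ws+1 contiguous rows centered on i (⌈ws/2⌉ to the
    left, ⌊ws/2⌋ to the right), truncated at the termini; chain flags are
    left exactly as encoded, not recomputed for the crop.
    """
    n = features.n_residues
    if not 0 <= i < n:
        raise IndexError(f"residue index {i} out of range for N={n}")
    if ws < 0:
        raise ValueError("ws must be >= 0")
    lo, hi = _window_bounds(i, ws, n)
    pred = model.predict(features.values[lo : hi + 1])
    return float(pred[i - lo])


def window_predict_all(model: Predictor, features: FeatureMatrix, ws: int) -> np.ndarray:
    """Window predictions for every residue, batched into one forward pass."""
    n = features.n_residues
    bounds = [_window_bounds(i, ws, n) for i in range(n)]
    lengths = np.array([hi - lo + 1 for lo, hi in bounds])
    T = int(lengths.max())
    x = np.zeros((n, T, features.values.shape[1]))
    for i, (lo, hi) in enumerate(bounds):
        x[i, : hi - lo + 1] = features.values[lo : hi + 1]
    out = model.forward_batch(x, lengths)
    return np.array([out[i, i - bounds[i][0]] for i in range(n)])


def window_sweep(
    model: Predictor,
    record: ProteinRecord,
    features: FeatureMatrix,
    target: np.ndarray,
    ws_grid: Sequence[int],
    plateau_tol: float = 0.02,
) -> WindowSweep:
    """PCC of window-restricted predictions versus window span.

    ``wsc_estimate`` is the smallest grid span whose PCC reaches the
    plateau (the PCC at the largest span) within ``plateau_tol``.
    """
    ws_grid = list(ws_grid)
    if any(b < a for a, b in zip(ws_grid, ws_grid[1:])):
        raise ValueError("ws_grid must be ascending")
    target = np.asarray(target, dtype=float)
    pccs: list[float] = []
    flagged: list[int] = []
    for ws in ws_grid:
        pred = window_predict_all(model, features, ws)
        try:
            pccs.append(pearson_cc(pred, target))
        except ConstantInputError:
            pccs.append(float("nan"))
            flagged.append(ws)
    finite = [(w, p) for w, p in zip(ws_grid, pccs) if np.isfinite(p)]
    if not finite:
        raise ValueError("PCC undefined at every window span")
    plateau = finite[-1][1]
    wsc = next(w for w, p in finite if p >= plateau - plateau_tol)
    return WindowSweep(ws_grid, pccs, wsc, flagged)


# ---- Euclidean-cutoff probes ---------------------------------------------------


def masked_predict_rcut(
    model: Predictor,
    record: ProteinRecord,
    features: FeatureMatrix,
    i: int,
    rcut: float,
) -> float:
    """Prediction at residue i when residues beyond ``rcut`` Å are blanked.

    Rows farther than ``rcut`` from site i (Euclidean distance on raw Å
    coordinates) have all 28 slots replaced by zeros; sequence length and
    row positions are preserved so sequence separations stay intact.  Row
    i itself is never masked.
    """
    if rcut < 0:
        raise ValueError("rcut must be nonnegative")
    n = features.n_residues
    if not 0 <= i < n:
        raise IndexError(f"residue index {i} out of range for N={n}")
    d = np.linalg.norm(record.coordinates - record.coordinates[i], axis=1)
    vals = features.values.copy()
    vals[d > rcut] = 0.0
    vals[i] = features.values[i]
    return float(model.predict(vals)[i])


def masked_predict_all(
    model: Predictor, record: ProteinRecord, features: FeatureMatrix, rcut: float
) -> np.ndarray:
    """Masked predictions for every probe residue, batched (N sequences of
    length N, one per probed site)."""
    if rcut < 0:
        raise ValueError("rcut must be nonnegative")
    n = features.n_residues
    d = cdist(record.coordinates, record.coordinates)
    x = np.repeat(features.values[None], n, axis=0)
    x[d > rcut] = 0.0
    x[np.arange(n), np.arange(n)] = features.values
    out = model.forward_batch(x, np.full(n, n))
    return out[np.arange(n), np.arange(n)]


def rcut_sweep(
    model: Predictor,
    items: Sequence[tuple[ProteinRecord, FeatureMatrix, np.ndarray]],
    rcut_grid: Sequence[float],
) -> RcutSweep:
    """Pooled PCC of cutoff-masked predictions over an ascending rcut grid.

    ``items`` pairs each record with its encoded features and target
    profile.  At each cutoff the predictions for all residues of all
    records are pooled into one PCC; ``atoms_considered`` counts the
    surviving (i, j≠i) neighbor pairs.
    """
    grid = list(rcut_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("rcut_grid must be ascending")
    targets = np.concatenate([np.asarray(t, float) for _, _, t in items])
    # baseline through the same batched path as the masked calls, so a
    # cutoff covering every pair reproduces it bit for bit
    full_preds = np.concatenate(
        [masked_predict_all(model, r, f, np.inf) for r, f, _ in items]
    )
    pcc_all = pearson_cc(full_preds, targets)
    dists = [cdist(r.coordinates, r.coordinates) for r, _, _ in items]
    pccs: list[float] = []
    ratios: list[float] = []
    atoms: list[int] = []
    for rc in grid:
        preds = np.concatenate(
            [masked_predict_all(model, r, f, rc) for r, f, _ in items]
        )
        pcc = pearson_cc(preds, targets)
        pccs.append(pcc)
        ratios.append(pcc / pcc_all)
        atoms.append(int(sum(((d <= rc).sum() - d.shape[0]) for d in dists)))
    return RcutSweep(grid, pccs, ratios, atoms, pcc_all)


def delta_pcc_per_atom(sweep: RcutSweep) -> tuple[list[float], list[float]]:
    """Marginal PCC gain per newly admitted atom between grid points.

    Returns (midpoint distances, ΔPCC/ΔAtoms); steps with zero atom
    increment are skipped.
    """
    if len(sweep.rcut_values) < 2:
        raise ValueError("need at least 2 grid points")
    mids: list[float] = []
    ratios: list[float] = []
    any_increment = False
    for k in range(len(sweep.rcut_values) - 1):
        d_atoms = sweep.atoms_considered[k + 1] - sweep.atoms_considered[k]
        if d_atoms == 0:
            continue
        any_increment = True
        d_pcc = sweep.pcc[k + 1] - sweep.pcc[k]
        mids.append(0.5 * (sweep.rcut_values[k] + sweep.rcut_values[k + 1]))
        ratios.append(d_pcc / d_atoms)
    if not any_increment:
        raise ValueError("no atom increment anywhere on the grid")
    return mids, ratios


# ---- the n̂ neighbor statistic --------------------------------------------------


def nhat(record: ProteinRecord, rcut: float, ws: int | None = None) -> NhatCurve:
    """Normalized neighbor count: n̄/(N−1), with n_i the number of other Cα
    atoms within ``rcut`` Å of site i (and within sequence separation
    ``ws``, when given)."""
    n = record.n_residues
    if n < 2:
        raise ValueError("need at least 2 residues")
    d = cdist(record.coordinates, record.coordinates)
    within = d <= rcut
    np.fill_diagonal(within, False)
    if ws is not None:
        seq = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        within &= seq <= ws
    ni = within.sum(axis=1)
    n_bar = float(ni.mean())
    return NhatCurve(rcut=rcut, n_bar=n_bar, n_hat=n_bar / (n - 1))


def nhat_curve(record: ProteinRecord, rcut: float, ws_grid: Sequence[int]) -> np.ndarray:
    """n̂ as a function of window span at fixed cutoff radius."""
    return np.array([nhat(record, rcut, ws).n_hat for ws in ws_grid])


def pccn_vs_rcut(
    window_curves: Sequence[tuple[ProteinRecord, Sequence[int], Sequence[float]]],
    rcut_grid: Sequence[float],
) -> PccnResult:
    """Correlate each protein's n̂(ws; rcut) curve with its PCC(ws) curve.

    ``window_curves`` holds (record, ws_grid, pcc_at_ws) per protein, as
    produced by :func:`window_sweep`.  For each cutoff, PCC_n is the
    Pearson correlation of the two curves over the window grid; the mean
    over proteins is reported, along with the cutoff where it peaks.
    Proteins whose n̂ curve is constant at a given cutoff are excluded
    there and counted.
    """
    grid = list(rcut_grid)
    pccn_means: list[float] = []
    n_excluded: list[int] = []
    for rc in grid:
        vals: list[float] = []
        excluded = 0
        for record, ws_grid, pcc_curve in window_curves:
            nh = nhat_curve(record, rc, ws_grid)
            pc = np.asarray(pcc_curve, dtype=float)
            keep = np.isfinite(pc)
            if keep.sum() < 3 or np.ptp(nh[keep]) == 0 or np.ptp(pc[keep]) == 0:
                excluded += 1
                continue
            vals.append(pearson_cc(nh[keep], pc[keep]))
        pccn_means.append(float(np.mean(vals)) if vals else float("nan"))
        n_excluded.append(excluded)
    finite = [(rc, v) for rc, v in zip(grid, pccn_means) if np.isfinite(v)]
    if not finite:
        raise ValueError("PCC_n undefined at every cutoff")
    argmax_rcut = max(finite, key=lambda t: t[1])[0]
    return PccnResult(grid, pccn_means, argmax_rcut, n_excluded)


# ---- per-group summaries -------------------------------------------------------


def group_summary(
    records: Sequence[ProteinRecord],
    actual: Sequence[np.ndarray],
    predicted: Sequence[np.ndarray],
    group_by: str = "amino_acid",
) -> list[GroupSummary]:
    """Mean ± population SD of normalized B (actual and predicted), pooled
    over all residues of all records, per amino-acid type or SS class."""
    if group_by not in ("amino_acid", "ss_class"):
        raise ValueError("group_by must be 'amino_acid' or 'ss_class'")
    buckets: dict[str, list[tuple[float, float]]] = {}
    for rec, act, pred in zip(records, actual, predicted):
        keys = rec.aa_codes if group_by == "amino_acid" else rec.ss_labels
        for k, a, p in zip(keys, np.asarray(act, float), np.asarray(pred, float)):
            buckets.setdefault(k, []).append((a, p))
    out: list[GroupSummary] = []
    for key in sorted(buckets):
        arr = np.array(buckets[key])
        out.append(
            GroupSummary(
                group=key,
                mean_actual=float(arr[:, 0].mean()),
                sd_actual=float(arr[:, 0].std()),
                mean_predicted=float(arr[:, 1].mean()),
                sd_predicted=float(arr[:, 1].std()),
                count=arr.shape[0],
            )
        )
    return out


def write_sweep_table(
    path: str | Path, columns: dict[str, Sequence]
) -> None:
    """Write a sweep as a delimited text table suitable for plotting."""
    keys = list(columns)
    n = len(columns[keys[0]])
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for i in range(n):
            fh.write("\t".join(str(columns[k][i]) for k in keys) + "\n")
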