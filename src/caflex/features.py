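"""Per-protein normalization and the 28-element per-residue encoding.

Every residue is encoded as a 28-vector: slots 1–21 a one-hot over the 20
canonical amino acids plus a catch-all for anything else, slots 22–24 a
one-hot over (sheet, helix, coil), slots 25–27 the per-protein Z-scored
Cα coordinates, and slot 28 a flag marking the first and last residue of
each polypeptide chain.  Feature groups (PS / SS / CoI / ChI) can be
disabled independently for ablation studies; a disabled group is zeroed.

B factors and coordinates are standardized per protein: the Z-score uses
the protein's own mean and *population* standard deviation (divisor N), so
a normalized profile always has mean 0 and SD 1 regardless of the
resolution the structure was solved at.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .structures_io import ProteinRecord

__all__ = [
    "NormStats",
    "FeatureMask",
    "FeatureMatrix",
    "CANONICAL_AA",
    "compute_norm_stats",
    "normalize_bfactors",
    "normalize_coordinates",
    "encode_protein",
    "apply_mask",
    "write_encoding_manifest",
]

#: canonical 20 amino acids, three-letter codes ordered alphabetically by
#: one-letter code (A C D E F G H I K L M N P Q R S T V W Y); slot 21 is
#: the catch-all for every other residue name.
CANONICAL_AA = (
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
)
_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: SS one-hot slot order within slots 22-24
SS_ORDER = ("sheet", "helix", "coil")

N_FEATURES = 28
_PS = slice(0, 21)
_SS = slice(21, 24)
_COI = slice(24, 27)
_CHI = 27

#: fixed scale for conditioning raw-B targets in unnormalized mode; equals
#: the curation ceiling, so scaled targets sit in (0, 1].
RAW_B_SCALE = 80.0


class DegenerateProteinError(ValueError):
    """A per-protein standard deviation is zero; the Z-score is undefined."""


@dataclasses.dataclass
class NormStats:
    """Per-protein means and population SDs of B factors and coordinates."""

    mu_b: float
    sigma_b: float
    mu_x: float
    mu_y: float
    mu_z: float
    sigma_x: float
    sigma_y: float
    sigma_z: float


@dataclasses.dataclass(frozen=True)
class FeatureMask:
    """Which feature groups are active: primary sequence, secondary
    structure, coordinate information, chain start/end information."""

    use_ps: bool = True
    use_ss: bool = True
    use_coi: bool = True
    use_chi: bool = True

    def __post_init__(self) -> None:
        if not (self.use_ps or self.use_ss or self.use_coi or self.use_chi):
            raise ValueError("at least one feature group must be active")

    def as_dict(self) -> dict[str, bool]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class FeatureMatrix:
    """N×28 per-residue encoding plus the mask it was built with."""

    values: np.ndarray
    mask: FeatureMask
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be N×{N_FEATURES}")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def compute_norm_stats(record: ProteinRecord) -> NormStats:
    """Means and population SDs (divisor N) of B and each coordinate axis."""
    b = record.b_factors
    xyz = record.coordinates
    sig_b = float(b.std())  # numpy default ddof=0: population SD
    sig_xyz = xyz.std(axis=0)
    if sig_b == 0.0 or np.any(sig_xyz == 0.0):
        raise DegenerateProteinError(
            f"{record.protein_id}: zero variance in B or a coordinate axis"
        )
    return NormStats(
        mu_b=float(b.mean()),
        sigma_b=sig_b,
        mu_x=float(xyz[:, 0].mean()),
        mu_y=float(xyz[:, 1].mean()),
        mu_z=float(xyz[:, 2].mean()),
        sigma_x=float(sig_xyz[0]),
        sigma_y=float(sig_xyz[1]),
        sigma_z=float(sig_xyz[2]),
    )


def normalize_bfactors(record: ProteinRecord, stats: NormStats | None = None) -> np.ndarray:
    """Per-protein Z-score of the B-factor profile, B̂ = (B − μ_B)/σ_B."""
    if stats is None:
        stats = compute_norm_stats(record)
    if stats.sigma_b <= 0:
        raise DegenerateProteinError("sigma_b must be positive")
    return (record.b_factors - stats.mu_b) / stats.sigma_b


def normalize_coordinates(record: ProteinRecord, stats: NormStats | None = None) -> np.ndarray:
    """Per-axis Z-score of the Cα coordinates (each axis independently)."""
    if stats is None:
        stats = compute_norm_stats(record)
    xyz = record.coordinates
    mu = np.array([stats.mu_x, stats.mu_y, stats.mu_z])
    sigma = np.array([stats.sigma_x, stats.sigma_y, stats.sigma_z])
    if np.any(sigma <= 0):
        raise DegenerateProteinError("coordinate sigmas must be positive")
    return (xyz - mu) / sigma


def _chain_flags(record: ProteinRecord) -> np.ndarray:
    """1 at the first and last residue of every chain, else 0."""
    flags = np.zeros(record.n_residues)
    chains = record.chain_ids
    for i in range(record.n_residues):
        first = i == 0 or chains[i] != chains[i - 1]
        last = i == record.n_residues - 1 or chains[i] != chains[i + 1]
        if first or last:
            flags[i] = 1.0
    return flags


def encode_protein(
    record: ProteinRecord,
    mask: FeatureMask = FeatureMask(),
    b_mode: str = "normalized",
) -> tuple[FeatureMatrix, np.ndarray]:
    """Build the N×28 feature matrix and the regression target.

    The target is the Z-scored B profile in ``normalized`` mode, or the raw
    B in Å² divided by :data:`RAW_B_SCALE` in ``unnormalized`` mode
    (predictions are rescaled back on output; the division only conditions
    the optimization).
    """
    if b_mode not in ("normalized", "unnormalized"):
        raise ValueError(f"unknown b_mode {b_mode!r}")
    n = record.n_residues
    vals = np.zeros((n, N_FEATURES))
    if mask.use_ps:
        for i, aa in enumerate(record.aa_codes):
            vals[i, _AA_INDEX.get(aa, 20)] = 1.0
    if mask.use_ss:
        for i, ss in enumerate(record.ss_labels):
            if ss == "unassigned":
                raise ValueError(
                    f"{record.protein_id}: SS requested but residue {i} unassigned"
                )
            vals[i, 21 + SS_ORDER.index(ss)] = 1.0
    if mask.use_coi:
        vals[:, _COI] = normalize_coordinates(record)
    if mask.use_chi:
        vals[:, _CHI] = _chain_flags(record)
    if b_mode == "normalized":
        target = normalize_bfactors(record)
    else:
        target = record.b_factors / RAW_B_SCALE
    return FeatureMatrix(vals, mask, record.protein_id), target


def apply_mask(features: FeatureMatrix, mask: FeatureMask) -> FeatureMatrix:
    """Zero out feature groups to realize a more restrictive mask."""
    vals = features.values.copy()
    if not mask.use_ps:
        vals[:, _PS] = 0.0
    if not mask.use_ss:
        vals[:, _SS] = 0.0
    if not mask.use_coi:
        vals[:, _COI] = 0.0
    if not mask.use_chi:
        vals[:, _CHI] = 0.0
    return FeatureMatrix(vals, mask, features.protein_id)


def write_encoding_manifest(
    encoded: Iterable[tuple[FeatureMatrix, np.ndarray]], path: str | Path
) -> None:
    """One JSON record per protein: id, mask, N, row-major values, targets."""
    with open(path, "w") as fh:
        for feats, target in encoded:
            rec = {
                "protein_id": feats.protein_id,
                "mask": feats.mask.as_dict(),
                "n_residues": feats.n_residues,
                "values": feats.values.ravel().tolist(),
                "targets": np.asarray(target).tolist(),
            }
            fh.write(json.dumps(rec) + "\n")
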