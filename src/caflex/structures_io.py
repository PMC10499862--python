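"""Cα-level structure I/O, secondary-structure assignment, curation and splits.

Reads fixed-column PDB files down to one :class:`ResidueSite` per Cα atom,
assigns three-class secondary structure from Cα geometry alone (P-SEA-style
distance/angle windows, via biotite), applies the four curation filters used
to build the training corpus, and produces deterministic train/val/test
splits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bstruc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ResidueSite",
    "ProteinRecord",
    "CurationDecision",
    "DatasetSplit",
    "read_structure",
    "write_structure",
    "assign_secondary_structure",
    "read_ss_sidecar",
    "curate_protein",
    "write_curation_audit",
    "split_dataset",
    "write_manifest",
    "read_manifest",
]

SS_LABELS = ("helix", "sheet", "coil", "unassigned")

#: biotite/P-SEA one-letter codes -> our three-class labels
_SSE_MAP = {"a": "helix", "b": "sheet", "c": "coil"}


@dataclasses.dataclass
class ResidueSite:
    """One Cα site: identity, position, B factor, chain and SS label."""

    aa_code: str  # three-letter residue name, e.g. "ALA"
    x: float
    y: float
    z: float
    b_factor: float  # Å², as deposited (un-normalized)
    chain_id: str
    ss_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("coordinates must be finite")
        if self.ss_label not in SS_LABELS:
            raise ValueError(f"bad ss_label {self.ss_label!r}")


@dataclasses.dataclass
class ProteinRecord:
    """An ordered list of Cα sites for one protein (chains concatenated)."""

    protein_id: str
    sites: list[ResidueSite]

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("a ProteinRecord needs at least one site")
        seen: list[str] = []
        for s in self.sites:
            if not seen or seen[-1] != s.chain_id:
                if s.chain_id in seen:
                    raise ValueError("sites of one chain must be contiguous")
                seen.append(s.chain_id)

    @property
    def n_residues(self) -> int:
        return len(self.sites)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) raw Cα coordinates in Å."""
        return np.array([[s.x, s.y, s.z] for s in self.sites], dtype=float)

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([s.b_factor for s in self.sites], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        return [s.chain_id for s in self.sites]

    @property
    def aa_codes(self) -> list[str]:
        return [s.aa_code for s in self.sites]

    @property
    def ss_labels(self) -> list[str]:
        return [s.ss_label for s in self.sites]


@dataclasses.dataclass
class CurationDecision:
    accepted: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted must be true iff reasons is empty")


@dataclasses.dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int


class EmptyProteinError(ValueError):
    """Raised when a structure file contains no Cα atoms."""


def read_structure(path: str | Path, protein_id: str | None = None) -> ProteinRecord:
    """Read a local PDB file into a :class:`ProteinRecord`.

    One site per Cα ATOM record, in file order; alternate locations resolve
    to the first-listed altloc; HETATM records are ignored; only MODEL 1 of
    multi-model (e.g. NMR) files is used.  ``ss_label`` starts out
    ``unassigned``.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, altloc="first", extra_fields=["b_factor"])
    except ValueError as err:  # no coordinate block at all
        raise EmptyProteinError(f"{path}: no Cα ATOM records") from err
    mask = (arr.atom_name == "CA") & ~arr.hetero
    arr = arr[mask]
    if arr.array_length() == 0:
        raise EmptyProteinError(f"{path}: no Cα ATOM records")
    sites = [
        ResidueSite(
            aa_code=str(arr.res_name[i]),
            x=float(arr.coord[i, 0]),
            y=float(arr.coord[i, 1]),
            z=float(arr.coord[i, 2]),
            b_factor=float(arr.b_factor[i]),
            chain_id=str(arr.chain_id[i]),
        )
        for i in range(arr.array_length())
    ]
    return ProteinRecord(protein_id or path.stem, sites)


def write_structure(record: ProteinRecord, path: str | Path) -> None:
    """Serialize a record as fixed-column PDB ATOM lines (Cα only).

    Round-trips through :func:`read_structure` at the precision of the PDB
    format: coordinates to 3 decimals, B factors to 2.
    """
    n = record.n_residues
    arr = bstruc.AtomArray(n)
    arr.coord = record.coordinates.astype(np.float32)
    arr.chain_id = np.array([s.chain_id for s in record.sites])
    arr.res_name = np.array([s.aa_code for s in record.sites])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    # residue numbering restarts per chain so biotite's continuity check
    # keeps chains separate
    res_id = np.empty(n, dtype=int)
    counter = 0
    prev_chain = None
    for i, s in enumerate(record.sites):
        counter = counter + 1 if s.chain_id == prev_chain else 1
        res_id[i] = counter
        prev_chain = s.chain_id
    arr.res_id = res_id
    arr.set_annotation("b_factor", record.b_factors.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _record_to_atom_array(record: ProteinRecord) -> bstruc.AtomArray:
    n = record.n_residues
    arr = bstruc.AtomArray(n)
    arr.coord = record.coordinates.astype(np.float32)
    arr.chain_id = np.array([s.chain_id for s in record.sites])
    arr.res_name = np.full(n, "ALA")  # identity irrelevant for Cα geometry
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    res_id = np.empty(n, dtype=int)
    counter = 0
    prev = None
    for i, s in enumerate(record.sites):
        counter = counter + 1 if s.chain_id == prev else 1
        res_id[i] = counter
        prev = s.chain_id
    arr.res_id = res_id
    return arr


def assign_secondary_structure(record: ProteinRecord) -> ProteinRecord:
    """Assign three-class SS labels from Cα geometry (P-SEA-style).

    Uses only Cα–Cα distances d(i,i+2..4) and pseudo bond/dihedral angles,
    evaluated per chain; chains shorter than 6 residues and anything not
    matching a helix or strand window fall through to coil.  Deterministic
    for fixed coordinates and invariant under rigid-body motion.
    """
    new_sites = [dataclasses.replace(s) for s in record.sites]
    # group contiguous chains
    start = 0
    for end in range(1, record.n_residues + 1):
        if end == record.n_residues or new_sites[end].chain_id != new_sites[start].chain_id:
            chain = ProteinRecord(record.protein_id, [dataclasses.replace(s) for s in record.sites[start:end]])
            if chain.n_residues <= 5:
                labels = ["coil"] * chain.n_residues
            else:
                sse = bstruc.annotate_sse(_record_to_atom_array(chain))
                labels = [_SSE_MAP.get(str(c), "coil") for c in sse]
            for i, lab in enumerate(labels):
                new_sites[start + i].ss_label = lab
            start = end
    return ProteinRecord(record.protein_id, new_sites)


def read_ss_sidecar(record: ProteinRecord, path: str | Path) -> ProteinRecord:
    """Apply precomputed SS labels from a two-column sidecar file.

    Each line: ``<residue index (1-based)> <label in {H,E,C}>``.
    """
    lab_map = {"H": "helix", "E": "sheet", "C": "coil"}
    sites = [dataclasses.replace(s) for s in record.sites]
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx_s, lab = line.split()
        sites[int(idx_s) - 1].ss_label = lab_map[lab]
    return ProteinRecord(record.protein_id, sites)


def curate_protein(
    record: ProteinRecord, max_b: float = 80.0, max_len: int = 500
) -> CurationDecision:
    """Apply the four corpus filters to one protein.

    Rejects if any Cα B factor exceeds ``max_b`` Å², if any is ≤ 0, if all
    B factors are exactly equal (unphysical, indicates a placeholder), or if
    the protein exceeds ``max_len`` residues.  All violated rules are
    reported, not just the first.
    """
    b = record.b_factors
    reasons = []
    if np.any(b > max_b):
        reasons.append("b_above_max")
    if np.any(b <= 0):
        reasons.append("b_nonpositive")
    if record.n_residues > 1 and np.all(b == b[0]):
        reasons.append("b_constant")
    if record.n_residues > max_len:
        reasons.append("too_long")
    return CurationDecision(accepted=not reasons, reasons=reasons)


def write_curation_audit(
    decisions: Iterable[tuple[str, CurationDecision]], path: str | Path
) -> None:
    """Write a delimited audit: protein_id, accepted, semicolon-joined reasons."""
    with open(path, "w") as fh:
        fh.write("protein_id\taccepted\treasons\n")
        for pid, dec in decisions:
            fh.write(f"{pid}\t{int(dec.accepted)}\t{';'.join(dec.reasons)}\n")


def split_dataset(
    ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.92, 0.04, 0.04),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministically partition protein ids into train/validation/test.

    Sizes are the rounded fractions with any remainder assigned to train.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    n = len(ids)
    n_val = int(round(fr[1] * n))
    n_test = int(round(fr[2] * n))
    n_train = n - n_val - n_test
    if n < sum(f > 0 for f in fr):
        raise ValueError("fewer ids than nonzero partitions")
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("rounding produced a negative partition")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    return DatasetSplit(
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
        seed=seed,
    )


def write_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Write a dataset manifest: one JSON record per line."""
    with open(path, "w") as fh:
        for part in ("train", "validation", "test"):
            for pid in getattr(split, part):
                fh.write(json.dumps({"protein_id": pid, "split": part}) + "\n")
        fh.write(json.dumps({"seed": split.seed, "split": "_meta"}) + "\n")


def read_manifest(path: str | Path) -> DatasetSplit:
    parts: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    seed = 0
    for line in Path(path).read_text().splitlines():
        rec = json.loads(line)
        if rec["split"] == "_meta":
            seed = rec["seed"]
        else:
            parts[rec["split"]].append(rec["protein_id"])
    return DatasetSplit(seed=seed, **parts)
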