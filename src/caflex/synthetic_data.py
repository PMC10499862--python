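"""Synthetic Cα chains with a known local-packing ("caging") flexibility law.

Generates curated-looking protein records entirely in memory: chains are
built from ideal helix / strand / coil segments (realistic 3.8 Å virtual
Cα–Cα bonds, excluded volume between non-bonded sites), and each residue's
B factor is derived from how strongly it is caged by its spatial
neighbors — the contact count within a generative radius ``r_star`` — with
additive Gaussian noise.  Residue identities are drawn with hydrophobic
types enriched at high-contact (buried) sites, mimicking the real tendency
of hydrophobic residues to sit in the ordered core.

Because the ground truth (contact counts, clean normalized B, ``r_star``)
is known exactly, every downstream analysis — training, evaluation, the
window and cutoff-radius sweeps, the n̂ statistic — can be validated as a
parameter-recovery exercise with no structure downloads.  The generative
law is synthetic: it mirrors the caging physics qualitatively, not any
fitted empirical model.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structures_io import CurationDecision, ProteinRecord, ResidueSite, curate_protein

__all__ = [
    "SyntheticConfig",
    "GenerationError",
    "generate_chain",
    "generate_dataset",
    "make_curation_fixtures",
    "contact_counts",
]

HYDROPHOBIC = ("ALA", "VAL", "PHE", "ILE", "LEU", "MET", "TRP")
POLAR = ("ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
         "LYS", "PRO", "SER", "THR", "TYR")

#: geometry of the ideal segment classes: (rise per residue Å, twist deg);
#: the helix radius is solved so the virtual bond equals the configured
#: bond length.  A strand is a 2-residue-per-turn "helix" with ~3.3 Å rise,
#: which lands inside the P-SEA strand distance windows.
_SEGMENT_GEOMETRY = {"helix": (1.5, 100.0), "sheet": (3.3, 190.0)}


class GenerationError(RuntimeError):
    pass


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    ``r_star`` is the generative caging radius: contacts within it set the
    clean flexibility profile.  ``noise_sd`` is the SD of Gaussian noise
    added on the standardized (unit-SD) profile, so it is directly the
    noise-to-signal ratio.
    """

    n_min: int = 60
    n_max: int = 200
    r_star: float = 8.0
    noise_sd: float = 0.3
    helix_frac: float = 0.35
    sheet_frac: float = 0.25
    n_chains: int = 1
    bond_length: float = 3.8
    excluded_volume: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_max > 500:
            raise ValueError("n_max must respect the 500-residue curation cap")
        if self.n_min < 2 or self.n_min > self.n_max:
            raise ValueError("need 2 <= n_min <= n_max")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.helix_frac < 0 or self.sheet_frac < 0 or self.helix_frac + self.sheet_frac > 1:
            raise ValueError("SS fractions must be nonnegative and sum to <= 1")


def _segment_template(kind: str, n_points: int, bond: float) -> np.ndarray:
    """Ideal local geometry for one segment, first point at the origin."""
    if kind in _SEGMENT_GEOMETRY:
        rise, twist_deg = _SEGMENT_GEOMETRY[kind]
        tw = math.radians(twist_deg)
        radius = math.sqrt(bond**2 - rise**2) / (2.0 * math.sin(tw / 2.0))
        t = np.arange(n_points)
        pts = np.stack(
            [radius * np.cos(tw * t), radius * np.sin(tw * t), rise * t], axis=1
        )
        return pts - pts[0]
    raise ValueError(kind)


def _coil_template(n_points: int, bond: float, rng: np.random.Generator) -> np.ndarray:
    """Random open turn: successive bonds bend by 20–75 degrees."""
    pts = [np.zeros(3)]
    d = np.array([1.0, 0.0, 0.0])
    for _ in range(n_points - 1):
        bend = math.radians(rng.uniform(20.0, 75.0))
        perp = np.cross(d, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        d = Rotation.from_rotvec(bend * perp).apply(d)
        pts.append(pts[-1] + bond * d)
    return np.array(pts)


def _orient_template(
    template: np.ndarray,
    anchor: np.ndarray,
    prev_dir: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rotate a template so its first bond leaves the anchor within an
    80-degree cone of the previous bond direction, with a random spin."""
    first = template[1] - template[0]
    first = first / np.linalg.norm(first)
    if prev_dir is None:
        target = rng.normal(size=3)
    else:
        # sample a direction within the cone around prev_dir
        cos_max = math.cos(math.radians(80.0))
        z = rng.uniform(cos_max, 1.0)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        s = math.sqrt(1.0 - z * z)
        local = np.array([s * math.cos(phi), s * math.sin(phi), z])
        rot_to_prev, _ = Rotation.align_vectors(prev_dir[None], np.array([[0.0, 0.0, 1.0]]))
        target = rot_to_prev.apply(local)
    target = target / np.linalg.norm(target)
    base, _ = Rotation.align_vectors(target[None], first[None])
    spin = Rotation.from_rotvec(rng.uniform(0.0, 2.0 * math.pi) * target)
    rotated = (spin * base).apply(template - template[0])
    return rotated + anchor


def _segment_plan(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Sequence of (kind, length) covering n residues with roughly the
    target helix/sheet/coil composition."""
    coil_frac = 1.0 - cfg.helix_frac - cfg.sheet_frac
    kinds = ("helix", "sheet", "coil")
    probs = np.array([cfg.helix_frac, cfg.sheet_frac, coil_frac])
    length_range = {"helix": (7, 15), "sheet": (6, 10), "coil": (3, 8)}
    # weight by inverse mean segment length so *residue* fractions track targets
    mean_len = np.array([np.mean(length_range[k]) for k in kinds])
    w = probs / mean_len
    w = w / w.sum()
    plan: list[tuple[str, int]] = []
    left = n
    while left > 0:
        kind = kinds[rng.choice(3, p=w)]
        lo, hi = length_range[kind]
        seg = int(min(left, rng.integers(lo, hi + 1)))
        if left - seg in (1, 2):  # avoid a dangling 1-2 residue tail
            seg = left
        plan.append((kind, seg))
        left -= seg
    return plan


def _grow_chain(
    n: int,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    existing: np.ndarray | None,
    start_anchor: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    """Grow one chain of n residues; returns coordinates and SS labels."""
    for _attempt in range(40):
        plan = _segment_plan(n, cfg, rng)
        coords = np.empty((0, 3))
        labels: list[str] = []
        prev_dir: np.ndarray | None = None
        ok = True
        for kind, seg_len in plan:
            # the first point of a segment template coincides with the
            # current chain end (or the chain anchor for the first segment)
            n_pts = seg_len + (0 if coords.shape[0] == 0 else 1)
            placed = None
            for _try in range(60):
                if kind == "coil":
                    template = _coil_template(max(n_pts, 2), cfg.bond_length, rng)
                else:
                    template = _segment_template(kind, max(n_pts, 2), cfg.bond_length)
                anchor = start_anchor if coords.shape[0] == 0 else coords[-1]
                oriented = _orient_template(template[:n_pts], anchor, prev_dir, rng)
                new_pts = oriented if coords.shape[0] == 0 else oriented[1:]
                # excluded volume: new points vs all points >=2 bonds away
                clash = False
                check_against = (
                    coords[:-1] if coords.shape[0] > 1 else np.empty((0, 3))
                )
                if existing is not None and existing.size:
                    check_against = np.vstack([check_against, existing])
                if check_against.shape[0] and new_pts.shape[0]:
                    if cdist(new_pts, check_against).min() < cfg.excluded_volume:
                        clash = True
                if not clash and new_pts.shape[0] >= 3:
                    d_self = cdist(new_pts, new_pts)
                    iu = np.triu_indices(new_pts.shape[0], k=2)
                    if d_self[iu].size and d_self[iu].min() < cfg.excluded_volume:
                        clash = True
                if not clash:
                    placed = new_pts
                    break
            if placed is None:
                ok = False
                break
            coords = np.vstack([coords, placed]) if coords.size else placed
            labels.extend([kind if kind != "sheet" else "sheet"] * seg_len)
            prev_dir = coords[-1] - coords[-2]
            prev_dir = prev_dir / np.linalg.norm(prev_dir)
        if ok and coords.shape[0] == n:
            return coords, labels
    raise GenerationError("excluded-volume retry budget exhausted")


def contact_counts(coords: np.ndarray, radius: float) -> np.ndarray:
    """Number of *other* Cα atoms within ``radius`` of each site."""
    d = cdist(coords, coords)
    return (d <= radius).sum(axis=1) - 1


def generate_chain(
    cfg: SyntheticConfig, seed: int, return_truth: bool = False
) -> ProteinRecord | tuple[ProteinRecord, dict]:
    """Generate one curated-by-construction synthetic protein.

    B factors follow the caging law: the clean standardized profile is the
    negated Z-score of the contact count within ``cfg.r_star`` (densely
    caged sites fluctuate least), plus Gaussian noise of SD
    ``cfg.noise_sd``; raw B is the fixed affine map ``40 + 10·B̂`` clipped
    to [5, 75] Å², safely inside the curation bounds.
    """
    rng = np.random.default_rng(seed)
    n_total = int(rng.integers(cfg.n_min, cfg.n_max + 1))
    # split residues across chains (each chain at least 6 residues)
    n_chains = min(cfg.n_chains, max(1, n_total // 6))
    cuts = np.sort(rng.choice(np.arange(6, n_total - 5), size=n_chains - 1, replace=False)) if n_chains > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [n_total]])).astype(int)

    all_coords = np.empty((0, 3))
    all_labels: list[str] = []
    chain_ids: list[str] = []
    for ci, size in enumerate(sizes):
        if all_coords.shape[0] == 0:
            anchor = np.zeros(3)
        else:
            # start the next chain near (but clear of) the existing body
            base = all_coords[rng.integers(all_coords.shape[0])]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            anchor = base + direction * (cfg.excluded_volume + 2.0)
        coords, labels = _grow_chain(int(size), cfg, rng, all_coords if all_coords.size else None, anchor)
        all_coords = np.vstack([all_coords, coords]) if all_coords.size else coords
        all_labels.extend(labels)
        chain_ids.extend([chr(ord("A") + ci)] * int(size))

    c = contact_counts(all_coords, cfg.r_star)
    c_sd = c.std()
    clean = -(c - c.mean()) / c_sd if c_sd > 0 else np.zeros(n_total)
    bhat = clean + rng.normal(0.0, cfg.noise_sd, size=n_total)
    raw_b = np.clip(40.0 + 10.0 * bhat, 5.0, 75.0)

    # hydrophobics enriched at strongly caged (high-contact) sites
    order = np.argsort(np.argsort(c))
    p_hydro = 0.2 + 0.5 * order / max(n_total - 1, 1)
    aa_codes = []
    for i in range(n_total):
        if rng.random() < 0.01:
            aa_codes.append("MSE")  # occasional non-canonical residue
        elif rng.random() < p_hydro[i]:
            aa_codes.append(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))])
        else:
            aa_codes.append(POLAR[rng.integers(len(POLAR))])

    sites = [
        ResidueSite(
            aa_code=aa_codes[i],
            x=float(all_coords[i, 0]),
            y=float(all_coords[i, 1]),
            z=float(all_coords[i, 2]),
            b_factor=float(round(raw_b[i], 2)),
            chain_id=chain_ids[i],
            ss_label=all_labels[i],
        )
        for i in range(n_total)
    ]
    record = ProteinRecord(f"syn{seed:08d}", sites)
    decision = curate_protein(record)
    if not decision.accepted:
        raise GenerationError(f"generated record failed curation: {decision.reasons}")
    if return_truth:
        truth = {
            "contact_counts": c,
            "clean_bhat": clean,
            "r_star": cfg.r_star,
            "seed": seed,
        }
        return record, truth
    return record


def generate_dataset(
    cfg: SyntheticConfig, n_proteins: int, seed: int
) -> tuple[list[ProteinRecord], dict]:
    """Generate a reproducible corpus plus a ground-truth manifest."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    root = np.random.default_rng(seed)
    # per-protein seeds derived reproducibly from the corpus seed
    child_seeds = root.integers(0, 2**31 - 1, size=n_proteins)
    records: list[ProteinRecord] = []
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "corpus_seed": seed,
        "proteins": [],
    }
    for s in child_seeds:
        rec, truth = generate_chain(cfg, int(s), return_truth=True)
        records.append(rec)
        manifest["proteins"].append(
            {
                "protein_id": rec.protein_id,
                "seed": int(s),
                "n_residues": rec.n_residues,
                "contact_counts": truth["contact_counts"].tolist(),
                "clean_bhat": truth["clean_bhat"].tolist(),
            }
        )
    return records, manifest


def make_curation_fixtures() -> list[tuple[ProteinRecord, CurationDecision]]:
    """Five labeled records: one per curation violation plus one clean."""

    def _trace(n: int) -> np.ndarray:
        return _segment_template("helix", n, 3.8)

    def _record(pid: str, n: int, b: Sequence[float]) -> ProteinRecord:
        xyz = _trace(n)
        return ProteinRecord(
            pid,
            [
                ResidueSite("ALA", *map(float, xyz[i]), b_factor=float(b[i]),
                            chain_id="A", ss_label="unassigned")
                for i in range(n)
            ],
        )

    base = [20.0 + 10.0 * math.sin(i / 3.0) for i in range(501)]
    fixtures = [
        (_record("fix_b_above_max", 30, [25.0] * 29 + [85.0]),
         CurationDecision(False, ["b_above_max"])),
        (_record("fix_b_nonpositive", 30, [25.0] * 29 + [0.0]),
         CurationDecision(False, ["b_nonpositive"])),
        (_record("fix_b_constant", 30, [20.0] * 30),
         CurationDecision(False, ["b_constant"])),
        (_record("fix_too_long", 501, base),
         CurationDecision(False, ["too_long"])),
        (_record("fix_clean", 30, base[:30]),
         CurationDecision(True, [])),
    ]
    return fixtures
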