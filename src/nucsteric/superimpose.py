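"""Rigid-body superimposition and steric-clash profiling.

For every contiguous placement of the enzyme-bound DNA segment along the
nucleosomal DNA, the deoxyribose-backbone coordinates of the probe are
fitted onto the nucleosomal window with the RMSD-minimizing proper
rotation (Kabsch), the transform is applied to the whole probe complex,
and the fraction of enzyme atoms sterically overlapping histone atoms
(``d < r1 + r2`` on van der Waals radii) is recorded.  The resulting
clash percentage as a function of mapping position is the accessibility
profile; its dominant periodicity reflects the helical twist of the
wrapped DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import (
    AtomRecord,
    BasePairFrame,
    BACKBONE_ATOMS,
    BONDI_RADII,
    DEFAULT_VDW_RADIUS,
    PairingError,
    SelectionError,
    StructureModel,
    select_backbone,
)

__all__ = [
    "RigidTransform",
    "ClashParams",
    "ClashProfile",
    "DegenerateGeometryError",
    "kabsch_fit",
    "enumerate_mappings",
    "clash_fraction",
    "compute_clash_profile",
    "profile_periodicity",
]


class DegenerateGeometryError(ValueError):
    """Raised for collinear/degenerate point sets or constant profiles."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation minimizing least-squares deviation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_fit(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """RMSD-minimizing rigid transform mapping ``moving`` onto ``fixed``.

    Uses the SVD of the covariance matrix with reflection correction so
    the returned rotation is always proper (det = +1).
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape:
        raise PairingError(f"point counts differ: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise PairingError("need >= 3 paired 3D points")
    cm, cf = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cm, Q - cf
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateGeometryError("moving points are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def enumerate_mappings(n_bp: int, probe_len: int) -> list[tuple[int, int]]:
    """All contiguous 1-based inclusive windows of ``probe_len`` bp.

    A probe alignment segment of L bp slid along N bp of nucleosomal DNA
    yields N - L + 1 placements (147 bp and a 12-bp segment give 136).
    """
    if probe_len <= 0 or n_bp <= 0:
        raise ValueError("lengths must be positive")
    if probe_len > n_bp:
        raise ValueError(f"probe_len {probe_len} exceeds n_bp {n_bp}")
    return [(s, s + probe_len - 1) for s in range(1, n_bp - probe_len + 2)]


@dataclass
class ClashParams:
    """Atom selection and radii for clash counting.

    Scored atoms default to protein class on both sides: the enzyme atoms
    of the probe complex against the nucleosome atoms excluding DNA.
    Hydrogens are excluded by default (crystal structures typically lack
    them; mixing would bias the normalization).
    """

    vdw: Mapping[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    include_hydrogens: bool = False
    default_radius: float | None = DEFAULT_VDW_RADIUS
    probe_selector: Callable[[AtomRecord], bool] | None = None
    target_selector: Callable[[AtomRecord], bool] | None = None

    def _keep(self, atom: AtomRecord, selector) -> bool:
        if not self.include_hydrogens and atom.element.upper() == "H":
            return False
        if selector is not None:
            return selector(atom)
        return atom.polymer_class == "protein"

    def probe_atoms(self, model: StructureModel) -> list[AtomRecord]:
        sel = [a for a in model.atoms if self._keep(a, self.probe_selector)]
        if not sel:
            raise SelectionError("probe selector matched no atoms")
        return sel

    def target_atoms(self, model: StructureModel) -> list[AtomRecord]:
        sel = [a for a in model.atoms if self._keep(a, self.target_selector)]
        if not sel:
            raise SelectionError("target selector matched no atoms")
        return sel

    def radius(self, element: str) -> float:
        key = element.upper()
        if key in self.vdw:
            return self.vdw[key]
        if self.default_radius is not None:
            return self.default_radius
        raise KeyError(f"no van der Waals radius for element {element!r}")


def _radii(elements: Sequence[str], params: ClashParams) -> np.ndarray:
    return np.array([params.radius(e) for e in elements], dtype=float)


def clash_fraction(
    probe_coords: np.ndarray,
    probe_elements: Sequence[str],
    target_coords: np.ndarray,
    target_elements: Sequence[str],
    params: ClashParams | None = None,
    target_tree: cKDTree | None = None,
    method: str = "tree",
) -> float:
    """Percentage of probe atoms with >= 1 target atom at ``d < r1 + r2``.

    The KD-tree path returns a candidate superset (ball radius r1 + max r2)
    and applies the exact per-pair criterion on squared distances, so the
    result equals the all-pairs brute force bit for bit.
    """
    params = params or ClashParams()
    P = np.asarray(probe_coords, float)
    T = np.asarray(target_coords, float)
    if len(P) == 0 or len(T) == 0:
        raise ValueError("probe and target atom sets must be non-empty")
    r1 = _radii(probe_elements, params)
    r2 = _radii(target_elements, params)
    if method == "brute":
        d2 = np.sum((P[:, None, :] - T[None, :, :]) ** 2, axis=2)
        cut2 = (r1[:, None] + r2[None, :]) ** 2
        clashing = np.any(d2 < cut2, axis=1)
        return 100.0 * float(np.count_nonzero(clashing)) / len(P)
    tree = target_tree if target_tree is not None else cKDTree(T)
    r2max = float(r2.max())
    hits = tree.query_ball_point(P, r1 + r2max)
    n_clash = 0
    for i, cand in enumerate(hits):
        if not cand:
            continue
        cand = np.asarray(cand, dtype=int)
        d2 = np.sum((T[cand] - P[i]) ** 2, axis=1)
        if np.any(d2 < (r1[i] + r2[cand]) ** 2):
            n_clash += 1
    return 100.0 * n_clash / len(P)


def _frame_coord_map(
    frames: Sequence[BasePairFrame], offset_base: int
) -> dict[tuple[int, int, str], np.ndarray]:
    """Key backbone coordinates by (frame offset, strand, atom name)."""
    out: dict[tuple[int, int, str], np.ndarray] = {}
    for k, frame in enumerate(frames):
        for strand, atoms in ((1, frame.strand1_atoms), (2, frame.strand2_atoms)):
            for a in atoms:
                out[(k + offset_base, strand, a.name)] = a.coords
    return out


@dataclass
class ClashProfile:
    """Per-mapping-position clash percentage and alignment RMSD."""

    positions: np.ndarray
    clash_pct: np.ndarray
    rmsd: np.ndarray
    n_probe_atoms: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.clash_pct = np.asarray(self.clash_pct, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if not (len(self.positions) == len(self.clash_pct) == len(self.rmsd)):
            raise ValueError("profile arrays must have equal length")
        if np.any(self.clash_pct < 0) or np.any(self.clash_pct > 100):
            raise ValueError("clash_pct must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "clash_pct": self.clash_pct, "rmsd": self.rmsd}
        )

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_probe_atoms: int = 0) -> "ClashProfile":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            positions=df["position"].to_numpy(),
            clash_pct=df["clash_pct"].to_numpy(),
            rmsd=df["rmsd"].to_numpy(),
            n_probe_atoms=n_probe_atoms,
        )


def compute_clash_profile(
    nucleosome: StructureModel,
    probe_complex: StructureModel,
    nuc_bp_range: tuple[int, int] | None = None,
    probe_bp_range: tuple[int, int] = (4, 15),
    params: ClashParams | None = None,
    nuc_chain_pair: tuple[str, str] | None = None,
    probe_chain_pair: tuple[str, str] | None = None,
    min_atoms_per_nucleotide: int = 4,
    pose_writer: Callable[[int, StructureModel], None] | None = None,
) -> ClashProfile:
    """Slide the probe's alignment segment along the nucleosomal DNA.

    For each of the ``N - L + 1`` mappings, the probe backbone (both
    strands, atoms matched across structures by base-pair offset, strand
    and atom name) is Kabsch-fitted onto the nucleosomal window, the
    transform is applied to the entire probe complex, and the clash
    fraction of the scored probe atoms against the scored nucleosome
    atoms is recorded.  Profile position j corresponds to the mapping
    whose first nucleosomal base pair is j (1-based).
    """
    params = params or ClashParams()
    nuc_frames = select_backbone(nucleosome, nuc_chain_pair, nuc_bp_range)
    probe_frames = select_backbone(probe_complex, probe_chain_pair, probe_bp_range)
    L = len(probe_frames)
    N = len(nuc_frames)
    if L > N:
        raise ValueError(f"probe alignment segment ({L} bp) exceeds target ({N} bp)")

    probe_map = _frame_coord_map(probe_frames, 0)
    target_atoms = params.target_atoms(nucleosome)
    target_coords = np.array([a.coords for a in target_atoms])
    target_elems = [a.element for a in target_atoms]
    target_tree = cKDTree(target_coords)

    scored_atoms = params.probe_atoms(probe_complex)
    scored_coords = np.array([a.coords for a in scored_atoms])
    scored_elems = [a.element for a in scored_atoms]

    positions, clash, rmsds = [], [], []
    for j0 in range(N - L + 1):
        window_map = _frame_coord_map(nuc_frames[j0 : j0 + L], 0)
        keys = sorted(set(probe_map) & set(window_map))
        if len(keys) < min_atoms_per_nucleotide * 2 * L:
            raise SelectionError(
                f"mapping {j0 + 1}: only {len(keys)} shared backbone atoms "
                f"(need >= {min_atoms_per_nucleotide} per nucleotide)"
            )
        moving = np.array([probe_map[k] for k in keys])
        fixed = np.array([window_map[k] for k in keys])
        transform = kabsch_fit(moving, fixed)
        placed = transform.apply(scored_coords)
        pct = clash_fraction(
            placed, scored_elems, target_coords, target_elems,
            params=params, target_tree=target_tree,
        )
        positions.append(j0 + 1)
        clash.append(pct)
        rmsds.append(transform.rmsd)
        if pose_writer is not None:
            pose_writer(
                j0 + 1,
                probe_complex.transformed(transform.rotation, transform.translation),
            )
    return ClashProfile(
        positions=np.array(positions),
        clash_pct=np.array(clash),
        rmsd=np.array(rmsds),
        n_probe_atoms=len(scored_atoms),
    )


def profile_periodicity(
    profile: ClashProfile | np.ndarray, lag_range: tuple[int, int] = (5, 20)
) -> int:
    """Dominant period (bp): lag maximizing the autocorrelation.

    The clash series is mean-centered and the normalized autocorrelation
    is evaluated at integer lags in ``lag_range``; the argmax is returned.
    A constant profile has no defined period.
    """
    x = profile.clash_pct if isinstance(profile, ClashProfile) else np.asarray(profile, float)
    if len(x) < 30:
        raise ValueError("profile too short for periodicity estimation (need >= 30)")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom < 1e-12:
        raise DegenerateGeometryError("constant profile: periodicity undefined")
    lo, hi = lag_range
    lags = np.arange(lo, min(hi, len(x) - 1) + 1)
    ac = np.array([np.dot(x[:-k], x[k:]) / denom for k in lags])
    return int(lags[int(np.argmax(ac))])
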