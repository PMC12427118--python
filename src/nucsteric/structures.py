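"""Macromolecular structures: PDB I/O, backbone selection, idealized builders.

Structures are held as flat, ordered atom tables (:class:`StructureModel`)
rather than residue hierarchies — every downstream operation (rigid-body
fitting, clash counting) works on coordinate arrays selected by simple
predicates.  Reading goes through Bio.PDB; writing uses the fixed-column
PDB format directly.

The idealized builders produce a synthetic nucleosome (two pseudo-backbone
strands on a left-handed superhelix around a pseudo-histone core) and a
synthetic enzyme–DNA probe (straight B-DNA duplex with a protein-class atom
blob on a fixed azimuth).  Both share one backbone construction so that
base-pair frames of the two structures are directly superimposable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "BasePairFrame",
    "BACKBONE_ATOMS",
    "BONDI_RADII",
    "PdbFormatError",
    "EmptyStructureError",
    "PairingError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_vdw_table",
    "select_backbone",
    "nucleic_chains",
    "build_idealized_nucleosome",
    "build_idealized_probe",
]


class PdbFormatError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed model contains no atoms."""


class PairingError(ValueError):
    """Raised when two strands cannot be paired base-by-base."""


class SelectionError(ValueError):
    """Raised when a requested atom selection is empty or impossible."""


# Canonical residue names used to assign the polymer class.
_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DI", "DU", "A", "C", "G", "U", "I"}

#: Deoxyribose-backbone atom set used for superimposition: the sugar ring
#: plus the phosphate linkage (P absent on 5'-terminal residues).
BACKBONE_ATOMS: tuple[str, ...] = (
    "P", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
)

#: Bondi-style van der Waals radii (Å) with a generic fallback.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "ZN": 1.39, "MN": 2.00, "FE": 2.00,
    "CA": 2.31, "CU": 1.40,
}
DEFAULT_VDW_RADIUS = 1.70


def polymer_class_of(residue_name: str) -> str:
    name = residue_name.strip().upper()
    if name in _AMINO_ACIDS:
        return "protein"
    if name in _NUCLEOTIDES:
        return "nucleic"
    return "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates (Å) and polymer class."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_number: int
    residue_name: str
    chain_id: str
    polymer_class: str
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")


class StructureModel:
    """Ordered collection of atoms with a chain index."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        if not atoms:
            raise EmptyStructureError("structure contains no atoms")
        self.atoms: list[AtomRecord] = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a model")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.chain_id, []).append(i)
        return out

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def select(self, predicate: Callable[[AtomRecord], bool]) -> list[AtomRecord]:
        return [a for a in self.atoms if predicate(a)]

    def protein_atoms(self, include_hydrogens: bool = False) -> list[AtomRecord]:
        return [
            a for a in self.atoms
            if a.polymer_class == "protein"
            and (include_hydrogens or a.element.upper() != "H")
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return StructureModel(
            [replace(a, coords=R @ a.coords + t) for a in self.atoms]
        )

    def chain_residues(self, chain_id: str) -> list[list[AtomRecord]]:
        """Residues of a chain, in file order, as lists of atoms."""
        groups: list[list[AtomRecord]] = []
        last: tuple[int, str] | None = None
        for i in self.chains.get(chain_id, []):
            a = self.atoms[i]
            key = (a.residue_number, a.residue_name)
            if key != last:
                groups.append([])
                last = key
            groups[-1].append(a)
        if not groups:
            raise SelectionError(f"chain {chain_id!r} not present")
        return groups


@dataclass
class BasePairFrame:
    """Backbone atoms of one base pair (both paired nucleotides)."""

    index: int
    strand1_atoms: list[AtomRecord]
    strand2_atoms: list[AtomRecord]


def read_pdb(path: str | Path) -> StructureModel:
    """Read the first model of a PDB file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc letter order); polymer class is assigned from
    the residue name.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("m", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise PdbFormatError(f"cannot parse {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise EmptyStructureError(f"{path}: no models")
    atoms: list[AtomRecord] = []
    for chain in models[0]:
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    # highest occupancy, ties by altloc letter order
                    best = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )[0]
                else:
                    best = atom
                resname = residue.get_resname().strip()
                atoms.append(
                    AtomRecord(
                        serial=best.get_serial_number(),
                        name=best.get_name(),
                        element=(best.element or "C").strip().upper(),
                        coords=np.asarray(best.get_coord(), dtype=float),
                        residue_number=residue.get_id()[1],
                        residue_name=resname,
                        chain_id=chain.get_id(),
                        polymer_class=polymer_class_of(resname),
                        occupancy=float(best.get_occupancy() or 1.0),
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: model contains no atoms")
    # re-serialize: Bio.PDB may repeat serials across altloc groups
    atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
    return StructureModel(atoms)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: 1-letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as fixed-column ATOM/HETATM records plus END."""
    lines = []
    for a in model.atoms:
        record = "ATOM  " if a.polymer_class in ("protein", "nucleic") else "HETATM"
        x, y, z = a.coords
        lines.append(
            f"{record}{a.serial % 100000:5d} {_format_atom_name(a.name, a.element)}"
            f" {a.residue_name:>3.3s} {a.chain_id[:1]}{a.residue_number % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vdw_table(path: str | Path) -> dict[str, float]:
    """Two-column text file ``element radius_Å`` -> radius map."""
    table: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'element radius'")
        radius = float(parts[1])
        if radius <= 0:
            raise ValueError(f"{path}:{lineno}: radius must be positive")
        table[parts[0].upper()] = radius
    return table


def nucleic_chains(model: StructureModel) -> list[str]:
    """Chain ids whose residues are predominantly nucleic, in file order."""
    out = []
    for cid, idx in model.chains.items():
        classes = [model.atoms[i].polymer_class for i in idx]
        if classes and classes.count("nucleic") > len(classes) / 2:
            out.append(cid)
    return out


def select_backbone(
    model: StructureModel,
    chain_pair: tuple[str, str] | None = None,
    bp_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> list[BasePairFrame]:
    """Backbone atoms of paired nucleotides for 1-based base-pair indices.

    Residue ``i`` of the first strand is paired with residue ``N+1-i`` of
    the second by chain residue ordering (duplex numbering convention; no
    hydrogen-bond detection).  Atoms are returned in the fixed
    ``atom_names`` order, independently of input file ordering.
    """
    if chain_pair is None:
        nc = nucleic_chains(model)
        if len(nc) < 2:
            raise PairingError("need two nucleic chains to pair strands")
        chain_pair = (nc[0], nc[1])
    s1 = model.chain_residues(chain_pair[0])
    s2 = model.chain_residues(chain_pair[1])
    if len(s1) != len(s2):
        raise PairingError(
            f"strands have different residue counts ({len(s1)} vs {len(s2)})"
        )
    n = len(s1)
    lo, hi = (1, n) if bp_range is None else bp_range
    if lo < 1 or hi > n or lo > hi:
        raise SelectionError(f"bp_range {lo}..{hi} outside duplex 1..{n}")
    order = {name: k for k, name in enumerate(atom_names)}

    def pick(residue: list[AtomRecord]) -> list[AtomRecord]:
        chosen = [a for a in residue if a.name in order]
        return sorted(chosen, key=lambda a: order[a.name])

    frames = []
    for i in range(lo, hi + 1):
        a1 = pick(s1[i - 1])
        a2 = pick(s2[n - i])
        if not a1 and not a2:
            raise SelectionError(f"base pair {i}: no backbone atoms present")
        frames.append(BasePairFrame(index=i, strand1_atoms=a1, strand2_atoms=a2))
    return frames


# ---------------------------------------------------------------------------
# Idealized builders
# ---------------------------------------------------------------------------

# Local backbone-atom offsets (radial Å, azimuthal rad, axial Å) relative to
# the strand's backbone reference point.  Values sketch a deoxyribose +
# phosphate footprint; what matters is that they are shared between the
# nucleosome and probe builders and are not collinear.
_ATOM_LOCAL_OFFSETS: dict[str, tuple[float, float, float]] = {
    "P": (0.9, 0.30, -1.4),
    "O5'": (0.5, 0.22, -0.8),
    "C5'": (0.2, 0.15, -0.4),
    "C4'": (0.0, 0.00, 0.0),
    "O4'": (-0.7, -0.08, 0.3),
    "C3'": (0.3, -0.12, 0.6),
    "O3'": (0.8, -0.20, 1.1),
    "C2'": (-0.3, -0.18, 0.8),
    "C1'": (-1.1, -0.10, 0.5),
}
_ATOM_ELEMENT = {name: name[0] for name in _ATOM_LOCAL_OFFSETS}

_HELIX_RADIUS = 9.0          # backbone distance from the duplex axis (Å)
_RISE_PER_BP = 3.38          # axial rise of B-DNA (Å/bp)
_STRAND2_PHASE = 2.0 * np.pi * 0.42   # azimuthal strand separation


def _backbone_atoms_for_bp(
    center: np.ndarray,
    tangent: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    phase: float,
    strand: int,
    include_p: bool,
) -> list[tuple[str, np.ndarray]]:
    """Backbone atom positions for one nucleotide in a local frame.

    ``u``/``v`` span the plane perpendicular to the helix axis tangent;
    ``phase`` is the azimuth of the strand's backbone at this base pair.
    Strand 2 runs antiparallel: its azimuthal offset and axial offsets are
    mirrored so that the construction is symmetric under strand exchange.
    """
    sign = 1.0 if strand == 1 else -1.0
    phi0 = phase if strand == 1 else phase + _STRAND2_PHASE
    out = []
    for name, (dr, dphi, dt) in _ATOM_LOCAL_OFFSETS.items():
        if name == "P" and not include_p:
            continue
        phi = phi0 + sign * dphi
        radius = _HELIX_RADIUS + dr
        pos = center + radius * (np.cos(phi) * u + np.sin(phi) * v) + sign * dt * tangent
        out.append((name, pos))
    return out


def _duplex_atoms(
    centers: np.ndarray,
    tangents: np.ndarray,
    us: np.ndarray,
    vs: np.ndarray,
    phases: np.ndarray,
    chain_ids: tuple[str, str],
) -> list[AtomRecord]:
    """Assemble two antiparallel pseudo-DNA strands as AtomRecords.

    Strand 1 residues run 1..N along increasing base-pair index; strand 2
    residues are numbered 1..N in their own 5'->3' direction, i.e. residue
    j sits at base-pair index N+1-j, matching the pairing convention of
    :func:`select_backbone`.
    """
    n = len(centers)
    atoms: list[AtomRecord] = []
    serial = 1

    def emit(bp_index: int, strand: int, chain: str, resnum: int, resname: str) -> None:
        nonlocal serial
        i = bp_index - 1
        include_p = resnum > 1
        for name, pos in _backbone_atoms_for_bp(
            centers[i], tangents[i], us[i], vs[i], phases[i], strand, include_p
        ):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=_ATOM_ELEMENT[name],
                    coords=pos,
                    residue_number=resnum,
                    residue_name=resname,
                    chain_id=chain,
                    polymer_class="nucleic",
                )
            )
            serial += 1

    for resnum in range(1, n + 1):
        emit(resnum, 1, chain_ids[0], resnum, "DA")
    for resnum in range(1, n + 1):
        emit(n + 1 - resnum, 2, chain_ids[1], resnum, "DT")
    return atoms


def _sphere_cloud(
    rng: np.random.Generator, n_atoms: int, radius: float, center: np.ndarray,
    chain_id: str, serial_start: int,
) -> list[AtomRecord]:
    """Uniform pseudo-protein atom cloud in a sphere (one atom per residue)."""
    pts = np.empty((0, 3))
    while len(pts) < n_atoms:
        cand = rng.uniform(-radius, radius, size=(2 * n_atoms, 3))
        cand = cand[np.sum(cand**2, axis=1) <= radius**2]
        pts = np.vstack([pts, cand])
    pts = pts[:n_atoms] + center
    return [
        AtomRecord(
            serial=serial_start + k,
            name="C1",
            element="C",
            coords=pts[k],
            residue_number=k + 1,
            residue_name="ALA",
            chain_id=chain_id,
            polymer_class="protein",
        )
        for k in range(n_atoms)
    ]


def build_idealized_nucleosome(
    n_bp: int = 147,
    bp_per_twist: float = 10.2,
    superhelix_radius: float = 41.9,
    superhelix_pitch: float = 25.9,
    wrap_turns: float = 1.65,
    core_radius: float = 32.0,
    n_core_atoms: int = 3000,
    seed: int = 0,
) -> StructureModel:
    """Idealized nucleosome: DNA superhelix around a pseudo-histone core.

    Two antiparallel pseudo-backbone strands (chains I and J) follow a
    left-handed superhelix of the given radius and pitch over ``wrap_turns``
    revolutions; the local double-helical twist completes one revolution
    every ``bp_per_twist`` base pairs.  A pseudo-histone core (chain A,
    protein-class carbon atoms uniform in a sphere of ``core_radius``) sits
    at the superhelix axis center.  Deterministic for a fixed seed.
    """
    if n_bp < 20:
        raise ValueError("n_bp must be >= 20")
    if bp_per_twist <= 0 or superhelix_radius <= 0 or wrap_turns <= 0:
        raise ValueError("bp_per_twist, superhelix_radius and wrap_turns must be positive")
    total_height = superhelix_pitch * wrap_turns
    if total_height > n_bp * _RISE_PER_BP * 2:
        raise ValueError("superhelix pitch/turns geometrically inconsistent with n_bp")

    i = np.arange(n_bp, dtype=float)
    frac = i / (n_bp - 1)
    theta = -2.0 * np.pi * wrap_turns * frac          # left-handed
    z = total_height * frac
    centers = np.stack(
        [superhelix_radius * np.cos(theta), superhelix_radius * np.sin(theta), z],
        axis=1,
    )
    # tangent of the superhelical path
    dtheta = -2.0 * np.pi * wrap_turns / (n_bp - 1)
    tangents = np.stack(
        [
            -superhelix_radius * np.sin(theta) * dtheta,
            superhelix_radius * np.cos(theta) * dtheta,
            np.full(n_bp, total_height / (n_bp - 1)),
        ],
        axis=1,
    )
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # radial direction, orthogonalized against the tangent
    e_r = np.stack([np.cos(theta), np.sin(theta), np.zeros(n_bp)], axis=1)
    us = e_r - np.sum(e_r * tangents, axis=1, keepdims=True) * tangents
    us /= np.linalg.norm(us, axis=1, keepdims=True)
    vs = np.cross(tangents, us)
    phases = 2.0 * np.pi * i / bp_per_twist

    atoms = _duplex_atoms(centers, tangents, us, vs, phases, ("I", "J"))
    core_center = np.array([0.0, 0.0, total_height / 2.0])
    rng = np.random.default_rng(seed)
    atoms += _sphere_cloud(
        rng, n_core_atoms, core_radius, core_center, "A", serial_start=len(atoms) + 1
    )
    return StructureModel(atoms)


def build_idealized_probe(
    n_bp: int = 19,
    bp_per_twist: float = 10.2,
    enzyme_atom_count: int = 500,
    enzyme_offset: float = 28.0,
    enzyme_radius: float = 12.0,
    enzyme_anchor_bp: float = 9.5,
    seed: int = 0,
) -> StructureModel:
    """Idealized enzyme–DNA probe: straight B-DNA plus a protein-atom blob.

    The duplex (chains C and D) lies along the z axis with canonical rise;
    the enzyme blob (chain E) is a sphere of ``enzyme_radius`` holding
    ``enzyme_atom_count`` protein-class atoms whose center sits
    ``enzyme_offset`` Å from the helix axis, on the azimuth bisecting the
    two strand backbones at base pair ``enzyme_anchor_bp`` (the groove face
    of the alignment segment).  Deterministic for a fixed seed.
    """
    if n_bp < 12:
        raise ValueError("n_bp must be >= 12")
    if enzyme_offset < enzyme_radius:
        warnings.warn(
            "enzyme blob overlaps its own DNA (enzyme_offset < enzyme_radius)",
            stacklevel=2,
        )
    i = np.arange(n_bp, dtype=float)
    centers = np.stack([np.zeros(n_bp), np.zeros(n_bp), i * _RISE_PER_BP], axis=1)
    tangents = np.tile([0.0, 0.0, 1.0], (n_bp, 1))
    us = np.tile([1.0, 0.0, 0.0], (n_bp, 1))
    vs = np.tile([0.0, 1.0, 0.0], (n_bp, 1))
    phases = 2.0 * np.pi * i / bp_per_twist

    atoms = _duplex_atoms(centers, tangents, us, vs, phases, ("C", "D"))
    # azimuth bisecting the two strands at the anchor base pair
    anchor_phase = 2.0 * np.pi * (enzyme_anchor_bp - 1.0) / bp_per_twist
    psi = anchor_phase + _STRAND2_PHASE / 2.0 + np.pi
    blob_center = np.array(
        [
            enzyme_offset * np.cos(psi),
            enzyme_offset * np.sin(psi),
            (enzyme_anchor_bp - 1.0) * _RISE_PER_BP,
        ]
    )
    rng = np.random.default_rng(seed)
    atoms += _sphere_cloud(
        rng, enzyme_atom_count, enzyme_radius, blob_center, "E",
        serial_start=len(atoms) + 1,
    )
    return StructureModel(atoms)
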