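"""Molecular structures and the geometry observables of a ligand–pocket complex.

Reads standard XYZ (Å) and Gaussian cube files (Bohr, converted on read)
into a light-weight :class:`StructureModel`, and computes the metrics a
protonation-state comparison needs: signed side-chain torsion angles,
donor–H⋯acceptor hydrogen-bond geometry, positional RMSD with optional
rigid-body superposition, centre of mass and point-charge dipole moments.
All coordinates are Å internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .errors import (
    AtomMismatchError,
    InvalidInputError,
    NoDonorHydrogenError,
    ParseError,
)

__all__ = [
    "BOHR_TO_ANGSTROM",
    "DEBYE_PER_E_ANGSTROM",
    "StructureModel",
    "HBondGeometry",
    "DipoleSummary",
    "read_xyz",
    "write_xyz",
    "read_cube",
    "torsion_angle",
    "hbond_geometry",
    "positional_rmsd",
    "point_charge_dipole",
    "center_of_mass",
    "combine",
]

BOHR_TO_ANGSTROM = 0.529177
DEBYE_PER_E_ANGSTROM = 4.80320

_PT = Chem.GetPeriodicTable()


def _check_symbol(sym: str) -> str:
    try:
        num = _PT.GetAtomicNumber(sym)
    except Exception:
        num = 0
    if num == 0:
        raise InvalidInputError(f"unknown element symbol {sym!r}")
    return sym


@dataclass
class StructureModel:
    """Atoms and Cartesian coordinates (Å) with optional point charges (e)."""

    atom_symbols: list
    coords: np.ndarray
    partial_charges: np.ndarray | None = None
    net_charge: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidInputError("coords must be an (n, 3) array")
        if len(self.atom_symbols) != self.coords.shape[0]:
            raise InvalidInputError("number of symbols and coordinate rows differ")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("coordinates contain non-finite values")
        self.atom_symbols = [_check_symbol(str(s)) for s in self.atom_symbols]
        if self.partial_charges is not None:
            self.partial_charges = np.asarray(self.partial_charges, dtype=float)
            if self.partial_charges.shape != (self.coords.shape[0],):
                raise InvalidInputError("partial_charges length must equal atom count")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray | None = None, translation=None) -> "StructureModel":
        """Copy with a rigid motion applied (rotation about the origin, then shift)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        return StructureModel(
            list(self.atom_symbols), xyz, self.partial_charges, self.net_charge, self.provenance
        )


def combine(*structures: StructureModel, provenance: str = "") -> StructureModel:
    """Concatenate structures into one frame (indices offset in order)."""
    syms = [s for st in structures for s in st.atom_symbols]
    coords = np.vstack([st.coords for st in structures])
    charges = None
    if all(st.partial_charges is not None for st in structures):
        charges = np.concatenate([st.partial_charges for st in structures])
    net = sum(st.net_charge for st in structures)
    return StructureModel(syms, coords, charges, net, provenance)


# ---------------------------------------------------------------------------
# File IO

def read_xyz(path) -> StructureModel:
    """Parse a standard XYZ file (coordinates in Å)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: line 1: expected atom count, got {lines[0]!r}") from exc
    if len(lines) < natoms + 2:
        raise ParseError(
            f"{path}: line {len(lines)}: file ends before the declared {natoms} atoms"
        )
    symbols, coords = [], []
    for i in range(natoms):
        ln = i + 3  # 1-based line number of this atom record
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {ln}: expected 'symbol x y z', got {lines[i + 2]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-numeric coordinate") from exc
        symbols.append(parts[0])
        coords.append(xyz)
    return StructureModel(symbols, np.array(coords), provenance=str(path))


def write_xyz(structure: StructureModel, path, comment: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(structure)}\n{comment}\n")
        for sym, (x, y, z) in zip(structure.atom_symbols, structure.coords):
            fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")


def read_cube(path) -> StructureModel:
    """Parse atoms from a Gaussian cube file; the density grid is ignored.

    Coordinates are Bohr by cube convention and converted to Å.  A
    negative atom count (the oriented-data convention, signalling a
    DSET_IDS record after the header) is honoured via its absolute value.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: line {len(lines)}: truncated cube header")
    try:
        head = lines[2].split()
        natoms_signed = int(head[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: line 3: expected atom count and grid origin") from exc
    natoms = abs(natoms_signed)
    if len(lines) < 6 + natoms:
        raise ParseError(f"{path}: line {len(lines)}: file ends before {natoms} atom records")
    symbols, coords = [], []
    for i in range(natoms):
        ln = i + 7
        parts = lines[i + 6].split()
        if len(parts) < 5:
            raise ParseError(f"{path}: line {ln}: expected 'Z charge x y z'")
        try:
            z = int(float(parts[0]))
            xyz = [float(v) * BOHR_TO_ANGSTROM for v in parts[2:5]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-numeric atom record") from exc
        try:
            symbols.append(_PT.GetElementSymbol(z))
        except Exception as exc:
            raise ParseError(f"{path}: line {ln}: unknown atomic number {z}") from exc
        coords.append(xyz)
    return StructureModel(symbols, np.array(coords), provenance=str(path))


# ---------------------------------------------------------------------------
# Geometry metrics

def torsion_angle(s: StructureModel, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral angle i–j–k–l in degrees on (−180, 180].

    Standard atan2 construction: anti ≈ ±180°, gauche ≈ ±60°.  The value
    is invariant under reversing the atom order and changes sign under
    mirror reflection.
    """
    if len({i, j, k, l}) != 4:
        raise InvalidInputError("torsion needs four distinct atom indices")
    r = s.coords
    b1, b2, b3 = r[j] - r[i], r[k] - r[j], r[l] - r[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    scale = max(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3), 1e-12)
    if np.linalg.norm(n1) < 1e-8 * scale**2 or np.linalg.norm(n2) < 1e-8 * scale**2:
        raise InvalidInputError("undefined torsion: three of the four atoms are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


@dataclass(frozen=True)
class HBondGeometry:
    """Donor–hydrogen⋯acceptor contact geometry."""

    donor_idx: int
    hydrogen_idx: int
    acceptor_idx: int
    d_HA: float
    d_DA: float
    angle_DHA: float


def _covalent_radius(sym: str) -> float:
    return float(_PT.GetRcovalent(sym))


def bonded_hydrogens(s: StructureModel, donor_idx: int, bond_scale: float = 1.2) -> list[int]:
    """Hydrogens within ``bond_scale`` × (covalent-radius sum) of the donor."""
    d_sym = s.atom_symbols[donor_idx]
    out = []
    for idx, sym in enumerate(s.atom_symbols):
        if idx == donor_idx or sym != "H":
            continue
        cutoff = bond_scale * (_covalent_radius(d_sym) + _covalent_radius("H"))
        if np.linalg.norm(s.coords[idx] - s.coords[donor_idx]) <= cutoff:
            out.append(idx)
    return out


def hbond_geometry(
    s: StructureModel, donor_idx: int, acceptor_idx: int, bond_scale: float = 1.2
) -> HBondGeometry:
    """Hydrogen-bond geometry using the donor hydrogen closest to the acceptor.

    Reports d(H⋯A), d(D⋯A) and the D–H⋯A angle measured at the hydrogen.
    """
    hs = bonded_hydrogens(s, donor_idx, bond_scale)
    if not hs:
        raise NoDonorHydrogenError(
            f"atom {donor_idx} ({s.atom_symbols[donor_idx]}) has no bonded hydrogen"
        )
    a = s.coords[acceptor_idx]
    h_idx = min(hs, key=lambda idx: np.linalg.norm(s.coords[idx] - a))
    h, d = s.coords[h_idx], s.coords[donor_idx]
    v1, v2 = d - h, a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return HBondGeometry(
        donor_idx=donor_idx,
        hydrogen_idx=h_idx,
        acceptor_idx=acceptor_idx,
        d_HA=float(np.linalg.norm(a - h)),
        d_DA=float(np.linalg.norm(a - d)),
        angle_DHA=math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))),
    )


def positional_rmsd(
    a: StructureModel,
    b: StructureModel,
    superpose: bool = False,
    mask_a=None,
    mask_b=None,
) -> float:
    """RMSD between corresponding atom positions, in Å.

    Default compares raw coordinates (both structures sharing one frame,
    e.g. a common receptor pocket); ``superpose=True`` first removes the
    optimal rigid-body motion (Kabsch least squares).  Index masks select
    the shared skeleton when atom counts differ (e.g. excluding the extra
    proton of a protonated form).
    """
    xa = a.coords[np.asarray(mask_a)] if mask_a is not None else a.coords
    xb = b.coords[np.asarray(mask_b)] if mask_b is not None else b.coords
    sa = [a.atom_symbols[i] for i in mask_a] if mask_a is not None else a.atom_symbols
    sb = [b.atom_symbols[i] for i in mask_b] if mask_b is not None else b.atom_symbols
    if xa.shape != xb.shape or sa != sb:
        raise AtomMismatchError(
            f"structures do not correspond atom-wise ({len(sa)} vs {len(sb)} atoms, "
            "or differing element sequences); supply index masks"
        )
    if superpose:
        ca, cb = xa - xa.mean(axis=0), xb - xb.mean(axis=0)
        _, rssd = Rotation.align_vectors(ca, cb)
        return float(rssd / math.sqrt(xa.shape[0]))
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


@dataclass(frozen=True)
class DipoleSummary:
    """Point-charge dipole: magnitude (debye) and negative→positive direction."""

    magnitude_D: float
    direction: np.ndarray | None
    origin: np.ndarray
    origin_dependent: bool


def center_of_mass(s: StructureModel) -> np.ndarray:
    """Mass-weighted mean position using standard atomic masses."""
    if len(s) == 0:
        raise InvalidInputError("empty structure")
    masses = np.array([_PT.GetAtomicWeight(sym) for sym in s.atom_symbols])
    return masses @ s.coords / masses.sum()


def point_charge_dipole(s: StructureModel, origin=None) -> DipoleSummary:
    """Dipole moment μ = Σ qᵢ (rᵢ − origin) of the partial-charge cloud.

    Magnitude in debye (1 e·Å = 4.80320 D).  For a net-neutral charge set
    the result is origin independent; for a charged set it depends on the
    reference point (default: centre of mass) and is flagged as such.
    """
    if s.partial_charges is None:
        raise InvalidInputError("structure carries no partial charges")
    org = center_of_mass(s) if origin is None else np.asarray(origin, dtype=float)
    mu = (s.partial_charges[:, None] * (s.coords - org)).sum(axis=0)
    mag_ea = float(np.linalg.norm(mu))
    direction = mu / mag_ea if mag_ea > 1e-12 else None
    return DipoleSummary(
        magnitude_D=mag_ea * DEBYE_PER_E_ANGSTROM,
        direction=direction,
        origin=org,
        origin_dependent=abs(float(s.partial_charges.sum())) > 1e-9,
    )
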