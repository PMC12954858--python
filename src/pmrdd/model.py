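"""PDB model handling and the two PMRDD perturbations.

The PMRDD test edits a known-good reference model in two ways before it
is used to phase maps: one core, well-ordered aromatic side chain is
removed entirely (truncated to an alanine-like stub), and a second core
aromatic is moved to a different, non-clashing rotamer.  Difference
density at the true (recorded) positions of those side chains then acts
as an internal gauge of whether the merged data have overcome model
phase bias.

This module owns the fixed-column PDB reader/writer, residue topology
for the aromatic types (TRP/TYR/PHE/HIS), chi-angle measurement and
rigid rotation, the automatic "core + well ordered" target selection,
and the :class:`PerturbationRecord` that keeps the true and false atom
positions needed later for scoring.  Hydrogens and alternate conformers
are dropped on read (highest-occupancy conformer kept).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formfactors import FORM_FACTORS
from .symmetry import UnitCell, build_cell, get_space_group

log = logging.getLogger(__name__)

__all__ = [
    "Atom", "Model", "PerturbationRecord", "ResidueId",
    "read_pdb", "write_pdb",
    "select_pmrdd_residues", "truncate_side_chain", "swap_rotamer",
    "clash_score", "measure_chi", "AROMATIC_RESIDUES", "ROTAMER_TABLE",
]

# ---------------------------------------------------------------------------
# Residue topology
# ---------------------------------------------------------------------------

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# side-chain atoms beyond CB, in build order
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "LEU": ("CG", "CD1", "CD2"),
    "SER": ("OG",),
    "VAL": ("CG1", "CG2"),
}

AROMATIC_RESIDUES = ("TRP", "TYR", "PHE", "HIS")

# chi dihedral definitions (atom name quadruples)
CHI_DEFS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
}

# canonical rotamer table: chi1 in {-60, 60, 180}, chi2 in {-90, 90}
ROTAMER_TABLE: dict[str, tuple[tuple[float, ...], ...]] = {
    res: tuple((chi1, chi2) for chi1 in (-60.0, 60.0, 180.0)
               for chi2 in (-90.0, 90.0))
    for res in AROMATIC_RESIDUES
}

CLASH_CUTOFF = 2.2          # Angstrom, heavy-atom contact considered a clash
BURIAL_RADIUS = 5.0         # Angstrom, neighbour count radius for "core"
DEFAULT_EXCLUDE_RADIUS = 8.0

ResidueId = tuple[str, int]  # (chain, residue_seq)


# ---------------------------------------------------------------------------
# Atoms and models
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_seq: int
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 20.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if self.element.strip().upper() not in FORM_FACTORS:
            raise ValueError(f"element {self.element!r} has no form factors")

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_seq, self.name)


@dataclass
class Model:
    """An ordered atom list plus the crystal frame it lives in."""

    atoms: list[Atom]
    cell: UnitCell
    space_group: str = "P1"
    _skip_unique_check: bool = False

    def __post_init__(self):
        if not self._skip_unique_check:
            keys = [a.key() for a in self.atoms]
            if len(set(keys)) != len(keys):
                seen, dup = set(), None
                for k in keys:
                    if k in seen:
                        dup = k
                        break
                    seen.add(k)
                raise ValueError(f"duplicate atom {dup} in model")

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residues(self) -> dict[ResidueId, list[Atom]]:
        out: dict[ResidueId, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.residue_seq), []).append(a)
        return out

    def residue_atoms(self, residue: ResidueId) -> list[Atom]:
        chain, seq = residue
        atoms = [a for a in self.atoms if a.chain == chain and a.residue_seq == seq]
        if not atoms:
            raise KeyError(f"residue {residue} not in model")
        return atoms

    def residue_name(self, residue: ResidueId) -> str:
        return self.residue_atoms(residue)[0].residue_name

    def atom(self, residue: ResidueId, name: str) -> Atom:
        for a in self.residue_atoms(residue):
            if a.name == name:
                return a
        raise KeyError(f"atom {name} missing from residue {residue}")

    def copy(self) -> "Model":
        atoms = [replace(a, position=a.position.copy()) for a in self.atoms]
        return Model(atoms=atoms, cell=self.cell, space_group=self.space_group,
                     _skip_unique_check=True)

    @property
    def ops(self):
        return get_space_group(self.space_group)

    def total_electrons(self) -> float:
        """Occupancy-weighted electron count (f(0) per atom)."""
        return float(sum(a.occupancy * (sum(FORM_FACTORS[a.element.upper()][0])
                                        + FORM_FACTORS[a.element.upper()][2])
                         for a in self.atoms))


# ---------------------------------------------------------------------------
# PDB input/output
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if len(name) >= 2 and name[:2].strip().upper() in FORM_FACTORS and name[0] != " ":
        two = name[:2].strip().upper()
        if two in ("FE", "ZN", "MG", "MN", "CL", "NA", "CA", "K"):
            return two
    return stripped[0].upper()


def read_pdb(path: str | Path) -> Model:
    """Parse ATOM/HETATM + CRYST1 records from a PDB file.

    A missing CRYST1 is a hard error: every downstream step needs the
    cell.  Alternate conformers keep the highest-occupancy copy;
    hydrogens are dropped.  Unknown residue names are retained.
    """
    path = Path(path)
    cell = None
    space_group = None
    records: list[tuple[int, Atom, str]] = []  # (line_no, atom, altloc)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    cell = build_cell(float(line[6:15]), float(line[15:24]),
                                      float(line[24:33]), float(line[33:40]),
                                      float(line[40:47]), float(line[47:54]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{line_no}: bad CRYST1 ({exc})")
                space_group = line[55:66].strip() or "P1"
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16]
                    altloc = line[16]
                    element = line[76:78].strip() or _guess_element(name)
                    atom = Atom(
                        serial=int(line[6:11]),
                        name=name.strip(),
                        element=element,
                        residue_name=line[17:20].strip(),
                        chain=line[21],
                        residue_seq=int(line[22:26]),
                        position=np.array([float(line[30:38]),
                                           float(line[38:46]),
                                           float(line[46:54])]),
                        occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
                        b_factor=float(line[60:66]) if line[60:66].strip() else 0.0,
                    )
                except (ValueError, IndexError) as exc:
                    if line[76:78].strip().upper() == "H" or _is_hydrogen(line[12:16]):
                        continue  # hydrogens may use exotic names; ignored anyway
                    raise ValueError(
                        f"{path}:{line_no}: unparseable ATOM record ({exc})")
                if atom.element.upper() == "H":
                    continue
                records.append((line_no, atom, altloc))
    if cell is None:
        raise ValueError(f"{path}: no CRYST1 record; a unit cell is required")
    if not records:
        raise ValueError(f"{path}: no ATOM/HETATM records")

    # collapse alternate conformers: keep highest occupancy per atom key
    best: dict[tuple, tuple[float, int, Atom]] = {}
    n_alt = 0
    for idx, (line_no, atom, altloc) in enumerate(records):
        k = atom.key()
        if k in best:
            n_alt += 1
            if atom.occupancy > best[k][0]:
                best[k] = (atom.occupancy, best[k][1], atom)
        else:
            best[k] = (atom.occupancy, idx, atom)
    if n_alt:
        log.warning("%s: dropped %d alternate-conformer atoms "
                    "(kept highest occupancy)", path, n_alt)
    atoms = [a for _, _, a in sorted(best.values(), key=lambda v: v[1])]
    return Model(atoms=atoms, cell=cell, space_group=space_group)


def _is_hydrogen(name_field: str) -> bool:
    s = name_field.strip()
    return bool(s) and (s[0] == "H" or (s[0].isdigit() and len(s) > 1 and s[1] == "H"))


def _format_atom_name(name: str, element: str) -> str:
    # single-letter elements start in column 14, two-letter in column 13
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: Model, path: str | Path) -> None:
    """Write fixed-column CRYST1/ATOM records (3 d.p. coords, 2 d.p. occ/B)."""
    c = model.cell
    lines = [
        f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
        f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {model.space_group:<11s}4"
    ]
    for a in model.atoms:
        x, y, z = a.position
        lines.append(
            f"ATOM  {a.serial:5d} {_format_atom_name(a.name, a.element)} "
            f"{a.residue_name:<3s} {a.chain}{a.residue_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element.strip().upper():>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Perturbation record
# ---------------------------------------------------------------------------

@dataclass
class PerturbationRecord:
    """Book-keeping for the two PMRDD edits.

    Positions of deleted/true atoms are in the ORIGINAL model frame;
    false positions are in the perturbed model frame.  Scoring needs
    both: recovery is measured where the atoms really are, displacement
    where the wrong rotamer put them.
    """

    deleted_residue: tuple[str, int, str] | None = None
    deleted_atom_positions: list[tuple[str, list[float]]] = field(default_factory=list)
    moved_residue: tuple[str, int, str] | None = None
    original_chi: list[float] = field(default_factory=list)
    new_chi: list[float] = field(default_factory=list)
    true_atom_positions: list[tuple[str, list[float]]] = field(default_factory=list)
    false_atom_positions: list[tuple[str, list[float]]] = field(default_factory=list)

    def validate(self) -> None:
        if self.deleted_residue and self.moved_residue:
            if self.deleted_residue[:2] == self.moved_residue[:2]:
                raise ValueError("deleted and moved residues must be distinct")
        for res in (self.deleted_residue, self.moved_residue):
            if res is not None and res[2] not in AROMATIC_RESIDUES:
                raise ValueError(f"{res} is not an aromatic residue")

    def merged_with(self, other: "PerturbationRecord") -> "PerturbationRecord":
        out = PerturbationRecord(
            deleted_residue=self.deleted_residue or other.deleted_residue,
            deleted_atom_positions=(self.deleted_atom_positions
                                    or other.deleted_atom_positions),
            moved_residue=self.moved_residue or other.moved_residue,
            original_chi=self.original_chi or other.original_chi,
            new_chi=self.new_chi or other.new_chi,
            true_atom_positions=(self.true_atom_positions
                                 or other.true_atom_positions),
            false_atom_positions=(self.false_atom_positions
                                  or other.false_atom_positions),
        )
        out.validate()
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        payload = {
            "deleted_residue": self.deleted_residue,
            "deleted_atom_positions": [[n, list(map(float, p))]
                                       for n, p in self.deleted_atom_positions],
            "moved_residue": self.moved_residue,
            "original_chi": [float(x) for x in self.original_chi],
            "new_chi": [float(x) for x in self.new_chi],
            "true_atom_positions": [[n, list(map(float, p))]
                                    for n, p in self.true_atom_positions],
            "false_atom_positions": [[n, list(map(float, p))]
                                     for n, p in self.false_atom_positions],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PerturbationRecord":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        rec = cls(
            deleted_residue=tuple(d["deleted_residue"]) if d["deleted_residue"] else None,
            deleted_atom_positions=[(n, p) for n, p in d["deleted_atom_positions"]],
            moved_residue=tuple(d["moved_residue"]) if d["moved_residue"] else None,
            original_chi=d["original_chi"],
            new_chi=d["new_chi"],
            true_atom_positions=[(n, p) for n, p in d["true_atom_positions"]],
            false_atom_positions=[(n, p) for n, p in d["false_atom_positions"]],
        )
        return rec


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return math.degrees(math.atan2(y, x))


def _rotation_about_axis(origin: np.ndarray, axis: np.ndarray,
                         angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (R, shift) so that p -> R (p - origin) + origin."""
    from scipy.spatial.transform import Rotation
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    return R, origin


def measure_chi(model: Model, residue: ResidueId) -> list[float]:
    """Current chi dihedrals of an aromatic residue, degrees."""
    name = model.residue_name(residue)
    if name not in CHI_DEFS:
        raise ValueError(f"no chi definition for residue type {name}")
    chis = []
    for quad in CHI_DEFS[name]:
        pts = [model.atom(residue, n).position for n in quad]
        chis.append(dihedral(*pts))
    return chis


def _side_chain_complete(model: Model, residue: ResidueId) -> bool:
    name = model.residue_name(residue)
    if name not in SIDE_CHAIN_ATOMS:
        return False
    present = {a.name for a in model.residue_atoms(residue)}
    return "CB" in present and set(SIDE_CHAIN_ATOMS[name]) <= present


# ---------------------------------------------------------------------------
# Target selection
# ---------------------------------------------------------------------------

def _side_chain_positions(model: Model, residue: ResidueId) -> np.ndarray:
    name = model.residue_name(residue)
    wanted = set(SIDE_CHAIN_ATOMS.get(name, ())) | {"CB"}
    pos = [a.position for a in model.residue_atoms(residue) if a.name in wanted]
    return np.array(pos).reshape(-1, 3)


def rank_aromatic_residues(model: Model,
                           exclude_center: np.ndarray | None = None,
                           exclude_radius: float = DEFAULT_EXCLUDE_RADIUS,
                           ) -> list[tuple[ResidueId, float]]:
    """Aromatic residues ranked by the "core, well ordered" score.

    Score = z(burial) - z(mean side-chain B): buried (many neighbours
    within 5 A of the side-chain centroid) and low-B residues rank
    first.  Residues whose side-chain centroid falls inside the
    exclusion sphere (e.g. an active site under study) are skipped, as
    are residues with incomplete side chains.
    """
    coords = model.coordinates()
    owner = [(a.chain, a.residue_seq) for a in model.atoms]
    cand: list[tuple[ResidueId, float, float]] = []
    for rid, atoms in model.residues().items():
        if atoms[0].residue_name not in AROMATIC_RESIDUES:
            continue
        if not _side_chain_complete(model, rid):
            continue
        sc = _side_chain_positions(model, rid)
        centroid = sc.mean(axis=0)
        if exclude_center is not None and (
                np.linalg.norm(centroid - np.asarray(exclude_center, float))
                <= exclude_radius):
            continue
        mask = np.array([o != rid for o in owner])
        burial = int(np.sum(np.linalg.norm(coords[mask] - centroid, axis=1)
                            <= BURIAL_RADIUS))
        mean_b = float(np.mean([a.b_factor for a in atoms
                                if a.name in set(SIDE_CHAIN_ATOMS[atoms[0].residue_name]) | {"CB"}]))
        cand.append((rid, float(burial), mean_b))
    if not cand:
        return []
    burials = np.array([c[1] for c in cand])
    bs = np.array([c[2] for c in cand])
    zb = (burials - burials.mean()) / (burials.std() or 1.0)
    zB = (bs - bs.mean()) / (bs.std() or 1.0)
    scores = zb - zB
    ranked = sorted(zip((c[0] for c in cand), scores),
                    key=lambda t: (-t[1], t[0]))
    return [(rid, float(s)) for rid, s in ranked]


def select_pmrdd_residues(model: Model,
                          exclude_center: np.ndarray | None = None,
                          exclude_radius: float = DEFAULT_EXCLUDE_RADIUS,
                          ) -> tuple[ResidueId, ResidueId]:
    """Pick the deletion target (rank 1) and the rotamer-swap target (rank 2)."""
    ranked = rank_aromatic_residues(model, exclude_center, exclude_radius)
    if len(ranked) < 2:
        raise ValueError(
            "need at least two eligible aromatic residues outside the "
            "exclusion sphere; consider relaxing exclude_radius")
    return ranked[0][0], ranked[1][0]


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def truncate_side_chain(model: Model, residue: ResidueId,
                        to_glycine: bool = False,
                        ) -> tuple[Model, PerturbationRecord]:
    """Remove an aromatic side chain, leaving an alanine-like stub.

    N, CA, C, O and (unless ``to_glycine``) CB are retained; the removed
    atom names and their true positions go into the record so the
    scoring stage knows where recovery density should appear.
    """
    name = model.residue_name(residue)
    if name not in AROMATIC_RESIDUES:
        raise ValueError(f"residue {residue} ({name}) is not aromatic")
    if not _side_chain_complete(model, residue):
        raise ValueError(f"residue {residue} ({name}) has an incomplete side chain")
    doomed = set(SIDE_CHAIN_ATOMS[name])
    if to_glycine:
        doomed.add("CB")
    chain, seq = residue
    removed: list[tuple[str, list[float]]] = []
    kept: list[Atom] = []
    for a in model.atoms:
        if a.chain == chain and a.residue_seq == seq and a.name in doomed:
            removed.append((a.name, [float(x) for x in a.position]))
        else:
            kept.append(a)
    rec = PerturbationRecord(
        deleted_residue=(chain, seq, name),
        deleted_atom_positions=removed,
    )
    out = Model(atoms=[replace(a, position=a.position.copy()) for a in kept],
                cell=model.cell, space_group=model.space_group,
                _skip_unique_check=True)
    return out, rec


def clash_score(model: Model, residue: ResidueId,
                cutoff: float = CLASH_CUTOFF) -> int:
    """Count of (side-chain atom, foreign atom) pairs closer than ``cutoff``.

    Atoms of sequence neighbours i-1, i, i+1 in the same chain are
    excluded, mirroring the usual treatment of bonded geometry.
    """
    chain, seq = residue
    name = model.residue_name(residue)
    sc_names = set(SIDE_CHAIN_ATOMS.get(name, ())) | {"CB"}
    sc = np.array([a.position for a in model.residue_atoms(residue)
                   if a.name in sc_names]).reshape(-1, 3)
    others = np.array([a.position for a in model.atoms
                       if not (a.chain == chain
                               and abs(a.residue_seq - seq) <= 1)]).reshape(-1, 3)
    if len(sc) == 0 or len(others) == 0:
        return 0
    d = np.linalg.norm(sc[:, None, :] - others[None, :, :], axis=2)
    return int(np.sum(d < cutoff))


def _apply_chi_rotation(positions: dict[str, np.ndarray], res_name: str,
                        chi_index: int, delta_deg: float) -> None:
    """Rigidly rotate the atoms distal to chi_index by delta (in place)."""
    quad = CHI_DEFS[res_name][chi_index]
    axis_from = positions[quad[1]]
    axis_to = positions[quad[2]]
    movers = [n for n in SIDE_CHAIN_ATOMS[res_name]
              if n not in quad[:3]]  # beyond the rotation axis
    # a right-handed rotvec about the b1->b2 axis decreases the measured
    # dihedral, hence the sign flip
    R, origin = _rotation_about_axis(axis_from, axis_to - axis_from, -delta_deg)
    for n in movers:
        positions[n] = R @ (positions[n] - origin) + origin


def swap_rotamer(model: Model, residue: ResidueId,
                 rotamer_index: int | None = None,
                 ) -> tuple[Model, PerturbationRecord]:
    """Move an aromatic side chain to a different canonical rotamer.

    The side chain is rigidly rotated about its chi axes, preserving all
    internal geometry.  With ``rotamer_index=None`` the non-clashing
    rotamer farthest from the current chi angles is chosen; if every
    table rotamer clashes, the error lists per-rotamer clash counts.
    """
    name = model.residue_name(residue)
    if name not in AROMATIC_RESIDUES:
        raise ValueError(f"residue {residue} ({name}) is not aromatic")
    if not _side_chain_complete(model, residue):
        raise ValueError(f"residue {residue} ({name}) has an incomplete side chain")
    chain, seq = residue
    original_chi = measure_chi(model, residue)
    sc_names = list(SIDE_CHAIN_ATOMS[name])
    true_pos = [(n, [float(x) for x in model.atom(residue, n).position])
                for n in sc_names]

    def build(target_chi: Sequence[float]) -> Model:
        out = model.copy()
        pos = {n: out.atom(residue, n).position.copy()
               for n in ("N", "CA", "CB", *sc_names)}
        for i, (cur, tgt) in enumerate(zip(measure_chi(out, residue), target_chi)):
            _apply_chi_rotation(pos, name, i, tgt - cur)
            # refresh measured chis via positions dict
            for n in sc_names:
                out.atom(residue, n).position[:] = pos[n]
        return out

    table = ROTAMER_TABLE[name]
    if rotamer_index is not None:
        if not 0 <= rotamer_index < len(table):
            raise IndexError(f"rotamer_index {rotamer_index} outside table "
                             f"of {len(table)} rotamers for {name}")
        choices = [rotamer_index]
    else:
        choices = list(range(len(table)))

    results: list[tuple[int, Model, int, float]] = []
    for idx in choices:
        cand = build(table[idx])
        score = clash_score(cand, residue)
        dist = _chi_distance(original_chi, table[idx])
        results.append((idx, cand, score, dist))
    ok = [r for r in results if r[2] == 0]
    if rotamer_index is not None:
        idx, cand, score, _ = results[0]
        if score > 0:
            log.warning("rotamer %d of %s clashes (%d contacts)", idx, name, score)
        chosen = results[0]
    elif ok:
        chosen = max(ok, key=lambda r: r[3])
    else:
        detail = ", ".join(f"rotamer {i}: {s} clashes" for i, _, s, _ in results)
        raise ValueError(f"every rotamer of {residue} clashes ({detail})")
    idx, out, _, _ = chosen
    rec = PerturbationRecord(
        moved_residue=(chain, seq, name),
        original_chi=original_chi,
        new_chi=list(table[idx]),
        true_atom_positions=true_pos,
        false_atom_positions=[(n, [float(x) for x in out.atom(residue, n).position])
                              for n in sc_names],
    )
    return out, rec


def _chi_distance(a: Sequence[float], b: Sequence[float]) -> float:
    d = 0.0
    for x, y in zip(a, b):
        delta = abs((x - y + 180.0) % 360.0 - 180.0)
        d += delta * delta
    return math.sqrt(d)
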