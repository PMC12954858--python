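"""Synthetic ground-truth models for simulation and testing.

Real serial datasets are far too large to ship or rebuild at desk
scale, so the package carries a generator of small protein-like models:
residues with ideal internal geometry (built from bond/angle/dihedral
internal coordinates) are packed into a unit cell with randomized
orientations, mixed B-factors and a guaranteed set of aromatic side
chains.  The result is chemically plausible enough for every stage the
toolkit exercises - rotamer perturbation, structure factors, maps and
difference-density scoring - while remaining fully deterministic from a
seed.

These models are synthetic: they have no secondary structure, no
connectivity between residues and no solvent, which is irrelevant for
the Fourier/merging math being tested but means absolute map quality is
not comparable to a real protein crystal.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (AROMATIC_RESIDUES, Atom, CHI_DEFS, Model,
                    SIDE_CHAIN_ATOMS)
from .symmetry import UnitCell, build_cell

__all__ = ["build_residue", "make_test_model", "make_toy_model",
           "DEFAULT_COMPOSITION"]


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from three predecessors and internal coordinates."""
    angle = math.radians(angle_deg)
    dihed = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(angle),
                   bond * math.sin(angle) * math.cos(dihed),
                   -bond * math.sin(angle) * math.sin(dihed)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# internal coordinates for side chains: atom -> (ref triple, bond, angle, dihedral)
# chi-bearing dihedrals are entered symbolically as "chi1"/"chi2" (+180 for the
# second branch) and substituted at build time.
_SIDE_CHAIN_IC: dict[str, list[tuple[str, tuple[str, str, str],
                                     float, float, object]]] = {
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, ("chi2", 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.51, 113.9, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 121.1, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 121.1, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.38, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.7, "chi1"),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.1, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.2, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, ("chi2", 120.0)),
    ],
    "SER": [
        ("OG", ("N", "CA", "CB"), 1.42, 110.8, "chi1"),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.52, 110.5, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi1", 120.0)),
    ],
    "ALA": [],
}

_ELEMENT_FROM_NAME = {"O": "O", "N": "N", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name[0], "C")


def build_residue(res_name: str, chi: tuple[float, ...] = (-60.0, 90.0),
                  ) -> dict[str, np.ndarray]:
    """Ideal-geometry heavy-atom coordinates for one residue at the origin.

    Returns an ordered dict atom name -> position (Angstrom), with N at
    the origin.  ``chi`` supplies chi1/chi2 where the type has them.
    """
    if res_name not in _SIDE_CHAIN_IC:
        raise ValueError(f"no template for residue type {res_name}")
    pos: dict[str, np.ndarray] = {}
    pos["N"] = np.zeros(3)
    pos["CA"] = np.array([1.458, 0.0, 0.0])
    # C in the xy plane, angle N-CA-C = 111.2 deg
    ang = math.radians(111.2)
    pos["C"] = pos["CA"] + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    pos["O"] = _nerf(pos["N"], pos["CA"], pos["C"], 1.231, 120.8, -40.0)
    if res_name != "GLY":
        pos["CB"] = _nerf(pos["C"], pos["N"], pos["CA"], 1.530, 110.4, -122.0)
    chi = tuple(chi) + (0.0, 0.0)
    subs = {"chi1": chi[0], "chi2": chi[1]}
    for name, refs, bond, angle, dihed in _SIDE_CHAIN_IC[res_name]:
        if isinstance(dihed, str):
            d = subs[dihed]
        elif isinstance(dihed, tuple):
            d = subs[dihed[0]] + dihed[1]
        else:
            d = dihed
        pos[name] = _nerf(pos[refs[0]], pos[refs[1]], pos[refs[2]],
                          bond, angle, d)
    return pos


DEFAULT_COMPOSITION: tuple[str, ...] = (
    # 37 residues, ~300 heavy atoms when placed; aromatics first so the
    # generator can bury them deliberately
    "TRP", "TYR", "TRP", "PHE", "TYR", "HIS", "PHE", "TYR", "HIS",
    "LEU", "LEU", "LEU", "VAL", "VAL", "VAL", "LEU", "SER", "SER",
    "ALA", "ALA", "LEU", "VAL", "LEU", "ALA", "SER", "LEU", "VAL",
    "ALA", "LEU", "VAL", "LEU", "VAL", "SER", "LEU", "ALA", "VAL",
    "LEU",
)


def make_test_model(n_residues: int | None = None,
                    cell: UnitCell | None = None,
                    space_group: str = "P1",
                    composition: tuple[str, ...] = DEFAULT_COMPOSITION,
                    seed: int = 0,
                    b_range: tuple[float, float] = (10.0, 30.0),
                    min_separation: float = 3.6) -> Model:
    """Pack ideal residues into a cell to form a ~300-atom test crystal.

    Residues are placed on a jittered grid with random orientations and
    re-drawn until no two residues approach closer than
    ``min_separation``.  The two leading aromatic residues (a TRP and a
    TYR) are placed centrally and given the lowest B-factors so the
    automatic target selection reliably treats them as "core, well
    ordered".  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    comp = list(composition if n_residues is None else composition[:n_residues])
    if cell is None:
        cell = build_cell(28.0, 28.0, 28.0, 90.0, 90.0, 90.0)

    # grid of candidate anchor sites with a margin off the cell walls
    margin = 4.5
    lo = np.array([margin] * 3)
    hi = np.array([cell.a, cell.b, cell.c]) - margin
    n_side = int(np.ceil(len(comp) ** (1.0 / 3.0))) + 1
    axes = [np.linspace(lo[i], hi[i], n_side) for i in range(3)]
    sites = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    center = (lo + hi) / 2.0
    # central sites first: aromatics at the front of the composition get buried
    sites = sites[np.argsort(np.linalg.norm(sites - center, axis=1))]

    placed: list[tuple[str, dict[str, np.ndarray], float]] = []
    all_coords: list[np.ndarray] = []
    used = np.zeros(len(sites), dtype=bool)
    upper = np.array([cell.a, cell.b, cell.c]) - 1.0
    target_sites: list[np.ndarray] = []   # anchor sites of residues 1 and 2
    for i, res_name in enumerate(comp):
        coords = None
        for j in np.flatnonzero(~used):
            site = sites[j]
            # the two designated perturbation targets (sequence-adjacent, so
            # exempt from each other's clash check) must not pack side by
            # side, or the false rotamer could occupy the deleted side
            # chain's true space
            if i == 1 and np.linalg.norm(site - target_sites[0]) < 9.0:
                continue
            for attempt in range(40):
                chi = (float(rng.choice([-60.0, 60.0, 180.0])),
                       float(rng.uniform(-180.0, 180.0)))
                template = build_residue(res_name, chi)
                R = Rotation.random(random_state=np.random.RandomState(
                    int(rng.integers(0, 2**31 - 1)))).as_matrix()
                jitter = rng.normal(scale=0.5, size=3)
                cand = {n: R @ p + site + jitter for n, p in template.items()}
                pts = np.array(list(cand.values()))
                if np.any(pts < 1.0) or np.any(pts > upper):
                    continue
                if all_coords:
                    prev = np.concatenate(all_coords)
                    dmin = np.min(np.linalg.norm(
                        pts[:, None, :] - prev[None, :, :], axis=2))
                    if dmin < min_separation:
                        continue
                coords = cand
                break
            if coords is not None:
                used[j] = True
                if i < 2:
                    target_sites.append(site)
                break
        if coords is None:
            raise RuntimeError(
                f"could not place residue {i} ({res_name}); cell too small "
                f"for the requested composition")
        if i < 2:   # the designated perturbation targets: well ordered
            b = float(rng.uniform(b_range[0], b_range[0] + 2.0))
        else:
            b = float(rng.uniform(*b_range))
        placed.append((res_name, coords, b))
        all_coords.append(np.array(list(coords.values())))

    atoms: list[Atom] = []
    serial = 1
    for seq, (res_name, coords, b) in enumerate(placed, start=1):
        order = ["N", "CA", "C", "O"] + (["CB"] if "CB" in coords else [])
        order += [n for n, *_ in _SIDE_CHAIN_IC[res_name]]
        for name in order:
            atoms.append(Atom(
                serial=serial, name=name, element=_element_of(name),
                residue_name=res_name, chain="A", residue_seq=seq,
                position=coords[name], occupancy=1.0,
                b_factor=b + rng.uniform(-1.0, 1.0)))
            serial += 1
    return Model(atoms=atoms, cell=cell, space_group=space_group)


def make_toy_model(cell: UnitCell | None = None) -> Model:
    """Three-atom P1 toy cell used by the direct-summation oracles."""
    if cell is None:
        cell = build_cell(10.0, 11.0, 12.0, 90.0, 90.0, 90.0)
    spec = [("C", np.array([1.2, 2.3, 3.4]), 1.0, 5.0),
            ("N", np.array([4.5, 5.6, 2.8]), 0.8, 12.0),
            ("O", np.array([7.1, 3.9, 8.2]), 1.0, 18.0)]
    atoms = [Atom(serial=i + 1, name=f"{el}{i+1}", element=el,
                  residue_name="LIG", chain="A", residue_seq=i + 1,
                  position=pos, occupancy=occ, b_factor=b)
             for i, (el, pos, occ, b) in enumerate(spec)]
    return Model(atoms=atoms, cell=cell, space_group="P1")
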