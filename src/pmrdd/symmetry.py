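"""Unit-cell math, space-group operators and Miller-index bookkeeping.

Serial-crystallography merging only needs a small amount of symmetry
machinery: the triclinic orthogonalization convention used by the PDB,
d-spacings, the rotational part of the space group for mapping every
observed Miller index onto one canonical representative per symmetry
orbit, and real-space operator application for expanding a model to P1
before any Fourier math.

The shipped operator table covers the point/space groups exercised by
the serial datasets this package emulates (P1, P21, P21212, I222,
P3221, P6122).  Operators are stored as generators in a versioned JSON
data file and expanded to the full group by closure at load time; the
closure is verified, so a corrupted table fails loudly.  Reflections
are reduced with a *lexicographic-max* canonicalization over the orbit
(plus Friedel mates) rather than per-group asymmetric-unit wedges: any
total, consistent convention is sufficient for merging, and this one is
trivially testable by brute-force orbit enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "SpaceGroupOps",
    "build_cell",
    "d_spacing",
    "get_space_group",
    "available_space_groups",
    "canonical_hkl",
    "canonicalize_array",
    "orbit",
    "generate_hkl_set",
    "expand_model_p1",
]


# --------------------------------------------------------------------------
# Unit cell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell with PDB-convention orthogonalization.

    The orthogonalization matrix maps fractional to Cartesian
    coordinates with ``a`` along x and ``b`` in the xy plane.  Lengths
    in Angstrom, angles in degrees.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    orthogonalization: np.ndarray = field(repr=False, compare=False, default=None)
    fractionalization: np.ndarray = field(repr=False, compare=False, default=None)
    volume: float = field(compare=False, default=None)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> Cartesian (rows are points)."""
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        """Cartesian -> fractional (rows are points)."""
        return np.asarray(cart, dtype=float) @ self.fractionalization.T

    @property
    def reciprocal_basis(self) -> np.ndarray:
        """Rows are the reciprocal basis vectors a*, b*, c* (1/Angstrom)."""
        return self.fractionalization  # B rows: s_cart = h @ B = B.T h

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def build_cell(a: float, b: float, c: float,
               alpha: float, beta: float, gamma: float) -> UnitCell:
    """Build a :class:`UnitCell` from lengths (A) and angles (deg).

    Raises ``ValueError`` for non-positive lengths, angles outside
    (0, 180) or a geometrically impossible angle combination.
    """
    if min(a, b, c) <= 0:
        raise ValueError("cell lengths must be positive")
    for name, ang in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not 0.0 < ang < 180.0:
            raise ValueError(f"cell angle {name}={ang} outside (0, 180)")
    ca, cb, cg = (np.cos(np.radians(x)) for x in (alpha, beta, gamma))
    sg = np.sin(np.radians(gamma))
    v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if v2 <= 0.0:
        raise ValueError("inconsistent cell angles (non-positive volume term)")
    v = float(np.sqrt(v2))
    ortho = np.array([
        [a, b * cg, c * cb],
        [0.0, b * sg, c * (ca - cb * cg) / sg],
        [0.0, 0.0, c * v / sg],
    ])
    frac = np.linalg.inv(ortho)
    vol = float(a * b * c * v)
    return UnitCell(a, b, c, alpha, beta, gamma,
                    orthogonalization=ortho, fractionalization=frac, volume=vol)


def d_spacing(hkl: Sequence[int] | np.ndarray, cell: UnitCell) -> float | np.ndarray:
    """Resolution d = 1/|s| in Angstrom for one index or an (n, 3) array."""
    H = np.atleast_2d(np.asarray(hkl, dtype=float))
    if np.any(np.all(H == 0, axis=1)):
        raise ValueError("d-spacing undefined for (0,0,0)")
    s = H @ cell.fractionalization  # rows: reciprocal vectors in cartesian
    d = 1.0 / np.linalg.norm(s, axis=1)
    return float(d[0]) if np.asarray(hkl).ndim == 1 else d


# --------------------------------------------------------------------------
# Space groups
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpaceGroupOps:
    """Explicit operator list for one space group.

    ``rotations[i]`` and ``translations[i]`` define the real-space
    operator x' = R x + t on fractional coordinates.  In reciprocal
    space the same rotation acts on a row Miller index as h' = h R.
    ``ambiguity_op`` is the integer reindexing matrix of the merohedral
    indexing ambiguity (h' = h M) for groups where one can occur.
    """

    symbol: str
    rotations: np.ndarray          # (n_ops, 3, 3) int
    translations: np.ndarray       # (n_ops, 3) float, fractions of a cell edge
    ambiguity_op: np.ndarray | None = None

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    def describe(self) -> str:
        """Human-readable operator dump (CLI inspection)."""
        lines = [f"space group {self.symbol}: {self.n_ops} operators"]
        for i, (R, t) in enumerate(zip(self.rotations, self.translations)):
            lines.append(f"  op {i}: R={R.tolist()} t={np.round(t, 6).tolist()}")
        if self.ambiguity_op is not None:
            lines.append(f"  indexing ambiguity: h' = h M, M={self.ambiguity_op.tolist()}")
        return "\n".join(lines)


def _close_group(generators: list[tuple[np.ndarray, np.ndarray]]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Expand a generator list to the full group, translations in 24ths."""
    ident = (np.eye(3, dtype=np.int64), np.zeros(3, dtype=np.int64))
    ops = {_op_key(*ident): ident}
    frontier = [ident]
    gens = [(np.asarray(R, dtype=np.int64), np.asarray(t, dtype=np.int64))
            for R, t in generators]
    while frontier:
        nxt = []
        for R1, t1 in frontier:
            for R2, t2 in gens:
                R = R2 @ R1
                t = (R2 @ t1 + t2) % 24
                key = _op_key(R, t)
                if key not in ops:
                    if len(ops) >= 192:
                        raise ValueError("operator closure did not terminate")
                    ops[key] = (R, t)
                    nxt.append((R, t))
        frontier = nxt
    rots = np.array([R for R, _ in ops.values()], dtype=np.int64)
    trans = np.array([t for _, t in ops.values()], dtype=np.int64)
    # verify closure: every pairwise product is in the set
    keys = set(ops)
    for R1, t1 in ops.values():
        for R2, t2 in ops.values():
            if _op_key(R2 @ R1, (R2 @ t1 + t2) % 24) not in keys:
                raise ValueError("operator set is not closed (corrupt table)")
    return rots, trans / 24.0


def _op_key(R: np.ndarray, t: np.ndarray) -> tuple:
    return (tuple(R.ravel().tolist()), tuple((t % 24).tolist()))


def _normalize_symbol(symbol: str) -> str:
    return symbol.replace(" ", "").replace("_", "").upper()


def _load_table() -> dict:
    with resources.files("pmrdd.data").joinpath("spacegroups.json").open() as fh:
        return json.load(fh)


_CACHE: dict[str, SpaceGroupOps] = {}
_TABLE = _load_table()
_ALIASES: dict[str, str] = {}
for _name, _entry in _TABLE["groups"].items():
    _ALIASES[_normalize_symbol(_name)] = _name
    for _al in _entry.get("aliases", []):
        _ALIASES[_normalize_symbol(_al)] = _name
# "P 1 21 1"-style full symbols reduce to the short key after stripping; also
# accept the short monoclinic form with explicit unique axis dropped.
_ALIASES.setdefault("P121", "P1")


def available_space_groups() -> list[str]:
    return sorted(_TABLE["groups"])


def get_space_group(symbol: str) -> SpaceGroupOps:
    """Look up a shipped space group by (forgiving) Hermann-Mauguin symbol."""
    key = _ALIASES.get(_normalize_symbol(symbol))
    if key is None:
        raise ValueError(
            f"space group {symbol!r} is not in the shipped table "
            f"(available: {', '.join(available_space_groups())})")
    if key not in _CACHE:
        entry = _TABLE["groups"][key]
        gens = [(g["rot"], g["trans24"]) for g in entry["generators"]]
        rots, trans = _close_group(gens)
        amb = entry.get("ambiguity")
        _CACHE[key] = SpaceGroupOps(
            symbol=key,
            rotations=rots,
            translations=trans,
            ambiguity_op=None if amb is None else np.asarray(amb, dtype=np.int64),
        )
    return _CACHE[key]


# --------------------------------------------------------------------------
# Canonical Miller indices
# --------------------------------------------------------------------------

_ENC = 4096  # encoding base for lexicographic comparison; |h| < 2048 always


def _encode(H: np.ndarray) -> np.ndarray:
    return ((H[..., 0].astype(np.int64) * _ENC) + H[..., 1]) * _ENC + H[..., 2]


def _orbit_stack(H: np.ndarray, ops: SpaceGroupOps, friedel: bool) -> np.ndarray:
    """All reciprocal images of each row of H: shape (n_images, n, 3)."""
    imgs = np.einsum("nj,kji->kni", H, ops.rotations)
    if friedel:
        imgs = np.concatenate([imgs, -imgs], axis=0)
    return imgs


def canonicalize_array(H: np.ndarray, ops: SpaceGroupOps,
                       friedel: bool = True) -> np.ndarray:
    """Map each row of an (n, 3) integer index array onto its canonical
    (lexicographically greatest) orbit representative."""
    H = np.asarray(H, dtype=np.int64)
    imgs = _orbit_stack(H, ops, friedel)
    best = np.argmax(_encode(imgs), axis=0)
    return imgs[best, np.arange(H.shape[0])]


def canonical_hkl(hkl: Sequence[int], ops: SpaceGroupOps,
                  friedel: bool = True) -> tuple[tuple[int, int, int], int, bool]:
    """Canonical representative of one index.

    Returns ``(canonical, op_index, friedel_applied)`` where
    ``canonical = (+/-) hkl @ rotations[op_index]``.  Idempotent and
    constant on the symmetry orbit.
    """
    H = np.asarray(hkl, dtype=np.int64)[None, :]
    imgs = _orbit_stack(H, ops, friedel)[:, 0, :]
    best = int(np.argmax(_encode(imgs)))
    n = ops.n_ops
    flipped = best >= n
    return tuple(int(x) for x in imgs[best]), best % n, bool(flipped)


def orbit(hkl: Sequence[int], ops: SpaceGroupOps,
          friedel: bool = True) -> list[tuple[int, int, int]]:
    """Distinct reciprocal images of ``hkl`` under the group (and Friedel)."""
    H = np.asarray(hkl, dtype=np.int64)[None, :]
    imgs = _orbit_stack(H, ops, friedel)[:, 0, :]
    return sorted({tuple(int(x) for x in row) for row in imgs})


def generate_hkl_set(cell: UnitCell, ops: SpaceGroupOps, d_min: float,
                     friedel: bool = True) -> np.ndarray:
    """All canonical Miller indices with d >= d_min, sorted, as (n, 3) ints.

    This is the denominator of completeness: the set of symmetry-unique
    reflections observable to the stated resolution.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    B = cell.fractionalization  # s_cart = h @ B
    smax = 1.0 / d_min
    # exact per-axis bounds: h = s . a, so |h| <= smax * |a| (and likewise
    # for k, l); real axis lengths are the columns of the orthogonalization
    axis_len = np.linalg.norm(cell.orthogonalization, axis=0)
    hmax = np.maximum(1, np.floor(smax * axis_len + 1e-9).astype(int))
    rng = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    s = np.linalg.norm(H @ B, axis=1)
    H = H[s <= smax + 1e-12]
    out = np.unique(canonicalize_array(H, ops, friedel=friedel), axis=0)
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))
    return out[order]


# --------------------------------------------------------------------------
# P1 expansion of models
# --------------------------------------------------------------------------

def expand_model_p1(model, ops: SpaceGroupOps):
    """Apply every symmetry operator to every atom and re-label as P1.

    All structure-factor and density math downstream runs in P1; the
    point group is used only for merging and completeness.  Fractional
    coordinates are wrapped into [0, 1).
    """
    from .model import Atom, Model  # local import to avoid a cycle

    cell = model.cell
    frac = cell.fractionalize(model.coordinates())
    atoms: list[Atom] = []
    serial = 1
    for R, t in zip(ops.rotations, ops.translations):
        new_frac = (frac @ R.T + t) % 1.0
        new_cart = cell.orthogonalize(new_frac)
        for atom, pos in zip(model.atoms, new_cart):
            atoms.append(Atom(
                serial=serial, name=atom.name, element=atom.element,
                residue_name=atom.residue_name, chain=atom.chain,
                residue_seq=atom.residue_seq, position=pos,
                occupancy=atom.occupancy, b_factor=atom.b_factor))
            serial += 1
    return Model(atoms=atoms, cell=cell, space_group="P1",
                 _skip_unique_check=True)
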