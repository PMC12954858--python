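"""Real-space scoring of difference density at the perturbed sites.

The visual judgement of the PMRDD test - green difference density
appearing where the true side chains belong, red density on the wrong
rotamer, and the biased 2mFo-DFc density on the wrong rotamer fading -
is quantified here as means of the normalized (r.m.s.d.-unit) maps over
the recorded atom positions:

* ``recovery_deleted`` - mFo-DFc at the deleted side chain's true atoms;
* ``recovery_moved``   - mFo-DFc at the moved side chain's TRUE atoms;
* ``displacement_negative`` - mFo-DFc at the FALSE rotamer atoms;
* ``bias_index`` - 2mFo-DFc at the false atoms divided by 2mFo-DFc at
  control atoms (unperturbed aromatic side chains): ~1 when the map is
  an Fc map (pure bias), small once the data dominate.

The +/-3 r.m.s.d. thresholds mirror the conventional difference-map
contour level; the bias threshold is this package's own calibration.
Both are configuration, and raw scores are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .maps import MapGrid
from .model import Model, PerturbationRecord

__all__ = ["SiteScores", "Thresholds", "sample_density", "score_sites",
           "verdict"]

STUB_EXCLUSION = 1.6  # Angstrom: scored atoms this close to a retained
                      # model atom are dominated by model density; skip.
                      # Just above the ~1.5 A CB-CG bond so the CG of a
                      # truncated side chain is reliably excluded.
FLAT_RATIO = 1e-6     # fofc map with raw rmsd below this fraction of the
                      # 2mFo-DFc map's is numerically flat: scores are 0


def sample_density(grid: MapGrid, positions: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a normalized map at Cartesian positions.

    Positions are wrapped into the unit cell; values are in r.m.s.d.
    units, which is the only scale scores are defined on.
    """
    if not grid.normalized:
        raise ValueError("sample_density requires a normalized map")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    frac = grid.cell.fractionalize(pos) % 1.0
    dims = np.asarray(grid.dims)
    coords = (frac * dims).T  # grid coordinates, periodic
    return map_coordinates(grid.values, coords, order=1, mode="grid-wrap")


@dataclass
class SiteScores:
    recovery_deleted: float
    recovery_moved: float
    displacement_negative: float
    bias_index: float
    control_density: float
    n_deleted_sites: int = 0
    n_moved_sites: int = 0
    n_false_sites: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "recovery_deleted", "recovery_moved", "displacement_negative",
            "bias_index", "control_density",
            "n_deleted_sites", "n_moved_sites", "n_false_sites")}


def _positions(pairs: list[tuple[str, list[float]]]) -> np.ndarray:
    return np.array([p for _, p in pairs], dtype=float).reshape(-1, 3)


def _exclude_near_model(positions: np.ndarray, model_coords: np.ndarray,
                        cutoff: float = STUB_EXCLUSION) -> np.ndarray:
    """Drop scored positions sitting on top of retained model atoms."""
    if len(positions) == 0 or len(model_coords) == 0:
        return positions
    d = np.linalg.norm(positions[:, None, :] - model_coords[None, :, :], axis=2)
    keep = np.min(d, axis=1) > cutoff
    return positions[keep]


def score_sites(two_fofc: MapGrid, fofc: MapGrid,
                record: PerturbationRecord,
                control_positions: np.ndarray,
                perturbed_model: Model | None = None) -> SiteScores:
    """Evaluate both maps at the perturbation sites.

    Maps must come from the same merged dataset phased with the same
    perturbed model.  ``control_positions`` are side-chain atoms of
    unperturbed, well-ordered residues; their 2mFo-DFc mean anchors the
    bias index.  Scored positions within 1.5 A of a retained model atom
    (e.g. the CB stub) are excluded - their density is dominated by the
    model, not by recovery.
    """
    if len(np.atleast_2d(control_positions)) == 0:
        raise ValueError("control position set is empty")
    model_coords = (perturbed_model.coordinates()
                    if perturbed_model is not None else np.empty((0, 3)))

    deleted = _exclude_near_model(_positions(record.deleted_atom_positions),
                                  model_coords)
    moved_true = _exclude_near_model(_positions(record.true_atom_positions),
                                     model_coords)
    false_pos = _positions(record.false_atom_positions)

    # a perfect-data difference map is flat; its rmsd normalization would
    # only amplify numerical noise, so report exact zeros instead
    diff_flat = fofc.rmsd_raw < FLAT_RATIO * two_fofc.rmsd_raw

    def mean_or_nan(grid, pts):
        if not len(pts):
            return float("nan")
        if grid is fofc and diff_flat:
            return 0.0
        return float(np.mean(sample_density(grid, pts)))

    control = np.atleast_2d(np.asarray(control_positions, dtype=float))
    control_density = float(np.mean(sample_density(two_fofc, control)))
    false_two = mean_or_nan(two_fofc, false_pos)
    denom = control_density if control_density > 0 else float("nan")
    return SiteScores(
        recovery_deleted=mean_or_nan(fofc, deleted),
        recovery_moved=mean_or_nan(fofc, moved_true),
        displacement_negative=mean_or_nan(fofc, false_pos),
        bias_index=false_two / denom,
        control_density=control_density,
        n_deleted_sites=len(deleted),
        n_moved_sites=len(moved_true),
        n_false_sites=len(false_pos),
    )


@dataclass
class Thresholds:
    """Numeric decision rule for "sufficient data".

    ``t_pos``/``t_neg`` follow the +/-3.0 r.m.s.d. contour convention
    for difference maps; ``t_bias`` (fraction of control density left on
    the false rotamer) is this package's calibration.
    """

    t_pos: float = 3.0
    t_neg: float = 3.0
    t_bias: float = 0.35


def verdict(scores: SiteScores,
            thresholds: Thresholds | None = None) -> tuple[bool, list[str]]:
    """Judge one merged dataset; returns (sufficient, failed criteria)."""
    t = thresholds or Thresholds()
    reasons: list[str] = []
    if not scores.recovery_deleted >= t.t_pos:
        reasons.append(
            f"recovery at deleted side chain {scores.recovery_deleted:.2f} "
            f"< {t.t_pos} r.m.s.d.")
    if not scores.recovery_moved >= t.t_pos:
        reasons.append(
            f"recovery at moved side chain's true position "
            f"{scores.recovery_moved:.2f} < {t.t_pos} r.m.s.d.")
    if not scores.displacement_negative <= -t.t_neg:
        reasons.append(
            f"negative density at false rotamer "
            f"{scores.displacement_negative:.2f} > -{t.t_neg} r.m.s.d.")
    if not scores.bias_index <= t.t_bias:
        reasons.append(
            f"2mFo-DFc bias index {scores.bias_index:.2f} > {t.t_bias}")
    return (len(reasons) == 0, reasons)
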