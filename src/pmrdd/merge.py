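"""Indexing-ambiguity resolution, per-crystal scaling and Monte Carlo merging.

The merge stage follows the classic serial pipeline: (1) if the space
group supports a merohedral indexing ambiguity, crystals are sorted
into the two indexing classes by iterative correlation clustering
against a running reference; (2) each crystal gets a multiplicative
scale from least squares against the current merged reference, with
sigma-based outlier rejection and rejection of crystals carrying too
few usable reflections; (3) scaled observations are averaged per
canonical reflection ("Monte Carlo" merging - the unweighted mean whose
error shrinks as 1/sqrt(multiplicity)); and (4) the familiar data-
quality block is computed: completeness, multiplicity, I/sigma, Rsplit,
CC1/2, overall and per resolution shell.

Because this toolkit never refines the model, the R_work/R_free slot of
a beamline "Table 1" is replaced by ``r_model``, a plain amplitude
residual against the (perturbed) model after overall k/B scaling.  It
tracks the same convergence but is NOT comparable to refinement R
factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import ObservationSet, StructureFactorSet
from .symmetry import (SpaceGroupOps, UnitCell, canonicalize_array,
                       d_spacing, generate_hkl_set)

log = logging.getLogger(__name__)

__all__ = [
    "MergedReflection", "MergeStats", "ScaleSolution",
    "resolve_ambiguity", "scale_crystals", "merge_observations",
    "compute_stats", "write_merged", "read_merged",
]

_ENC = 4096


def _encode(H: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=np.int64)
    return ((H[:, 0] + _ENC // 2) * _ENC + (H[:, 1] + _ENC // 2)) * _ENC \
        + (H[:, 2] + _ENC // 2)


def _decode(codes: np.ndarray) -> np.ndarray:
    l = codes % _ENC - _ENC // 2
    rest = codes // _ENC
    k = rest % _ENC - _ENC // 2
    h = rest // _ENC - _ENC // 2
    return np.stack([h, k, l], axis=1)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class MergedReflection:
    hkl: tuple[int, int, int]
    i_mean: float
    sig_i: float
    n_obs: int
    i_half1: float | None = None
    i_half2: float | None = None


@dataclass
class ShellStats:
    d_max: float
    d_min: float
    n_unique: int
    completeness: float
    multiplicity: float
    i_over_sig: float
    r_split: float | None
    cc_half: float | None


@dataclass
class MergeStats:
    """The Table-1-style data-quality block for one merged dataset."""

    completeness: float          # %
    multiplicity: float
    i_over_sig: float
    r_split: float | None        # %
    cc_half: float | None
    n_unique: int
    n_possible: int
    n_obs_total: int
    n_crystals_used: int = 0
    n_crystals_rejected: int = 0
    r_model: float | None = None  # %, no-refinement amplitude residual
    per_shell: list[ShellStats] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "completeness", "multiplicity", "i_over_sig", "r_split",
            "cc_half", "n_unique", "n_possible", "n_obs_total",
            "n_crystals_used", "n_crystals_rejected", "r_model")}
        d["per_shell"] = [vars(s) for s in self.per_shell]
        return d

    def table_text(self) -> str:
        """Fixed-width summary block in the style of a beamline Table 1."""
        def fmt(v, pct=False):
            if v is None:
                return "   n/a"
            return f"{v:6.1f}" if pct else f"{v:6.2f}"
        lines = [
            "Data-processing statistics (overall / by shell)",
            f"  unique reflections   {self.n_unique} of {self.n_possible}",
            f"  completeness (%)     {fmt(self.completeness, pct=True)}",
            f"  multiplicity         {fmt(self.multiplicity)}",
            f"  <I/sigma(I)>         {fmt(self.i_over_sig)}",
            f"  Rsplit (%)           {fmt(self.r_split, pct=True)}",
            f"  CC1/2                {fmt(self.cc_half)}",
            f"  crystals used        {self.n_crystals_used}"
            f" (rejected {self.n_crystals_rejected})",
        ]
        if self.r_model is not None:
            lines.append(f"  Rmodel (%)           {fmt(self.r_model, pct=True)}"
                         "   [amplitude residual, not a refinement R]")
        if self.per_shell:
            lines.append("  shell  d_max  d_min  nuniq  compl%  mult   "
                         "I/sig  Rsplit%  CC1/2")
            for i, s in enumerate(self.per_shell):
                rs = "   n/a" if s.r_split is None else f"{s.r_split:6.1f}"
                cc = "  n/a" if s.cc_half is None else f"{s.cc_half:5.2f}"
                lines.append(
                    f"  {i + 1:4d} {s.d_max:6.2f} {s.d_min:6.2f} "
                    f"{s.n_unique:6d} {s.completeness:6.1f} "
                    f"{s.multiplicity:5.1f} {s.i_over_sig:6.1f} {rs}  {cc}")
        return "\n".join(lines)


@dataclass
class ScaleSolution:
    scales: dict[int, float]             # crystal_id -> k (retained crystals)
    rejected_crystals: list[int]
    n_rejected_obs: int
    converged: bool
    iterations: int


# ---------------------------------------------------------------------------
# Internal stacked representation
# ---------------------------------------------------------------------------

def _stack(sets: Sequence[ObservationSet], ops: SpaceGroupOps
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate observations: (crystal_id, canonical code, I, sigI)."""
    cids, codes, ii, ss = [], [], [], []
    for s in sets:
        if len(s) == 0:
            continue
        canon = canonicalize_array(s.hkl, ops)
        cids.append(np.full(len(s), s.crystal_id, dtype=np.int64))
        codes.append(_encode(canon))
        ii.append(np.asarray(s.intensity, dtype=float))
        ss.append(np.asarray(s.sig, dtype=float))
    if not cids:
        return (np.empty(0, np.int64), np.empty(0, np.int64),
                np.empty(0), np.empty(0))
    return (np.concatenate(cids), np.concatenate(codes),
            np.concatenate(ii), np.concatenate(ss))


def _group_means(codes: np.ndarray, values: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(unique codes, group mean, group count)."""
    uniq, inv = np.unique(codes, return_inverse=True)
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=values)
    return uniq, sums / counts, counts


# ---------------------------------------------------------------------------
# Ambiguity resolution
# ---------------------------------------------------------------------------

def resolve_ambiguity(sets: Sequence[ObservationSet], ops: SpaceGroupOps,
                      max_iter: int = 50, min_common: int = 5,
                      seed: int = 0,
                      reference_fc: StructureFactorSet | None = None,
                      ) -> tuple[list[ObservationSet], np.ndarray]:
    """Sort crystals into consistent indexing by correlation clustering.

    Starting from random assignments, a merged reference is built from
    the currently assigned indexings; each crystal then adopts
    whichever of its two indexings correlates better with the
    reference.  Iterated until stable (or ``max_iter``).  The result is
    consistent only up to one global flip of every crystal - the
    ambiguity is, by construction, unresolvable in an absolute sense.

    Returns the re-indexed sets and an assignment array (0 = kept as
    indexed, 1 = flipped, -1 = unassigned: fewer than ``min_common``
    reflections in common with the reference).

    When ``reference_fc`` (calculated structure factors of the phasing
    model) is supplied, the otherwise arbitrary global orientation is
    anchored to whichever choice correlates better with |Fc|^2 - the
    step a refinement program performs implicitly downstream.
    """
    if ops.ambiguity_op is None:
        raise ValueError(f"space group {ops.symbol} has no ambiguity operator")
    M = ops.ambiguity_op
    n = len(sets)
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, 2, size=n)

    # per-crystal canonical codes for both indexing choices
    codes0, codes1, ivals = [], [], []
    for s in sets:
        codes0.append(_encode(canonicalize_array(s.hkl, ops)))
        codes1.append(_encode(canonicalize_array(s.hkl @ M, ops)))
        ivals.append(np.asarray(s.intensity, dtype=float))

    # running reference: per-code intensity sum and count over all crystals
    # under their current assignment
    ref_sum: dict[int, float] = {}
    ref_cnt: dict[int, int] = {}

    def add(i, sign):
        codes = codes1[i] if assign[i] else codes0[i]
        for c, v in zip(codes.tolist(), ivals[i].tolist()):
            ref_sum[c] = ref_sum.get(c, 0.0) + sign * v
            ref_cnt[c] = ref_cnt.get(c, 0) + sign

    for i in range(n):
        add(i, +1)

    def corr_loo(i, codes):
        """Correlation of crystal i against the leave-one-out reference."""
        cur = codes1[i] if assign[i] else codes0[i]
        own_sum: dict[int, float] = {}
        own_cnt: dict[int, int] = {}
        for c, v in zip(cur.tolist(), ivals[i].tolist()):
            own_sum[c] = own_sum.get(c, 0.0) + v
            own_cnt[c] = own_cnt.get(c, 0) + 1
        xs, ys = [], []
        for c, v in zip(codes.tolist(), ivals[i].tolist()):
            cnt = ref_cnt.get(c, 0) - own_cnt.get(c, 0)
            if cnt <= 0:
                continue
            xs.append(v)
            ys.append((ref_sum[c] - own_sum.get(c, 0.0)) / cnt)
        ncom = len(xs)
        if ncom < 3:
            return -2.0, ncom
        xs, ys = np.asarray(xs), np.asarray(ys)
        if xs.std() == 0 or ys.std() == 0:
            return -2.0, ncom
        return float(np.corrcoef(xs, ys)[0, 1]), ncom

    for _ in range(max_iter):
        changed = 0
        for i in rng.permutation(n):
            keep = corr_loo(i, codes0[i])
            alt = corr_loo(i, codes1[i])
            if keep[1] < min_common and alt[1] < min_common:
                continue
            want = 1 if alt[0] > keep[0] else 0
            if want != assign[i]:
                add(i, -1)
                assign[i] = want
                add(i, +1)
                changed += 1
        if changed == 0:
            break

    if reference_fc is not None:
        # anchor the global flip to the phasing model
        def model_corr(flip_all):
            a = assign ^ 1 if flip_all else assign
            codes = np.concatenate([codes1[i] if a[i] else codes0[i]
                                    for i in range(n)])
            uniq, mean, _ = _group_means(codes, np.concatenate(ivals))
            i_calc = np.abs(reference_fc.lookup(_decode(uniq))) ** 2
            if mean.std() == 0 or i_calc.std() == 0:
                return -2.0
            return float(np.corrcoef(mean, i_calc)[0, 1])

        if model_corr(True) > model_corr(False):
            assign = assign ^ 1

    # flag crystals that never had enough common reflections
    out_assign = assign.astype(np.int64)
    out_sets: list[ObservationSet] = []
    for i, s in enumerate(sets):
        ncom = max(corr_loo(i, codes0[i])[1], corr_loo(i, codes1[i])[1])
        if ncom < min_common:
            out_assign[i] = -1
            out_sets.append(s)
            continue
        if out_assign[i] == 1:
            out_sets.append(ObservationSet(
                crystal_id=s.crystal_id, hkl=s.hkl @ M,
                intensity=s.intensity.copy(), sig=s.sig.copy(),
                true_scale=s.true_scale, flipped=s.flipped))
        else:
            out_sets.append(s)
    return out_sets, out_assign


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def scale_crystals(sets: Sequence[ObservationSet], ops: SpaceGroupOps,
                   min_refl: int = 10, max_iter: int = 30,
                   tol: float = 1e-6, sigma_cut: float = 4.0,
                   ) -> ScaleSolution:
    """Per-crystal multiplicative scales by alternating least squares.

    Alternates (a) reference = merge of currently scaled data and
    (b) k_c = sum(I_ref I_c) / sum(I_c^2) over each crystal's
    reflections, which is the non-negative least-squares scale against
    the reference.  Observations deviating by more than ``sigma_cut``
    pooled sigmas from the reference (two rejection passes) and
    crystals with fewer than ``min_refl`` usable observations or a
    non-positive scale are rejected.  Scales are normalized to mean 1.
    """
    sets = [s for s in sets if len(s) > 0]
    if len(sets) < 2:
        raise ValueError("scaling needs at least two crystals")
    cids, codes, ii, ss = _stack(sets, ops)
    ids = np.array([s.crystal_id for s in sets], dtype=np.int64)
    id_to_row = {cid: r for r, cid in enumerate(ids.tolist())}
    rows = np.array([id_to_row[c] for c in cids.tolist()], dtype=np.int64)

    k = np.ones(len(sets))
    alive_obs = np.ones(len(codes), dtype=bool)
    alive_xtal = np.ones(len(sets), dtype=bool)
    n_rej_obs = 0
    converged = False
    it = 0
    rejection_passes = 0
    while it < max_iter:
        it += 1
        use = alive_obs & alive_xtal[rows]
        scaled = k[rows] * ii
        uniq, ref_mean, _ = _group_means(codes[use], scaled[use])
        pos = np.searchsorted(uniq, codes)
        ok = (pos < len(uniq))
        ok[ok] &= uniq[pos[ok]] == codes[ok]
        ref = np.where(ok, ref_mean[np.clip(pos, 0, len(uniq) - 1)], np.nan)

        usable = alive_obs & alive_xtal[rows] & np.isfinite(ref)
        n_use = np.bincount(rows[usable], minlength=len(sets))
        denom = np.bincount(rows[usable], weights=ii[usable] ** 2,
                            minlength=len(sets))
        numer = np.bincount(rows[usable],
                            weights=np.where(usable, ref, 0.0)[usable] * ii[usable],
                            minlength=len(sets))
        with np.errstate(divide="ignore", invalid="ignore"):
            kk = numer / denom
        good = alive_xtal & (n_use >= min_refl) & (denom > 0) \
            & np.isfinite(kk) & (kk > 0)
        alive_xtal &= good
        k_new = np.where(good, kk, k)
        if not np.any(alive_xtal):
            raise ValueError("all crystals rejected during scaling")
        delta = np.max(np.abs(k_new[alive_xtal] - k[alive_xtal])
                       / np.maximum(np.abs(k[alive_xtal]), 1e-30))
        k = k_new
        if delta < tol:
            if rejection_passes < 2:
                rejection_passes += 1
                n_new = _reject_outliers(codes, ii, rows, k, alive_obs,
                                         alive_xtal, sigma_cut)
                n_rej_obs += n_new
                if n_new == 0:
                    converged = True
                    break
            else:
                converged = True
                break

    # normalize retained scales to mean 1
    k_live = k[alive_xtal]
    k = k / k_live.mean()
    scales = {int(ids[r]): float(k[r]) for r in np.flatnonzero(alive_xtal)}
    rejected = [int(ids[r]) for r in np.flatnonzero(~alive_xtal)]
    return ScaleSolution(scales=scales, rejected_crystals=rejected,
                         n_rejected_obs=n_rej_obs, converged=converged,
                         iterations=it)


def _reject_outliers(codes, ii, rows, k, alive_obs, alive_xtal,
                     sigma_cut) -> int:
    """One pass of sigma-based outlier rejection; returns count rejected."""
    use = alive_obs & alive_xtal[rows]
    scaled = k[rows] * ii
    uniq, inv = np.unique(codes[use], return_inverse=True)
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=scaled[use])
    means = sums / counts
    sq = np.bincount(inv, weights=(scaled[use] - means[inv]) ** 2)
    sd = np.sqrt(sq / np.maximum(counts - 1, 1))
    # pooled sigma per reflection; no rejection where n < 3 or sd ~ 0
    thresh = sigma_cut * sd
    floor = 1e-8 * np.abs(means) + 1e-12
    thresh = np.maximum(thresh, floor)
    resid = np.abs(scaled[use] - means[inv])
    bad_local = (resid > thresh[inv]) & (counts[inv] >= 3)
    n_bad = int(bad_local.sum())
    if n_bad:
        idx_use = np.flatnonzero(use)
        alive_obs[idx_use[bad_local]] = False
    return n_bad


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_observations(sets: Sequence[ObservationSet],
                       scales: ScaleSolution | None,
                       ops: SpaceGroupOps) -> list[MergedReflection]:
    """Monte Carlo merge: unweighted mean of scaled intensities per
    canonical reflection, standard error from the sample spread (the
    propagated sigma where only one observation exists), and odd/even
    crystal-parity half-set means for Rsplit/CC1/2."""
    keep = []
    for s in sets:
        if scales is not None and s.crystal_id not in scales.scales:
            continue
        keep.append(s)
    cids, codes, ii, ss = _stack(keep, ops)
    if len(codes) == 0:
        return []
    k = np.array([1.0 if scales is None else scales.scales[int(c)]
                  for c in cids])
    scaled = k * ii
    scaled_sig = k * ss
    uniq, inv = np.unique(codes, return_inverse=True)
    counts = np.bincount(inv)
    mean = np.bincount(inv, weights=scaled) / counts
    sq = np.bincount(inv, weights=(scaled - mean[inv]) ** 2)
    sd = np.sqrt(sq / np.maximum(counts - 1, 1))
    sem = sd / np.sqrt(counts)
    # single observations: fall back to the propagated sigma
    prop = np.bincount(inv, weights=scaled_sig) / counts
    sem = np.where(counts == 1, prop, sem)

    parity = cids % 2
    out: list[MergedReflection] = []
    half_mean = {}
    for p in (0, 1):
        m = parity == p
        if np.any(m):
            u, mn, _ = _group_means(codes[m], scaled[m])
            half_mean[p] = dict(zip(u.tolist(), mn.tolist()))
        else:
            half_mean[p] = {}
    hkls = _decode(uniq)
    for j, code in enumerate(uniq.tolist()):
        out.append(MergedReflection(
            hkl=tuple(int(x) for x in hkls[j]),
            i_mean=float(mean[j]), sig_i=float(sem[j]), n_obs=int(counts[j]),
            i_half1=half_mean[0].get(code), i_half2=half_mean[1].get(code)))
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _rsplit(h1: np.ndarray, h2: np.ndarray) -> float | None:
    denom = 0.5 * float(np.sum(h1 + h2))
    if len(h1) == 0 or denom == 0:
        return None
    return 100.0 / math.sqrt(2.0) * float(np.sum(np.abs(h1 - h2))) / denom


def _cc(h1: np.ndarray, h2: np.ndarray) -> float | None:
    if len(h1) < 3 or h1.std() == 0 or h2.std() == 0:
        return None
    return float(np.corrcoef(h1, h2)[0, 1])


def compute_stats(merged: Sequence[MergedReflection], cell: UnitCell,
                  ops: SpaceGroupOps, d_min: float, n_shells: int = 10,
                  fc: StructureFactorSet | None = None,
                  n_crystals_used: int = 0, n_crystals_rejected: int = 0,
                  ) -> MergeStats:
    """Completeness, multiplicity, I/sigma, Rsplit, CC1/2 - overall and
    in ``n_shells`` equal-volume resolution shells.

    When ``fc`` (calculated structure factors of the phasing model) is
    given, ``r_model`` - the overall amplitude residual after k/B
    scaling - is included as the no-refinement stand-in for R factors.
    """
    if not merged:
        raise ValueError("no merged reflections")
    H = np.array([m.hkl for m in merged], dtype=np.int64)
    d = d_spacing(H, cell)
    i_mean = np.array([m.i_mean for m in merged])
    sig = np.array([m.sig_i for m in merged])
    nobs = np.array([m.n_obs for m in merged])
    possible = generate_hkl_set(cell, ops, d_min)
    n_possible = len(possible)
    both = np.array([m.i_half1 is not None and m.i_half2 is not None
                     for m in merged])
    h1 = np.array([m.i_half1 for m in merged if m.i_half1 is not None
                   and m.i_half2 is not None])
    h2 = np.array([m.i_half2 for m in merged if m.i_half1 is not None
                   and m.i_half2 is not None])

    stats = MergeStats(
        completeness=100.0 * len(merged) / n_possible,
        multiplicity=float(nobs.sum() / len(merged)),
        i_over_sig=float(np.mean(i_mean / np.where(sig > 0, sig, np.inf))),
        r_split=_rsplit(h1, h2),
        cc_half=_cc(h1, h2),
        n_unique=len(merged),
        n_possible=n_possible,
        n_obs_total=int(nobs.sum()),
        n_crystals_used=n_crystals_used,
        n_crystals_rejected=n_crystals_rejected,
    )

    if fc is not None:
        from .maps import scale_fobs_to_fc  # late import; maps depends on merge
        try:
            scale = scale_fobs_to_fc(merged, fc)
            stats.r_model = scale.r_model
        except ValueError:
            stats.r_model = None

    # equal-volume shells in 1/d^3 between d_max(observed) and d_min
    d_all = d_spacing(possible, cell)
    inv3 = np.linspace(1.0 / d_all.max() ** 3, 1.0 / d_min ** 3, n_shells + 1)
    inv3[0] = 0.0  # catch anything at lower resolution than the possible max
    for j in range(n_shells):
        lo, hi = inv3[j], inv3[j + 1]
        sel = (1.0 / d ** 3 > lo) & (1.0 / d ** 3 <= hi + 1e-12)
        sel_all = (1.0 / d_all ** 3 > lo) & (1.0 / d_all ** 3 <= hi + 1e-12)
        if not np.any(sel_all):
            continue
        sb = sel & both
        stats.per_shell.append(ShellStats(
            d_max=float(np.max(d[sel])) if np.any(sel) else float("nan"),
            d_min=float(hi ** (-1.0 / 3.0)),
            n_unique=int(sel.sum()),
            completeness=100.0 * sel.sum() / sel_all.sum(),
            multiplicity=float(nobs[sel].mean()) if np.any(sel) else 0.0,
            i_over_sig=float(np.mean(i_mean[sel] / np.where(sig[sel] > 0,
                                                            sig[sel], np.inf)))
            if np.any(sel) else 0.0,
            r_split=_rsplit(np.array([m.i_half1 for m, b in zip(merged, sb) if b]),
                            np.array([m.i_half2 for m, b in zip(merged, sb) if b])),
            cc_half=_cc(np.array([m.i_half1 for m, b in zip(merged, sb) if b]),
                        np.array([m.i_half2 for m, b in zip(merged, sb) if b])),
        ))
    return stats


# ---------------------------------------------------------------------------
# Merged-reflection text format
# ---------------------------------------------------------------------------

def write_merged(merged: Sequence[MergedReflection], path: str | Path,
                 header: dict | None = None) -> None:
    """CrystFEL-hkl-like text table: ``h k l I sigI nmeas`` plus comments."""
    lines = ["# pmrdd merged reflections v1"]
    for key, val in (header or {}).items():
        lines.append(f"# {key} {val}")
    lines.append("#  h   k   l          I       sigI  nmeas")
    for m in merged:
        h, k, l = m.hkl
        lines.append(f"{h:4d}{k:4d}{l:4d} {m.i_mean:12.4f} {m.sig_i:10.4f} "
                     f"{m.n_obs:6d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_merged(path: str | Path) -> list[MergedReflection]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{line_no}: expected 6 columns")
            h, k, l = (int(x) for x in parts[:3])
            out.append(MergedReflection(hkl=(h, k, l), i_mean=float(parts[3]),
                                        sig_i=float(parts[4]),
                                        n_obs=int(parts[5])))
    return out
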