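"""Model-phased electron-density maps from merged serial intensities.

The chain is the standard one that a refinement program would normally
perform after its last cycle, minus the refinement itself: observed
amplitudes |Fo| = sqrt(max(I, 0)) are brought onto the scale of the
calculated amplitudes by an overall k/B (Wilson-style) fit; a
sigmaA-like figure of merit m and Luzzati-like scale D are estimated
per resolution shell from the correlation of normalized amplitudes;
2m|Fo| - D|Fc| and m|Fo| - D|Fc| coefficients are formed with
calculated phases; and an inverse FFT produces a real-space grid
normalized to mean 0 / r.m.s.d. 1 - the unit in which maps are
contoured and in which PMRDD scores are defined.

The "filled" behaviour of the 2mFo-DFc map is reproduced exactly:
reflections with no observation receive amplitude D|Fc|, which is why a
weak dataset yields a map that is effectively an Fc map - the model
phase bias the PMRDD test is designed to expose.  All reflections are
treated as acentric (the centric Bessel branch is omitted; see the
methods note).
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import special

from .merge import MergedReflection
from .simulate import StructureFactorSet
from .symmetry import SpaceGroupOps, UnitCell, canonicalize_array, d_spacing

__all__ = [
    "AmplitudeScale", "WeightSet", "MapCoefficients", "MapGrid",
    "scale_fobs_to_fc", "estimate_weights", "make_coefficients",
    "synthesize_map", "write_ccp4",
]

MAX_GRID = 512  # per-axis FFT guard


# ---------------------------------------------------------------------------
# Fo -> Fc scaling
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeScale:
    k: float
    b_overall: float
    n_common: int
    r_model: float | None = None       # % amplitude residual at the solution
    per_shell_ratio: list[tuple[float, float]] = field(default_factory=list)

    def apply(self, fc_amp: np.ndarray, s: np.ndarray) -> np.ndarray:
        """k exp(-B s^2/4) |Fc| on the observed scale."""
        return self.k * np.exp(-self.b_overall * s ** 2 / 4.0) * fc_amp


def _observed_amplitudes(merged: Sequence[MergedReflection]
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    H = np.array([m.hkl for m in merged], dtype=np.int64).reshape(-1, 3)
    I = np.array([m.i_mean for m in merged])
    fo = np.sqrt(np.clip(I, 0.0, None))
    weight = (I > 0).astype(float)   # negative-I reflections: |Fo|=0, weight 0
    return H, fo, weight


def scale_fobs_to_fc(merged: Sequence[MergedReflection],
                     fc: StructureFactorSet, n_shells: int = 10,
                     min_common: int = 20) -> AmplitudeScale:
    """Fit |Fo| ~ k exp(-B s^2/4) |Fc|.

    A log-linear fit on shell-mean amplitude ratios seeds (k, B), then
    one Gauss-Newton polish minimizes the unlogged least-squares
    residual.  Negative-intensity reflections enter with |Fo| = 0 and
    zero weight.
    """
    H, fo, w = _observed_amplitudes(merged)
    fc_amp = fc.amplitudes(H)
    s = 1.0 / d_spacing(H, fc.cell)
    ok = (fc_amp > 0) & (w > 0)
    if int(ok.sum()) < min_common:
        raise ValueError(f"only {int(ok.sum())} common reflections; "
                         f"need >= {min_common} for amplitude scaling")

    s2 = s[ok] ** 2
    edges = np.quantile(s2, np.linspace(0, 1, min(n_shells, max(2, ok.sum() // 5)) + 1))
    which = np.clip(np.searchsorted(edges, s2, side="right") - 1, 0, len(edges) - 2)
    xs, ys, ratios = [], [], []
    for j in range(len(edges) - 1):
        m = which == j
        if m.sum() < 3:
            continue
        ratio = float(np.sum(fo[ok][m]) / np.sum(fc_amp[ok][m]))
        if ratio <= 0:
            continue
        xs.append(float(np.mean(s2[m])))
        ys.append(math.log(ratio))
        ratios.append((float(np.mean(s2[m])), ratio))
    if len(xs) >= 2:
        slope, intercept = np.polyfit(xs, ys, 1)
        k0 = float(np.exp(intercept))
        b0 = float(-4.0 * slope)
    else:
        k0 = float(np.sum(fo[ok]) / np.sum(fc_amp[ok]))
        b0 = 0.0

    # Gauss-Newton polish on r = fo - k exp(-B s^2/4) fc
    k, b = k0, b0
    for _ in range(20):
        e = np.exp(-b * s[ok] ** 2 / 4.0)
        model = k * e * fc_amp[ok]
        r = fo[ok] - model
        J = np.stack([e * fc_amp[ok], -k * (s[ok] ** 2 / 4.0) * e * fc_amp[ok]],
                     axis=1)
        try:
            step, *_ = np.linalg.lstsq(J, r, rcond=None)
        except np.linalg.LinAlgError:
            break
        k_new, b_new = k + step[0], b + step[1]
        if k_new <= 0:
            break
        if abs(step[0]) < 1e-12 * max(abs(k), 1.0) and abs(step[1]) < 1e-10:
            k, b = k_new, b_new
            break
        k, b = k_new, b_new
    scaled_fc = k * np.exp(-b * s[ok] ** 2 / 4.0) * fc_amp[ok]
    denom = float(np.sum(fo[ok]))
    r_model = (100.0 * float(np.sum(np.abs(fo[ok] - scaled_fc))) / denom
               if denom > 0 else None)
    return AmplitudeScale(k=float(k), b_overall=float(b),
                          n_common=int(ok.sum()), r_model=r_model,
                          per_shell_ratio=ratios)


# ---------------------------------------------------------------------------
# sigmaA-style weights
# ---------------------------------------------------------------------------

@dataclass
class WeightSet:
    hkl: np.ndarray              # (n, 3) observed reflections
    m: np.ndarray                # (n,) figure of merit in [0, 1]
    d_of: np.ndarray             # (n,) Luzzati-like D per reflection's shell
    shell_sigma_a: list[float]
    shell_d: list[float]
    shell_edges_s3: np.ndarray   # shell boundaries in s^3 = 1/d^3
    default_d: float = 1.0       # used for reflections with no observations

    def d_for(self, s: np.ndarray) -> np.ndarray:
        """Shell D for arbitrary reflections (fill amplitudes)."""
        if not self.shell_d:
            return np.full(len(s), self.default_d)
        which = np.clip(np.searchsorted(self.shell_edges_s3, s ** 3,
                                        side="right") - 1,
                        0, len(self.shell_d) - 1)
        return np.asarray(self.shell_d)[which]


def estimate_weights(merged: Sequence[MergedReflection],
                     fc: StructureFactorSet, scale: AmplitudeScale,
                     n_shells: int = 10, sigma_a_clamp=(0.05, 0.99),
                     min_per_shell: int = 5) -> WeightSet:
    """Per-shell sigmaA, D and per-reflection figure of merit m.

    Within each equal-volume shell, amplitudes are normalized
    (E = F / sqrt(<F^2>)), sigmaA is the clamped correlation of Eo and
    Ec, D = sigmaA sqrt(<Fo^2>/<Fc^2>), and each acentric reflection
    gets m = I1(X)/I0(X) with X = 2 sigmaA Eo Ec / (1 - sigmaA^2).
    Shells thinner than ``min_per_shell`` merge into their neighbour.
    """
    H, fo, w = _observed_amplitudes(merged)
    s = 1.0 / d_spacing(H, fc.cell)
    fc_amp = scale.apply(fc.amplitudes(H), s)

    s3 = s ** 3
    order = np.argsort(s3)
    edges = np.quantile(s3, np.linspace(0, 1, n_shells + 1))
    edges[0] -= 1e-12
    # merge thin shells into the neighbour below
    bins = []
    lo = edges[0]
    for j in range(1, len(edges)):
        sel = (s3 > lo) & (s3 <= edges[j])
        if sel.sum() >= min_per_shell or j == len(edges) - 1:
            bins.append((lo, edges[j]))
            lo = edges[j]
    if len(bins) >= 2:
        lo0, hi0 = bins[-1]
        if np.sum((s3 > lo0) & (s3 <= hi0)) < min_per_shell:
            bins[-2] = (bins[-2][0], hi0)
            bins.pop()

    m_out = np.zeros(len(H))
    d_out = np.ones(len(H))
    shell_sa, shell_d = [], []
    shell_edges = [bins[0][0]] if bins else [0.0]
    lo_c, hi_c = sigma_a_clamp
    for lo, hi in bins:
        sel = (s3 > lo) & (s3 <= hi)
        shell_edges.append(hi)
        fo_s, fc_s = fo[sel], fc_amp[sel]
        mean_fo2 = float(np.mean(fo_s ** 2))
        mean_fc2 = float(np.mean(fc_s ** 2))
        if mean_fo2 <= 0 or mean_fc2 <= 0 or sel.sum() < 3:
            sa = lo_c
        else:
            eo = fo_s / math.sqrt(mean_fo2)
            ec = fc_s / math.sqrt(mean_fc2)
            if eo.std() == 0 or ec.std() == 0:
                sa = hi_c
            else:
                sa = float(np.corrcoef(eo, ec)[0, 1])
        sa = float(np.clip(sa, lo_c, hi_c))
        D = sa * math.sqrt(mean_fo2 / mean_fc2) if mean_fc2 > 0 else 1.0
        shell_sa.append(sa)
        shell_d.append(D)
        if sel.sum() and mean_fo2 > 0 and mean_fc2 > 0:
            eo = fo_s / math.sqrt(mean_fo2)
            ec = fc_s / math.sqrt(mean_fc2)
            X = 2.0 * sa * eo * ec / (1.0 - sa * sa)
            m_out[sel] = special.i1e(X) / special.i0e(X)
        d_out[sel] = D
    return WeightSet(hkl=H, m=m_out, d_of=d_out,
                     shell_sigma_a=shell_sa, shell_d=shell_d,
                     shell_edges_s3=np.asarray(shell_edges))


# ---------------------------------------------------------------------------
# Map coefficients
# ---------------------------------------------------------------------------

@dataclass
class MapCoefficients:
    """Canonical-reflection map coefficients (amplitude + phase deg)."""

    hkl: np.ndarray              # (n, 3)
    amplitude: np.ndarray        # (n,)
    phase_deg: np.ndarray        # (n,) calculated phase
    map_type: str                # "two_fofc" | "fofc"
    mode: str                    # "simple" | "ml"
    fill_missing: bool

    def as_table(self) -> str:
        lines = ["#  h   k   l      amp    phase"]
        for (h, k, l), a, p in zip(self.hkl.tolist(), self.amplitude,
                                   self.phase_deg):
            lines.append(f"{h:4d}{k:4d}{l:4d} {a:10.4f} {p:8.2f}")
        return "\n".join(lines)


def make_coefficients(merged: Sequence[MergedReflection],
                      fc: StructureFactorSet, ops: SpaceGroupOps,
                      scale: AmplitudeScale, weights: WeightSet | None,
                      map_type: str = "two_fofc", mode: str = "ml",
                      fill_missing: bool = True,
                      all_hkl: np.ndarray | None = None) -> MapCoefficients:
    """Form 2m|Fo| - D|Fc| or m|Fo| - D|Fc| coefficients with phi_c.

    ``all_hkl`` is the complete canonical set to the resolution limit
    (usually ``generate_hkl_set``); canonical reflections without an
    observation get D|Fc| in a filled 2mFo-DFc map and 0 in a
    difference map.  In ``simple`` mode m = D = 1.
    """
    if map_type not in ("two_fofc", "fofc"):
        raise ValueError("map_type must be 'two_fofc' or 'fofc'")
    if mode not in ("simple", "ml"):
        raise ValueError("mode must be 'simple' or 'ml'")
    H_obs, fo, wpos = _observed_amplitudes(merged)
    s_obs = 1.0 / d_spacing(H_obs, fc.cell)
    fc_complex = fc.lookup(H_obs)
    fc_scaled = scale.apply(np.abs(fc_complex), s_obs)
    if mode == "ml":
        if weights is None:
            raise ValueError("ml mode needs a WeightSet")
        m = weights.m
        D = weights.d_of
    else:
        m = np.ones(len(H_obs))
        D = np.ones(len(H_obs))
    if map_type == "two_fofc":
        amp = 2.0 * m * fo - D * fc_scaled
    else:
        amp = m * fo - D * fc_scaled
    phase = np.degrees(np.angle(fc_complex))
    hkl_list = [tuple(h) for h in H_obs.tolist()]
    amps = dict(zip(hkl_list, amp.tolist()))
    phases = dict(zip(hkl_list, phase.tolist()))

    if all_hkl is not None:
        observed = set(hkl_list)
        missing = [tuple(h) for h in np.asarray(all_hkl, dtype=np.int64).tolist()
                   if tuple(h) not in observed]
        if missing:
            Hm = np.array(missing, dtype=np.int64)
            sm = 1.0 / d_spacing(Hm, fc.cell)
            fcm = fc.lookup(Hm)
            if map_type == "two_fofc" and fill_missing:
                Dm = (weights.d_for(sm) if (mode == "ml" and weights is not None)
                      else np.ones(len(Hm)))
                fill_amp = Dm * scale.apply(np.abs(fcm), sm)
            else:
                fill_amp = np.zeros(len(Hm))
            for h, a, p in zip(missing, fill_amp, np.degrees(np.angle(fcm))):
                amps[h] = float(a)
                phases[h] = float(p)
    H_all = np.array(sorted(amps), dtype=np.int64)
    return MapCoefficients(
        hkl=H_all,
        amplitude=np.array([amps[tuple(h)] for h in H_all.tolist()]),
        phase_deg=np.array([phases[tuple(h)] for h in H_all.tolist()]),
        map_type=map_type, mode=mode, fill_missing=fill_missing)


# ---------------------------------------------------------------------------
# Real-space synthesis
# ---------------------------------------------------------------------------

@dataclass
class MapGrid:
    """Real-space density sampled on the unit cell, mean 0 / r.m.s.d. 1."""

    values: np.ndarray           # (nx, ny, nz), x fastest logical axis
    cell: UnitCell
    normalized: bool
    mean_raw: float
    rmsd_raw: float

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape


def _grid_dims(cell: UnitCell, d_min: float, grid_factor: int) -> tuple[int, int, int]:
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = max(4, int(math.ceil(grid_factor * length / d_min)))
        n += n % 2  # even sizes keep FFT layouts simple
        if n > MAX_GRID:
            raise ValueError(
                f"grid dimension {n} exceeds {MAX_GRID}; use a coarser "
                "grid_factor or lower resolution")
        dims.append(n)
    return tuple(dims)


def synthesize_map(coeffs: MapCoefficients, ops: SpaceGroupOps,
                   fc_p1: StructureFactorSet, grid_factor: int = 3,
                   ) -> MapGrid:
    """Inverse-FFT map synthesis on a grid with spacing <= d_min/grid_factor.

    Canonical coefficients are expanded to the full P1 half-sphere by
    copying each amplitude to every orbit member and taking that
    member's phase from the P1-expanded calculated structure factors -
    equivalent to applying per-operator phase-shift rules, but directly
    verifiable.  F(000) is excluded, so the raw map has mean zero; the
    stored values are normalized to r.m.s.d. 1 (the contouring unit).
    """
    cell = fc_p1.cell
    dims = _grid_dims(cell, fc_p1.d_min, grid_factor)
    amp_of = {tuple(h): a for h, a in zip(coeffs.hkl.tolist(), coeffs.amplitude)}

    canon = canonicalize_array(fc_p1.hkl, ops)
    phases = np.angle(fc_p1.f)
    G = np.zeros(dims, dtype=complex)
    nmax = np.max(np.abs(fc_p1.hkl), axis=0)
    if np.any(nmax >= np.asarray(dims) // 2):
        raise ValueError("grid too coarse for the reflection set (aliasing)")
    for (h, k, l), ckey, phi in zip(fc_p1.hkl.tolist(),
                                    map(tuple, canon.tolist()), phases):
        a = amp_of.get(ckey)
        if a is None or a == 0.0:
            continue
        F = a * np.exp(1j * phi)
        G[h % dims[0], k % dims[1], l % dims[2]] += F
        G[-h % dims[0], -k % dims[1], -l % dims[2]] += np.conj(F)
    # rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x): a forward FFT of G
    rho = np.fft.fftn(G).real / cell.volume
    mean = float(rho.mean())
    rmsd = float(np.sqrt(np.mean((rho - mean) ** 2)))
    if rmsd > 0:
        values = (rho - mean) / rmsd
    else:
        values = rho - mean  # flat map (e.g. perfect-data difference map)
    return MapGrid(values=values, cell=cell, normalized=True,
                   mean_raw=mean, rmsd_raw=rmsd)


# ---------------------------------------------------------------------------
# CCP4/MRC output (inspection only)
# ---------------------------------------------------------------------------

def write_ccp4(grid: MapGrid, path: str | Path) -> None:
    """Minimal mode-2 CCP4/MRC map (X fastest, full cell) for viewers."""
    nx, ny, nz = grid.dims
    c = grid.cell
    data = np.ascontiguousarray(
        np.transpose(grid.values, (2, 1, 0)).astype("<f4"))  # section=z
    header = bytearray(1024)
    def put(i, fmt, *vals):
        struct.pack_into(fmt, header, i, *vals)
    put(0, "<3i", nx, ny, nz)
    put(12, "<i", 2)                       # mode 2: float32
    put(16, "<3i", 0, 0, 0)                # start
    put(28, "<3i", nx, ny, nz)             # sampling
    put(40, "<6f", c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    put(64, "<3i", 1, 2, 3)                # axis order X, Y, Z
    vals = grid.values
    put(76, "<3f", float(vals.min()), float(vals.max()), float(vals.mean()))
    put(88, "<i", 1)                       # P1 expanded
    put(208, "<4s", b"MAP ")
    put(212, "<4B", 0x44, 0x44, 0, 0)      # little-endian machine stamp
    put(216, "<f", float(vals.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
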