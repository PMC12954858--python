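"""Amplitude scaling, sigmaA weights, map coefficients and FFT synthesis."""

import numpy as np
import pytest

from pmrdd.maps import (AmplitudeScale, estimate_weights, make_coefficients,
                        scale_fobs_to_fc, synthesize_map, write_ccp4)
from pmrdd.merge import MergedReflection
from pmrdd.simulate import calc_structure_factors
from pmrdd.symmetry import (build_cell, d_spacing, expand_model_p1,
                            generate_hkl_set, get_space_group)


def _merged_from_amplitudes(fc, amp, n_obs=4):
    out = []
    for h, a in zip(fc.hkl.tolist(), amp):
        i = float(a) ** 2 if a >= 0 else -float(a) ** 2
        out.append(MergedReflection(hkl=tuple(h), i_mean=i,
                                    sig_i=max(abs(i), 1.0) * 0.01,
                                    n_obs=n_obs, i_half1=i, i_half2=i))
    return out


# ---------------------------------------------------------------------------
# Fo -> Fc scaling
# ---------------------------------------------------------------------------

def test_scale_recovers_constructed_k_and_b(toy_fc):
    s = 1.0 / d_spacing(toy_fc.hkl, toy_fc.cell)
    fo = 2.0 * np.exp(-5.0 * s ** 2 / 4.0) * np.abs(toy_fc.f)
    merged = _merged_from_amplitudes(toy_fc, fo)
    scale = scale_fobs_to_fc(merged, toy_fc)
    assert scale.k == pytest.approx(2.0, abs=1e-6)
    assert scale.b_overall == pytest.approx(5.0, abs=1e-5)


def test_scale_identity(toy_fc):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    scale = scale_fobs_to_fc(merged, toy_fc)
    assert scale.k == pytest.approx(1.0, abs=1e-9)
    assert scale.b_overall == pytest.approx(0.0, abs=1e-7)
    assert scale.r_model == pytest.approx(0.0, abs=1e-9)


def test_negative_intensities_excluded_from_fit(toy_fc):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    # corrupt a handful of reflections with negative intensities
    for m in merged[:5]:
        m.i_mean = -50.0
    scale = scale_fobs_to_fc(merged, toy_fc)
    assert scale.n_common == len(merged) - 5
    assert scale.k == pytest.approx(1.0, abs=1e-9)


def test_too_few_common_reflections(toy_fc):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))[:10]
    with pytest.raises(ValueError, match="common"):
        scale_fobs_to_fc(merged, toy_fc)


# ---------------------------------------------------------------------------
# sigmaA weights
# ---------------------------------------------------------------------------

def test_perfect_data_hits_sigma_a_clamp(toy_fc):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    scale = scale_fobs_to_fc(merged, toy_fc)
    w = estimate_weights(merged, toy_fc, scale, n_shells=4)
    assert all(sa == pytest.approx(0.99) for sa in w.shell_sigma_a)
    # weak-E reflections legitimately keep lower m even with perfect data
    assert np.median(w.m) > 0.95 and w.m.mean() > 0.9
    assert np.all((0.0 <= w.m) & (w.m <= 1.0))


def test_uncorrelated_data_gives_low_weights(toy_fc):
    rng = np.random.default_rng(0)
    fake = rng.permutation(np.abs(toy_fc.f))
    merged = _merged_from_amplitudes(toy_fc, fake)
    scale = scale_fobs_to_fc(merged, toy_fc)
    w = estimate_weights(merged, toy_fc, scale, n_shells=4)
    assert np.mean(w.shell_sigma_a) < 0.6
    assert w.m.mean() < 0.7


def test_bessel_figure_of_merit_limits():
    """m = I1(X)/I0(X): 0 at X = 0, saturating toward 1 for large X."""
    from scipy import special
    assert special.i1e(0.0) / special.i0e(0.0) == 0.0
    assert special.i1e(50.0) / special.i0e(50.0) == pytest.approx(
        1.0 - 1.0 / 100.0, abs=2e-4)  # asymptotic 1 - 1/(2X)
    assert special.i1e(200.0) / special.i0e(200.0) > 0.99


def test_thin_shells_are_merged(toy_fc):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))[:40]
    scale = AmplitudeScale(k=1.0, b_overall=0.0, n_common=40)
    w = estimate_weights(merged, toy_fc, scale, n_shells=12, min_per_shell=5)
    assert len(w.shell_sigma_a) <= 8
    assert len(w.shell_sigma_a) >= 1


# ---------------------------------------------------------------------------
# Coefficients
# ---------------------------------------------------------------------------

def test_fofc_identity_data_is_zero(toy_fc, p1):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    scale = scale_fobs_to_fc(merged, toy_fc)
    co = make_coefficients(merged, toy_fc, p1, scale, None,
                           map_type="fofc", mode="simple")
    np.testing.assert_allclose(co.amplitude, 0.0, atol=1e-9)


def test_fill_only_pure_model_coefficients(toy_fc, p1):
    """No observations at all: a filled 2mFo-DFc map is exactly D|Fc|."""
    scale = AmplitudeScale(k=1.0, b_overall=0.0, n_common=0)
    co = make_coefficients([], toy_fc, p1, scale, None,
                           map_type="two_fofc", mode="simple",
                           fill_missing=True, all_hkl=toy_fc.hkl)
    amp_of = dict(zip(map(tuple, co.hkl.tolist()), co.amplitude))
    for h, f in zip(toy_fc.hkl.tolist(), toy_fc.f):
        assert amp_of[tuple(h)] == pytest.approx(abs(f), rel=1e-12)


def test_ml_coefficients_match_hand_computation(toy_fc, p1):
    rng = np.random.default_rng(9)
    fo = np.abs(toy_fc.f) * rng.uniform(0.7, 1.3, size=len(toy_fc.f))
    merged = _merged_from_amplitudes(toy_fc, fo)
    scale = scale_fobs_to_fc(merged, toy_fc)
    w = estimate_weights(merged, toy_fc, scale, n_shells=4)
    co = make_coefficients(merged, toy_fc, p1, scale, w,
                           map_type="two_fofc", mode="ml", fill_missing=False)
    amp_of = dict(zip(map(tuple, co.hkl.tolist()), co.amplitude))
    s = 1.0 / d_spacing(w.hkl, toy_fc.cell)
    fc_scaled = scale.k * np.exp(-scale.b_overall * s ** 2 / 4.0) \
        * np.abs(toy_fc.lookup(w.hkl))
    fo_of = {tuple(h): np.sqrt(max(m.i_mean, 0.0))
             for h, m in zip(w.hkl.tolist(), merged)}
    for j, h in enumerate(w.hkl.tolist()):
        expect = 2.0 * w.m[j] * fo_of[tuple(h)] - w.d_of[j] * fc_scaled[j]
        assert amp_of[tuple(h)] == pytest.approx(expect, rel=1e-10)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def test_single_atom_peak_location():
    from pmrdd.model import Atom, Model
    cell = build_cell(12, 12, 12, 90, 90, 90)
    pos = np.array([3.0, 7.0, 5.0])
    m = Model([Atom(serial=1, name="C1", element="C", residue_name="LIG",
                    chain="A", residue_seq=1, position=pos, occupancy=1.0,
                    b_factor=10.0)], cell, "P1")
    p1 = get_space_group("P1")
    fc = calc_structure_factors(m, 2.0)
    merged = _merged_from_amplitudes(fc, np.abs(fc.f))
    scale = scale_fobs_to_fc(merged, fc)
    co = make_coefficients(merged, fc, p1, scale, None, map_type="two_fofc",
                           mode="simple", all_hkl=fc.hkl)
    grid = synthesize_map(co, p1, fc)
    peak = np.unravel_index(np.argmax(grid.values), grid.dims)
    frac_peak = np.array(peak) / np.array(grid.dims)
    frac_atom = cell.fractionalize(pos)
    step = 1.0 / np.array(grid.dims)
    assert np.all(np.abs(((frac_peak - frac_atom + 0.5) % 1.0) - 0.5) <= step)


def test_map_mean_is_zero_without_f000(toy_fc, p1):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    scale = scale_fobs_to_fc(merged, toy_fc)
    co = make_coefficients(merged, toy_fc, p1, scale, None,
                           map_type="two_fofc", mode="simple",
                           all_hkl=toy_fc.hkl)
    grid = synthesize_map(co, p1, toy_fc)
    assert grid.mean_raw == pytest.approx(0.0, abs=1e-12)
    assert grid.normalized
    assert np.mean(grid.values) == pytest.approx(0.0, abs=1e-9)
    assert np.sqrt(np.mean(grid.values ** 2)) == pytest.approx(1.0, abs=1e-9)


def test_parseval_half_sphere(toy_fc, p1):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    scale = scale_fobs_to_fc(merged, toy_fc)
    co = make_coefficients(merged, toy_fc, p1, scale, None,
                           map_type="two_fofc", mode="simple",
                           all_hkl=toy_fc.hkl)
    grid = synthesize_map(co, p1, toy_fc)
    raw = grid.values * grid.rmsd_raw + grid.mean_raw
    V = toy_fc.cell.volume
    lhs = np.sum(raw ** 2) * V / raw.size
    rhs = (2.0 / V) * np.sum(co.amplitude ** 2)
    assert lhs == pytest.approx(rhs, rel=1e-6)


def test_symmetry_expanded_map_is_group_invariant():
    """Density sampled at x and at (R x + t) agrees for every operator."""
    from pmrdd.synthetic import make_test_model
    model = make_test_model(n_residues=6, cell=build_cell(24, 20, 22, 90, 90, 90),
                            space_group="P21212", seed=8)
    ops = get_space_group("P21212")
    fc_p1 = calc_structure_factors(expand_model_p1(model, ops), 2.5)
    canon = generate_hkl_set(model.cell, ops, 2.5)
    i_true = np.abs(fc_p1.lookup(canon)) ** 2
    merged = [MergedReflection(hkl=tuple(h), i_mean=float(v),
                               sig_i=max(float(v), 1.0) * 0.01, n_obs=3)
              for h, v in zip(canon.tolist(), i_true)]
    scale = scale_fobs_to_fc(merged, fc_p1)
    co = make_coefficients(merged, fc_p1, ops, scale, None,
                           map_type="two_fofc", mode="simple", all_hkl=canon)
    grid = synthesize_map(co, ops, fc_p1, grid_factor=3)
    nx, ny, nz = grid.dims
    rng = np.random.default_rng(1)
    # evaluate on grid nodes whose symmetry images are again grid nodes
    for _ in range(40):
        ijk = rng.integers(0, [nx, ny, nz])
        frac = ijk / np.array([nx, ny, nz])
        for R, t in zip(ops.rotations, ops.translations):
            node2 = (R @ frac + t) % 1.0 * [nx, ny, nz]
            ijk2 = np.round(node2).astype(int) % [nx, ny, nz]
            assert np.allclose(node2, np.round(node2), atol=1e-9)  # on-node
            a = grid.values[tuple(ijk)]
            b = grid.values[tuple(ijk2)]
            assert b == pytest.approx(a, abs=1e-6 * max(1.0, abs(a)))


def test_grid_overflow_guard(toy_fc, p1):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    scale = scale_fobs_to_fc(merged, toy_fc)
    co = make_coefficients(merged, toy_fc, p1, scale, None,
                           map_type="two_fofc", mode="simple")
    with pytest.raises(ValueError, match="grid"):
        synthesize_map(co, p1, toy_fc, grid_factor=600)


def test_ccp4_writer_emits_valid_header(tmp_path, toy_fc, p1):
    merged = _merged_from_amplitudes(toy_fc, np.abs(toy_fc.f))
    scale = scale_fobs_to_fc(merged, toy_fc)
    co = make_coefficients(merged, toy_fc, p1, scale, None,
                           map_type="two_fofc", mode="simple")
    grid = synthesize_map(co, p1, toy_fc)
    path = tmp_path / "m.ccp4"
    write_ccp4(grid, path)
    blob = path.read_bytes()
    assert blob[208:212] == b"MAP "
    nx, ny, nz = np.frombuffer(blob[:12], dtype="<i4")
    assert (nx, ny, nz) == grid.dims
    assert len(blob) == 1024 + 4 * nx * ny * nz
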