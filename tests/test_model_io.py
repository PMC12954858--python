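"""PDB round-trips, target selection and the two PMRDD perturbations."""

import json

import numpy as np
import pytest

from pmrdd.model import (Atom, Model, PerturbationRecord, clash_score,
                         measure_chi, rank_aromatic_residues, read_pdb,
                         select_pmrdd_residues, swap_rotamer,
                         truncate_side_chain, write_pdb, ROTAMER_TABLE,
                         SIDE_CHAIN_ATOMS, BURIAL_RADIUS)
from pmrdd.symmetry import build_cell
from pmrdd.synthetic import build_residue, make_test_model

MINIMAL_PDB = """\
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1
ATOM      1  CA  ALA A   1       1.234   2.345   3.456  1.00 20.00           C
END
"""


def _isolated_residue_model(res_name="TYR", chi=(-60.0, 90.0), cell_edge=60.0):
    coords = build_residue(res_name, chi)
    cell = build_cell(cell_edge, cell_edge, cell_edge, 90, 90, 90)
    center = np.array([cell_edge / 2] * 3)
    atoms = [Atom(serial=i + 1, name=n, element=("O" if n.startswith("O") else
                                                 "N" if n.startswith("N") else "C"),
                  residue_name=res_name, chain="A", residue_seq=5,
                  position=p + center, occupancy=1.0, b_factor=15.0)
             for i, (n, p) in enumerate(coords.items())]
    return Model(atoms=atoms, cell=cell, space_group="P1")


# ---------------------------------------------------------------------------
# PDB input/output
# ---------------------------------------------------------------------------

def test_read_minimal_pdb(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(MINIMAL_PDB)
    m = read_pdb(path)
    assert len(m) == 1
    assert m.cell.a == m.cell.b == m.cell.c == 10.0
    np.testing.assert_allclose(m.atoms[0].position, [1.234, 2.345, 3.456])


def test_roundtrip_bit_exact_at_format_precision(tmp_path, test_model):
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_pdb(test_model, p1)
    write_pdb(read_pdb(p1), p2)
    assert p1.read_text() == p2.read_text()


def test_cryst1_space_group_resolution(tmp_path):
    path = tmp_path / "hex.pdb"
    path.write_text(
        "CRYST1   50.000   50.000   40.000  90.00  90.00 120.00 P 32 2 1\n"
        "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00 10.00"
        "           C\nEND\n")
    m = read_pdb(path)
    assert m.ops.symbol == "P3221" and m.ops.n_ops == 6


def test_missing_cryst1_is_hard_error(tmp_path):
    path = tmp_path / "nocell.pdb"
    path.write_text(MINIMAL_PDB.split("\n", 1)[1])
    with pytest.raises(ValueError, match="CRYST1"):
        read_pdb(path)


def test_bad_atom_line_names_line_number(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text(MINIMAL_PDB.replace("   3.456", "   x.456"))
    with pytest.raises(ValueError, match=":2"):
        read_pdb(path)


def test_atom_name_columns_and_occupancy_format(tmp_path, test_model):
    path = tmp_path / "fmt.pdb"
    write_pdb(test_model, path)
    ca_lines = [l for l in path.read_text().splitlines()
                if l.startswith("ATOM") and l[12:16] == " CA "]
    assert ca_lines, "CA must occupy columns 13-16 with a leading space"
    assert all(l[54:60] == "  1.00" for l in ca_lines)


def test_altloc_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(
        "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.40 20.00"
        "           C\n"
        "ATOM      2  CA BALA A   1       5.000   6.000   7.000  0.60 20.00"
        "           C\nEND\n")
    m = read_pdb(path)
    assert len(m) == 1
    np.testing.assert_allclose(m.atoms[0].position, [5.0, 6.0, 7.0])


# ---------------------------------------------------------------------------
# Target selection
# ---------------------------------------------------------------------------

def test_selection_brute_force_oracle(test_model):
    """Ranking must equal exhaustive scoring over every aromatic residue."""
    coords = test_model.coordinates()
    owner = [(a.chain, a.residue_seq) for a in test_model.atoms]
    scores = {}
    for rid, atoms in test_model.residues().items():
        name = atoms[0].residue_name
        if name not in ("TRP", "TYR", "PHE", "HIS"):
            continue
        sc_names = set(SIDE_CHAIN_ATOMS[name]) | {"CB"}
        sc = np.array([a.position for a in atoms if a.name in sc_names])
        centroid = sc.mean(axis=0)
        mask = np.array([o != rid for o in owner])
        burial = np.sum(np.linalg.norm(coords[mask] - centroid, axis=1)
                        <= BURIAL_RADIUS)
        mean_b = np.mean([a.b_factor for a in atoms if a.name in sc_names])
        scores[rid] = (burial, mean_b)
    burials = np.array([v[0] for v in scores.values()], dtype=float)
    bs = np.array([v[1] for v in scores.values()])
    z = ((burials - burials.mean()) / burials.std()
         - (bs - bs.mean()) / bs.std())
    expect = [rid for _, rid in
              sorted(zip(-z, scores), key=lambda t: (t[0], t[1]))]
    got = [rid for rid, _ in rank_aromatic_residues(test_model)]
    assert got == expect


def test_selection_forced_choice():
    m = make_test_model(n_residues=2, seed=3)  # exactly TRP + TYR
    a, b = select_pmrdd_residues(m)
    assert {m.residue_name(a), m.residue_name(b)} == {"TRP", "TYR"}


def test_exclusion_sphere_filters(test_model):
    ranked = rank_aromatic_residues(test_model)
    target = ranked[0][0]
    sc = [a.position for a in test_model.residue_atoms(target)
          if a.name != "N"]
    center = np.mean(sc, axis=0)
    filtered = rank_aromatic_residues(test_model, exclude_center=center,
                                      exclude_radius=3.0)
    assert target not in [rid for rid, _ in filtered]


def test_too_few_aromatics_raises():
    m = make_test_model(n_residues=1, seed=3)
    with pytest.raises(ValueError, match="exclude_radius"):
        select_pmrdd_residues(m)


# ---------------------------------------------------------------------------
# Truncation
# ---------------------------------------------------------------------------

def test_truncate_trp_topology(test_model):
    rid = ("A", 1)
    assert test_model.residue_name(rid) == "TRP"
    out, rec = truncate_side_chain(test_model, rid)
    remaining = {a.name for a in out.residue_atoms(rid)}
    assert remaining == {"N", "CA", "C", "O", "CB"}
    assert {n for n, _ in rec.deleted_atom_positions} == {
        "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}
    assert len(test_model) - len(out) == len(rec.deleted_atom_positions)


def test_truncate_phe_topology():
    m = _isolated_residue_model("PHE")
    out, rec = truncate_side_chain(m, ("A", 5))
    # benzene ring (CG, CD1, CD2, CE1, CE2, CZ) beyond the retained CB
    assert {n for n, _ in rec.deleted_atom_positions} == {
        "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
    assert len(m) - len(out) == 6


def test_truncate_to_glycine_drops_cb(test_model):
    out, rec = truncate_side_chain(test_model, ("A", 1), to_glycine=True)
    assert {a.name for a in out.residue_atoms(("A", 1))} == {"N", "CA", "C", "O"}


def test_truncate_non_aromatic_rejected(test_model):
    leu = next(rid for rid, atoms in test_model.residues().items()
               if atoms[0].residue_name == "LEU")
    with pytest.raises(ValueError):
        truncate_side_chain(test_model, leu)


# ---------------------------------------------------------------------------
# Rotamer swap
# ---------------------------------------------------------------------------

def test_swap_identity_rotamer_is_noop():
    m = _isolated_residue_model("TYR", chi=(-60.0, 90.0))
    idx = ROTAMER_TABLE["TYR"].index((-60.0, 90.0))
    out, rec = swap_rotamer(m, ("A", 5), rotamer_index=idx)
    np.testing.assert_allclose(out.coordinates(), m.coordinates(), atol=1e-9)


def test_swap_preserves_internal_geometry():
    m = _isolated_residue_model("TRP", chi=(60.0, -90.0))
    out, rec = swap_rotamer(m, ("A", 5), rotamer_index=4)  # chi1 180
    t = np.array([p for _, p in rec.true_atom_positions])
    f = np.array([p for _, p in rec.false_atom_positions])
    dist_t = np.linalg.norm(t[:, None] - t[None, :], axis=2)
    dist_f = np.linalg.norm(f[:, None] - f[None, :], axis=2)
    assert np.abs(dist_t - dist_f).max() < 1e-6
    chi = measure_chi(out, ("A", 5))
    diff = [(a - b + 180.0) % 360.0 - 180.0 for a, b in zip(chi, (180.0, -90.0))]
    assert diff == pytest.approx([0.0, 0.0], abs=1e-6)


def test_swap_hits_requested_chi_exactly(test_model):
    out, rec = swap_rotamer(test_model, ("A", 2), rotamer_index=0)
    assert measure_chi(out, ("A", 2)) == pytest.approx(list(rec.new_chi),
                                                       abs=1e-6)


def test_isolated_residue_all_rotamers_clash_free():
    m = _isolated_residue_model("HIS")
    for idx in range(len(ROTAMER_TABLE["HIS"])):
        out, _ = swap_rotamer(m, ("A", 5), rotamer_index=idx)
        assert clash_score(out, ("A", 5)) == 0


def test_perturbations_commute(test_model):
    from dataclasses import replace
    a1, _ = truncate_side_chain(test_model, ("A", 1))
    a2, _ = swap_rotamer(a1, ("A", 2), rotamer_index=3)
    b1, _ = swap_rotamer(test_model, ("A", 2), rotamer_index=3)
    b2, _ = truncate_side_chain(b1, ("A", 1))
    keys_a = [a.key() for a in a2.atoms]
    keys_b = [b.key() for b in b2.atoms]
    assert set(keys_a) == set(keys_b)
    pos_b = {a.key(): a.position for a in b2.atoms}
    for a in a2.atoms:
        np.testing.assert_allclose(a.position, pos_b[a.key()], atol=1e-9)


# ---------------------------------------------------------------------------
# Clash score
# ---------------------------------------------------------------------------

def test_clash_isolated_zero():
    assert clash_score(_isolated_residue_model("TRP"), ("A", 5)) == 0


def test_clash_constructed_violation():
    m = _isolated_residue_model("TYR")
    cz = m.atom(("A", 5), "CZ").position
    intruder = Atom(serial=99, name="O", element="O", residue_name="HOH",
                    chain="W", residue_seq=1, position=cz + [1.0, 0, 0])
    m2 = Model(atoms=m.atoms + [intruder], cell=m.cell, space_group="P1")
    assert clash_score(m2, ("A", 5)) >= 1


def test_clash_matches_brute_force(test_model):
    """Vectorized count equals an O(N^2) loop with the same exclusions."""
    rid = ("A", 2)
    name = test_model.residue_name(rid)
    sc_names = set(SIDE_CHAIN_ATOMS[name]) | {"CB"}
    count = 0
    for a in test_model.residue_atoms(rid):
        if a.name not in sc_names:
            continue
        for b in test_model.atoms:
            if b.chain == rid[0] and abs(b.residue_seq - rid[1]) <= 1:
                continue
            if np.linalg.norm(a.position - b.position) < 3.8:
                count += 1
    assert clash_score(test_model, rid, cutoff=3.8) == count


# ---------------------------------------------------------------------------
# Perturbation record
# ---------------------------------------------------------------------------

def test_record_json_roundtrip(tmp_path, test_model):
    from pmrdd.pipeline import perturb_model
    _, rec = perturb_model(test_model, delete_residue=("A", 1),
                           move_residue=("A", 2))
    path = tmp_path / "rec.json"
    rec.to_json(path)
    back = PerturbationRecord.from_json(path)
    assert back.deleted_residue == rec.deleted_residue
    assert back.moved_residue == rec.moved_residue
    assert back.new_chi == pytest.approx(rec.new_chi)
    np.testing.assert_allclose(
        np.array([p for _, p in back.false_atom_positions]),
        np.array([p for _, p in rec.false_atom_positions]))


def test_record_rejects_same_residue():
    rec = PerturbationRecord(
        deleted_residue=("A", 1, "TRP"), moved_residue=("A", 1, "TRP"))
    with pytest.raises(ValueError):
        rec.validate()
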