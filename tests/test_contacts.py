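"""Probe-sphere contact detection: dot lattice, scoring oracles, hydrogen
bonds, covalent exclusion, and grid/brute equivalence."""

import numpy as np
import pytest
from scipy.integrate import quad

from rinvar.contacts import (
    AtomicContact,
    ProbeConfig,
    detect_contacts,
    dot_contact_score,
    infer_covalent_bonds,
    lens_volume,
    surface_dots,
)
from rinvar.structure import Atom


def _carbon(serial, x, r=1.70):
    return Atom(serial, "CA", "C", np.array([x, 0.0, 0.0]), r, 0.0)


# --------------------------------------------------------------------------
# surface dots
# --------------------------------------------------------------------------

def test_dot_count_closed_form():
    a = Atom(1, "CA", "C", np.zeros(3), 1.0, 0.0)
    dots = surface_dots(a, 16.0)
    assert len(dots) == round(16 * 4 * np.pi)  # 201


def test_dots_lie_on_sphere_and_scale_with_density():
    a = _carbon(1, 0.0)
    dots = surface_dots(a, 16.0)
    radii = np.linalg.norm(dots - a.coords, axis=1)
    assert np.abs(radii - a.vdw_radius).max() < 1e-9
    n1, n2 = len(surface_dots(a, 16.0)), len(surface_dots(a, 32.0))
    assert abs(n2 - 2 * n1) <= 1


# --------------------------------------------------------------------------
# contact scoring oracles
# --------------------------------------------------------------------------

def _quadrature_score(ri, rj, d, probe):
    """Independent oracle: the dot score is a surface integral over the cap
    of atom i's sphere facing atom j, of the linear weight of the dot-to-
    surface gap; evaluate it by 1D quadrature in the polar angle."""
    span = 2.0 * probe

    def integrand(theta):
        dist = np.sqrt(d * d + ri * ri - 2 * d * ri * np.cos(theta))
        g = dist - rj
        w = (1.0 - g / span) if 0.0 <= g <= span else 0.0
        return w * np.sin(theta)

    val, _ = quad(integrand, 0.0, np.pi, limit=200)
    return ri * ri * 2.0 * np.pi * val


def test_pair_beyond_probe_diameter_has_no_contact():
    s = _two_atom_structure(3.95)  # g = 0.55 > 0.5
    assert detect_contacts(s) == []


def test_contact_score_matches_quadrature_oracle():
    cfg = ProbeConfig()
    a, b = _carbon(1, 0.0), _carbon(2, 3.60)  # g = 0.20
    s_ij, n_ij = dot_contact_score(a, b, cfg)
    assert n_ij > 0
    expect = _quadrature_score(1.70, 1.70, 3.60, cfg.probe_radius)
    assert s_ij == pytest.approx(expect, rel=0.05)


def test_contact_scores_match_high_density_dot_loop():
    """50 random in-contact pairs: default-density score within 5% of an
    independently coded 16x-density brute-force dot loop."""
    cfg = ProbeConfig()
    rng = np.random.default_rng(42)
    radii_pool = [1.52, 1.55, 1.70, 1.80]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for _ in range(50):
        ri, rj = rng.choice(radii_pool, size=2)
        g = rng.uniform(0.02, 0.48)
        d = ri + rj + g
        ai = Atom(1, "X", "C", np.zeros(3), ri, 0.0)
        aj = Atom(2, "X", "C", np.array([d, 0.0, 0.0]), rj, 0.0)

        def brute(atom_a, atom_b, density=256.0):
            r = atom_a.vdw_radius
            n = round(density * 4 * np.pi * r * r)
            total = 0.0
            k = np.arange(n)
            z = 1.0 - (2.0 * k + 1.0) / n
            rho = np.sqrt(1.0 - z * z)
            phi = k * golden
            pts = atom_a.coords + r * np.column_stack(
                [rho * np.cos(phi), rho * np.sin(phi), z])
            gaps = np.linalg.norm(pts - atom_b.coords, axis=1) - atom_b.vdw_radius
            sel = (gaps >= 0) & (gaps <= 0.5)
            total = np.sum(1.0 - gaps[sel] / 0.5)
            return total / density

        ours = 0.5 * (dot_contact_score(ai, aj, cfg)[0]
                      + dot_contact_score(aj, ai, cfg)[0])
        dense = 0.5 * (brute(ai, aj) + brute(aj, ai))
        assert ours == pytest.approx(dense, rel=0.05)


def test_score_symmetry_within_sampling_tolerance():
    cfg = ProbeConfig()
    rng = np.random.default_rng(7)
    for _ in range(10):
        ri, rj = rng.choice([1.52, 1.70, 1.80], size=2)
        d = ri + rj + rng.uniform(0.05, 0.45)
        ai = Atom(1, "X", "C", np.zeros(3), ri, 0.0)
        aj = Atom(2, "X", "C", np.array([d, 0.0, 0.0]), rj, 0.0)
        s_ij = dot_contact_score(ai, aj, cfg)[0]
        s_ji = dot_contact_score(aj, ai, cfg)[0]
        assert abs(s_ij - s_ji) / max(s_ij, s_ji) < 0.1


def test_contact_score_monotone_in_distance():
    cfg = ProbeConfig()
    ai = _carbon(1, 0.0)
    prev = np.inf
    for g in np.linspace(0.01, 0.49, 12):
        aj = _carbon(2, 3.40 + g)
        s = 0.5 * (dot_contact_score(ai, aj, cfg)[0]
                   + dot_contact_score(aj, ai, cfg)[0])
        assert s <= prev + 1e-9
        prev = s


def test_overlap_volume_strictly_decreasing_and_symmetric():
    vols = [lens_volume(1.70, 1.52, d) for d in np.linspace(1.0, 3.2, 15)]
    assert all(a > b for a, b in zip(vols, vols[1:]))
    assert lens_volume(1.70, 1.52, 2.0) == pytest.approx(lens_volume(1.52, 1.70, 2.0))
    assert lens_volume(1.70, 1.52, 3.3) == 0.0
    # fully enclosed sphere: full volume of the smaller sphere
    assert lens_volume(2.0, 0.5, 0.1) == pytest.approx(4 / 3 * np.pi * 0.5**3)


# --------------------------------------------------------------------------
# detection on structures
# --------------------------------------------------------------------------

def _two_atom_structure(d):
    from rinvar.structure import Residue, Structure

    r1 = Residue(1, None, "ALA", 0, [_carbon(1, 0.0)])
    r2 = Residue(2, None, "ALA", 1, [_carbon(2, d)])
    return Structure("A", [r1, r2])


def test_two_carbons_in_contact_range():
    contacts = detect_contacts(_two_atom_structure(3.60))
    assert len(contacts) == 1
    assert contacts[0].kind == "contact"
    assert contacts[0].score > 0


def test_two_carbons_overlapping_scored_by_lens_volume():
    contacts = detect_contacts(_two_atom_structure(3.0))
    assert len(contacts) == 1
    assert contacts[0].kind == "overlap"
    assert contacts[0].score == pytest.approx(lens_volume(1.70, 1.70, 3.0))


def test_helix_i_i4_backbone_hydrogen_bonds(helix20):
    """Ideal alpha-helix: O(i)..N(i+4) pairs within 3.5 A come out as hbond."""
    serial_to_res = {a.serial: r.seq_index
                     for r in helix20.residues for a in r.atoms}
    names = {a.serial: a.name for r in helix20.residues for a in r.atoms}
    contacts = detect_contacts(helix20)
    hbond_offsets = set()
    for c in contacts:
        if c.kind != "hbond":
            continue
        pair = {names[c.atom_i], names[c.atom_j]}
        if pair == {"O", "N"}:
            hbond_offsets.add(abs(serial_to_res[c.atom_i] - serial_to_res[c.atom_j]))
        assert c.score > 0
    assert 4 in hbond_offsets


def test_hbond_scored_by_inflated_lens_volume(helix20):
    cfg = ProbeConfig()
    atoms = {a.serial: a for a in helix20.atoms()}
    hbonds = [c for c in detect_contacts(helix20, cfg) if c.kind == "hbond"]
    assert hbonds
    c = hbonds[0]
    ai, aj = atoms[c.atom_i], atoms[c.atom_j]
    d = np.linalg.norm(ai.coords - aj.coords)
    expect = lens_volume(ai.vdw_radius + cfg.probe_radius,
                         aj.vdw_radius + cfg.probe_radius, d)
    assert c.score == pytest.approx(expect)


def test_no_intra_residue_or_covalent_neighbor_contacts(helix20):
    serial_to_res = {a.serial: r.seq_index
                     for r in helix20.residues for a in r.atoms}
    names = {a.serial: a.name for r in helix20.residues for a in r.atoms}
    for c in detect_contacts(helix20):
        ri, rj = serial_to_res[c.atom_i], serial_to_res[c.atom_j]
        assert ri != rj
        # O(i)-N(i+1) is 2 covalent bonds away (O=C-N): must be excluded
        pair = {(names[c.atom_i], ri), (names[c.atom_j], rj)}
        for i in (ri, rj):
            assert pair != {("O", i), ("N", i + 1)}


def test_covalent_bond_inference_on_backbone(helix20):
    atoms = list(helix20.atoms())
    bonds = infer_covalent_bonds(atoms)
    index_of = {a.serial: k for k, a in enumerate(atoms)}
    # residue 0: N-CA, CA-C, C-O plus C(0)-N(1) peptide bond must be present
    n0, ca0, c0, o0 = (index_of[helix20.residues[0].atom(nm).serial]
                       for nm in ("N", "CA", "C", "O"))
    n1 = index_of[helix20.residues[1].atom("N").serial]
    bondset = set(bonds)
    for pair in [(n0, ca0), (ca0, c0), (c0, o0), (c0, n1)]:
        assert tuple(sorted(pair)) in bondset
    # no spurious bond between CA(0) and CA(1) (3.8 A apart)
    ca1 = index_of[helix20.residues[1].atom("CA").serial]
    assert tuple(sorted((ca0, ca1))) not in bondset


def test_grid_and_brute_force_detection_agree(helix20):
    grid = detect_contacts(helix20, method="grid")
    brute = detect_contacts(helix20, method="brute")
    assert sorted(grid, key=lambda c: (c.atom_i, c.atom_j)) == \
        sorted(brute, key=lambda c: (c.atom_i, c.atom_j))


def test_config_validation_and_json_round_trip(tmp_path):
    with pytest.raises(ValueError):
        ProbeConfig(probe_radius=0.0)
    with pytest.raises(ValueError):
        ProbeConfig(dot_density=-1.0)
    cfg = ProbeConfig(probe_radius=0.3, dot_density=8.0)
    cfg.to_json(tmp_path / "probe.json")
    assert ProbeConfig.from_json(tmp_path / "probe.json") == cfg
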