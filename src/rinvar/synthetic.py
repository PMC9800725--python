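"""Self-contained synthetic structures and labeled datasets.

Stands in for predicted mutant structures so the whole pipeline —
structure -> contacts -> network -> matrix -> classifier — runs with known
ground truth and no external data.

Geometry: an ideal alpha-helix built residue-by-residue from standard
internal coordinates (phi = -57, psi = -47, omega = 180 degrees; N-CA 1.458,
CA-C 1.525, C-N 1.329, C=O 1.231 A), which yields the canonical helix (rise
about 1.5 A per residue, about 100 degrees of turn, CA radius about 2.3 A,
consecutive CA-CA distance 3.8 A, and i -> i+4 backbone hydrogen-bond
geometry).  Each non-glycine residue carries one side-chain pseudo-atom on
the CB direction whose sphere radius grows with the residue's heavy-atom
count — a unified side chain that moves packing signal without rotamers.

A "variant" is a point perturbation at one residue: enlarge the side-chain
sphere, displace it outward, or delete it.  The label rule is deterministic:
pathogenic iff the perturbation magnitude reaches the cutoff at a designated
core position.  Positives use the spec magnitude at core positions;
negatives get sub-cutoff magnitudes anywhere.  Small seeded coordinate
jitter emulates prediction noise across variant structures.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contacts import ProbeConfig, detect_contacts
from .encoding import encode, save_dataset
from .network import CombiWeights, build_rin
from .structure import AA1_TO_3, Atom, Residue, Structure

__all__ = [
    "SyntheticSpec",
    "make_structure",
    "perturb_structure",
    "make_labeled_dataset",
    "SIDECHAIN_HEAVY_ATOMS",
]

# heavy atoms in each side chain (drives the pseudo-atom radius)
SIDECHAIN_HEAVY_ATOMS = {
    "A": 1, "R": 7, "N": 4, "D": 4, "C": 2, "Q": 5, "E": 5, "G": 0,
    "H": 6, "I": 4, "L": 4, "K": 5, "M": 4, "F": 7, "P": 3, "S": 2,
    "T": 3, "W": 10, "Y": 8, "V": 3,
}

_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_DEFAULT_ALPHABET = "ARNDQEHILKMFSTWYV"  # no G (keeps a side chain everywhere)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom."""
    angle, torsion = np.deg2rad(angle), np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_direction(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal L-amino-acid CB direction from the backbone frame."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    v = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return v / np.linalg.norm(v)


def _sidechain_geometry(aa1: str) -> tuple[float, float]:
    """(distance from CA, sphere radius) of the side-chain pseudo-atom."""
    k = SIDECHAIN_HEAVY_ATOMS[aa1]
    dist = 1.5 + 0.25 * np.sqrt(k)
    radius = 1.6 + 0.12 * k
    return dist, radius


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    n_residues: int = 60
    sequence: str | None = None          # default: seeded mixed sequence
    perturb_mode: str = "enlarge_sidechain"
    magnitude: float = 1.0               # positive-class perturbation size
    label_cutoff: float = 0.5            # pathogenic iff magnitude >= cutoff at core
    core_positions: tuple[int, ...] | None = None   # default: middle third
    coord_jitter: float = 0.02           # A, per-sample Gaussian noise
    rng_seed: int = 0

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues:
                raise ValueError("sequence length must equal n_residues")
            return self.sequence
        rng = np.random.default_rng(self.rng_seed + 101)
        return "".join(rng.choice(list(_DEFAULT_ALPHABET), size=self.n_residues))

    def resolved_core(self) -> tuple[int, ...]:
        if self.core_positions is not None:
            return tuple(self.core_positions)
        lo, hi = self.n_residues // 3, 2 * self.n_residues // 3
        return tuple(range(lo, hi))


def make_structure(spec: SyntheticSpec | int, seed: int | None = None,
                   pdb_path: str | Path | None = None) -> Structure:
    """Build the ideal-helix structure for a spec (or a residue count).

    Deterministic under the spec seed; per-residue B-factors emulate pLDDT
    (high-confidence range).  Optionally also writes the PDB file.
    """
    if isinstance(spec, int):
        spec = SyntheticSpec(n_residues=spec)
    if spec.n_residues < 5:
        raise ValueError("need at least 5 residues for a helix")
    seq = spec.resolved_sequence()
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)

    n_xyz = np.array([0.0, 0.0, 0.0])
    ca_xyz = np.array([1.458, 0.0, 0.0])
    c_xyz = _place(np.array([0.0, 1.0, 0.0]), n_xyz, ca_xyz, 1.525, 111.2, 0.0)

    residues: list[Residue] = []
    serial = 0
    for i, aa in enumerate(seq):
        if i > 0:
            n_xyz = _place(prev_n, prev_ca, prev_c, 1.329, 116.2, _PSI)
            ca_xyz = _place(prev_ca, prev_c, n_xyz, 1.458, 121.7, _OMEGA)
            c_xyz = _place(prev_c, n_xyz, ca_xyz, 1.525, 111.2, _PHI)
        o_xyz = _place(n_xyz, ca_xyz, c_xyz, 1.231, 120.8, _PSI + 180.0)
        plddt = float(np.round(88.0 + 10.0 * rng.random(), 2))
        atoms = []
        for name, element, xyz, radius in (
                ("N", "N", n_xyz, 1.55), ("CA", "C", ca_xyz, 1.70),
                ("C", "C", c_xyz, 1.70), ("O", "O", o_xyz, 1.52)):
            serial += 1
            atoms.append(Atom(serial, name, element, xyz.copy(), radius, plddt))
        if aa != "G":
            dist, radius = _sidechain_geometry(aa)
            sc_xyz = ca_xyz + dist * _cb_direction(n_xyz, ca_xyz, c_xyz)
            serial += 1
            atoms.append(Atom(serial, "CB", "C", sc_xyz, radius, plddt))
        residues.append(Residue(i + 1, None, AA1_TO_3[aa], i, atoms))
        prev_n, prev_ca, prev_c = n_xyz, ca_xyz, c_xyz

    structure = Structure("A", residues, source="synthetic ideal helix")
    if pdb_path is not None:
        from .structure import write_pdb

        write_pdb(structure, pdb_path)
    return structure


def perturb_structure(structure: Structure, position: int, mode: str,
                      magnitude: float) -> Structure:
    """Return a copy with a point perturbation at a residue's side chain."""
    if not 0 <= position < structure.L:
        raise ValueError(f"position {position} out of range (L={structure.L})")
    out = copy.deepcopy(structure)
    res = out.residues[position]
    sc = res.atom("CB")
    if sc is None:
        raise ValueError(f"residue {res.label} has no side chain to perturb")
    if mode == "enlarge_sidechain":
        sc.vdw_radius *= 1.0 + magnitude
    elif mode == "displace_sidechain":
        ca = res.atom("CA")
        direction = sc.coords - ca.coords
        direction /= np.linalg.norm(direction)
        sc.coords = sc.coords + magnitude * direction
    elif mode == "delete_sidechain":
        res.atoms.remove(sc)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    out.source = (f"{structure.source} | {mode} at {res.label} "
                  f"magnitude {magnitude:g}")
    return out


def _jitter(structure: Structure, sigma: float, rng: np.random.Generator) -> None:
    if sigma <= 0:
        return
    for atom in structure.atoms():
        atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)


def make_labeled_dataset(spec: SyntheticSpec, n_pos: int, n_neg: int,
                         probe_cfg: ProbeConfig | None = None,
                         combi_weights: CombiWeights | None = None,
                         out_path: str | Path | None = None):
    """Generate an encoded, labeled interaction-matrix dataset.

    Positives: perturbation of the spec magnitude at a core position
    (refused if the magnitude is below the label cutoff — the label rule
    would be violated).  Negatives: sub-cutoff magnitudes at any eligible
    position.  Returns ``(X, y, variant_ids, meta)`` with X of shape
    (n_pos + n_neg, L, L, 7); optionally writes the HDF5 dataset.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one example of each class")
    if spec.magnitude < spec.label_cutoff:
        raise ValueError(
            f"pathogenic magnitude {spec.magnitude} below label cutoff "
            f"{spec.label_cutoff}: label rule would be violated")
    probe_cfg = probe_cfg or ProbeConfig()
    rng = np.random.default_rng(spec.rng_seed)
    base = make_structure(spec)
    seq = spec.resolved_sequence()
    eligible = [i for i in range(2, spec.n_residues - 2) if seq[i] != "G"]
    core = [i for i in spec.resolved_core() if i in set(eligible)]
    if not core:
        raise ValueError("no eligible core positions with side chains")

    X = []
    labels = []
    ids = []
    meta = []
    for k in range(n_pos + n_neg):
        positive = k < n_pos
        if positive:
            pos = int(rng.choice(core))
            mag = spec.magnitude
        else:
            pos = int(rng.choice(eligible))
            mag = float(rng.uniform(0.0, 0.3 * spec.label_cutoff))
        label = int(mag >= spec.label_cutoff and pos in set(core))
        assert label == int(positive)
        s = perturb_structure(base, pos, spec.perturb_mode, mag)
        _jitter(s, spec.coord_jitter, rng)
        contacts = detect_contacts(s, probe_cfg)
        rin = build_rin(contacts, s, combi_weights)
        vid = f"var{k:04d}"
        X.append(encode(rin, variant_id=vid, label=label).tensor)
        labels.append(label)
        ids.append(vid)
        meta.append(dict(variant_id=vid, position=pos, mode=spec.perturb_mode,
                         magnitude=mag, label=label))
    X = np.stack(X)
    y = np.array(labels)
    if out_path is not None:
        save_dataset(out_path, X, y, ids)
    return X, y, ids, meta
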