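"""Probe-sphere detection and scoring of non-covalent atomic interactions.

A virtual probe sphere (default radius 0.25 A) is rolled over the van der
Waals surface of every atom.  For an atom pair with centre distance d and
radii ri, rj the surface gap is g = d - ri - rj:

* ``contact``   0 <= g <= 2*probe_radius — scored by a deterministic dot
  lattice on the first atom's vdW sphere: each dot whose gap to the partner
  surface lies in [0, 2*probe_radius] contributes a weight falling linearly
  from 1 at gap 0 to 0 at the probe diameter; the sum is divided by the dot
  density, so the score (units A^2) is stable under density refinement.  The
  emitted score is the mean of the two per-atom directions.
* ``overlap``   g < 0 — scored by the analytic sphere-sphere lens
  (interpenetration) volume, reported as a positive magnitude.
* ``hbond``     a donor/acceptor-eligible pair with heavy-atom distance at
  most ``hbond_heavy_cutoff`` is reclassified from contact/overlap to a
  hydrogen bond and scored by the overlap volume of the two spheres inflated
  by the probe radius.

Atom pairs within the same residue, and pairs connected by at most
``covalent_exclusion_bonds`` covalent bonds, are skipped.  Covalent bonds
are inferred from distance < 0.6*(ri + rj) on vdW radii.  The dot lattice is
a Fibonacci spiral, so all scores are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Structure

__all__ = [
    "ProbeConfig",
    "AtomicContact",
    "surface_dots",
    "dot_contact_score",
    "lens_volume",
    "detect_contacts",
    "infer_covalent_bonds",
    "is_donor",
    "is_acceptor",
    "dump_contacts_tsv",
]


@dataclass(frozen=True)
class ProbeConfig:
    probe_radius: float = 0.25      # A
    dot_density: float = 16.0       # dots per A^2
    covalent_exclusion_bonds: int = 3
    hbond_heavy_cutoff: float = 3.5  # A, donor-acceptor heavy-atom distance

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.dot_density <= 0:
            raise ValueError("dot_density must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbeConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class AtomicContact:
    atom_i: int      # atom serial
    atom_j: int
    kind: str        # contact | overlap | hbond
    score: float
    n_dots: int = 0


# -- hydrogen-bond donor/acceptor templates (heavy atoms, per residue) -------
_BACKBONE_DONORS = {"N"}        # except proline
_BACKBONE_ACCEPTORS = {"O", "OXT"}
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"},
}


def is_donor(atom_name: str, resname: str) -> bool:
    if atom_name in _BACKBONE_DONORS and resname != "PRO":
        return True
    return atom_name in _SIDECHAIN_DONORS.get(resname, ())


def is_acceptor(atom_name: str, resname: str) -> bool:
    if atom_name in _BACKBONE_ACCEPTORS:
        return True
    return atom_name in _SIDECHAIN_ACCEPTORS.get(resname, ())


# -- geometric primitives ----------------------------------------------------

def surface_dots(atom: Atom, density: float) -> np.ndarray:
    """Quasi-uniform Fibonacci-spiral dots on the atom's vdW sphere.

    The dot count is ``round(density * 4 pi r^2)``; every dot lies exactly at
    distance ``vdw_radius`` from the centre.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    r = atom.vdw_radius
    n = max(1, round(density * 4.0 * np.pi * r * r))
    i = np.arange(n)
    # Fibonacci lattice: uniform in z, golden-angle in azimuth
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    dots = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return atom.coords + r * dots


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Deterministic rotation matrix taking the +z axis onto ``axis``."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def dot_contact_score(atom_i: Atom, atom_j: Atom, cfg: ProbeConfig,
                      density: float | None = None) -> tuple[float, int]:
    """One-directional contact score: dots on atom_i against atom_j's surface.

    Returns (score, contributing dot count); score = sum of linear weights
    divided by density (area units), weight 1 at gap 0 falling to 0 at the
    probe diameter.
    """
    density = density if density is not None else cfg.dot_density
    dots = surface_dots(atom_i, density)
    # orient the lattice pole along the pair axis: the gap depends only on
    # the polar angle, so the uniform-z spiral integrates it midpoint-style
    axis = atom_j.coords - atom_i.coords
    axis = axis / np.linalg.norm(axis)
    dots = atom_i.coords + (dots - atom_i.coords) @ _rotation_to(axis).T
    gaps = np.linalg.norm(dots - atom_j.coords, axis=1) - atom_j.vdw_radius
    span = 2.0 * cfg.probe_radius
    mask = (gaps >= 0.0) & (gaps <= span)
    weights = 1.0 - gaps[mask] / span
    return float(weights.sum() / density), int(mask.sum())


def lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of intersection of two spheres (0 when disjoint)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rmin = min(r1, r2)
        return 4.0 / 3.0 * np.pi * rmin**3
    return (np.pi * (r1 + r2 - d) ** 2
            * (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
            / (12.0 * d))


# -- covalent-bond inference -------------------------------------------------

def infer_covalent_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    """Bonded atom index pairs by the distance < 0.6*(ri+rj) criterion.

    Radii come from the element table (chemistry), not the per-atom scoring
    radius, so perturbing an atom's sphere never rewires the bond graph.
    """
    from .structure import VDW_RADII

    coords = np.array([a.coords for a in atoms])
    radii = np.array([VDW_RADII.get(a.element, a.vdw_radius) for a in atoms])
    tree = cKDTree(coords)
    cutoff = 0.6 * 2.0 * radii.max()
    bonds = []
    for i, j in tree.query_pairs(cutoff):
        d = np.linalg.norm(coords[i] - coords[j])
        if d < 0.6 * (radii[i] + radii[j]):
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def _excluded_pairs(n_atoms: int, bonds: list[tuple[int, int]],
                    max_bonds: int) -> set[tuple[int, int]]:
    """All index pairs connected by a covalent path of <= max_bonds bonds."""
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    excluded: set[tuple[int, int]] = set()
    for start in range(n_atoms):
        frontier = {start}
        seen = {start}
        for _ in range(max_bonds):
            nxt = set()
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.add(v)
            frontier = nxt
        for v in seen:
            if v > start:
                excluded.add((start, v))
    return excluded


# -- main detection ----------------------------------------------------------

def detect_contacts(structure: Structure, cfg: ProbeConfig | None = None,
                    method: str = "grid") -> list[AtomicContact]:
    """Detect and score all inter-residue non-covalent atomic interactions.

    ``method="grid"`` prunes candidate pairs with a k-d tree; ``"brute"``
    scans all pairs.  Both return the identical contact list (the grid cutoff
    covers every pair the brute scan can emit).
    """
    cfg = cfg or ProbeConfig()
    atoms: list[Atom] = []
    residue_of: list[int] = []
    resname_of: list[str] = []
    for res in structure.residues:
        for a in res.atoms:
            atoms.append(a)
            residue_of.append(res.seq_index)
            resname_of.append(res.name3)
    n = len(atoms)
    if n < 2:
        raise ValueError("structure must have at least 2 atoms")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])

    bonds = infer_covalent_bonds(atoms)
    excluded = _excluded_pairs(n, bonds, cfg.covalent_exclusion_bonds)

    span = 2.0 * cfg.probe_radius
    if method == "grid":
        cutoff = 2.0 * radii.max() + span
        candidates = sorted(cKDTree(coords).query_pairs(cutoff))
    elif method == "brute":
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        raise ValueError(f"unknown method {method!r}")

    out: list[AtomicContact] = []
    for i, j in candidates:
        if residue_of[i] == residue_of[j] or (i, j) in excluded:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        g = d - radii[i] - radii[j]
        if g > span:
            continue
        ai, aj = atoms[i], atoms[j]
        donor_acceptor = ((is_donor(ai.name, resname_of[i]) and is_acceptor(aj.name, resname_of[j]))
                          or (is_donor(aj.name, resname_of[j]) and is_acceptor(ai.name, resname_of[i])))
        if donor_acceptor and d <= cfg.hbond_heavy_cutoff:
            score = lens_volume(radii[i] + cfg.probe_radius,
                                radii[j] + cfg.probe_radius, d)
            out.append(AtomicContact(ai.serial, aj.serial, "hbond", score))
        elif g < 0:
            out.append(AtomicContact(ai.serial, aj.serial, "overlap",
                                     lens_volume(radii[i], radii[j], d)))
        else:
            s_ij, n_ij = dot_contact_score(ai, aj, cfg)
            s_ji, n_ji = dot_contact_score(aj, ai, cfg)
            score = 0.5 * (s_ij + s_ji)
            if score > 0.0:
                out.append(AtomicContact(ai.serial, aj.serial, "contact",
                                         score, n_ij + n_ji))
    return out


def dump_contacts_tsv(contacts: list[AtomicContact], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("atom_i\tatom_j\tkind\tn_dots\tscore\n")
        for c in contacts:
            fh.write(f"{c.atom_i}\t{c.atom_j}\t{c.kind}\t{c.n_dots}\t{c.score:.6g}\n")
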