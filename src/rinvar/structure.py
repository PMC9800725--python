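"""Protein structure I/O, comparison, and sequence-level variant application.

Structures are single-chain lists of residues with explicit atoms.  The PDB
reader is a strict fixed-column parser: a malformed ATOM record is a hard
error naming the offending line, because silently mis-read coordinates would
corrupt every downstream contact score.  B-factors are preserved per atom and
interpreted as per-atom pLDDT for AlphaFold-style models.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "VDW_RADII",
    "MAINCHAIN_ATOMS",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "read_variant_table",
    "mean_plddt",
    "ca_rmsd",
    "apply_missense",
    "parse_hgvs_p",
]

#: Probe-style van der Waals radii (Angstrom), element-keyed.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

#: Backbone heavy atoms; everything else is side chain (glycine: none).
MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class PDBParseError(ValueError):
    """Raised for malformed PDB records (message includes the line number)."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Angstrom
    vdw_radius: float
    bfactor: float
    segment: str = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial} {self.name}: vdw_radius must be > 0")
        self.segment = "mainchain" if self.name in MAINCHAIN_ATOMS else "sidechain"


@dataclass
class Residue:
    author_number: int
    insertion_code: str | None
    name3: str
    seq_index: int
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        ins = self.insertion_code or ""
        return f"{self.name3}{self.author_number}{ins}"


@dataclass
class Structure:
    chain_id: str
    residues: list[Residue]
    source: str = ""

    @property
    def L(self) -> int:
        return len(self.residues)

    def atoms(self):
        for res in self.residues:
            yield from res.atoms

    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(r.name3, "X") for r in self.residues)

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()])


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record too short")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        icode = line[26].strip() or None
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip().upper()
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
    if not element:
        # fall back on the atom-name convention: first letter is the element
        element = re.sub(r"[^A-Za-z]", "", name)[:1].upper()
    return dict(serial=serial, name=name, altloc=altloc, resname=resname,
                chain=chain, resseq=resseq, icode=icode,
                coords=(x, y, z), bfactor=bfac, element=element)


def read_pdb(path: str | Path, vdw_radii: dict[str, float] | None = None) -> Structure:
    """Read the first chain of a PDB file into a :class:`Structure`.

    Only ATOM records are used.  If the file contains several chains a
    warning is emitted and the first is taken.  Unknown elements (no entry in
    the vdW radius table) are an error naming the atom.
    """
    radii = vdw_radii or VDW_RADII
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("ENDMDL"):
                break  # first model only
            if line.startswith("ATOM"):
                records.append(_parse_atom_line(line, lineno))
    if not records:
        raise ValueError(f"{path}: no ATOM records")
    chains = []
    for rec in records:
        if rec["chain"] not in chains:
            chains.append(rec["chain"])
    if len(chains) > 1:
        warnings.warn(
            f"{path}: {len(chains)} chains found; using first chain "
            f"{chains[0]!r}", stacklevel=2)
    chain_id = chains[0]

    residues: list[Residue] = []
    seen: dict[tuple, Residue] = {}
    seen_altloc: set[tuple] = set()
    for rec in records:
        if rec["chain"] != chain_id:
            continue
        if rec["element"] not in radii:
            raise ValueError(
                f"atom {rec['serial']} {rec['name']} ({rec['resname']}"
                f"{rec['resseq']}): unknown element {rec['element']!r} "
                f"with no vdW radius entry")
        key = (rec["resseq"], rec["icode"])
        if key not in seen:
            res = Residue(rec["resseq"], rec["icode"], rec["resname"],
                          len(residues), [])
            seen[key] = res
            residues.append(res)
        # keep the first altloc of each atom
        akey = (key, rec["name"])
        if rec["altloc"] and akey in seen_altloc:
            continue
        seen_altloc.add(akey)
        seen[key].atoms.append(Atom(rec["serial"], rec["name"], rec["element"],
                                    rec["coords"], radii[rec["element"]],
                                    rec["bfactor"]))
    return Structure(chain_id or "A", residues, source=str(path))


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as standard fixed-column ATOM records + TER/END."""
    lines = []
    serial = 0
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            icode = res.insertion_code or " "
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {res.name3:<3s} "
                f"{structure.chain_id:1.1s}{res.author_number:4d}{icode:1s}   "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{1.0:6.2f}{atom.bfactor:6.2f}          {atom.element:>2s}")
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> str:
    """Return the first sequence of a FASTA file (uppercase one-letter)."""
    for record in SeqIO.parse(str(path), "fasta"):
        return str(record.seq).upper()
    raise ValueError(f"{path}: no FASTA records")


def read_variant_table(path: str | Path):
    """Read a variant CSV with columns variant_id, hgvs_p, label (0/1)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"variant_id", "hgvs_p", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: labels must be 0/1")
    return df


# --------------------------------------------------------------------------
# Structure metrics
# --------------------------------------------------------------------------

def _ca_or_raise(res: Residue, what: str) -> Atom:
    ca = res.atom("CA")
    if ca is None:
        raise ValueError(f"{what}: residue {res.label} has no CA atom")
    return ca


def mean_plddt(structure: Structure) -> float:
    """Mean per-residue pLDDT, taking each residue's value from its CA B-factor."""
    vals = [_ca_or_raise(r, "mean_plddt").bfactor for r in structure.residues]
    return float(np.mean(vals))


def ca_rmsd(a: Structure, b: Structure) -> float:
    """C-alpha RMSD (Angstrom) after optimal rigid-body (Kabsch) superposition.

    Residues are paired 1:1 by sequence index; both structures must have the
    same length and a CA atom in every residue.  Symmetric in its arguments
    and invariant under rigid transforms of either.
    """
    if a.L != b.L:
        raise ValueError(f"length mismatch: {a.L} vs {b.L} residues")
    pa = np.array([_ca_or_raise(r, "ca_rmsd").coords for r in a.residues])
    pb = np.array([_ca_or_raise(r, "ca_rmsd").coords for r in b.residues])
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(a.L))


# --------------------------------------------------------------------------
# HGVS protein-level substitutions
# --------------------------------------------------------------------------

_HGVS_P = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_hgvs_p(hgvs_p: str) -> tuple[str, int, str]:
    """Parse ``p.Ala1708Glu`` into (one-letter ref, author position, one-letter alt)."""
    m = _HGVS_P.match(hgvs_p.strip())
    if not m:
        raise ValueError(f"cannot parse HGVS protein substitution: {hgvs_p!r}")
    ref3, pos, alt3 = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for code in (ref3, alt3):
        if code not in AA3_TO_1:
            raise ValueError(f"{hgvs_p}: unknown amino-acid code {code}")
    return AA3_TO_1[ref3], pos, AA3_TO_1[alt3]


def apply_missense(seq: str, hgvs_p: str, offset: int) -> str:
    """Apply a protein-level missense substitution to a sequence.

    ``offset`` maps author numbering onto the 0-based sequence: residue
    number ``pos`` lives at index ``pos - offset`` (for a domain fragment
    whose first residue is author number 1646, ``offset=1646``).
    """
    ref, pos, alt = parse_hgvs_p(hgvs_p)
    idx = pos - offset
    if not 0 <= idx < len(seq):
        raise ValueError(
            f"{hgvs_p}: position {pos} (index {idx}) out of range for "
            f"sequence of length {len(seq)} with offset {offset}")
    if seq[idx] != ref:
        raise ValueError(
            f"{hgvs_p}: reference mismatch at index {idx} — expected "
            f"{ref}, sequence holds {seq[idx]}")
    return seq[:idx] + alt + seq[idx + 1:]
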