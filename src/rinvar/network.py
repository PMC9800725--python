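"""Residue interaction networks: aggregation of atomic contacts into typed,
subtyped, weighted residue-pair edges, plus Cytoscape SIF/NA serialization.

Edge types: ``cnt`` (contact), ``hbond``, ``ovl`` (overlap) and ``combi``
(generic residue interaction — the weighted sum of the other three over all
subtypes).  Subtypes record which chain segments interact: ``mc_mc``,
``mc_sc`` (either direction), ``sc_sc``; combi edges always carry the
``all_all`` subtype.  The network is undirected; edges are stored with
i < j on 0-based residue indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .contacts import AtomicContact
from .structure import Structure

__all__ = [
    "EDGE_TYPES",
    "SUBTYPES",
    "CombiWeights",
    "ResidueInteractionNetwork",
    "build_rin",
    "write_sif",
    "read_sif",
    "write_na",
    "read_na",
    "read_network",
]

EDGE_TYPES = ("cnt", "hbond", "ovl", "combi")
SUBTYPES = ("mc_mc", "mc_sc", "sc_sc", "all_all")

_KIND_TO_ETYPE = {"contact": "cnt", "hbond": "hbond", "overlap": "ovl"}


@dataclass(frozen=True)
class CombiWeights:
    w_cnt: float = 1.0
    w_hbond: float = 1.0
    w_ovl: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_cnt, self.w_hbond, self.w_ovl) < 0:
            raise ValueError("combi weights must be >= 0")
        if self.w_cnt == self.w_hbond == self.w_ovl == 0:
            raise ValueError("combi weights must not all be zero")


class ResidueInteractionNetwork:
    """Undirected weighted multigraph over residues.

    Backed by a :class:`networkx.MultiGraph` whose edge keys are
    ``(etype, subtype)`` tuples with a ``weight`` attribute.  ``node_labels``
    are ``chain:resnum:name3`` strings used by the SIF/NA files.
    """

    def __init__(self, n_nodes: int, node_labels: list[str] | None = None) -> None:
        if node_labels is not None and len(node_labels) != n_nodes:
            raise ValueError("node_labels length must equal n_nodes")
        self.graph = nx.MultiGraph()
        labels = node_labels or [f"A:{i + 1}:UNK" for i in range(n_nodes)]
        for i, lab in enumerate(labels):
            self.graph.add_node(i, label=lab)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def node_labels(self) -> list[str]:
        return [self.graph.nodes[i]["label"] for i in range(self.n_nodes)]

    def add_edge(self, i: int, j: int, etype: str, subtype: str, weight: float) -> None:
        if etype not in EDGE_TYPES or subtype not in SUBTYPES:
            raise ValueError(f"unknown edge type/subtype {etype}:{subtype}")
        if (etype == "combi") != (subtype == "all_all"):
            raise ValueError("combi edges must (and only they may) use subtype all_all")
        if not 0 <= i < self.n_nodes or not 0 <= j < self.n_nodes or i == j:
            raise ValueError(f"invalid edge endpoints ({i}, {j})")
        i, j = min(i, j), max(i, j)
        self.graph.add_edge(i, j, key=(etype, subtype), weight=float(weight))

    def edges(self):
        """Yield (i, j, etype, subtype, weight) with i < j, sorted."""
        items = []
        for u, v, (etype, subtype), data in self.graph.edges(keys=True, data=True):
            i, j = min(u, v), max(u, v)
            items.append((i, j, etype, subtype, data["weight"]))
        return sorted(items)

    def weight(self, i: int, j: int, etype: str, subtype: str) -> float:
        i, j = min(i, j), max(i, j)
        try:
            return self.graph[i][j][(etype, subtype)]["weight"]
        except KeyError:
            return 0.0

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def equals(self, other: "ResidueInteractionNetwork", rtol: float = 1e-6) -> bool:
        if self.n_nodes != other.n_nodes:
            return False
        a, b = self.edges(), other.edges()
        if len(a) != len(b):
            return False
        for (i1, j1, e1, s1, w1), (i2, j2, e2, s2, w2) in zip(a, b):
            if (i1, j1, e1, s1) != (i2, j2, e2, s2):
                return False
            if abs(w1 - w2) > rtol * max(1.0, abs(w1), abs(w2)):
                return False
        return True


def build_rin(contacts: list[AtomicContact], structure: Structure,
              weights: CombiWeights | None = None) -> ResidueInteractionNetwork:
    """Aggregate atomic contacts into a residue interaction network.

    For each residue pair, each interaction kind is summed per subtype
    (main-chain/side-chain combination of the two atoms); the combi edge is
    the weighted sum of the three kinds over all subtypes.  Zero-weight edges
    are omitted.
    """
    weights = weights or CombiWeights()
    atom_info: dict[int, tuple[int, str]] = {}
    for res in structure.residues:
        for a in res.atoms:
            atom_info[a.serial] = (res.seq_index, a.segment)
    labels = [f"{structure.chain_id}:{r.author_number}:{r.name3}"
              for r in structure.residues]
    rin = ResidueInteractionNetwork(structure.L, labels)

    acc: dict[tuple[int, int, str, str], float] = {}
    combi: dict[tuple[int, int], float] = {}
    kind_w = {"cnt": weights.w_cnt, "hbond": weights.w_hbond, "ovl": weights.w_ovl}
    for c in contacts:
        if c.atom_i not in atom_info or c.atom_j not in atom_info:
            missing = c.atom_i if c.atom_i not in atom_info else c.atom_j
            raise ValueError(f"contact references unknown atom serial {missing}")
        ri, seg_i = atom_info[c.atom_i]
        rj, seg_j = atom_info[c.atom_j]
        if ri == rj:
            continue
        i, j = min(ri, rj), max(ri, rj)
        segs = {seg_i, seg_j}
        if segs == {"mainchain"}:
            subtype = "mc_mc"
        elif segs == {"sidechain"}:
            subtype = "sc_sc"
        else:
            subtype = "mc_sc"
        etype = _KIND_TO_ETYPE[c.kind]
        acc[(i, j, etype, subtype)] = acc.get((i, j, etype, subtype), 0.0) + c.score
        combi[(i, j)] = combi.get((i, j), 0.0) + kind_w[etype] * c.score

    for (i, j, etype, subtype), w in acc.items():
        if w != 0.0:
            rin.add_edge(i, j, etype, subtype, w)
    for (i, j), w in combi.items():
        if w != 0.0:
            rin.add_edge(i, j, "combi", "all_all", w)
    return rin


# --------------------------------------------------------------------------
# SIF / NA (Cytoscape) serialization
# --------------------------------------------------------------------------

def write_sif(rin: ResidueInteractionNetwork, path: str | Path) -> None:
    """Write the unweighted topology as SIF; isolated nodes as bare lines."""
    connected = set()
    lines = []
    for i, j, etype, subtype, _ in rin.edges():
        labels = rin.node_labels
        lines.append(f"{labels[i]}\t{etype}:{subtype}\t{labels[j]}")
        connected.update((i, j))
    for i, lab in enumerate(rin.node_labels):
        if i not in connected:
            lines.append(lab)
    Path(path).write_text("\n".join(lines) + "\n")


def read_sif(path: str | Path) -> ResidueInteractionNetwork:
    """Read a SIF file back into a network (unit weights)."""
    nodes: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[str, str, str, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            name = parts[0].strip()
            if name not in index:
                index[name] = len(nodes)
                nodes.append(name)
        elif len(parts) == 3:
            a, rel, b = parts
            etype, subtype = rel.split(":")
            for name in (a, b):
                if name not in index:
                    index[name] = len(nodes)
                    nodes.append(name)
            edges.append((a, b, etype, subtype))
        else:
            raise ValueError(f"{path}: malformed SIF line {line!r}")
    order = sorted(nodes, key=_label_sort_key)
    index = {name: k for k, name in enumerate(order)}
    rin = ResidueInteractionNetwork(len(order), order)
    for a, b, etype, subtype in edges:
        rin.add_edge(index[a], index[b], etype, subtype, 1.0)
    return rin


def _label_sort_key(label: str):
    chain, num, name3 = label.split(":")
    return (chain, int(num), name3)


def _na_path(prefix: str | Path, etype: str) -> Path:
    return Path(f"{prefix}.{etype}.na")


def write_na(rin: ResidueInteractionNetwork, path_prefix: str | Path) -> list[Path]:
    """Write Cytoscape 2.x edge-attribute files, one per edge type.

    Each file starts with a header naming the attribute, then lines
    ``nodeA (etype:subtype) nodeB = weight`` (6 significant digits).
    """
    labels = rin.node_labels
    by_etype: dict[str, list[str]] = {e: [] for e in EDGE_TYPES}
    for i, j, etype, subtype, w in rin.edges():
        by_etype[etype].append(
            f"{labels[i]} ({etype}:{subtype}) {labels[j]} = {w:.6g}")
    written = []
    for etype, lines in by_etype.items():
        if not lines:
            continue
        p = _na_path(path_prefix, etype)
        p.write_text(f"{etype}_weight\n" + "\n".join(lines) + "\n")
        written.append(p)
    return written


def read_na(path_prefix: str | Path) -> dict[tuple[str, str, str, str], float]:
    """Read NA files back into {(labelA, labelB, etype, subtype): weight}."""
    out: dict[tuple[str, str, str, str], float] = {}
    for etype in EDGE_TYPES:
        p = _na_path(path_prefix, etype)
        if not p.exists():
            continue
        lines = p.read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            left, w = line.rsplit(" = ", 1)
            a, rel, b = left.split(" ")
            out[(a, b) + tuple(rel.strip("()").split(":"))] = float(w)
    return out


def read_network(sif_path: str | Path, na_prefix: str | Path) -> ResidueInteractionNetwork:
    """Reassemble a weighted network from its SIF topology and NA weights."""
    rin = read_sif(sif_path)
    index = {lab: i for i, lab in enumerate(rin.node_labels)}
    for (a, b, etype, subtype), w in read_na(na_prefix).items():
        rin.add_edge(index[a], index[b], etype, subtype, w)
    return rin
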