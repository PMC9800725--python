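"""Interaction-matrix encoding: residue network -> symmetric L x L x 7 tensor.

Channel map (fixed):

1. cnt,   mc_mc + sc_sc (summed)
2. cnt,   mc_sc
3. hbond, mc_mc + sc_sc
4. hbond, mc_sc
5. combi, all_all
6. ovl,   mc_mc + sc_sc
7. ovl,   mc_sc

Every channel is symmetric with a zero diagonal; absent edges are zero.
Datasets of equal-length matrices are exchanged as HDF5 files with the
channel semantics stored as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .network import ResidueInteractionNetwork

__all__ = [
    "CHANNEL_SEMANTICS",
    "FEATURE_CHANNELS",
    "InteractionMatrix",
    "encode",
    "decode",
    "diff_channels",
    "save_dataset",
    "load_dataset",
]

#: channel index (0-based) -> (etype, subtypes aggregated into it)
CHANNEL_SEMANTICS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("cnt", ("mc_mc", "sc_sc")),
    ("cnt", ("mc_sc",)),
    ("hbond", ("mc_mc", "sc_sc")),
    ("hbond", ("mc_sc",)),
    ("combi", ("all_all",)),
    ("ovl", ("mc_mc", "sc_sc")),
    ("ovl", ("mc_sc",)),
)

#: named feature -> 0-based channel indices (for ablation studies)
FEATURE_CHANNELS: dict[str, tuple[int, ...]] = {
    "cnt": (0, 1),
    "hbond": (2, 3),
    "combi": (4,),
    "ovl": (5, 6),
    "all": (0, 1, 2, 3, 4, 5, 6),
}

_CHANNEL_OF: dict[tuple[str, str], int] = {
    (etype, sub): c
    for c, (etype, subs) in enumerate(CHANNEL_SEMANTICS)
    for sub in subs
}


@dataclass
class InteractionMatrix:
    tensor: np.ndarray          # (L, L, 7)
    variant_id: str = ""
    label: int | None = None
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.ndim != 3 or t.shape[0] != t.shape[1] or t.shape[2] != 7:
            raise ValueError(f"tensor must be (L, L, 7), got {t.shape}")
        if not np.allclose(t, t.transpose(1, 0, 2)):
            raise ValueError("every channel must be symmetric")
        if np.abs(np.einsum("iic->ic", t)).max() > 0:
            raise ValueError("diagonal must be zero")
        self.tensor = t

    @property
    def L(self) -> int:
        return self.tensor.shape[0]


def encode(rin: ResidueInteractionNetwork, variant_id: str = "",
           label: int | None = None, normalize: bool = False) -> InteractionMatrix:
    """Encode a residue network into the 7-channel interaction matrix.

    ``normalize=True`` divides each channel by its maximum absolute entry
    (channels that are all zero are left untouched); default is the raw
    weighted scores.
    """
    L = rin.n_nodes
    t = np.zeros((L, L, 7))
    for i, j, etype, subtype, w in rin.edges():
        if not (0 <= i < L and 0 <= j < L):
            raise ValueError(f"edge index ({i}, {j}) out of range for L={L}")
        c = _CHANNEL_OF[(etype, subtype)]
        t[i, j, c] += w
        t[j, i, c] += w
    if normalize:
        for c in range(7):
            m = np.abs(t[:, :, c]).max()
            if m > 0:
                t[:, :, c] /= m
    return InteractionMatrix(t, variant_id=variant_id, label=label,
                             normalized=normalize)


def decode(matrix: InteractionMatrix) -> dict[tuple[int, int, int], float]:
    """Nonzero entries as {(i, j, channel): weight} with i < j.

    Subtypes are collapsed exactly as the channel map dictates; this is the
    inverse of :func:`encode` up to that collapse.
    """
    out: dict[tuple[int, int, int], float] = {}
    t = matrix.tensor
    for i, j in zip(*np.triu_indices(matrix.L, k=1)):
        for c in range(7):
            if t[i, j, c] != 0.0:
                out[(int(i), int(j), c)] = float(t[i, j, c])
    return out


def diff_channels(a: InteractionMatrix, b: InteractionMatrix):
    """Element-wise difference a - b with a per-channel magnitude summary.

    Returns (diff tensor, summary) where summary is a list of
    ``(channel_1based, frobenius_norm)`` sorted by decreasing norm.
    """
    if a.L != b.L:
        raise ValueError(f"shape mismatch: L={a.L} vs L={b.L}")
    diff = a.tensor - b.tensor
    norms = np.sqrt((diff ** 2).sum(axis=(0, 1)))
    order = np.argsort(-norms)
    summary = [(int(c) + 1, float(norms[c])) for c in order]
    return diff, summary


# --------------------------------------------------------------------------
# HDF5 dataset exchange
# --------------------------------------------------------------------------

def save_dataset(path: str | Path, matrices: np.ndarray, labels: np.ndarray,
                 variant_ids: list[str]) -> None:
    """Write (N, L, L, 7) matrices with labels and ids to an HDF5 file."""
    matrices = np.asarray(matrices)
    if matrices.ndim != 4 or matrices.shape[1] != matrices.shape[2] \
            or matrices.shape[3] != 7:
        raise ValueError(f"matrices must be (N, L, L, 7), got {matrices.shape}")
    if not (len(labels) == len(variant_ids) == matrices.shape[0]):
        raise ValueError("matrices, labels and variant_ids must align")
    with h5py.File(path, "w") as f:
        # track_times off so identical inputs give byte-identical files
        f.create_dataset("matrices", data=matrices, track_times=False)
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int8),
                         track_times=False)
        f.create_dataset("variant_ids", track_times=False,
                         data=np.array(variant_ids, dtype=h5py.string_dtype()))
        f.attrs["channel_semantics"] = [
            f"{c + 1}: {etype} {'+'.join(subs)}"
            for c, (etype, subs) in enumerate(CHANNEL_SEMANTICS)]


def load_dataset(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    with h5py.File(path, "r") as f:
        matrices = f["matrices"][()]
        labels = f["labels"][()].astype(int)
        variant_ids = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["variant_ids"][()]]
    return matrices, labels, variant_ids
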