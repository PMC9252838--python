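"""Residue-residue contact-probability maps.

Instead of a hard distance cutoff, each residue pair (i, j) gets a contact
probability from a logistic transform of its Cα-Cα distance d_ij:

    p_ij = 1 / (1 + exp((d_ij - d0) / delta))

so p = 0.5 at d = d0 and decays smoothly with steepness delta.  The map is
the single shared input of peeling, domain assembly and all compactness /
separation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .structure_io import Structure

#: Defaults: the conventional Cα contact midpoint and a soft shoulder.
DEFAULT_D0 = 8.0
DEFAULT_DELTA = 1.5
#: Sequence separation below which a pair counts as "local".
NONLOCAL_MIN_SEPARATION = 3


@dataclass
class ContactMap:
    probs: np.ndarray
    d0: float
    delta: float
    min_sequence_separation: int = 0

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("contact map must be a square matrix")
        self.probs = p

    def nonlocal_view(self, min_separation: int = NONLOCAL_MIN_SEPARATION) -> "ContactMap":
        """A copy with all pairs of sequence separation < min_separation zeroed."""
        if min_separation <= self.min_sequence_separation:
            return self
        idx = np.arange(self.n)
        sep = np.abs(idx[:, None] - idx[None, :])
        probs = np.where(sep >= min_separation, self.probs, 0.0)
        return replace(self, probs=probs, min_sequence_separation=min_separation)


def compute_contact_map(
    structure: Structure,
    d0: float = DEFAULT_D0,
    delta: float = DEFAULT_DELTA,
    min_sequence_separation: int = 0,
) -> ContactMap:
    """Logistic contact-probability matrix of a cleaned structure."""
    if len(structure) < 2:
        raise ValueError("need at least 2 residues to build a contact map")
    if d0 <= 0 or delta <= 0:
        raise ValueError("d0 and delta must be positive")
    xyz = structure.ca_coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    probs = expit((d0 - dist) / delta)
    np.fill_diagonal(probs, 0.0)
    if min_sequence_separation > 0:
        idx = np.arange(len(structure))
        sep = np.abs(idx[:, None] - idx[None, :])
        probs[sep < min_sequence_separation] = 0.0
    return ContactMap(
        probs=probs,
        d0=d0,
        delta=delta,
        min_sequence_separation=min_sequence_separation,
    )


def contact_mass(cm: ContactMap, set_a, set_b) -> float:
    """Summed contact probability inside a set or between two disjoint sets.

    With ``set_a == set_b`` this is the intra mass Σ_{i<j} p_ij over pairs
    inside the set; for disjoint sets it is the inter mass Σ_{i∈A, j∈B} p_ij.
    Overlapping distinct sets have no defined semantics and raise.
    """
    a = frozenset(set_a)
    b = frozenset(set_b)
    _check_indices(cm, a | b)
    ia = np.fromiter((i - 1 for i in sorted(a)), dtype=int)
    if a == b:
        if len(a) < 2:
            return 0.0
        return float(cm.probs[np.ix_(ia, ia)].sum() / 2.0)
    if a & b:
        raise ValueError("contact_mass between overlapping distinct sets is undefined")
    if not a or not b:
        return 0.0
    ib = np.fromiter((i - 1 for i in sorted(b)), dtype=int)
    return float(cm.probs[np.ix_(ia, ib)].sum())


def _check_indices(cm: ContactMap, indices) -> None:
    for i in indices:
        if not 1 <= i <= cm.n:
            raise IndexError(f"residue index {i} outside 1..{cm.n}")


def write_dense(cm: ContactMap, path: str | Path) -> Path:
    """Whitespace-delimited dense matrix, one row per residue."""
    path = Path(path)
    np.savetxt(path, cm.probs, fmt="%.6f")
    return path


def write_sparse(cm: ContactMap, path: str | Path, threshold: float = 1e-6) -> Path:
    """Sparse TSV (i, j, p) for i < j, 1-based, entries below threshold omitted."""
    path = Path(path)
    iu, ju = np.triu_indices(cm.n, k=1)
    keep = cm.probs[iu, ju] >= threshold
    with path.open("w") as fh:
        fh.write("i\tj\tp\n")
        for i, j in zip(iu[keep], ju[keep]):
            fh.write(f"{i + 1}\t{j + 1}\t{cm.probs[i, j]:.6f}\n")
    return path
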