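"""Three-state secondary-structure annotation (first hierarchical level).

Secondary structure is report-only: it never feeds into peeling or domain
assembly.  The canonical source is a DSSP output file; when none is given, a
deliberately crude Cα-geometry heuristic provides an approximate 3-state
string so that Cα-only inputs remain self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ProtPeelError
from .structure_io import Structure

logger = logging.getLogger(__name__)

#: DSSP 8-state -> 3-state reduction: helices to H, strands/bridges to E,
#: everything else (bends, turns, coil) to C.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "S": "C", "T": "C", "C": "C",
}


@dataclass
class SecondaryStructure:
    """Per-residue 8-state and reduced 3-state strings, plus provenance."""

    states8: str
    states3: str
    method: str = "dssp"

    def __post_init__(self):
        if len(self.states8) != len(self.states3):
            raise ValueError("states8 and states3 must have equal length")

    @classmethod
    def from_states8(cls, states8: str, method: str = "dssp") -> "SecondaryStructure":
        return cls(states8=states8, states3=reduce_states(states8), method=method)


def reduce_states(states8: str) -> str:
    """Reduce an 8-state DSSP string to 3 states (H/E/C).

    H, G, I -> H;  E, B -> E;  S, T, C -> C.  A blank is treated as C.
    """
    out = []
    for pos, ch in enumerate(states8, start=1):
        if ch == " ":
            ch = "C"
        try:
            out.append(SS8_TO_SS3[ch])
        except KeyError:
            raise ValueError(
                f"unknown secondary-structure state {ch!r} at position {pos}"
            ) from None
    return "".join(out)


def parse_dssp(path: str | Path, chain: str, structure: Structure) -> SecondaryStructure:
    """Read a classic-format DSSP file and align it to a cleaned structure.

    Alignment is by original residue number; residues of the structure that
    the DSSP file does not cover are coded C.  Only DSSP rows without an
    insertion code are considered (insertion-code residues were removed
    during cleaning).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ProtPeelError(f"{path}: malformed DSSP file (no '#  RESIDUE' header)")

    by_orig: dict[int, str] = {}
    seen_chain = False
    for line in lines[start:]:
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break marker
            continue
        if line[11] != chain:
            continue
        seen_chain = True
        if line[10].strip():
            continue  # insertion-code residue; dropped during cleaning
        try:
            orig = int(line[5:10])
        except ValueError:
            continue
        ss = line[16]
        by_orig[orig] = "C" if ss == " " else ss
    if not seen_chain:
        raise ProtPeelError(f"{path}: chain {chain!r} not present in DSSP output")

    states8 = "".join(by_orig.get(r.original_number, "C") for r in structure.residues)
    return SecondaryStructure.from_states8(states8, method="dssp")


def assign_ss_from_ca(structure: Structure) -> SecondaryStructure:
    """Approximate 3-state assignment from Cα geometry alone.

    A residue window i is helix-like when the i→i+3 Cα distance falls in
    [4.5, 6.0] Å; a run of ≥ 4 consecutive helix-like windows marks the
    covered residues H.  A window is extended when the i→i+2 distance is
    ≥ 6.4 Å; a run of ≥ 3 such windows marks the covered residues E.
    Everything else is C.  Helix takes precedence over strand.  Structures
    shorter than 5 residues are returned as all-C with a warning.
    """
    n = len(structure)
    if n < 5:
        logger.warning(
            "structure of length %d too short for geometric SS assignment; all C", n
        )
        return SecondaryStructure("C" * n, "C" * n, method="ca-geometric-approximate")

    xyz = structure.ca_coords
    d3 = np.linalg.norm(xyz[3:] - xyz[:-3], axis=1)  # i -> i+3, i = 0..n-4
    d2 = np.linalg.norm(xyz[2:] - xyz[:-2], axis=1)  # i -> i+2, i = 0..n-3

    states = np.full(n, "C", dtype="<U1")

    helix_win = (d3 >= 4.5) & (d3 <= 6.0)
    for run_start, run_len in _runs(helix_win):
        if run_len >= 4:
            states[run_start:run_start + run_len + 3] = "H"

    ext_win = d2 >= 6.4
    for run_start, run_len in _runs(ext_win):
        if run_len >= 3:
            seg = slice(run_start, run_start + run_len + 2)
            states[seg] = np.where(states[seg] == "H", "H", "E")

    s3 = "".join(states)
    return SecondaryStructure(states8=s3, states3=s3, method="ca-geometric-approximate")


def _runs(mask: np.ndarray):
    """Yield (start, length) of maximal runs of True in a boolean array."""
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            yield start, i - start
            start = None
    if start is not None:
        yield start, len(mask) - start
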