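"""Read, clean and renumber protein structures.

The whole pipeline works on a C-alpha-only view of a single chain.  Cleaning
follows the rules applied by domain-assignment servers before analysis:
heteroatoms are dropped, residues with non-standard names are dropped,
residues carrying insertion codes are dropped, and the survivors are
renumbered contiguously from 1 while the original author numbering is kept
for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import ChainNotFoundError, EmptyStructureError, StructureParseError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, 3-letter -> 1-letter.
STANDARD_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA_1TO3 = {v: k for k, v in STANDARD_AA_3TO1.items()}


@dataclass(frozen=True)
class Residue:
    """One cleaned residue, reduced to its C-alpha atom.

    ``internal_index`` runs 1..N with no gaps; ``original_number`` (plus the
    insertion code, always empty after cleaning) preserves the author
    numbering of the source file.
    """

    internal_index: int
    original_number: int
    original_insertion_code: str
    amino_acid: str
    ca_xyz: tuple[float, float, float]


@dataclass
class Structure:
    """A cleaned single-chain structure: ordered residues with Cα coordinates."""

    chain_id: str
    residues: list[Residue]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in Å, row i = internal index i+1."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    def original_numbering(self) -> list[int]:
        return [r.original_number for r in self.residues]

    def original_range(self, start: int, end: int) -> tuple[int, int]:
        """Map an internal inclusive interval to original author numbers."""
        return (
            self.residues[start - 1].original_number,
            self.residues[end - 1].original_number,
        )


def resolve_altloc(atom_records: list) -> "gemmi.Atom":
    """Pick the single Cα record among alternate locations.

    Highest occupancy wins; exact ties go to the alphabetically first
    alt-loc identifier.
    """
    if not atom_records:
        raise ValueError("no atom records to resolve")
    return min(atom_records, key=lambda a: (-a.occ, a.altloc or ""))


def load_structure(
    path: str | Path,
    chain: str = "A",
    model_index: int = 0,
) -> Structure:
    """Load one chain of a PDB file and clean it.

    Heteroatom records, non-standard residues and residues with insertion
    codes are removed; residues lacking a Cα are dropped with a warning;
    survivors are renumbered from 1.  Only the model at ``model_index``
    (default: the first) is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no coordinate model found")
    if model_index >= len(st):
        raise StructureParseError(
            f"{path}: model index {model_index} out of range ({len(st)} models)"
        )
    model = st[model_index]
    available = [ch.name for ch in model]
    if not available:
        raise StructureParseError(
            f"{path}: no ATOM records found (not a valid PDB coordinate file?)"
        )
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ChainNotFoundError(chain, available)

    residues: list[Residue] = []
    for res in target:
        if res.het_flag != "A":
            continue  # heteroatom record (HETATM)
        if res.name not in STANDARD_AA_3TO1:
            continue  # non-standard residue, removed (no remapping of MSE etc.)
        icode = res.seqid.icode.strip()
        if icode:
            continue  # residues with insertion codes are removed
        ca_records = [a for a in res if a.name == "CA" and a.element.name == "C"]
        if not ca_records:
            logger.warning(
                "residue %s %d of chain %s has no C-alpha atom; dropped",
                res.name, res.seqid.num, chain,
            )
            continue
        ca = resolve_altloc(ca_records)
        residues.append(
            Residue(
                internal_index=len(residues) + 1,
                original_number=res.seqid.num,
                original_insertion_code="",
                amino_acid=STANDARD_AA_3TO1[res.name],
                ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
            )
        )
    if not residues:
        raise EmptyStructureError(
            f"{path}: chain {chain} holds no standard residue with a C-alpha "
            "after cleaning"
        )
    return Structure(chain_id=chain, residues=residues, source_label=path.name)


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write the cleaned Cα trace back out as a single-chain PDB file.

    Residues are written with their internal numbering so that reloading the
    file reproduces the same indices, sequence and coordinates.
    """
    path = Path(path)
    lines = []
    for res in structure.residues:
        x, y, z = res.ca_xyz
        lines.append(
            "ATOM  {serial:>5} {name:<4}{alt}{res:>3} {chain}{num:>4}{icode}   "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2}".format(
                serial=res.internal_index,
                name=" CA ",
                alt=" ",
                res=STANDARD_AA_1TO3[res.amino_acid],
                chain=structure.chain_id,
                num=res.internal_index,
                icode=" ",
                x=x, y=y, z=z,
                occ=1.00, b=0.00, el="C",
            )
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
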