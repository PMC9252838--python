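"""Synthetic Cα-only structures and toy contact maps with known ground truth.

The main generator builds "globule chains": compact self-avoiding random
walks (the globules) joined by near-straight extended linkers.  Because the
globule boundaries are known exactly, these structures serve as ground
truth for peeling and domain assembly.  An ideal helix generator and an
analytic block contact map round out the toolbox.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contact_map import ContactMap
from .errors import FixtureError
from .structure_io import Residue, Structure

AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_STEP = 3.8       # Cα-Cα virtual bond length, Å
DEFAULT_RADIUS = 10.0    # globule confinement sphere radius, Å
MIN_CLASH = 3.5          # minimal non-consecutive Cα-Cα distance, Å
CENTER_SPACING_FACTOR = 3.0


@dataclass
class FixtureSpec:
    globule_sizes: list[int]
    linker_lengths: list[int]
    globule_radius: float = DEFAULT_RADIUS
    step_length: float = DEFAULT_STEP
    seed: int = 0

    def __post_init__(self):
        if len(self.linker_lengths) != len(self.globule_sizes) - 1:
            raise ValueError("need exactly one linker fewer than globules")
        if any(g < 5 for g in self.globule_sizes):
            raise ValueError("every globule needs at least 5 residues")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")

    @property
    def total_residues(self) -> int:
        return sum(self.globule_sizes) + sum(self.linker_lengths)


@dataclass
class GlobuleChain:
    """Generated structure plus its ground truth."""

    structure: Structure
    #: (kind, start, end) segments in internal numbering, kind in {globule, linker}
    segments: list[tuple[str, int, int]]
    spec: FixtureSpec

    @property
    def linker_midpoints(self) -> list[int]:
        """True boundary positions: residue k such that the natural cut is
        between k and k+1, at the middle of each linker."""
        out = []
        for kind, s, e in self.segments:
            if kind == "linker":
                out.append((s + e) // 2)
        return out

    @property
    def globule_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for kind, s, e in self.segments if kind == "globule"]


def _confined_walk(rng, n, center, start, radius, step, prior_points):
    """Self-avoiding 3.8 Å-step walk inside a sphere; returns n points."""
    pts = [np.asarray(start, dtype=float)]
    all_prior = prior_points
    for _ in range(1, n):
        placed = False
        for _attempt in range(200):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = pts[-1] + step * v
            if np.linalg.norm(cand - center) > radius:
                continue
            near = pts[:-1] + all_prior
            if near and min(np.linalg.norm(cand - q) for q in near) < MIN_CLASH:
                continue
            pts.append(cand)
            placed = True
            break
        if not placed:
            return None
    return pts


def make_globule_chain(spec: FixtureSpec) -> GlobuleChain:
    """Build a chain of compact globules joined by extended linkers.

    Globule g is confined to a sphere of ``globule_radius`` whose center
    sits at least ``3 * globule_radius`` from the previous one; linkers run
    nearly straight along the chain axis.  Fully deterministic under
    ``spec.seed``; raises :class:`FixtureError` when the requested residue
    counts cannot fit the geometry.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.globule_radius
    step = spec.step_length
    min_spacing = CENTER_SPACING_FACTOR * r

    points: list[np.ndarray] = []
    segments: list[tuple[str, int, int]] = []
    entry = np.zeros(3)
    center = entry + np.array([0.8 * r, 0.0, 0.0])
    prev_center = None

    for g, size in enumerate(spec.globule_sizes):
        is_last = g == len(spec.globule_sizes) - 1
        linker_len = 0 if is_last else spec.linker_lengths[g]
        walk = None
        for _retry in range(200):
            candidate = _confined_walk(rng, size, center, entry, r, step, points)
            if candidate is None:
                continue
            if is_last:
                walk = candidate
                break
            # exit must sit far enough forward that the next center keeps
            # the required spacing while staying within linker reach
            exit_x = candidate[-1][0]
            reach = (linker_len + 1) * step * 0.98  # jitter shortens the x-advance
            next_center_x = max(exit_x + reach + 0.8 * r,
                                center[0] + min_spacing)
            if next_center_x - (exit_x + reach) <= 0.95 * r:
                walk = candidate
                break
        if walk is None:
            raise FixtureError(
                f"could not place globule {g + 1} ({size} residues) in a sphere of "
                f"radius {r} Å reachable by a {linker_len}-residue linker; try a "
                "larger globule_radius or longer linkers"
            )
        seg_start = len(points) + 1
        points.extend(walk)
        segments.append(("globule", seg_start, len(points)))

        if prev_center is not None:
            assert np.linalg.norm(center - prev_center) >= min_spacing - 1e-9
        prev_center = center

        if not is_last:
            # near-straight linker along +x with small lateral jitter
            lk_start = len(points) + 1
            for _ in range(linker_len):
                jitter = rng.normal(scale=0.35, size=2)
                d = np.array([1.0, jitter[0], jitter[1]])
                d /= np.linalg.norm(d)
                points.append(points[-1] + step * d)
            if linker_len:
                segments.append(("linker", lk_start, len(points)))
            d = np.array([1.0, 0.0, 0.0])
            entry = points[-1] + step * d
            reach_x = entry[0]
            center = np.array(
                [max(reach_x + 0.8 * r, center[0] + min_spacing), entry[1], entry[2]]
            )

    residues = [
        Residue(
            internal_index=i + 1,
            original_number=i + 1,
            original_insertion_code="",
            amino_acid=AA20[rng.integers(0, 20)],
            ca_xyz=(round(p[0], 3), round(p[1], 3), round(p[2], 3)),
        )
        for i, p in enumerate(points)
    ]
    structure = Structure(
        chain_id="A",
        residues=residues,
        source_label=f"synthetic-globule-chain-seed{spec.seed}",
    )
    return GlobuleChain(structure=structure, segments=segments, spec=spec)


def make_ideal_helix(n: int) -> Structure:
    """Canonical α-helix Cα trace: 1.5 Å rise, 100° twist, 2.3 Å radius."""
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    residues = []
    for i in range(n):
        theta = math.radians(100.0 * i)
        residues.append(
            Residue(
                internal_index=i + 1,
                original_number=i + 1,
                original_insertion_code="",
                amino_acid="A",
                ca_xyz=(2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * i),
            )
        )
    return Structure(chain_id="A", residues=residues, source_label=f"ideal-helix-{n}")


def make_extended_chain(n: int, step: float = DEFAULT_STEP) -> Structure:
    """Fully extended collinear chain with 3.8 Å steps."""
    residues = [
        Residue(
            internal_index=i + 1,
            original_number=i + 1,
            original_insertion_code="",
            amino_acid="G",
            ca_xyz=(step * i, 0.0, 0.0),
        )
        for i in range(n)
    ]
    return Structure(chain_id="A", residues=residues, source_label=f"extended-{n}")


def make_block_map(
    block_sizes: list[int],
    intra_p: float,
    inter_p: float = 0.0,
) -> ContactMap:
    """Analytic block-diagonal contact map (diagonal zero)."""
    if not 0.0 <= inter_p <= intra_p <= 1.0:
        raise ValueError("need 0 <= inter_p <= intra_p <= 1")
    n = sum(block_sizes)
    probs = np.full((n, n), inter_p, dtype=float)
    offset = 0
    for size in block_sizes:
        probs[offset:offset + size, offset:offset + size] = intra_p
        offset += size
    np.fill_diagonal(probs, 0.0)
    return ContactMap(probs=probs, d0=float("nan"), delta=float("nan"))


def write_fixture(chain: GlobuleChain, out_prefix: str | Path) -> tuple[Path, Path]:
    """Emit a fixture as PDB plus a sidecar ground-truth JSON."""
    from .structure_io import write_structure

    out_prefix = Path(out_prefix)
    pdb_path = out_prefix.with_suffix(".pdb")
    json_path = out_prefix.with_suffix(".truth.json")
    write_structure(chain.structure, pdb_path)
    truth = {
        "seed": chain.spec.seed,
        "globule_sizes": chain.spec.globule_sizes,
        "linker_lengths": chain.spec.linker_lengths,
        "globule_radius": chain.spec.globule_radius,
        "step_length": chain.spec.step_length,
        "segments": [list(s) for s in chain.segments],
        "linker_midpoints": chain.linker_midpoints,
    }
    json_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return pdb_path, json_path
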