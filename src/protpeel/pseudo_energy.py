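"""Knowledge-based pseudo-energy, decoy Z-scores and autonomy likelihood.

Each substructure (Protein Unit or domain) is scored by a pairwise contact
pseudo-energy E.  Because such scores scale with size, E is standardized
against sequence-shuffled decoys: the residue labels of the unit are
permuted uniformly at random over the fixed coordinates, the energy is
recomputed for each decoy, and

    Z = (E - mu) / sigma

with mu, sigma the decoy sample mean and standard deviation.  The decoy
distribution is not assumed normal, so the one-sided likelihood that a
random sequence would score at least as well is bounded with Chebyshev's
inequality, giving the Autonomous Unit Likelihood

    AUL = 100 * (1 - 1/Z^2)   for Z <= -1,   else 0   (percent).

A Z of -2 maps to 75%, -4 to 93.75% (reported 94%); any Z > -1 carries no
signal and maps to 0%.

The bundled 20x20 propensity table is a synthetic hydrophobicity-derived
contact log-odds surface (see ``data/contact_logodds_synthetic.txt``); the
decoy / Z / AUL machinery is exact regardless of the table used, and any
whitespace-delimited 20x20 table in the residue order ACDEFGHIKLMNPQRSTVWY
can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import DegenerateDistributionError
from .structure_io import Structure

#: Row/column order of the propensity table.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

DEFAULT_N_DECOYS = 2000
DEFAULT_DISTANCE_CUTOFF = 8.0
DEFAULT_MIN_SEPARATION = 3


@dataclass
class PropensityTable:
    """Symmetric 20x20 residue-pair contact log-odds."""

    log_odds: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        t = np.asarray(self.log_odds, dtype=float)
        if t.shape != (20, 20):
            raise ValueError("propensity table must be 20x20")
        if not np.allclose(t, t.T):
            raise ValueError("propensity table must be symmetric")
        if not np.all(np.isfinite(t)):
            raise ValueError("propensity table must be finite")
        self.log_odds = t


@dataclass
class DecoyStats:
    mean: float
    sd: float
    degenerate: bool
    n_decoys: int
    seed: int


@dataclass
class EnergyAssessment:
    """Full native-likeness assessment of one substructure."""

    pseudo_energy: float
    decoy_mean: float
    decoy_sd: float
    z_score: float | None
    aul_percent: float | None
    degenerate: bool
    n_decoys: int
    seed: int


def load_propensity_table(path: str | Path | None = None) -> PropensityTable:
    """Load a propensity table; defaults to the bundled synthetic surrogate."""
    if path is None:
        ref = resources.files("protpeel.data").joinpath("contact_logodds_synthetic.txt")
        text = ref.read_text()
        label = "bundled synthetic hydrophobicity-derived surrogate"
    else:
        text = Path(path).read_text()
        label = str(path)
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return PropensityTable(log_odds=np.array(rows), source_label=label)


def _contact_pairs(structure: Structure, unit, cutoff: float, min_sep: int):
    """Qualifying pairs (as positions within the sorted unit) and aa indices."""
    idx = sorted(frozenset(unit))
    xyz = structure.ca_coords[[i - 1 for i in idx]]
    seq = np.array([AA_TO_INDEX[structure.residues[i - 1].amino_acid] for i in idx])
    k = len(idx)
    pi, pj = [], []
    for a in range(k):
        for b in range(a + 1, k):
            if abs(idx[a] - idx[b]) < min_sep:
                continue
            if np.linalg.norm(xyz[a] - xyz[b]) <= cutoff:
                pi.append(a)
                pj.append(b)
    return seq, np.array(pi, dtype=int), np.array(pj, dtype=int)


def pseudo_energy(
    structure: Structure,
    unit,
    table: PropensityTable,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> float:
    """E = -sum of contact log-odds over qualifying pairs within the unit.

    A pair qualifies when its sequence separation is >= ``min_separation``
    and its Cα distance is <= ``distance_cutoff``.  Lower (more negative) E
    means more favorable contacts.
    """
    seq, pi, pj = _contact_pairs(structure, unit, distance_cutoff, min_separation)
    if len(pi) == 0:
        return 0.0
    return float(-table.log_odds[seq[pi], seq[pj]].sum())


def decoy_distribution(
    structure: Structure,
    unit,
    table: PropensityTable,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = 0,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> DecoyStats:
    """Mean and sd of pseudo-energies over sequence-shuffled decoys.

    Each decoy permutes the unit's residue labels uniformly at random while
    coordinates stay fixed.  Fully determined by ``seed``.  A unit whose
    decoy energies show zero spread (e.g. a homopolymer) is flagged
    degenerate.
    """
    if n_decoys < 2:
        raise ValueError("need at least 2 decoys")
    unit = frozenset(unit)
    if len(unit) < 2:
        raise ValueError("unit must hold at least 2 residues")
    seq, pi, pj = _contact_pairs(structure, unit, distance_cutoff, min_separation)
    rng = np.random.default_rng(seed)
    k = len(seq)
    perms = np.argsort(rng.random((n_decoys, k)), axis=1)
    shuffled = seq[perms]  # (n_decoys, k)
    if len(pi) == 0:
        energies = np.zeros(n_decoys)
    else:
        energies = -table.log_odds[shuffled[:, pi], shuffled[:, pj]].sum(axis=1)
    mean = float(energies.mean())
    sd = float(energies.std(ddof=1))
    # label-permutation-invariant units (e.g. homopolymers) give identical
    # decoys up to float summation order; treat that spread as zero
    if sd <= 1e-10 * max(1.0, abs(mean)):
        sd = 0.0
    return DecoyStats(
        mean=mean, sd=sd, degenerate=(sd == 0.0), n_decoys=n_decoys, seed=seed
    )


def z_score(energy: float, mean: float, sd: float) -> float:
    """Standardized energy (E - mu) / sigma; undefined for sigma = 0."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        raise DegenerateDistributionError(
            "decoy distribution has zero spread; Z-score undefined"
        )
    return (energy - mean) / sd


def aul_from_zscore(z: float) -> float:
    """Chebyshev-bound Autonomous Unit Likelihood, in percent.

    AUL = 100*(1 - 1/Z^2) for Z <= -1; 0 otherwise.  Callers report it
    rounded to the nearest integer percent.
    """
    if not np.isfinite(z):
        raise ValueError("Z-score must be finite")
    if z <= -1.0:
        return 100.0 * (1.0 - 1.0 / (z * z))
    return 0.0


def assess_unit(
    structure: Structure,
    unit,
    table: PropensityTable,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = 0,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> EnergyAssessment:
    """Energy, decoy statistics, Z-score and AUL for one substructure.

    Degenerate units (zero decoy spread) carry no Z-score or AUL — both are
    reported as None ("n/a"), never as 0, to keep "no signal" distinct from
    "not native-like".
    """
    energy = pseudo_energy(structure, unit, table, distance_cutoff, min_separation)
    stats = decoy_distribution(
        structure, unit, table, n_decoys, seed, distance_cutoff, min_separation
    )
    if stats.degenerate:
        return EnergyAssessment(
            pseudo_energy=energy,
            decoy_mean=stats.mean,
            decoy_sd=0.0,
            z_score=None,
            aul_percent=None,
            degenerate=True,
            n_decoys=n_decoys,
            seed=seed,
        )
    z = z_score(energy, stats.mean, stats.sd)
    return EnergyAssessment(
        pseudo_energy=energy,
        decoy_mean=stats.mean,
        decoy_sd=stats.sd,
        z_score=z,
        aul_percent=aul_from_zscore(z),
        degenerate=False,
        n_decoys=n_decoys,
        seed=seed,
    )
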