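"""End-to-end pipeline: structure -> contact map -> peeling -> assembly ->
energy assessment, plus serialization of the full result bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .assembly import PartitionSet, build_partition_set
from .contact_map import (
    ContactMap,
    compute_contact_map,
    write_dense,
    write_sparse,
)
from .peeling import PI_FORM, PeelingTree, peel
from .pseudo_energy import (
    DEFAULT_N_DECOYS,
    EnergyAssessment,
    assess_unit,
    load_propensity_table,
)
from .ss_annotation import SecondaryStructure, assign_ss_from_ca, parse_dssp
from .structure_io import Structure, load_structure

logger = logging.getLogger(__name__)

ALL_FORMATS = ("json", "summary", "tsv", "contact_map")


@dataclass
class RunConfig:
    input_path: str | None = None
    chain: str = "A"
    model_index: int = 0
    dssp_path: str | None = None
    d0: float = 8.0
    delta: float = 1.5
    min_sequence_separation: int = 0
    min_pu_size: int = 15
    max_pus: int = 16
    max_cuts: int = 2
    max_coupling: float = 0.05
    beam_width: int = 3
    n_decoys: int = DEFAULT_N_DECOYS
    seed: int = 0
    include_pu_extremities: bool = True
    propensity_table: str | None = None

    def __post_init__(self):
        for name in ("d0", "delta", "min_pu_size", "max_pus", "max_cuts",
                     "beam_width", "n_decoys"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ResultBundle:
    config: RunConfig
    structure: Structure
    secondary_structure: SecondaryStructure
    contact_map: ContactMap
    peeling_tree: PeelingTree
    partition_set: PartitionSet
    pu_assessments: list[tuple[tuple[int, int], EnergyAssessment]]
    domain_assessments: list[tuple[tuple[tuple[int, int], ...], EnergyAssessment]]

    def to_dict(self) -> dict:
        return _bundle_to_dict(self)


def _unit_seed(root_seed: int, key: tuple[int, ...]) -> int:
    """Stable per-unit decoy seed derived from the run seed."""
    h = root_seed & 0x7FFFFFFF
    for k in key:
        h = (h * 1000003 + k) & 0x7FFFFFFF
    return h


def run_pipeline(config: RunConfig, structure: Structure | None = None) -> ResultBundle:
    """Execute every stage on one structure; deterministic given the config.

    ``structure`` may be supplied directly (e.g. a synthetic fixture);
    otherwise it is loaded and cleaned from ``config.input_path``.
    """
    if structure is None:
        if config.input_path is None:
            raise ValueError("either a structure or config.input_path is required")
        structure = load_structure(
            config.input_path, chain=config.chain, model_index=config.model_index
        )
    logger.info("[structure] %s: %d residues", structure.source_label, len(structure))

    if config.dssp_path:
        ss = parse_dssp(config.dssp_path, structure.chain_id, structure)
    else:
        ss = assign_ss_from_ca(structure)
    logger.info("[ss] method=%s", ss.method)

    cm = compute_contact_map(
        structure,
        d0=config.d0,
        delta=config.delta,
        min_sequence_separation=config.min_sequence_separation,
    )
    tree = peel(
        cm,
        min_pu_size=config.min_pu_size,
        max_pus=config.max_pus,
        max_cuts=config.max_cuts,
        max_coupling=config.max_coupling,
    )
    logger.info("[peeling] %d levels, %d terminal PUs",
                len(tree.levels), len(tree.terminal_pus))

    pset = build_partition_set(
        cm,
        tree.terminal_pus,
        beam_width=config.beam_width,
        include_pu_extremities=config.include_pu_extremities,
    )
    logger.info("[assembly] %d acceptable partitions, optimal has %d domains, "
                "A-index %d", len(pset.partitions),
                pset.optimal.n_domains, pset.a_index)

    table = load_propensity_table(config.propensity_table)
    pu_assessments = []
    for pu in tree.terminal_pus:
        unit = frozenset(range(pu.start, pu.end + 1))
        seed = _unit_seed(config.seed, (pu.start, pu.end))
        pu_assessments.append(
            ((pu.start, pu.end),
             assess_unit(structure, unit, table, config.n_decoys, seed))
        )

    seen_domains = {}
    for p in pset.partitions:
        for d in p.domains:
            segs = tuple(d.segments())
            if segs not in seen_domains:
                seed = _unit_seed(config.seed, tuple(x for s in segs for x in s))
                seen_domains[segs] = assess_unit(
                    structure, d.residue_set, table, config.n_decoys, seed
                )
    domain_assessments = sorted(seen_domains.items())

    return ResultBundle(
        config=config,
        structure=structure,
        secondary_structure=ss,
        contact_map=cm,
        peeling_tree=tree,
        partition_set=pset,
        pu_assessments=pu_assessments,
        domain_assessments=domain_assessments,
    )


def _fmt_assessment(a: EnergyAssessment) -> dict:
    return {
        "pseudo_energy": round(a.pseudo_energy, 6),
        "decoy_mean": round(a.decoy_mean, 6),
        "decoy_sd": round(a.decoy_sd, 6),
        "z_score": None if a.z_score is None else round(a.z_score, 4),
        "aul_percent": None if a.aul_percent is None else int(round(a.aul_percent)),
        "degenerate": a.degenerate,
        "n_decoys": a.n_decoys,
        "seed": a.seed,
    }


def _segments_both_numberings(structure: Structure, segments) -> list[dict]:
    out = []
    for s, e in segments:
        os, oe = structure.original_range(s, e)
        out.append({"start": s, "end": e, "orig_start": os, "orig_end": oe})
    return out


def _bundle_to_dict(bundle: ResultBundle) -> dict:
    structure = bundle.structure
    pset = bundle.partition_set
    cfg = asdict(bundle.config)

    partitions = []
    for idx, p in enumerate(pset.partitions):
        partitions.append({
            "n_domains": p.n_domains,
            "quality": p.quality,
            "is_acceptable": p.is_acceptable,
            "is_optimal": idx == pset.optimal_index,
            "separation_fraction": round(p.separation_fraction, 6),
            "min_compactness_ratio": round(p.min_compactness_ratio, 6),
            "domains": [
                {
                    "pu_members": sorted(d.pu_members),
                    "segments": _segments_both_numberings(structure, d.segments()),
                    "compactness": round(d.compactness, 6),
                }
                for d in p.domains
            ],
        })

    domain_freq = [
        {
            "segments": _segments_both_numberings(
                structure, _set_to_segments(residue_set)
            ),
            "count": count,
        }
        for residue_set, count in pset.domain_frequency
    ]

    return {
        "tool": {"name": "protpeel", "version": __version__},
        "config": cfg,
        "metadata": {
            "partition_index_form": PI_FORM,
            "contact_map_parameters": "artifact-chosen defaults (d0, delta)",
            "propensity_table": "synthetic hydrophobicity-derived surrogate"
            if bundle.config.propensity_table is None
            else bundle.config.propensity_table,
            "secondary_structure_method": bundle.secondary_structure.method,
        },
        "structure": {
            "source": structure.source_label,
            "chain": structure.chain_id,
            "n_residues": len(structure),
            "sequence": structure.sequence,
            "original_numbering": structure.original_numbering(),
        },
        "secondary_structure": {
            "states8": bundle.secondary_structure.states8,
            "states3": bundle.secondary_structure.states3,
        },
        "peeling": {
            "n_levels": len(bundle.peeling_tree.levels),
            "levels": [
                {
                    "level": lvl,
                    "pus": [
                        {
                            "start": pu.start,
                            "end": pu.end,
                            "orig_start": structure.original_range(pu.start, pu.end)[0],
                            "orig_end": structure.original_range(pu.start, pu.end)[1],
                            "compaction_index": round(pu.compaction_index, 6),
                        }
                        for pu in pus
                    ],
                }
                for lvl, pus in enumerate(bundle.peeling_tree.levels)
            ],
        },
        "partitions": partitions,
        "a_index": pset.a_index,
        "junctions": [
            {
                "position": j.position,
                "orig_position": structure.residues[j.position - 1].original_number,
                "count": j.count,
                "frequency": round(j.frequency, 6),
                "weight": round(j.weight, 6),
            }
            for j in pset.junctions
        ],
        "domain_frequency": domain_freq,
        "energy": {
            "protein_units": [
                {
                    "start": s, "end": e,
                    "orig_start": structure.original_range(s, e)[0],
                    "orig_end": structure.original_range(s, e)[1],
                    **_fmt_assessment(a),
                }
                for (s, e), a in bundle.pu_assessments
            ],
            "domains": [
                {
                    "segments": _segments_both_numberings(structure, segs),
                    **_fmt_assessment(a),
                }
                for segs, a in bundle.domain_assessments
            ],
        },
    }


def _set_to_segments(residue_set: frozenset) -> list[tuple[int, int]]:
    import itertools

    out = []
    for _, grp in itertools.groupby(
        enumerate(sorted(residue_set)), key=lambda t: t[1] - t[0]
    ):
        block = [g[1] for g in grp]
        out.append((block[0], block[-1]))
    return out


def validate_result_dict(data: dict) -> None:
    """Light structural validation of a serialized result bundle.

    Checks the presence and basic types of the versioned schema's required
    sections and that every partition is a disjoint exhaustive cover.
    """
    for key in ("tool", "config", "structure", "secondary_structure",
                "peeling", "partitions", "a_index", "junctions",
                "domain_frequency", "energy"):
        if key not in data:
            raise ValueError(f"results bundle missing section {key!r}")
    n = data["structure"]["n_residues"]
    for p in data["partitions"]:
        covered: set[int] = set()
        for d in p["domains"]:
            for seg in d["segments"]:
                block = set(range(seg["start"], seg["end"] + 1))
                if covered & block:
                    raise ValueError("partition domains overlap")
                covered |= block
        if covered != set(range(1, n + 1)):
            raise ValueError("partition does not cover 1..N")


def write_outputs(
    bundle: ResultBundle,
    out_dir: str | Path,
    formats=ALL_FORMATS,
) -> list[Path]:
    """Serialize a bundle; returns the manifest of written files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise NotADirectoryError(out_dir)
    data = bundle.to_dict()
    validate_result_dict(data)
    manifest: list[Path] = []

    if "json" in formats:
        path = out_dir / "results.json"
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        manifest.append(path)

    if "summary" in formats:
        manifest.append(_write_summary(data, out_dir / "summary.txt"))

    if "tsv" in formats:
        manifest.append(_write_pus_tsv(data, out_dir / "pus.tsv"))
        manifest.append(_write_junctions_tsv(data, out_dir / "junctions.tsv"))
        manifest.append(
            _write_domain_frequency_tsv(data, out_dir / "domain_frequency.tsv")
        )

    if "contact_map" in formats:
        manifest.append(write_dense(bundle.contact_map, out_dir / "contact_map.txt"))
        manifest.append(write_sparse(bundle.contact_map, out_dir / "contact_map.tsv"))

    return manifest


def _fmt_partition(p: dict) -> str:
    doms = "; ".join(
        ",".join(f"{s['orig_start']}-{s['orig_end']}" for s in d["segments"])
        for d in p["domains"]
    )
    tag = " (optimal)" if p["is_optimal"] else ""
    return f"{p['n_domains']} domains, quality {p['quality']}{tag}: {doms}"


def _write_summary(data: dict, path: Path) -> Path:
    lines = [
        f"protpeel {data['tool']['version']} — {data['structure']['source']} "
        f"chain {data['structure']['chain']} ({data['structure']['n_residues']} residues)",
        f"A-index: {data['a_index']}",
        "",
        "Domain partitions (optimal first, then by ascending number of domains):",
    ]
    ordered = [p for p in data["partitions"] if p["is_optimal"]] + [
        p for p in data["partitions"] if not p["is_optimal"]
    ]
    for p in ordered:
        lines.append("  " + _fmt_partition(p))
    lines.append("")
    lines.append("Terminal protein units:")
    for pu in data["peeling"]["levels"][-1]["pus"]:
        lines.append(
            f"  {pu['orig_start']}-{pu['orig_end']} (CI {pu['compaction_index']:.3f})"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _write_pus_tsv(data: dict, path: Path) -> Path:
    rows = ["level\tpu_index\tstart\tend\torig_start\torig_end\tcompaction_index"]
    for level in data["peeling"]["levels"]:
        for i, pu in enumerate(level["pus"], start=1):
            rows.append(
                f"{level['level']}\t{i}\t{pu['start']}\t{pu['end']}\t"
                f"{pu['orig_start']}\t{pu['orig_end']}\t{pu['compaction_index']:.6f}"
            )
    path.write_text("\n".join(rows) + "\n")
    return path


def _write_junctions_tsv(data: dict, path: Path) -> Path:
    rows = ["position\torig_position\tcount\tfrequency\tweight"]
    for j in data["junctions"]:
        rows.append(
            f"{j['position']}\t{j['orig_position']}\t{j['count']}\t"
            f"{j['frequency']:.6f}\t{j['weight']:.6f}"
        )
    path.write_text("\n".join(rows) + "\n")
    return path


def _write_domain_frequency_tsv(data: dict, path: Path) -> Path:
    rows = ["domain_segments\tcount"]
    for d in data["domain_frequency"]:
        segs = ",".join(f"{s['orig_start']}-{s['orig_end']}" for s in d["segments"])
        rows.append(f"{segs}\t{d['count']}")
    path.write_text("\n".join(rows) + "\n")
    return path
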