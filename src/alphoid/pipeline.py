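"""End-to-end pipeline: segment -> classify -> consensus -> HOR -> SF -> insertion -> tree."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .consensus import align_monomers, build_consensus
from .core import AnnotationRecord, ConsensusSet, SatArray
from .families import assign_array_sf, assign_monomer_sf
from .hor import HORParams, call_hor, periodicity_profile
from .insertions import characterize_insertion, detect_long_monomers
from .io import load_builtin_consensuses, read_fasta, write_annotations, write_fasta
from .motifs import classify_ab
from .phylo import DistanceMatrix, nj_tree
from .segmentation import SegmentationParams, normalize_orientation, segment_monomers

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ref: str = "GGO_consensus"
    bref: str = "GGO_consensus_Btype"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    hor: HORParams = field(default_factory=HORParams)
    sf_majority: float = 0.8
    require_order: bool = False
    long_monomer_min_len: int = 180
    build_tree: bool = False
    tree_max_leaves: int = 500
    seed: int = 0
    float_precision: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg_raw = raw.pop("segmentation", {})
        if "align" in seg_raw:
            from .core import AlignParams

            seg_raw["align"] = AlignParams(**seg_raw["align"])
        seg = SegmentationParams(**seg_raw)
        hor = HORParams(**raw.pop("hor", {}))
        return cls(segmentation=seg, hor=hor, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _round(x: float | None, digits: int) -> float | None:
    return None if x is None else round(float(x), digits)


def process_array(
    array: SatArray, cset: ConsensusSet, config: PipelineConfig
) -> tuple[dict, list[AnnotationRecord], list]:
    """All per-array analyses; returns (report, monomer annotations, monomers)."""
    p = config.float_precision
    ref = cset[config.ref]
    try:
        oriented = normalize_orientation(array, ref)
    except ValueError as exc:
        return {"array_id": array.id, "error": str(exc)}, [], []
    monomers = segment_monomers(oriented, ref, config.segmentation)
    full = [m for m in monomers if not m.partial]
    records = [
        AnnotationRecord(
            array_id=array.id, start=m.start, end=m.end,
            label="partial_monomer" if m.partial else "monomer",
            score=0.0,
            strand="-" if oriented.orientation == "reverse-complemented" else "+",
        )
        for m in monomers
    ]
    calls = [classify_ab(m, cset) for m in full]
    classification = [
        {
            "monomer_id": m.id, "ab_type": c.ab_type,
            "dist_A": _round(c.dist_A, p), "dist_B": _round(c.dist_B, p),
            "motif": c.prd.motif if c.prd else None,
            "offset": c.prd.offset if c.prd else None,
            "mismatches": c.prd.mismatches if c.prd else None,
            "core_intact": c.prd.core_intact if c.prd else None,
            "full_intact": c.prd.full_intact if c.prd else None,
        }
        for m, c in zip(full, calls)
    ]
    report: dict = {
        "array_id": array.id,
        "orientation": oriented.orientation,
        "n_monomers": len(full),
        "n_partial": len(monomers) - len(full),
        "classification": classification,
    }
    if len(full) >= 4:
        profile = periodicity_profile(full)
        hor = call_hor(profile, config.hor)
        assignments = [assign_monomer_sf(m, cset) for m in full]
        sf = assign_array_sf(
            assignments, hor, cset, config.sf_majority, config.require_order, array.id
        )
        report["hor"] = {
            "period": hor.period, "label": hor.label,
            "d_at_period": _round(hor.d_at_period, p), "n_units": hor.n_units,
        }
        report["sf"] = {
            "sf": sf.sf, "order_match": sf.order_match,
            "per_monomer": [(n, _round(d, p)) for n, d in sf.per_monomer],
        }
    else:
        report["hor"] = {"period": None, "label": "monomeric",
                         "d_at_period": None, "n_units": 0}
        report["sf"] = {"sf": "unassigned", "order_match": False, "per_monomer": []}
    long_monomers = detect_long_monomers(full, config.long_monomer_min_len)
    report["insertions"] = [
        dataclasses.asdict(characterize_insertion(m, cset[config.bref]))
        for m in long_monomers
    ]
    return report, records, full


def run_pipeline(
    fasta: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    cset: ConsensusSet | None = None,
) -> dict:
    """Run every stage over a FASTA of arrays; optionally write artifacts."""
    config = config or PipelineConfig()
    cset = cset or load_builtin_consensuses()
    arrays = read_fasta(fasta)
    if not arrays:
        log.warning("%s: empty FASTA, nothing to do", fasta)
    reports = []
    all_records: list[AnnotationRecord] = []
    all_monomers = []
    for array in arrays:
        report, records, monomers = process_array(array, cset, config)
        if "error" in report:
            log.error("array %s failed: %s", report["array_id"], report["error"])
        reports.append(report)
        all_records.extend(records)
        all_monomers.extend(monomers)
    result: dict = {"n_arrays": len(arrays), "arrays": reports}

    # one consensus per detected family with >= 2 member monomers
    family_monomers: dict[str, list] = {}
    for report, _ in zip(reports, arrays):
        sf = report.get("sf", {}).get("sf")
        if sf in ("SF1", "SF2", "SF3"):
            ids = {c["monomer_id"] for c in report["classification"]}
            family_monomers.setdefault(sf, []).extend(
                m for m in all_monomers if m.id in ids
            )
    consensuses = {}
    ref = cset[config.ref]
    for sf, members in sorted(family_monomers.items()):
        if len(members) >= 2:
            entry = build_consensus(align_monomers(members, ref), name=f"{sf}_consensus")
            consensuses[sf] = entry.sequence
    result["family_consensuses"] = consensuses

    if config.build_tree and len(all_monomers) >= 3:
        leaves = all_monomers[: config.tree_max_leaves]
        dm = DistanceMatrix.from_sequences(
            [m.id for m in leaves], [m.sequence for m in leaves]
        )
        result["tree_newick"] = nj_tree(dm).newick()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        write_annotations(all_records, out / "monomers.bed", "BED")
        write_annotations(all_records, out / "monomers.gff3", "GFF3")
        if all_monomers:
            write_fasta(
                [SatArray(m.id, m.sequence) for m in all_monomers],
                out / "monomers.fasta",
            )
        (out / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result
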