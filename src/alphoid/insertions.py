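"""Extra-long (~189 bp) monomers and their tandem-duplication insertion.

The extra-long monomer arose by a duplication that interrupted the CENP-B
box, copied ~22 bp upstream (the unfinished box plus nine more bases) and
so regenerated a complete, fully conserved box; a 4-bp deletion nearby
leaves a net 18-bp length gain.  This parameterization is degenerate with
a shorter perfect duplication plus spacer — the report notes both
readings.  The insertion may be present in one, two or three tandem
copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from .align import DEFAULT_PARAMS, align_pair
from .core import AlignParams, ConsensusEntry, Monomer
from .motifs import CENPB, MotifSpec, score_core

log = logging.getLogger(__name__)


@dataclass
class InsertionReport:
    monomer_id: str
    monomer_length: int
    net_insertion: int
    dup_unit_len: int
    dup_unit_seq: str
    copies: int
    box_break_pos: int | None  # 1-based on the 17-mer pattern, first divergence
    regenerated_box_core_intact: bool
    notes: str = ""


def detect_long_monomers(monomers: list[Monomer], min_len: int = 180) -> list[Monomer]:
    """Non-partial monomers at least ``min_len`` bases long."""
    return [m for m in monomers if not m.partial and m.length >= min_len]


def _insertion_runs(ref_row: str, mon_row: str) -> tuple[list[tuple[int, int]], int]:
    """Monomer-coordinate intervals inserted relative to the reference, and
    the count of reference bases deleted."""
    runs: list[tuple[int, int]] = []
    deleted = 0
    pos = 0  # position in monomer coordinates
    start = None
    for rc, mc in zip(ref_row, mon_row):
        if rc == "-":
            if start is None:
                start = pos
            pos += 1
        else:
            if start is not None:
                runs.append((start, pos))
                start = None
            if mc == "-":
                deleted += 1
            else:
                pos += 1
    if start is not None:
        runs.append((start, pos))
    return runs, deleted


def _tandem_chain(window: str, net: int, max_copy_edits: int,
                  min_unit: int = 14, max_unit: int = 30):
    """Longest chain of consecutive near-identical unit blocks in a window.

    Alignment gap placement inside a tandem repeat is ambiguous, so the
    duplication unit is recovered by direct phase search: for each unit
    length and phase, consecutive blocks are chained while adjacent blocks
    stay within ``max_copy_edits`` edits.  Returns (chain, unit_len, unit
    start offset, unit sequence) of the best chain, preferring longer
    chains, then chains whose implied insertion length matches ``net``.
    """
    best_key = None
    best_result = None
    n = len(window)
    for unit in range(min_unit, max_unit + 1):
        for phase in range(unit):
            starts = list(range(phase, n - unit + 1, unit))
            if len(starts) < 2:
                continue
            chain, run_start, edits = 1, 0, 0
            runs = []
            for idx in range(len(starts) - 1):
                a = window[starts[idx] : starts[idx] + unit]
                b = window[starts[idx + 1] : starts[idx + 1] + unit]
                d = edlib.align(a, b, mode="NW", k=max_copy_edits)["editDistance"]
                if d != -1:
                    chain += 1
                    edits += d
                else:
                    runs.append((chain, -edits, run_start))
                    chain, run_start, edits = 1, idx + 1, 0
            runs.append((chain, -edits, run_start))
            chain, neg_edits, run_start = max(runs)
            if chain < 2:
                continue
            # prefer the longest chain, then the cleanest copies, then the
            # longest unit (the duplication reading over shorter rotations)
            key = (chain, neg_edits, unit)
            if best_key is None or key > best_key:
                best_key = key
                unit_seq = window[starts[run_start + 1] : starts[run_start + 1] + unit]
                best_result = (chain, unit, starts[run_start], unit_seq)
    return best_result


def _prefix_break(window: str, spec: MotifSpec) -> int | None:
    """Longest pattern-prefix match ending anywhere in ``window``; returns the
    1-based pattern position of the first divergence (17-mer coordinates)."""
    best = 0
    for s in range(len(window)):
        run = 0
        for base, allowed in zip(window[s:], spec.pattern):
            if base in allowed:
                run += 1
            else:
                break
        best = max(best, run)
    if best == 0:
        return None
    return min(best + 1, 17)


def characterize_insertion(
    monomer: Monomer | str,
    bref: ConsensusEntry,
    spec: MotifSpec = CENPB,
    params: AlignParams = DEFAULT_PARAMS,
    max_copy_edits: int = 4,
) -> InsertionReport:
    """Align an extra-long monomer to the B-type reference and characterize
    the inserted block as a tandem duplication of the immediately upstream
    segment (allowing ``max_copy_edits`` edits per copy)."""
    seq = monomer.sequence if isinstance(monomer, Monomer) else monomer
    mon_id = monomer.id if isinstance(monomer, Monomer) else "monomer"
    # degenerate reference symbols match their expansion bases in the aligner
    ref_row, mon_row, _ = align_pair(bref.sequence, seq, params)
    runs, deleted = _insertion_runs(ref_row, mon_row)
    inserted = sum(e - s for s, e in runs)
    net = inserted - deleted
    if net < 10:
        log.warning("monomer %s: no insertion found (net gain %d < 10)", mon_id, net)
        return InsertionReport(
            monomer_id=mon_id, monomer_length=len(seq), net_insertion=net,
            dup_unit_len=0, dup_unit_seq="", copies=0, box_break_pos=None,
            regenerated_box_core_intact=False, notes="no insertion",
        )
    big_runs = [r for r in runs if r[1] - r[0] >= 4] or runs
    lo = max(0, min(s for s, _ in big_runs) - 30)
    hi = min(len(seq), max(e for _, e in big_runs) + 30)
    found = _tandem_chain(seq[lo:hi], net, max_copy_edits)
    if found is None:
        copies, unit_len, unit_seq = 1, net, ""
        last_copy_end = max(e for _, e in big_runs)
        notes = "insertion not recognized as a tandem duplication; "
    else:
        chain, unit_len, chain_off, unit_seq = found
        copies = chain - 1
        last_copy_end = lo + chain_off + chain * unit_len
        notes = ""
    notes += (
        f"duplication unit {unit_len} bp x{copies} with nearby deletion; "
        f"net gain {net} bp (equivalently a {net}-bp perfect duplication "
        "separated by a short spacer)"
    )
    # where the upstream (interrupted) box copy diverges from the 17-mer
    first_copy_end = last_copy_end - copies * unit_len
    box_break = _prefix_break(seq[max(0, first_copy_end - 30) : first_copy_end], spec)
    # a core-intact box whose completion lies beyond the last inserted copy
    regenerated = False
    scan_from = max(0, last_copy_end - unit_len)
    tail = seq[scan_from:]
    for offset in range(max(0, len(tail) - 16)):
        if scan_from + offset + 17 <= last_copy_end:
            continue  # box fully inside the duplication; not the regenerated one
        core, _ = score_core(tail[offset : offset + 17], spec)
        if core:
            regenerated = True
            break
    return InsertionReport(
        monomer_id=mon_id, monomer_length=len(seq), net_insertion=net,
        dup_unit_len=unit_len, dup_unit_seq=unit_seq, copies=copies,
        box_break_pos=box_break, regenerated_box_core_intact=regenerated,
        notes=notes,
    )
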