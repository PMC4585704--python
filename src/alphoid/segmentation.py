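"""Orientation normalization and monomer segmentation.

An array is partitioned into head-to-tail monomers by a dynamic program
that tiles the array with copies of a reference consensus, minimizing the
total edit distance of the intervals to the reference.  Degenerate
reference symbols match any base of their expansion at no cost; gap-code
symbols (F/I/J, plus the -/T symbol) are optional — they match their base
or are skipped for free.  The DP is exact, deterministic, and recovers
unit boundaries exactly on noise-free tandem input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alphabet import expansion, is_optional, revcomp
from .align import DEFAULT_PARAMS, local_score
from .core import AlignParams, ConsensusEntry, Monomer, SatArray

log = logging.getLogger(__name__)

#: minimum acceptable local-alignment score of the reference against an array
MIN_ALPHOID_SCORE = 50.0


@dataclass
class SegmentationParams:
    align: AlignParams = field(default_factory=AlignParams)
    min_len: int = 140
    max_len: int = 220
    min_flank_keep: int = 100


def detect_orientation(
    array: SatArray,
    ref: ConsensusEntry,
    params: AlignParams = DEFAULT_PARAMS,
) -> str:
    """Return "forward" or "reverse" by comparing local-alignment scores of
    the reference on both strands; below a floor on both, the array carries
    no alphoid signal."""
    fwd = local_score(ref.sequence, array.sequence, params)
    rev = local_score(ref.sequence, revcomp(array.sequence), params)
    if max(fwd, rev) < MIN_ALPHOID_SCORE:
        raise ValueError(
            f"array {array.id!r}: no alphoid signal "
            f"(best local score {max(fwd, rev):.0f} < {MIN_ALPHOID_SCORE:.0f})"
        )
    return "forward" if fwd >= rev else "reverse"


def normalize_orientation(array: SatArray, ref: ConsensusEntry) -> SatArray:
    """Reverse-complement the array if the reference matches the minus strand."""
    strand = detect_orientation(array, ref)
    if strand == "forward":
        return SatArray(array.id, array.sequence, orientation="forward")
    return SatArray(array.id, revcomp(array.sequence), orientation="reverse-complemented")


def estimate_period(
    array: SatArray, min_len: int = 140, max_len: int = 220
) -> int:
    """Dominant tandem period in [min_len, max_len] via shift autocorrelation.

    For each lag k the fraction of positions with array[i] == array[i+k] is
    computed; the argmax is the period.  On noise-free tandem input this is
    exact.  A maximum below 0.5 (random sequence gives ~0.25) means no
    tandem periodicity in range.
    """
    seq = np.frombuffer(array.sequence.encode(), dtype=np.uint8)
    n = len(seq)
    if n < 2 * min_len:
        raise ValueError(f"array {array.id!r}: too short to estimate a period")
    best_k, best_f = 0, -1.0
    for k in range(min_len, min(max_len, n - 1) + 1):
        f = float(np.mean(seq[:-k] == seq[k:]))
        if f > best_f + 1e-12:
            best_k, best_f = k, f
    if best_f < 0.5:
        raise ValueError(
            f"array {array.id!r}: non-tandem (best autocorrelation "
            f"{best_f:.2f} at lag {best_k})"
        )
    return best_k


# ---------------------------------------------------------------------------
# tiling DP

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@njit(cache=True)
def _tile_dp(arr: np.ndarray, sub: np.ndarray, dele: np.ndarray):  # pragma: no cover
    """Fill the tiling DP matrix.

    State M[i, j]: minimal cost of explaining array[:j] by complete monomers
    plus a current partial monomer that has consumed i reference positions.
    Monomer boundaries are free transitions from i == m to i == 0.  The
    first monomer may start mid-reference (free at j == 0) and the last may
    end mid-reference (min over i at j == n).
    """
    n = arr.shape[0]
    m = sub.shape[0]
    M = np.empty((m + 1, n + 1), dtype=np.int32)
    for i in range(m + 1):
        M[i, 0] = 0
    for j in range(1, n + 1):
        b = arr[j - 1]
        M[0, j] = M[0, j - 1] + 1  # insertion before consuming any reference
        for i in range(1, m + 1):
            best = M[i, j - 1] + 1  # insertion
            diag = M[i - 1, j - 1] + sub[i - 1, b]
            if diag < best:
                best = diag
            M[i, j] = best
        for i in range(1, m + 1):  # deletions within the column
            v = M[i - 1, j] + dele[i - 1]
            if v < M[i, j]:
                M[i, j] = v
        if M[m, j] < M[0, j]:  # monomer boundary, free
            M[0, j] = M[m, j]
            for i in range(1, m + 1):  # deletions into the fresh monomer
                v = M[i - 1, j] + dele[i - 1]
                if v < M[i, j]:
                    M[i, j] = v
    return M


def _ref_costs(ref: str) -> tuple[np.ndarray, np.ndarray]:
    m = len(ref)
    sub = np.ones((m, 5), dtype=np.int32)
    dele = np.ones(m, dtype=np.int32)
    for i, symbol in enumerate(ref):
        for base in expansion(symbol):
            sub[i, _BASE_INDEX[base]] = 0
        sub[i, 4] = 0  # N matches anything at no cost
        if is_optional(symbol):
            dele[i] = 0
    return sub, dele


def _traceback(M: np.ndarray, arr: np.ndarray, sub: np.ndarray, dele: np.ndarray):
    """Recover monomer boundaries and the ref offsets at both array ends."""
    m = M.shape[0] - 1
    n = M.shape[1] - 1
    # deepest reference offset achieving the optimum: a complete last monomer
    # traces back from i == m, not from the equally-scored fresh i == 0 state
    i = m - int(np.argmin(M[::-1, n]))
    end_ref_offset = i
    j = n
    boundaries = []  # array positions where a monomer starts (descending)
    while j > 0:
        v = M[i, j]
        if i == 0 and v == M[m, j]:
            boundaries.append(j)
            i = m
            continue
        if i > 0 and j > 0 and v == M[i - 1, j - 1] + sub[i - 1, arr[j - 1]]:
            i -= 1
            j -= 1
            continue
        if i > 0 and v == M[i - 1, j] + dele[i - 1]:
            i -= 1
            continue
        # insertion
        j -= 1
    start_ref_offset = i
    return boundaries[::-1], start_ref_offset, end_ref_offset, float(M[:, n].min())


def segment_monomers(
    array: SatArray,
    ref: ConsensusEntry,
    params: SegmentationParams | None = None,
) -> list[Monomer]:
    """Partition a forward-normalized array into consecutive monomers.

    The returned monomers tile the array without gaps or overlaps except for
    clipped flanks: a flank (first/last interval that covers only part of
    the reference) shorter than ``min_flank_keep`` is dropped; longer flanks
    are emitted with ``partial=True``.
    """
    params = params or SegmentationParams()
    seq = array.sequence
    n = len(seq)
    if n < params.min_len:
        log.warning("array %s: shorter than min_len, no monomers", array.id)
        return []
    arr = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    sub, dele = _ref_costs(ref.sequence)
    M = _tile_dp(arr, sub, dele)
    boundaries, start_off, end_off, _ = _traceback(M, arr, sub, dele)
    cuts = [0] + boundaries + [n]
    cuts = sorted(set(cuts))
    monomers: list[Monomer] = []
    index = 0
    for k, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
        first = k == 0
        last = k == len(cuts) - 2
        partial = (first and start_off > 0) or (last and end_off < len(ref.sequence))
        length = e - s
        if not partial and not (params.min_len <= length <= params.max_len):
            partial = True  # out-of-range interval; treat as clipped
        if partial and length < params.min_flank_keep:
            log.debug("array %s: dropping %d bp flank at %d", array.id, length, s)
            continue
        monomers.append(
            Monomer(
                array_id=array.id,
                index=index,
                start=s,
                end=e,
                sequence=seq[s:e],
                partial=partial,
            )
        )
        index += 1
    return monomers
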