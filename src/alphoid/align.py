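"""Pairwise alignment on the extended alphabet.

All alignments in the package use bl2seq-style scoring (+1 match, -2
mismatch, gap open 5 / extend 2, i.e. a gap of length L costs 5 + 2L) via
``Bio.Align.PairwiseAligner``.  A degenerate consensus symbol scores as a
match against any base of its expansion; gap-code symbols score as their
base (their "optional" reading is honoured by the segmentation DP, which
owns its own cost model).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import expansion
from .core import AlignParams

DEFAULT_PARAMS = AlignParams()

_ALPHABET = "ACGTRYSWKMBDHVNFIJO"


def _matrix(params: AlignParams) -> substitution_matrices.Array:
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        ea = expansion(a)
        for b in _ALPHABET:
            mat[a, b] = (
                params.match_reward if ea & expansion(b) else params.mismatch_penalty
            )
    return mat


@lru_cache(maxsize=8)
def get_aligner(params: AlignParams = DEFAULT_PARAMS, mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _matrix(params)
    # gap of length L costs open + extend * L
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    a: str,
    b: str,
    params: AlignParams = DEFAULT_PARAMS,
    mode: str = "global",
) -> tuple[str, str, float]:
    """Align two sequences; returns the two gapped rows and the score.

    The first optimal alignment reported by the aligner is used, which is
    deterministic for fixed inputs.
    """
    aln = get_aligner(params, mode).align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def local_score(query: str, target: str, params: AlignParams = DEFAULT_PARAMS) -> float:
    """Best local alignment score of query against target."""
    return get_aligner(params, "local").score(query, target)
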