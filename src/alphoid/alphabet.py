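"""Extended nucleotide alphabet used by the alphoid consensus sequences.

Besides the concrete bases the consensus alphabet carries the standard IUPAC
degeneracy codes and three "gap codes" that encode a position which is either
absent or a fixed base (F = -/A, I = -/C, J = -/G).  The -/T case has no code
in the published set; ``GAP_T_SYMBOL`` ("O") is the package default for it.
"""

from __future__ import annotations

# IUPAC degeneracy codes (subset actually used by alphoid consensuses, plus
# the remaining standard ones so arbitrary IUPAC input does not crash).
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: gap codes: position is either the given base or absent entirely
GAP_CODES: dict[str, str] = {"F": "A", "I": "C", "J": "G"}

#: package default symbol for the -/T ambiguity (absent from the printed code
#: list); configurable where consensus sequences are built
GAP_T_SYMBOL = "O"

#: every symbol a ConsensusEntry may contain
CONSENSUS_ALPHABET = frozenset(IUPAC) | frozenset(GAP_CODES) | {GAP_T_SYMBOL}

#: symbols allowed in a SatArray
ARRAY_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def expansion(symbol: str) -> frozenset[str]:
    """Concrete bases a consensus symbol can stand for (gap not included)."""
    if symbol in IUPAC:
        return IUPAC[symbol]
    if symbol in GAP_CODES:
        return frozenset(GAP_CODES[symbol])
    if symbol == GAP_T_SYMBOL:
        return frozenset("T")
    raise ValueError(f"unknown alphabet symbol {symbol!r}")


def is_optional(symbol: str) -> bool:
    """True for gap codes, whose position may be skipped entirely."""
    return symbol in GAP_CODES or symbol == GAP_T_SYMBOL


def code_for(bases: frozenset[str] | set[str], with_gap: bool = False) -> str:
    """Inverse of :func:`expansion`: the (possibly degenerate) code covering
    exactly ``bases``; with ``with_gap`` the -/base gap codes are used.

    Returns "N" when no single code covers the set (the published alphabet has
    no gap code for multi-base sets).
    """
    bases = frozenset(bases)
    if with_gap:
        for sym, base in GAP_CODES.items():
            if bases == frozenset(base):
                return sym
        if bases == frozenset("T"):
            return GAP_T_SYMBOL
        return "N"
    for sym, exp in IUPAC.items():
        if exp == bases:
            return sym
    return "N"


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]
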