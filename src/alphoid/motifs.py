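"""Protein-recognition domains and A/B monomer typing.

Two 17-bp protein-recognition domains (PRDs) occur in alphoid monomers:
the pJ-alpha motif CTAPyGGTGPuAAAAGGAA of A-type monomers and the CENP-B
box PyTTCGTTGGAAPuCGGGA of B-type monomers (Py = C/T, Pu = A/G).  Each
motif carries a set of "core" positions essential for protein binding.
Monomers are typed A or B by p-distance to the published A- and B-type
consensus sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import IUPAC
from .core import ConsensusSet, Monomer
from .phylo import pairwise_p_distance

_DEGENERATE = {"Py": frozenset("CT"), "Pu": frozenset("AG")}


def _parse_pattern(text: str) -> tuple[frozenset[str], ...]:
    """Parse a pattern written with Py/Pu shorthand into per-position base sets."""
    out = []
    i = 0
    while i < len(text):
        if text[i : i + 2] in _DEGENERATE:
            out.append(_DEGENERATE[text[i : i + 2]])
            i += 2
        else:
            out.append(IUPAC[text[i]])
            i += 1
    return tuple(out)


@dataclass(frozen=True)
class MotifSpec:
    kind: str  # "pJalpha" | "cenpb"
    pattern: tuple[frozenset[str], ...]
    core_positions: frozenset[int]  # 1-based positions within the 17-mer
    max_mismatch_call: int = 5

    def __post_init__(self) -> None:
        if len(self.pattern) != 17:
            raise ValueError("PRD patterns are 17 positions long")
        if not self.core_positions <= frozenset(range(1, 18)):
            raise ValueError("core positions must lie in 1..17")

    def mismatches(self, window: str) -> int:
        return sum(
            1 for base, allowed in zip(window, self.pattern) if base not in allowed
        )


#: CENP-B core default: the nine invariant TTCG..A..CGGG nucleotides of the
#: 17-mer.  The published account cites nine essential positions without
#: listing them; this standard reading is overridable per MotifSpec.
CENPB_CORE = frozenset({2, 3, 4, 5, 10, 13, 14, 15, 16})

PJALPHA = MotifSpec(
    kind="pJalpha",
    pattern=_parse_pattern("CTAPyGGTGPuAAAAGGAA"),
    # no published core for pJ-alpha: default to all non-degenerate positions
    core_positions=frozenset(range(1, 18)) - {4, 9},
)
CENPB = MotifSpec(
    kind="cenpb",
    pattern=_parse_pattern("PyTTCGTTGGAAPuCGGGA"),
    core_positions=CENPB_CORE,
)

DEFAULT_SPECS = (PJALPHA, CENPB)


@dataclass
class PRDHit:
    motif: str
    offset: int  # 0-based start within the monomer
    mismatches: int
    core_intact: bool
    full_intact: bool


def scan_prd(
    monomer: Monomer | str, specs: tuple[MotifSpec, ...] = DEFAULT_SPECS
) -> PRDHit | None:
    """Best PRD hit over both motifs, or None.

    Each 17-position degenerate pattern slides over the monomer (no scan
    across the monomer junction).  The hit with the fewest mismatches wins;
    ties between motifs go to the motif listed first (pJ-alpha); ties in
    offset go to the smallest offset.  No hit is reported if the best
    mismatch count exceeds ``max_mismatch_call``.
    """
    seq = monomer.sequence if isinstance(monomer, Monomer) else monomer
    if len(seq) < 17:
        return None
    best: tuple[int, int, int] | None = None  # (mismatches, spec_idx, offset)
    for spec_idx, spec in enumerate(specs):
        for offset in range(len(seq) - 16):
            mm = spec.mismatches(seq[offset : offset + 17])
            key = (mm, spec_idx, offset)
            if best is None or key < best:
                best = key
    mm, spec_idx, offset = best
    spec = specs[spec_idx]
    if mm > spec.max_mismatch_call:
        return None
    core, full = score_core(seq[offset : offset + 17], spec)
    return PRDHit(
        motif=spec.kind, offset=offset, mismatches=mm, core_intact=core, full_intact=full
    )


def score_core(window: str, spec: MotifSpec) -> tuple[bool, bool]:
    """(core_intact, full_intact) of a 17-bp window against a motif spec."""
    ok = [base in allowed for base, allowed in zip(window, spec.pattern)]
    full = all(ok)
    core = all(ok[p - 1] for p in sorted(spec.core_positions))
    return core, full


@dataclass
class MonomerCall:
    monomer: Monomer | str
    ab_type: str  # "A" | "B" | "undetermined"
    dist_A: float
    dist_B: float
    prd: PRDHit | None


def classify_ab(
    monomer: Monomer | str,
    cset: ConsensusSet,
    delta: float = 0.0,
    max_assign_dist: float = 0.40,
    specs: tuple[MotifSpec, ...] = DEFAULT_SPECS,
) -> MonomerCall:
    """Type a monomer A or B by p-distance to the two general A/B consensuses.

    The nearer consensus wins when it is closer by more than ``delta``;
    otherwise, or when both distances exceed ``max_assign_dist`` (the upper
    end of the published monomeric divergence range), the monomer is left
    undetermined.
    """
    seq = monomer.sequence if isinstance(monomer, Monomer) else monomer
    dist_a = pairwise_p_distance(seq, cset["GGO_consensus_Atype"].sequence)
    dist_b = pairwise_p_distance(seq, cset["GGO_consensus_Btype"].sequence)
    if min(dist_a, dist_b) > max_assign_dist:
        ab = "undetermined"
    elif dist_a + delta < dist_b:
        ab = "A"
    elif dist_b + delta < dist_a:
        ab = "B"
    else:
        ab = "undetermined"
    return MonomerCall(
        monomer=monomer, ab_type=ab, dist_A=dist_a, dist_B=dist_b,
        prd=scan_prd(seq, specs),
    )
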