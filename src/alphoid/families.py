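"""Suprachromosomal family (SF) assignment.

A monomer is assigned to its nearest family consensus by p-distance; an
array is assigned to an SF only when the evidence is concordant: the HOR
period equals the family's unit count and a clear majority of monomers
are nearest to that family's unit consensuses (optionally also requiring
the cyclic unit order to match the published succession).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import DEFAULT_PARAMS
from .core import AlignParams, ConsensusSet, Monomer
from .hor import HORCall
from .phylo import pairwise_p_distance

log = logging.getLogger(__name__)


@dataclass
class SFAssignment:
    array_id: str
    sf: str  # SF1 | SF2 | SF3 | monomeric | unassigned
    per_monomer: list[tuple[str, float]]
    order_match: bool


def assign_monomer_sf(
    monomer: Monomer | str,
    cset: ConsensusSet,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[str, float]:
    """Nearest family/monomeric consensus by p-distance.

    Ties go to the lexicographically smallest name (logged)."""
    seq = monomer.sequence if isinstance(monomer, Monomer) else monomer
    best_name, best_d = None, None
    tied = False
    for entry in sorted(cset.family_members(), key=lambda e: e.name):
        d = pairwise_p_distance(seq, entry.sequence, params)
        if best_d is None or d < best_d - 1e-12:
            best_name, best_d, tied = entry.name, d, False
        elif abs(d - best_d) <= 1e-12:
            tied = True
    if tied:
        log.warning("monomer tied between consensuses; kept %s", best_name)
    return best_name, best_d


def _cyclic_order_match(names: list[str], unit_order: tuple[str, ...]) -> bool:
    """True if the monomer succession follows the published unit order up to
    rotation (flanking truncation of the first/last unit allowed)."""
    k = len(unit_order)
    if not names:
        return False
    for rot in range(k):
        expected = [unit_order[(rot + i) % k] for i in range(len(names))]
        if names == expected:
            return True
    return False


def assign_array_sf(
    assignments: list[tuple[str, float]],
    hor: HORCall,
    cset: ConsensusSet,
    majority: float = 0.8,
    require_order: bool = False,
    array_id: str = "",
) -> SFAssignment:
    """Concordance rule: SF X iff the HOR period equals |units(X)| and at
    least ``majority`` of monomers are nearest to units of X.  Arrays whose
    HOR call is monomeric are monomeric; everything else is unassigned."""
    names = [n for n, _ in assignments]
    order_match = False
    sf = "unassigned"
    if hor.period is None or hor.label == "monomeric":
        sf = "monomeric"
    else:
        for family, units in cset.sf_units.items():
            if hor.period != len(units):
                continue
            share = sum(1 for n in names if n in units) / len(names)
            if share >= majority:
                sf = family
                order_match = _cyclic_order_match(names, units)
                break
        if sf != "unassigned" and require_order and not order_match:
            sf = "unassigned"
    return SFAssignment(
        array_id=array_id, sf=sf, per_monomer=list(assignments), order_match=order_match
    )
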