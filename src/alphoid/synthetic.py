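"""Synthetic satellite arrays with known ground truth.

Arrays are generated from the published consensus sequences: an SF array
is the family's HOR unit (consensus monomers in published succession)
tiled ``n_units`` times with i.i.d. substitutions; a monomeric array draws
each monomer from gM1 and mutates it at a per-monomer rate uniform in
[0.10, 0.40], emulating the 10-40% divergence of monomeric alphoid DNA.
HOR noise defaults mirror the published regimes: corresponding positions
of adjacent units diverge by <2%.

The SF2 unit contains the extra-long 189-bp monomer (gD1.4);
``insertion_copies`` = 2 or 3 tandem-duplicates its insertion further, as
observed in some assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP_CODES, GAP_T_SYMBOL, IUPAC, revcomp
from .core import ConsensusEntry, ConsensusSet, SatArray
from .io import load_builtin_consensuses
from .motifs import DEFAULT_SPECS, scan_prd

_BASES = "ACGT"


@dataclass
class SimParams:
    sf: str  # SF1 | SF2 | SF3 | monomeric
    n_units: int = 4
    sub_rate: float = 0.01
    indel_rate: float = 0.0
    insertion_copies: int = 1  # SF2 only: tandem copies of the gD1.4 insertion
    revcomp: bool = False
    protect_motifs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate <= 0.45 and 0 <= self.indel_rate <= 0.45):
            raise ValueError("mutation rates must lie in [0, 0.45]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.insertion_copies not in (1, 2, 3):
            raise ValueError("insertion_copies must be 1, 2 or 3")


@dataclass
class SyntheticTruth:
    array_id: str
    boundaries: list[tuple[int, int]]  # per monomer, forward coordinates
    sources: list[str]  # consensus name per monomer
    ab_labels: list[str]  # A | B | unspecified per monomer
    sf: str
    hor_period: int | None
    insertion_copies: int
    strand: str  # forward | reverse


def resolve_ambiguity(entry: ConsensusEntry, seed: int | np.random.Generator) -> str:
    """Replace each degenerate symbol by a uniform draw from its expansion;
    gap codes draw uniformly from {absent, base}.  Deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for symbol in entry.sequence:
        if symbol in "ACGT":
            out.append(symbol)
        elif symbol in IUPAC:
            out.append(rng.choice(sorted(IUPAC[symbol])))
        elif symbol in GAP_CODES:
            out.append(rng.choice(["", GAP_CODES[symbol]]))
        elif symbol == GAP_T_SYMBOL:
            out.append(rng.choice(["", "T"]))
        else:
            raise ValueError(f"unknown symbol {symbol!r} in {entry.name}")
    return "".join(out)


def _gd14_dup_unit(cset: ConsensusSet) -> tuple[int, str]:
    """Duplication unit of the extra-long monomer, derived by characterizing
    gD1.4 against gD1.0; returns (position of the inserted copy, unit)."""
    from .insertions import characterize_insertion  # local import avoids a cycle

    rep = characterize_insertion(cset["gD1.4"].sequence, cset["gD1.0"])
    idx = cset["gD1.4"].sequence.find(rep.dup_unit_seq)
    if rep.copies < 1 or idx < 0:
        raise RuntimeError("could not derive the gD1.4 duplication unit")
    return idx, rep.dup_unit_seq


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protected: frozenset[int] = frozenset()) -> str:
    if rate == 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        if int(i) in protected:
            continue
        out[i] = rng.choice([b for b in _BASES if b != seq[i]])
    return "".join(out)


def _indel(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    out = []
    for c in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(c)
        if rate / 2 <= r < rate:
            out.append(rng.choice(list(_BASES)))  # insertion after
    return "".join(out)


def simulate_array(
    params: SimParams, cset: ConsensusSet | None = None, array_id: str | None = None
) -> tuple[SatArray, SyntheticTruth]:
    """Generate one array plus its ground truth.

    Ambiguity codes are resolved once per array; truth boundaries refer to
    the forward orientation (the emitted sequence is reverse-complemented
    when ``revcomp`` is set, and the truth strand records it).
    """
    cset = cset or load_builtin_consensuses()
    rng = np.random.default_rng(params.seed)
    array_id = array_id or f"sim_{params.sf}_{params.seed}"

    monomer_seqs: list[str] = []
    sources: list[str] = []
    ab_labels: list[str] = []
    if params.sf == "monomeric":
        period = None
        for _ in range(params.n_units):
            base = resolve_ambiguity(cset["gM1"], rng)
            rate = rng.uniform(0.10, 0.40)
            monomer_seqs.append(_mutate(base, rate, rng))
            sources.append("gM1")
            ab_labels.append(cset["gM1"].unit_type)
    elif params.sf in cset.sf_units:
        units = cset.sf_units[params.sf]
        period = len(units)
        resolved = {n: resolve_ambiguity(cset[n], rng) for n in units}
        if params.sf == "SF2" and params.insertion_copies > 1:
            idx, unit = _gd14_dup_unit(cset)
            gd14 = resolved["gD1.4"]
            extra = unit * (params.insertion_copies - 1)
            resolved["gD1.4"] = gd14[:idx] + extra + gd14[idx:]
        for _ in range(params.n_units):
            for name in units:
                protected: frozenset[int] = frozenset()
                if params.protect_motifs:
                    hit = scan_prd(resolved[name], DEFAULT_SPECS)
                    if hit is not None:
                        protected = frozenset(range(hit.offset, hit.offset + 17))
                seq = _mutate(resolved[name], params.sub_rate, rng, protected)
                seq = _indel(seq, params.indel_rate, rng)
                monomer_seqs.append(seq)
                sources.append(name)
                ab_labels.append(cset[name].unit_type)
    else:
        raise ValueError(f"unknown family {params.sf!r}")

    boundaries = []
    pos = 0
    for seq in monomer_seqs:
        boundaries.append((pos, pos + len(seq)))
        pos += len(seq)
    forward = "".join(monomer_seqs)
    emitted = revcomp(forward) if params.revcomp else forward
    array = SatArray(id=array_id, sequence=emitted)
    truth = SyntheticTruth(
        array_id=array_id,
        boundaries=boundaries,
        sources=sources,
        ab_labels=ab_labels,
        sf=params.sf,
        hor_period=period,
        insertion_copies=params.insertion_copies if params.sf == "SF2" else 0,
        strand="reverse" if params.revcomp else "forward",
    )
    return array, truth
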