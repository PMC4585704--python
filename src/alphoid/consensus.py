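"""Majority-rule consensus over monomer sets, with extended ambiguity codes.

Monomers are aligned pairwise-globally to a reference and projected into
reference coordinates (a deterministic stand-in for progressive multiple
alignment, adequate for the near-identical monomers of a satellite
family).  The consensus emits the symbol carried by more than 50% of rows
per column; otherwise the ambiguity code covering the observed symbols
with frequency >= ``min_component_freq``, using the -/base gap codes
(F = -/A, I = -/C, J = -/G, and a configurable symbol for -/T) when the
set includes a gap.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .align import DEFAULT_PARAMS, align_pair
from .alphabet import GAP_T_SYMBOL, code_for
from .core import AlignParams, ConsensusEntry, Monomer


@dataclass
class MonomerAlignment:
    """Rectangular alignment of monomers in reference-projected coordinates.

    Insertions relative to the reference open columns only when shared by
    more than half of the rows; private insertions are kept as per-row
    metadata (``insertions[row_id]`` is a list of ``(column, sequence)``
    with the insertion placed before ``column``).  ``row_sequence`` splices
    them back, reproducing the input monomer exactly.
    """

    ids: list[str]
    rows: list[str]
    insertions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row_sequence(self, row_id: str) -> str:
        """The original monomer sequence of a row (gaps removed, private
        insertions restored)."""
        idx = self.ids.index(row_id)
        row = self.rows[idx]
        pieces = []
        pending = defaultdict(str)
        for col, seq in self.insertions.get(row_id, []):
            pending[col] += seq
        for col, symbol in enumerate(row):
            if col in pending:
                pieces.append(pending.pop(col))
            if symbol != "-":
                pieces.append(symbol)
        pieces.append(pending.pop(len(row), ""))
        return "".join(pieces)


def align_monomers(
    monomers: list[Monomer | str],
    ref: ConsensusEntry,
    params: AlignParams = DEFAULT_PARAMS,
) -> MonomerAlignment:
    """Project each monomer into reference coordinates by global alignment."""
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers to align")
    ids: list[str] = []
    projected: list[list[str]] = []
    raw_insertions: list[dict[int, str]] = []
    for k, monomer in enumerate(monomers):
        seq = monomer.sequence if isinstance(monomer, Monomer) else monomer
        ids.append(monomer.id if isinstance(monomer, Monomer) else f"m{k}")
        ref_row, mon_row, _ = align_pair(ref.sequence, seq, params)
        cells = ["-"] * len(ref.sequence)
        inserts: dict[int, str] = {}
        ref_pos = 0
        for rc, mc in zip(ref_row, mon_row):
            if rc == "-":
                inserts[ref_pos] = inserts.get(ref_pos, "") + mc
            else:
                if mc != "-":
                    cells[ref_pos] = mc
                ref_pos += 1
        projected.append(cells)
        raw_insertions.append(inserts)

    n_rows = len(monomers)
    # insertion sites shared by a strict majority of rows become columns
    site_counts = Counter()
    for ins in raw_insertions:
        site_counts.update(ins.keys())
    shared = {
        site: max(len(ins.get(site, "")) for ins in raw_insertions)
        for site, cnt in site_counts.items()
        if cnt > n_rows / 2
    }
    rows: list[str] = []
    insertions: dict[str, list[tuple[int, str]]] = {}
    for row_id, cells, ins in zip(ids, projected, raw_insertions):
        out = []
        col = 0
        priv: list[tuple[int, str]] = []
        for ref_pos in range(len(ref.sequence) + 1):
            if ref_pos in shared:
                block = ins.get(ref_pos, "")
                out.append(block.ljust(shared[ref_pos], "-"))
                col += shared[ref_pos]
            elif ref_pos in ins:
                priv.append((col, ins[ref_pos]))
            if ref_pos < len(ref.sequence):
                out.append(cells[ref_pos])
                col += 1
        rows.append("".join(out))
        if priv:
            insertions[row_id] = priv
    return MonomerAlignment(ids=ids, rows=rows, insertions=insertions)


def consensus_column(column: list[str], min_component_freq: float = 0.2,
                     gap_t_symbol: str = GAP_T_SYMBOL) -> str:
    """Majority-rule symbol for one alignment column (may be "-")."""
    n = len(column)
    counts = Counter(column)
    symbol, top = counts.most_common(1)[0]
    if top / n > 0.5:
        return symbol
    comp = {s for s, c in counts.items() if c / n >= min_component_freq}
    if not comp:
        return "N"
    if "-" in comp:
        bases = comp - {"-"}
        if len(bases) != 1:
            return "N"  # no published code for a multi-base/gap set
        if bases == {"T"}:
            return gap_t_symbol
        return code_for(bases, with_gap=True)
    return code_for(comp)


def build_consensus(
    aln: MonomerAlignment,
    name: str = "consensus",
    min_component_freq: float = 0.2,
    gap_t_symbol: str = GAP_T_SYMBOL,
) -> ConsensusEntry:
    """Majority-rule consensus of an alignment (strict >50% per column;
    a majority gap deletes the column)."""
    if not aln.ids:
        raise ValueError("empty alignment")
    symbols = []
    for col in range(aln.n_columns):
        column = [row[col] for row in aln.rows]
        s = consensus_column(column, min_component_freq, gap_t_symbol)
        if s != "-":
            symbols.append(s)
    seq = "".join(symbols)
    return ConsensusEntry(name=name, sequence=seq, declared_length=len(seq))
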