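"""Domain types shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import ARRAY_ALPHABET, CONSENSUS_ALPHABET


@dataclass
class SatArray:
    """One input DNA sequence presumed to contain a tandem alpha-satellite array."""

    id: str
    sequence: str
    orientation: str = "unknown"  # forward | reverse-complemented | unknown

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"array {self.id!r}: empty sequence")
        bad = set(self.sequence) - ARRAY_ALPHABET
        if bad:
            raise ValueError(f"array {self.id!r}: illegal symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Monomer:
    """An interval of a forward-normalized array; coordinates are 0-based half-open."""

    array_id: str
    index: int
    start: int
    end: int
    sequence: str
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"monomer {self.array_id}:{self.index}: interval/sequence length mismatch"
            )

    @property
    def id(self) -> str:
        return f"{self.array_id}/{self.index}"


@dataclass(frozen=True)
class AlignParams:
    """bl2seq-style scoring: +1 match, -2 mismatch, gap open 5, gap extend 2."""

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = 5
    gap_extend: int = 2


@dataclass
class ConsensusEntry:
    """A named consensus sequence over the extended alphabet."""

    name: str
    sequence: str
    declared_length: int
    sf: str = "general"  # SF1 | SF2 | SF3 | monomeric | general
    unit_type: str = "unspecified"  # A | B | unspecified

    def __post_init__(self) -> None:
        bad = set(self.sequence) - CONSENSUS_ALPHABET
        if bad:
            raise ValueError(f"consensus {self.name!r}: illegal symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


#: HOR unit composition per suprachromosomal family, in published order
SF_UNITS: dict[str, tuple[str, ...]] = {
    "SF1": ("gJ1", "gJ2"),
    "SF2": ("gD1.0", "gD1.3", "gD1.4", "gD2.1", "gD1.2", "gD2.0", "gD1.1", "gD2.2"),
    "SF3": ("gW1", "gW2", "gW3", "gW4", "gW5"),
}


@dataclass
class ConsensusSet:
    """Ordered collection of consensus entries with the SF unit orders."""

    entries: list[ConsensusEntry]
    sf_units: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(SF_UNITS))

    def __post_init__(self) -> None:
        self._by_name = {e.name: e for e in self.entries}

    def __getitem__(self, name: str) -> ConsensusEntry:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def family_members(self) -> list[ConsensusEntry]:
        """The SF-specific and monomeric consensuses (the three general ones excluded)."""
        return [e for e in self.entries if e.sf != "general"]


@dataclass
class AnnotationRecord:
    """A labelled interval on an array; serializes losslessly to BED6/GFF3."""

    array_id: str
    start: int  # 0-based half-open
    end: int
    label: str
    score: float = 0.0
    strand: str = "+"
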