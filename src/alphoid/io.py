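"""Readers and writers: FASTA arrays, builtin consensuses, BED/GFF3/TSV annotations."""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ARRAY_ALPHABET
from .core import AnnotationRecord, ConsensusEntry, ConsensusSet, SatArray

log = logging.getLogger(__name__)

_NORMALIZE = {c: c for c in "ACGTN"}
_NORMALIZE["U"] = "T"


def _normalize_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - ARRAY_ALPHABET
    if bad:
        log.warning(
            "array %s: mapping non-ACGTN symbols %s to N", record_id, sorted(bad)
        )
        seq = "".join(c if c in ARRAY_ALPHABET else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SatArray]:
    """Read satellite arrays from a FASTA file.

    Lowercase is normalized to uppercase, U to T, and any other symbol to N
    (with a warning).  An empty file yields an empty list; a file whose first
    non-blank line is not a FASTA header is rejected with the line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA header at line {lineno}: {line.strip()!r}"
                    )
                break
    arrays = []
    for rec in SeqIO.parse(path, "fasta"):
        arrays.append(SatArray(id=rec.id, sequence=_normalize_sequence(str(rec.seq), rec.id)))
    return arrays


def write_fasta(arrays: Iterable[SatArray], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(a.sequence), id=a.id, description="") for a in arrays]
    SeqIO.write(records, path, "fasta")
    return path


def load_builtin_consensuses() -> ConsensusSet:
    """The 19 published gorilla alphoid consensus sequences, as package data."""
    entries = []
    ref = importlib.resources.files("alphoid.data") / "gorilla_consensus.fasta"
    with importlib.resources.as_file(ref) as path:
        for rec in SeqIO.parse(path, "fasta"):
            fields = dict(kv.split("=") for kv in rec.description.split()[1:])
            entries.append(
                ConsensusEntry(
                    name=rec.id,
                    sequence=str(rec.seq),
                    declared_length=int(fields["size"]),
                    sf=fields["sf"],
                    unit_type=fields["unit_type"],
                )
            )
    return ConsensusSet(entries=entries)


# ---------------------------------------------------------------------------
# annotation tables

_COLUMNS = ["array_id", "start", "end", "label", "score", "strand"]


def write_annotations(
    records: Iterable[AnnotationRecord], path: str | Path, format: str = "BED"
) -> Path:
    """Write annotation records as BED6 (0-based half-open), GFF3 (1-based
    closed) or TSV.  Internal coordinates are 0-based half-open; conversion
    happens only here."""
    path = Path(path)
    records = list(records)
    fmt = format.upper()
    if fmt == "BED":
        df = pd.DataFrame(
            [(r.array_id, r.start, r.end, r.label, r.score, r.strand) for r in records],
            columns=_COLUMNS,
        )
        df.to_csv(path, sep="\t", header=False, index=False)
    elif fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                attrs = f"Name={r.label}"
                fh.write(
                    f"{r.array_id}\talphoid\tsatellite_DNA\t{r.start + 1}\t{r.end}\t"
                    f"{r.score}\t{r.strand}\t.\t{attrs}\n"
                )
    elif fmt == "TSV":
        df = pd.DataFrame(
            [(r.array_id, r.start, r.end, r.label, r.score, r.strand) for r in records],
            columns=_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return path


def read_annotations(path: str | Path, format: str = "BED") -> list[AnnotationRecord]:
    """Inverse of :func:`write_annotations` (BED and GFF3)."""
    path = Path(path)
    fmt = format.upper()
    records: list[AnnotationRecord] = []
    if fmt == "BED":
        df = pd.read_csv(path, sep="\t", header=None, names=_COLUMNS)
        for row in df.itertuples(index=False):
            records.append(
                AnnotationRecord(row.array_id, int(row.start), int(row.end),
                                 str(row.label), float(row.score), str(row.strand))
            )
    elif fmt == "GFF3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                label = f[8].removeprefix("Name=")
                records.append(
                    AnnotationRecord(f[0], int(f[3]) - 1, int(f[4]), label,
                                     float(f[5]), f[6])
                )
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return records
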