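"""FASTQ input/output with exact round-trip fidelity.

Only the 4-line FASTQ dialect produced by modern basecallers is supported
(one record = header / sequence / ``+`` / quality). Qualities are Phred+33.
``U`` is mapped to ``T`` at read time so a single DNA alphabet flows through
the rest of the pipeline. Files written by :func:`write_fastq` round-trip
byte-for-byte through :func:`read_fastq`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np

PHRED_OFFSET = 33
MAX_PHRED = 93  # highest quality encodable in Phred+33 printable ASCII ('~')

VALID_BASES = frozenset("ACGTN")
_U_TO_T = str.maketrans("U", "T")

PathLike = Union[str, Path]


class FastqFormatError(ValueError):
    """Raised when a FASTQ file violates the 4-line dialect."""


@dataclass
class ReadRecord:
    """One sequencing read: id, bases and per-base Phred qualities.

    ``qualities`` is stored as a numpy integer array of the same length as
    ``sequence``; values must lie in ``[0, 93]``. ``description`` holds any
    text after the first whitespace on the header line so that headers with
    comments survive a round trip.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        # int16 comfortably holds Phred 0..93 and keeps million-read sets small
        self.qualities = np.asarray(self.qualities, dtype=np.int16)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.read_id or any(c.isspace() for c in self.read_id):
            raise ValueError(f"invalid read id {self.read_id!r}")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > MAX_PHRED
        ):
            raise ValueError(
                f"read {self.read_id!r}: qualities outside [0, {MAX_PHRED}]"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")


def quality_string_to_phred(text: str) -> np.ndarray:
    """Decode a Phred+33 quality string to integer scores."""
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64)
    return arr - PHRED_OFFSET


def phred_to_quality_string(qualities: np.ndarray) -> str:
    """Encode integer Phred scores as a Phred+33 string."""
    q = np.asarray(qualities, dtype=np.int64)
    if q.size and (q.min() < 0 or q.max() > MAX_PHRED):
        raise ValueError(f"quality values outside encodable range [0, {MAX_PHRED}]")
    return (q + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")


def _open_text(path: PathLike):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(path: PathLike) -> List[ReadRecord]:
    """Read a 4-line FASTQ file (optionally gzipped) into ReadRecords.

    ``U`` bases are converted to ``T`` at ingest. A record whose sequence and
    quality lines differ in length is a hard error naming the record.
    """
    records: List[ReadRecord] = []
    with _open_text(path) as fh:
        text = fh.read()
    # strip exactly the final newline so empty sequence/quality lines survive
    if text.endswith("\n"):
        text = text[:-1]
    lines = text.split("\n") if text else []
    if len(lines) % 4 != 0:
        raise FastqFormatError(
            f"{path}: number of lines ({len(lines)}) is not a multiple of 4"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise FastqFormatError(f"{path}: record {i // 4 + 1} header {header!r}")
        if not plus.startswith("+"):
            raise FastqFormatError(
                f"{path}: record {header!r} separator line {plus!r}"
            )
        name = header[1:]
        read_id, _, description = name.partition(" ")
        if not read_id:
            raise FastqFormatError(f"{path}: record {i // 4 + 1} has empty id")
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"{path}: record {read_id!r} sequence length {len(seq)} "
                f"!= quality length {len(qual)}"
            )
        seq = seq.upper().translate(_U_TO_T)
        rec = ReadRecord(read_id, seq, quality_string_to_phred(qual), description)
        rec.validate()
        records.append(rec)
    return records


def write_fastq(records: Iterable[ReadRecord], path: PathLike) -> None:
    """Write records as 4-line Phred+33 FASTQ. Empty input yields an empty file."""
    path = Path(path)
    chunks: List[str] = []
    for rec in records:
        rec.validate()
        header = f"@{rec.read_id}"
        if rec.description:
            header += f" {rec.description}"
        chunks.append(
            f"{header}\n{rec.sequence}\n+\n{phred_to_quality_string(rec.qualities)}\n"
        )
    with open(path, "wt", encoding="ascii") as fh:
        fh.write("".join(chunks))
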