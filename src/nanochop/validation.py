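"""Chimeric-alignment concordance and adapter-identity utilities.

A chimeric alignment is a read whose alignment comprises a primary SAM record
plus one or more supplementary alignments (SA tag): the read spans multiple
genomic loci. To quantify how many dRNA-seq chimeras are corroborated by an
orthogonal (cDNA-based) platform, each chimera is converted to a list of
genomic intervals; two chimeras are concordant when their interval lists can
be matched one-to-one with the same chromosome and strand and both endpoint
offsets below a tolerance (default 1000 bp). The support rate is the fraction
of query chimeras concordant with at least one reference chimera.

BLAT-style identity -- matched bases over query length -- is provided to show
that excised adapter regions are non-genomic.
"""

from __future__ import annotations

import logging
import re
import tempfile
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import edlib
import pysam

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_BP = 1000

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open reference interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class ChimericAlignment:
    """Ordered genomic intervals of one chimeric read (primary first)."""

    read_id: str
    intervals: List[GenomicInterval]

    def __post_init__(self) -> None:
        if len(self.intervals) < 2:
            raise ValueError(
                "a chimeric alignment needs a primary plus >=1 supplementary interval"
            )


@dataclass
class SupportResult:
    n_query: int
    n_supported: int
    support_rate: float


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string (M/D/N/=/X)."""
    if not cigar:
        raise ValueError("empty CIGAR")
    pos = 0
    span = 0
    for match in _CIGAR_RE.finditer(cigar):
        if match.start() != pos:
            raise ValueError(f"unparsable CIGAR {cigar!r}")
        length, op = int(match.group(1)), match.group(2)
        if op in _REF_CONSUMING:
            span += length
        pos = match.end()
    if pos != len(cigar):
        raise ValueError(f"unparsable CIGAR {cigar!r}")
    return span


def _parse_sa_tag(sa_tag: str) -> List[GenomicInterval]:
    intervals = []
    for entry in sa_tag.rstrip(";").split(";"):
        if not entry:
            continue
        fields = entry.split(",")
        if len(fields) != 6:
            raise ValueError(f"malformed SA entry {entry!r}")
        rname, pos, strand, cigar = fields[0], int(fields[1]), fields[2], fields[3]
        if strand not in "+-":
            raise ValueError(f"malformed SA strand in {entry!r}")
        start = pos - 1  # SAM is 1-based
        intervals.append(
            GenomicInterval(rname, start, start + cigar_reference_span(cigar), strand)
        )
    return intervals


SamInput = Union[str, Path, Iterable[str]]


def extract_chimeras(sam: SamInput) -> List[ChimericAlignment]:
    """Chimeric alignments (primary + SA-tag supplementaries) from SAM input.

    ``sam`` is a path to a SAM file or an iterable of SAM lines (header
    included). Secondary and supplementary records are ignored as primaries;
    a primary without an SA tag is not a chimera. Records whose SA tag or
    CIGAR cannot be parsed are skipped with a warning.
    """
    if isinstance(sam, (str, Path)):
        return _extract_from_path(str(sam))
    text = "".join(line if line.endswith("\n") else line + "\n" for line in sam)
    with tempfile.NamedTemporaryFile("wt", suffix=".sam", delete=False) as fh:
        fh.write(text)
        tmp = fh.name
    try:
        return _extract_from_path(tmp)
    finally:
        Path(tmp).unlink(missing_ok=True)


def _extract_from_path(path: str) -> List[ChimericAlignment]:
    chimeras: List[ChimericAlignment] = []
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.has_tag("SA"):
                continue
            try:
                primary = GenomicInterval(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
                supplementary = _parse_sa_tag(str(rec.get_tag("SA")))
                chimeras.append(
                    ChimericAlignment(rec.query_name, [primary] + supplementary)
                )
            except (ValueError, TypeError) as exc:
                logger.warning("skipping record %s: %s", rec.query_name, exc)
    return chimeras


def _intervals_match(a: GenomicInterval, b: GenomicInterval, tol: int) -> bool:
    return (
        a.chrom == b.chrom
        and a.strand == b.strand
        and abs(a.start - b.start) < tol
        and abs(a.end - b.end) < tol
    )


def is_concordant(
    a: ChimericAlignment, b: ChimericAlignment, tol: int = DEFAULT_TOLERANCE_BP
) -> bool:
    """True iff the two interval lists admit a one-to-one concordant matching.

    Matched intervals must share chromosome and strand with both endpoint
    offsets strictly below ``tol``. Lists of unequal length are never
    concordant (a 2-part chimera cannot support a 3-part one).
    """
    if len(a.intervals) != len(b.intervals):
        return False
    ints_a, ints_b = a.intervals, b.intervals
    if len(ints_a) <= 6:
        for perm in permutations(range(len(ints_b))):
            if all(
                _intervals_match(ints_a[i], ints_b[j], tol)
                for i, j in enumerate(perm)
            ):
                return True
        return False
    # long chimeras: match in sorted genomic order
    key = lambda iv: (iv.chrom, iv.start, iv.end, iv.strand)
    return all(
        _intervals_match(x, y, tol)
        for x, y in zip(sorted(ints_a, key=key), sorted(ints_b, key=key))
    )


def support_rate(
    query: Sequence[ChimericAlignment],
    reference: Sequence[ChimericAlignment],
    tol: int = DEFAULT_TOLERANCE_BP,
) -> SupportResult:
    """Fraction of query chimeras concordant with >=1 reference chimera."""
    n_query = len(query)
    if n_query == 0:
        return SupportResult(0, 0, 0.0)
    n_supported = sum(
        1 for q in query if any(is_concordant(q, r, tol) for r in reference)
    )
    return SupportResult(n_query, n_supported, n_supported / n_query)


def supported_flags(
    query: Sequence[ChimericAlignment],
    reference: Sequence[ChimericAlignment],
    tol: int = DEFAULT_TOLERANCE_BP,
) -> List[bool]:
    """Per-query support flags (same order as ``query``)."""
    return [any(is_concordant(q, r, tol) for r in reference) for q in query]


def blat_identity(match_length: int, sequence_length: int) -> float:
    """Identity = matched bases / query sequence length."""
    if sequence_length <= 0:
        raise ValueError("sequence_length must be positive")
    if not 0 <= match_length <= sequence_length:
        raise ValueError("match_length must be in [0, sequence_length]")
    return match_length / sequence_length


def approximate_identity(query: str, reference: str) -> float:
    """Edit-distance-based stand-in for an aligner's identity.

    Aligns ``query`` within ``reference`` (infix mode) and feeds the implied
    match count -- query length minus edit distance, floored at 0 -- into
    :func:`blat_identity`. Useful for self-contained tests; not a BLAT run.
    """
    if not query:
        raise ValueError("empty query")
    result = edlib.align(query, reference, mode="HW", task="distance")
    matches = max(0, len(query) - result["editDistance"])
    return blat_identity(matches, len(query))
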