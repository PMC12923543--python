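"""Turn refined label tracks into adapter intervals and split reads.

Four filtering rules are applied in order when chopping a read:

1. a predicted adapter must be at least ``min_adapter_len`` (13) nt long;
2. if more than ``max_adapters`` (4) adapters survive, the whole read is
   retained untouched (a read that fragmented that much is suspect);
3. otherwise the surviving adapter spans are excised and the read is divided
   into the between-the-cuts segments, which keep their original qualities;
4. segments shorter than ``min_segment_len`` (20) nt are discarded.

All three thresholds are configurable. Every base of the source read is
accounted for: segments + removed adapter spans + discarded short segments
partition the read exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_fastq import ReadRecord

MIN_ADAPTER_LEN = 13
MAX_ADAPTERS = 4
MIN_SEGMENT_LEN = 20


@dataclass(frozen=True)
class AdapterCall:
    """A maximal predicted adapter interval on a read (0-based, half-open)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid adapter call ({self.start}, {self.end})")


@dataclass
class ChopResult:
    """Outcome of chopping one read.

    ``segments`` are the emitted sub-reads (ids ``source_id:ordinal``);
    ``removed`` the excised adapter spans; ``discarded`` the sub-read spans
    dropped by the minimum-segment-length rule; ``calls`` the adapter calls
    that survived the length filter (identical to ``removed`` unless the
    multi-adapter rule retained the read). ``action`` is one of ``unchanged``,
    ``trimmed_end``, ``split``, ``retained_multiadapter``.
    """

    source_id: str
    segments: List[ReadRecord]
    removed: List[AdapterCall]
    action: str
    discarded: List[AdapterCall] = field(default_factory=list)
    calls: List[AdapterCall] = field(default_factory=list)
    read_length: int = 0


def labels_to_intervals(labels) -> List[AdapterCall]:
    """Maximal runs of 1s as sorted, disjoint half-open adapter candidates."""
    arr = np.asarray(labels)
    if arr.size == 0:
        return []
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    padded = np.concatenate([[0], arr.astype(np.int8), [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [AdapterCall(int(s), int(e)) for s, e in zip(starts, ends)]


def chop(
    record: ReadRecord,
    candidates: Sequence[AdapterCall],
    min_adapter_len: int = MIN_ADAPTER_LEN,
    max_adapters: int = MAX_ADAPTERS,
    min_segment_len: int = MIN_SEGMENT_LEN,
) -> ChopResult:
    """Apply the four filtering rules and split the read into segments."""
    n = len(record)
    prev_end = -1
    for call in candidates:
        if call.end > n:
            raise ValueError(
                f"read {record.read_id!r}: candidate ({call.start}, {call.end}) "
                f"exceeds read length {n}"
            )
        if call.start < prev_end:
            raise ValueError(
                f"read {record.read_id!r}: overlapping/unsorted adapter candidates"
            )
        prev_end = call.end

    surviving = [c for c in candidates if c.length >= min_adapter_len]
    if not surviving:
        return ChopResult(record.read_id, [record], [], "unchanged", read_length=n)
    if len(surviving) > max_adapters:
        return ChopResult(
            record.read_id,
            [record],
            [],
            "retained_multiadapter",
            calls=surviving,
            read_length=n,
        )

    segments: List[ReadRecord] = []
    discarded: List[AdapterCall] = []
    bounds = [0]
    for call in surviving:
        bounds.extend([call.start, call.end])
    bounds.append(n)
    ordinal = 1
    for seg_start, seg_end in zip(bounds[::2], bounds[1::2]):
        if seg_end <= seg_start:
            continue
        if seg_end - seg_start < min_segment_len:
            discarded.append(AdapterCall(seg_start, seg_end))
            continue
        segments.append(
            ReadRecord(
                f"{record.read_id}:{ordinal}",
                record.sequence[seg_start:seg_end],
                record.qualities[seg_start:seg_end].copy(),
            )
        )
        ordinal += 1

    if len(surviving) == 1 and surviving[0].end == n:
        action = "trimmed_end"
    else:
        action = "split"
    return ChopResult(
        record.read_id,
        segments,
        list(surviving),
        action,
        discarded=discarded,
        calls=list(surviving),
        read_length=n,
    )


def chop_read(
    record: ReadRecord,
    raw_labels,
    window: int = 21,
    min_adapter_len: int = MIN_ADAPTER_LEN,
    max_adapters: int = MAX_ADAPTERS,
    min_segment_len: int = MIN_SEGMENT_LEN,
) -> ChopResult:
    """Convenience: smooth raw labels, extract intervals, chop."""
    from .refine import refine

    refined = refine(raw_labels, window)
    return chop(
        record,
        labels_to_intervals(refined),
        min_adapter_len=min_adapter_len,
        max_adapters=max_adapters,
        min_segment_len=min_segment_len,
    )


def summarize(results: Iterable[ChopResult]) -> pd.DataFrame:
    """Per-read summary table.

    One row per read: adapter count, adapter lengths, relative adapter
    positions (call start / read length, i.e. the fraction of the read before
    the adapter), number of segments emitted, and the chop action. A 3'-end
    trimmed read has one segment; two or more indicate internal adapters.
    """
    rows = []
    for res in results:
        length = res.read_length or (
            sum(len(s) for s in res.segments)
            + sum(c.length for c in res.removed)
            + sum(c.length for c in res.discarded)
        )
        rows.append(
            dict(
                read_id=res.source_id,
                read_length=length,
                n_adapters=len(res.calls),
                adapter_lengths=[c.length for c in res.calls],
                relative_positions=[c.start / length for c in res.calls]
                if length
                else [],
                n_segments=len(res.segments),
                action=res.action,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "read_length",
            "n_adapters",
            "adapter_lengths",
            "relative_positions",
            "n_segments",
            "action",
        ],
    )


def aggregate_summary(table: pd.DataFrame) -> Dict[str, object]:
    """Aggregate histograms over a per-read summary table."""
    adapter_lengths = np.array(
        [l for ls in table["adapter_lengths"] for l in ls], dtype=np.int64
    )
    rel_positions = np.array(
        [p for ps in table["relative_positions"] for p in ps], dtype=np.float64
    )
    segs = table["n_segments"].value_counts().sort_index()
    return dict(
        n_reads=int(len(table)),
        adapter_length_counts=np.bincount(adapter_lengths)
        if adapter_lengths.size
        else np.zeros(0, np.int64),
        relative_position_histogram=np.histogram(rel_positions, bins=20, range=(0, 1))
        if rel_positions.size
        else (np.zeros(20, np.int64), np.linspace(0, 1, 21)),
        segments_per_read={int(k): int(v) for k, v in segs.items()},
        actions=table["action"].value_counts().to_dict(),
    )
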