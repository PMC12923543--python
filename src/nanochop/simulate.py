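"""Synthetic labeled dRNA-seq reads for training and testing the adapter classifier.

Reads emulate the structure of basecalled nanopore direct RNA sequencing data:
transcript-like bodies ending in a polyA tail, with a corrupted, low-quality
~70 bp DNA adapter either at the 3' end of the read (``end3``) or bridging two
transcript bodies (``internal``, the chimera-artifact case). Adapter bases are
labeled 1; everything else -- including the polyA tail -- is labeled 0.

The DNA adapter of the dRNA-seq kit is basecalled under an RNA model, so it
appears heavily corrupted and at low quality. The generator emulates this with
per-base substitutions/indels and a low adapter quality mean (default Phred 10,
matching the ~Q10 observed for real internal adapters), against transcript
bodies at a higher quality mean (default Phred 12). Because the kit adapter's
exact sequence is proprietary, a fixed arbitrary 70-mer ships as the default
template; any template can be supplied, and ``randomize_template`` draws a
fresh template per read (making adapters sequence-ambiguous, which isolates
the quality signal for ablation studies).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_fastq import MAX_PHRED, ReadRecord, write_fastq

logger = logging.getLogger(__name__)

#: Fixed arbitrary 70-mer standing in for the (unpublished) dRNA-seq kit adapter.
DEFAULT_ADAPTER = (
    "GAGTGCTTGCGTCAGTCTACGCTAGGTTCAATGCACGGTTCACGAGTCCGATCTAGCGTTGCATGGATCC"
)

CATEGORIES = ("internal", "end3", "negative")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

Distribution = Tuple[str, Dict[str, float]]


@dataclass
class AdapterModel:
    """Corruption and quality model for inserted adapter sequences.

    ``substitution_rate`` and ``indel_rate`` are per-base probabilities; the
    defaults (0.07 + 0.03) give ~10% per-base error, consistent with the ~Q10
    qualities of real internal adapters. With ``randomize_template`` a fresh
    uniform-composition template of the same length is drawn per read.
    """

    reference_sequence: str = DEFAULT_ADAPTER
    substitution_rate: float = 0.07
    indel_rate: float = 0.03
    quality_mean: float = 10.0
    quality_sd: float = 3.0
    randomize_template: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if not 0.0 <= self.quality_mean <= MAX_PHRED:
            raise ValueError(f"quality_mean must be in [0, {MAX_PHRED}]")
        if len(self.reference_sequence) < 13:
            raise ValueError("reference_sequence must be at least 13 nt")


@dataclass
class BodyModel:
    """Length, composition and quality model for non-adapter transcript bodies.

    Named distributions: ``("lognormal", {"median": m, "sigma": s})``,
    ``("geometric", {"mean": m})``, ``("fixed", {"length": n})`` and
    ``("uniform", {"low": a, "high": b})``. Sampled body lengths are clipped to
    ``[min_length, max_length]``; the floor of 20 guarantees that every body
    survives the chopper's minimum-segment filter by construction.
    """

    length_distribution: Distribution = ("lognormal", None)
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    quality_mean: float = 12.0
    quality_sd: float = 3.0
    polyA_length_distribution: Distribution = ("geometric", None)
    min_length: int = 20
    max_length: int = 3000

    def __post_init__(self) -> None:
        if self.length_distribution[1] is None:
            self.length_distribution = ("lognormal", {"median": 700.0, "sigma": 0.6})
        if self.polyA_length_distribution[1] is None:
            self.polyA_length_distribution = ("geometric", {"mean": 30.0})
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.min_length < 20:
            raise ValueError("min_length must be >= 20")


@dataclass
class LabeledRead:
    """A ReadRecord with per-base ground-truth adapter labels and intervals."""

    record: ReadRecord
    labels: np.ndarray  # uint8, 1 = adapter base
    truth_intervals: List[Tuple[int, int]]  # 0-based half-open, sorted, disjoint
    category: str

    def validate(self) -> None:
        self.record.validate()
        if len(self.labels) != len(self.record):
            raise ValueError("labels/sequence length mismatch")
        expect = labels_from_intervals(len(self.record), self.truth_intervals)
        if not np.array_equal(np.asarray(self.labels, dtype=np.uint8), expect):
            raise ValueError("labels inconsistent with truth intervals")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def labels_from_intervals(length: int, intervals: Sequence[Tuple[int, int]]) -> np.ndarray:
    """Build a 0/1 per-base label array from half-open adapter intervals."""
    labels = np.zeros(length, dtype=np.uint8)
    for start, end in intervals:
        if not 0 <= start < end <= length:
            raise ValueError(f"interval ({start}, {end}) outside [0, {length})")
        labels[start:end] = 1
    return labels


def _sample_length(rng: np.random.Generator, dist: Distribution) -> int:
    name, params = dist
    if name == "lognormal":
        value = rng.lognormal(mean=math.log(params["median"]), sigma=params["sigma"])
        return int(round(value))
    if name == "geometric":
        return int(rng.geometric(1.0 / params["mean"]))
    if name == "fixed":
        return int(params["length"])
    if name == "uniform":
        return int(rng.integers(int(params["low"]), int(params["high"]) + 1))
    raise ValueError(f"unknown length distribution {name!r}")


def _random_base_indices(
    rng: np.random.Generator, n: int, probs: Optional[Sequence[float]] = None
) -> np.ndarray:
    if probs is None or np.allclose(probs, 0.25):
        return rng.integers(0, 4, size=n, dtype=np.int64)
    cum = np.cumsum(np.asarray(probs, dtype=np.float64))
    return np.searchsorted(cum, rng.random(n)).astype(np.int64)


def _indices_to_seq(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


def _sample_qualities(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    q = rng.normal(mean, sd, size=n)
    return np.clip(np.round(q), 0, MAX_PHRED).astype(np.int64)


def sample_adapter(
    rng: np.random.Generator, model: AdapterModel
) -> Tuple[str, np.ndarray]:
    """Draw one corrupted adapter copy: (sequence, qualities).

    Substitutions replace a base by one of the three others; indels are split
    evenly between single-base deletions and insertions. Qualities are normal
    around ``quality_mean`` clipped to [0, 93].
    """
    if model.randomize_template:
        idx = _random_base_indices(rng, len(model.reference_sequence))
    else:
        idx = np.array(
            [_BASE_INDEX[b] for b in model.reference_sequence], dtype=np.int64
        )
    n = idx.size
    sub = rng.random(n) < model.substitution_rate
    n_sub = int(sub.sum())
    if n_sub:
        idx = idx.copy()
        idx[sub] = (idx[sub] + rng.integers(1, 4, size=n_sub)) % 4
    r = rng.random(n)
    deleted = r < model.indel_rate / 2.0
    inserted = (r >= model.indel_rate / 2.0) & (r < model.indel_rate)
    counts = (~deleted).astype(np.int64) + inserted.astype(np.int64)
    total = int(counts.sum())
    out = np.empty(total, dtype=np.int64)
    pos = np.cumsum(counts) - counts  # output offset of each template base
    keep = ~deleted
    out[pos[keep]] = idx[keep]
    n_ins = int(inserted.sum())
    if n_ins:
        ins_at = pos[inserted] + keep[inserted].astype(np.int64)
        out[ins_at] = rng.integers(0, 4, size=n_ins)
    quals = _sample_qualities(rng, total, model.quality_mean, model.quality_sd)
    return _indices_to_seq(out), quals


def _sample_body(
    rng: np.random.Generator, model: BodyModel, length: Optional[int] = None
) -> Tuple[str, np.ndarray]:
    if length is None:
        length = _sample_length(rng, model.length_distribution)
        length = int(np.clip(length, model.min_length, model.max_length))
    idx = _random_base_indices(rng, length, model.base_composition)
    quals = _sample_qualities(rng, length, model.quality_mean, model.quality_sd)
    return _indices_to_seq(idx), quals


def _sample_polya(rng: np.random.Generator, model: BodyModel) -> Tuple[str, np.ndarray]:
    length = _sample_length(rng, model.polyA_length_distribution)
    quals = _sample_qualities(rng, length, model.quality_mean, model.quality_sd)
    return "A" * length, quals


def build_labeled_read(
    rng: np.random.Generator,
    bodies: BodyModel,
    adapters: AdapterModel,
    category: str,
    read_id: str = "simread",
    body_lengths: Optional[Tuple[int, ...]] = None,
) -> LabeledRead:
    """Assemble one labeled read of the given category.

    ``internal``: body1 + polyA + adapter + body2; ``end3``: body + polyA +
    adapter; ``negative``: body + polyA. PolyA bases are non-adapter (label 0);
    only the inserted adapter span is labeled 1. ``body_lengths`` pins the body
    lengths (useful for deterministic tests); otherwise lengths are sampled
    from the body model.
    """
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}, got {category!r}")

    def body(i: int) -> Tuple[str, np.ndarray]:
        length = body_lengths[i] if body_lengths is not None else None
        return _sample_body(rng, bodies, length)

    parts: List[Tuple[str, np.ndarray, bool]] = []  # (seq, quals, is_adapter)
    if category == "negative":
        parts.append(body(0) + (False,))
        parts.append(_sample_polya(rng, bodies) + (False,))
    elif category == "end3":
        parts.append(body(0) + (False,))
        parts.append(_sample_polya(rng, bodies) + (False,))
        parts.append(sample_adapter(rng, adapters) + (True,))
    else:  # internal
        parts.append(body(0) + (False,))
        parts.append(_sample_polya(rng, bodies) + (False,))
        parts.append(sample_adapter(rng, adapters) + (True,))
        parts.append(body(1) + (False,))

    seq = "".join(p[0] for p in parts)
    quals = np.concatenate([p[1] for p in parts]) if parts else np.zeros(0, np.int64)
    intervals: List[Tuple[int, int]] = []
    offset = 0
    for s, _, is_adapter in parts:
        if is_adapter and len(s):
            intervals.append((offset, offset + len(s)))
        offset += len(s)
    labels = labels_from_intervals(len(seq), intervals)
    record = ReadRecord(read_id, seq, quals)
    return LabeledRead(record, labels, intervals, category)


def build_multi_adapter_read(
    rng: np.random.Generator,
    bodies: BodyModel,
    adapters: AdapterModel,
    n_adapters: int,
    read_id: str = "multiread",
) -> LabeledRead:
    """Read with several internal adapters (polyA before each), for chopper tests."""
    if n_adapters < 2:
        raise ValueError("n_adapters must be >= 2 (use build_labeled_read otherwise)")
    parts: List[Tuple[str, np.ndarray, bool]] = [_sample_body(rng, bodies) + (False,)]
    for _ in range(n_adapters):
        parts.append(_sample_polya(rng, bodies) + (False,))
        parts.append(sample_adapter(rng, adapters) + (True,))
        parts.append(_sample_body(rng, bodies) + (False,))
    seq = "".join(p[0] for p in parts)
    quals = np.concatenate([p[1] for p in parts])
    intervals = []
    offset = 0
    for s, _, is_adapter in parts:
        if is_adapter and len(s):
            intervals.append((offset, offset + len(s)))
        offset += len(s)
    labels = labels_from_intervals(len(seq), intervals)
    return LabeledRead(ReadRecord(read_id, seq, quals), labels, intervals, "internal")


def _largest_remainder(n: int, weights: Sequence[float]) -> List[int]:
    """Apportion ``n`` items to categories in proportion to ``weights`` exactly."""
    weights = np.asarray(weights, dtype=np.float64)
    if n < 0 or weights.min() < 0 or weights.sum() <= 0:
        raise ValueError("invalid count/weights")
    shares = n * weights / weights.sum()
    counts = np.floor(shares).astype(np.int64)
    remainder = n - int(counts.sum())
    if remainder:
        # stable tie-break: larger fractional part first, then lower index
        order = sorted(
            range(len(weights)), key=lambda i: (-(shares[i] - counts[i]), i)
        )
        for i in order[:remainder]:
            counts[i] += 1
    return [int(c) for c in counts]


@dataclass
class DatasetSplits:
    train: List[LabeledRead]
    val: List[LabeledRead]
    test: List[LabeledRead]

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def category_counts(
    n_total: int,
    pos_neg_ratio: Tuple[float, float] = (9, 1),
    internal_end3_ratio: Tuple[float, float] = (1, 1),
) -> Dict[str, int]:
    """Exact per-category read counts by largest-remainder apportionment."""
    pos_w, neg_w = pos_neg_ratio
    int_w, e3_w = internal_end3_ratio
    pos_total = pos_w / (pos_w + neg_w)
    weights = [
        pos_total * int_w / (int_w + e3_w),  # internal
        pos_total * e3_w / (int_w + e3_w),  # end3
        neg_w / (pos_w + neg_w),  # negative
    ]
    counts = _largest_remainder(n_total, weights)
    return dict(zip(CATEGORIES, counts))


def generate_dataset(
    n_total: int,
    pos_neg_ratio: Tuple[float, float] = (9, 1),
    internal_end3_ratio: Tuple[float, float] = (1, 1),
    split_ratios: Tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
    bodies: Optional[BodyModel] = None,
    adapters: Optional[AdapterModel] = None,
) -> DatasetSplits:
    """Generate a stratified train/val/test dataset of labeled reads.

    Category counts and split sizes are exact under largest-remainder rounding
    (600,000 reads at 9:1 / 1:1 / 8:1:1 yields 480,000 / 60,000 / 60,000).
    The split is stratified: each partition preserves the category mix. If
    ``n_total`` is not divisible by the sum of the split ratio parts it is
    truncated down to the nearest multiple, with a logged warning. Fully
    reproducible from ``seed``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    parts = sum(split_ratios)
    if any(r < 0 for r in split_ratios) or parts <= 0:
        raise ValueError("split_ratios must be non-negative with positive sum")
    if n_total % int(parts) != 0 and float(parts).is_integer():
        truncated = n_total - n_total % int(parts)
        logger.warning(
            "n_total=%d not divisible by split parts %d; truncating to %d",
            n_total,
            int(parts),
            truncated,
        )
        n_total = truncated
        if n_total == 0:
            raise ValueError("n_total too small for the requested split ratios")

    bodies = bodies if bodies is not None else BodyModel()
    adapters = adapters if adapters is not None else AdapterModel()
    rng = np.random.default_rng(seed)

    counts = category_counts(n_total, pos_neg_ratio, internal_end3_ratio)
    splits: Tuple[List[LabeledRead], ...] = ([], [], [])
    serial = 0
    for category in CATEGORIES:
        per_split = _largest_remainder(counts[category], split_ratios)
        for split_idx, n in enumerate(per_split):
            for _ in range(n):
                read = build_labeled_read(
                    rng, bodies, adapters, category, read_id=f"sim_{serial:07d}"
                )
                splits[split_idx].append(read)
                serial += 1
    # interleave categories within each partition (stratified random order)
    for part in splits:
        rng.shuffle(part)  # type: ignore[arg-type]
    return DatasetSplits(*splits)


def ablation_adapter_model() -> AdapterModel:
    """Adapter model for quality-block ablation studies.

    The substitution rate is raised to 0.20 so the adapter's sequence content
    drifts toward the body composition and sequence alone becomes ambiguous at
    the adapter boundaries, while the adapter quality mean is set to 8.0, the
    low end of what real internal adapters show, against the body default of
    12.0 -- making per-base quality the signal that separates the classes.
    """
    return AdapterModel(substitution_rate=0.20, quality_mean=8.0)


def write_bed(reads: Sequence[LabeledRead], path) -> None:
    """Sidecar BED of truth intervals (0-based half-open; name = category).

    Negative reads have no intervals and therefore contribute no lines.
    """
    with open(path, "wt", encoding="ascii") as fh:
        for read in reads:
            for start, end in read.truth_intervals:
                fh.write(f"{read.record.read_id}\t{start}\t{end}\t{read.category}\n")


def load_bed(path) -> Dict[str, List[Tuple[int, int]]]:
    """Load truth intervals keyed by read id from a sidecar BED."""
    intervals: Dict[str, List[Tuple[int, int]]] = {}
    with open(path, "rt", encoding="ascii") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            read_id, start, end = fields[0], int(fields[1]), int(fields[2])
            intervals.setdefault(read_id, []).append((start, end))
    for spans in intervals.values():
        spans.sort()
    return intervals


def write_dataset(reads: Sequence[LabeledRead], fastq_path, bed_path) -> None:
    """Write reads as FASTQ plus a sidecar BED of adapter truth intervals."""
    write_fastq([r.record for r in reads], fastq_path)
    write_bed(reads, bed_path)
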