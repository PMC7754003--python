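"""Read-pair quality control.

Filters applied before any annotation, in fixed order per pair:
length (R1 < 66 or R2 < 64), mean base quality (either mate < 20), and
single-nucleotide frequency — the fraction of the read occupied by its
most common base, a low-complexity screen (R1 >= 0.55 or R2 >= 0.80
drops the pair; both bounds inclusive).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence


@dataclass
class ReadPair:
    """One R1/R2 record pair with per-base Phred scores."""

    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: Sequence[int]
    r2_qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual):
            raise ValueError(f"{self.read_id}: R1 seq/qual length mismatch")
        if len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"{self.read_id}: R2 seq/qual length mismatch")


@dataclass
class QcThresholds:
    """Configurable filter bounds; defaults are the standard pipeline values."""

    min_r1_len: int = 66
    min_r2_len: int = 64
    min_mean_qual: float = 20.0
    max_r1_snf: float = 0.55  # drop if SNF >= this (inclusive)
    max_r2_snf: float = 0.80

    def __post_init__(self) -> None:
        if self.min_r1_len <= 0 or self.min_r2_len <= 0:
            raise ValueError("length thresholds must be positive")
        for v in (self.max_r1_snf, self.max_r2_snf):
            if not 0 < v <= 1:
                raise ValueError("SNF bounds must lie in (0, 1]")


@dataclass
class QcMetrics:
    """Per-reason drop accounting; reads_in = kept + sum(dropped)."""

    reads_in: int = 0
    reads_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def record(self, kept: bool, reason: str | None) -> None:
        self.reads_in += 1
        if kept:
            self.reads_kept += 1
        else:
            self.dropped[reason] += 1

    def conserved(self) -> bool:
        return self.reads_in == self.reads_kept + sum(self.dropped.values())

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_kept": self.reads_kept,
            "dropped": dict(self.dropped),
        }


def snf(seq: str) -> float:
    """Single-nucleotide frequency: max base count / read length."""
    if not seq:
        raise ValueError("empty sequence")
    return max(Counter(seq).values()) / len(seq)


def mean_quality(qual: Sequence[int]) -> float:
    """Arithmetic mean of Phred scores."""
    if len(qual) == 0:
        raise ValueError("empty quality sequence")
    return sum(qual) / len(qual)


def filter_read_pair(
    pair: ReadPair,
    th: QcThresholds | None = None,
    metrics: QcMetrics | None = None,
) -> tuple[bool, str | None]:
    """Apply the filters in fixed order; returns (kept, drop_reason).

    The first failing rule is recorded as the reason.  SNF bounds are
    inclusive: a read at exactly the bound is dropped.
    """
    th = th or QcThresholds()
    reason = None
    if len(pair.r1_seq) < th.min_r1_len or len(pair.r2_seq) < th.min_r2_len:
        reason = "length"
    elif (
        mean_quality(pair.r1_qual) < th.min_mean_qual
        or mean_quality(pair.r2_qual) < th.min_mean_qual
    ):
        reason = "quality"
    elif snf(pair.r1_seq) >= th.max_r1_snf:
        reason = "snf_r1"
    elif snf(pair.r2_seq) >= th.max_r2_snf:
        reason = "snf_r2"
    kept = reason is None
    if metrics is not None:
        metrics.record(kept, reason)
    return kept, reason
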