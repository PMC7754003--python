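"""Molecule collapsing and the two UMI error-correction schemes.

Valid read pairs sharing (cell label, UMI, feature) collapse into one raw
molecule whose depth is the number of contributing reads.

RSEC (recursive substitution error correction) repairs single-base UMI
substitutions within each (cell, feature) group: the lowest-depth UMI
with a strictly deeper Hamming-1 neighbor is merged into its deepest
such neighbor (ties broken lexicographically), depths add, and the graph
is re-evaluated — so a merged child's other neighbors recursively see the
grown parent.

DBEC (distribution-based error correction) removes residual artifact
molecules per feature: molecule depths are split at the threshold that
maximizes a two-component geometric likelihood (brute-force search over
all split points); if the two components' mean depths differ by at least
``min_fold_separation`` the low side is removed, otherwise the depth
distribution is considered unimodal and nothing is removed.  Features
with fewer than ``min_group`` molecules pass through untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

CellLabel = tuple[int, int, int]


@dataclass
class RawMolecule:
    """One (cell label, UMI, feature) group of reads."""

    cell_label: CellLabel
    umi: str
    feature: str
    depth: int

    def key(self) -> tuple:
        return (self.cell_label, self.umi, self.feature)


@dataclass
class CorrectionReport:
    n_molecules_in: int = 0
    n_rsec_merged: int = 0
    n_dbec_removed: int = 0
    per_feature_dbec_threshold: dict = field(default_factory=dict)

    @property
    def n_molecules_out(self) -> int:
        return self.n_molecules_in - self.n_rsec_merged - self.n_dbec_removed

    def as_dict(self) -> dict:
        return {
            "n_molecules_in": self.n_molecules_in,
            "n_rsec_merged": self.n_rsec_merged,
            "n_dbec_removed": self.n_dbec_removed,
            "n_molecules_out": self.n_molecules_out,
            "per_feature_dbec_threshold": dict(self.per_feature_dbec_threshold),
        }


def collapse_to_molecules(
    valid_pairs: Iterable[tuple[CellLabel, str, str]],
) -> list[RawMolecule]:
    """Collapse (cell_label, umi, feature) read records into raw molecules.

    Input items are either (cell label index triple, UMI string, feature
    name) triples, or (R1Annotation, AlignmentResult) pairs for valid
    reads; output depth sums to the number of inputs.
    """
    counts: dict[tuple, int] = {}
    for item in valid_pairs:
        if len(item) == 2 and hasattr(item[0], "cls_indices"):
            ann, aln = item
            key = (tuple(ann.cls_indices), ann.umi, aln.feature.name)
        else:
            cell, umi, feature = item
            key = (tuple(cell), umi, feature)
        counts[key] = counts.get(key, 0) + 1
    return [
        RawMolecule(cell_label=cell, umi=umi, feature=feat, depth=d)
        for (cell, umi, feat), d in sorted(counts.items())
    ]


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def rsec_merge_group(depths: dict[str, int]) -> dict[str, int]:
    """Apply the RSEC merge rule to one (cell, feature) UMI->depth group."""
    depths = dict(depths)
    while True:
        # children: UMIs with at least one strictly deeper Hamming-1 neighbor
        candidates = []
        umis = list(depths)
        for u in umis:
            du = depths[u]
            if any(_hamming1(u, v) and depths[v] > du for v in umis):
                candidates.append(u)
        if not candidates:
            return depths
        child = min(candidates, key=lambda u: (depths[u], u))
        parents = [
            v for v in depths if _hamming1(child, v) and depths[v] > depths[child]
        ]
        parent = min(parents, key=lambda v: (-depths[v], v))
        depths[parent] += depths.pop(child)


def rsec_correct(
    mols: Sequence[RawMolecule], report: Optional[CorrectionReport] = None
) -> tuple[list[RawMolecule], CorrectionReport]:
    """Merge single-substitution UMI errors into their parent molecules."""
    report = report or CorrectionReport()
    report.n_molecules_in = len(mols)
    groups: dict[tuple, dict[str, int]] = {}
    for m in mols:
        groups.setdefault((m.cell_label, m.feature), {})[m.umi] = m.depth
    out: list[RawMolecule] = []
    merged = 0
    for (cell, feature), depths in sorted(groups.items()):
        fixed = rsec_merge_group(depths)
        merged += len(depths) - len(fixed)
        out.extend(
            RawMolecule(cell_label=cell, umi=u, feature=feature, depth=d)
            for u, d in sorted(fixed.items())
        )
    report.n_rsec_merged = merged
    return out, report


def _geometric_loglik(depths: Sequence[int]) -> float:
    """Log-likelihood of depths under a geometric fit by moments (p=1/mean)."""
    n = len(depths)
    total = sum(depths)
    if n == 0:
        return 0.0
    mean = total / n
    if mean <= 1.0:
        return 0.0  # p=1: all mass at depth 1
    p = 1.0 / mean
    return (total - n) * math.log1p(-p) + n * math.log(p)


def dbec_split_threshold(depths: Sequence[int]) -> Optional[tuple[int, float, float]]:
    """Best split of depths into error/signal components.

    Returns (threshold t, mean_low, mean_high) maximizing the summed
    geometric log-likelihood of the two sides (depths <= t vs > t), or
    None when no split exists (fewer than two distinct depths).
    """
    depths = sorted(depths)
    distinct = sorted(set(depths))
    if len(distinct) < 2:
        return None
    best = None
    for t in distinct[:-1]:
        low = [d for d in depths if d <= t]
        high = [d for d in depths if d > t]
        ll = _geometric_loglik(low) + _geometric_loglik(high)
        if best is None or ll > best[0]:
            low_mean = sum(low) / len(low)
            high_mean = sum(high) / len(high)
            best = (ll, t, low_mean, high_mean)
    _, t, ml, mh = best
    return t, ml, mh


def dbec_filter(
    mols: Sequence[RawMolecule],
    min_group: int = 20,
    min_fold_separation: float = 4.0,
    report: Optional[CorrectionReport] = None,
) -> tuple[list[RawMolecule], CorrectionReport]:
    """Remove low-depth artifact molecules per feature (see module docs)."""
    report = report or CorrectionReport()
    if report.n_molecules_in == 0:
        report.n_molecules_in = len(mols)
    by_feature: dict[str, list[RawMolecule]] = {}
    for m in mols:
        by_feature.setdefault(m.feature, []).append(m)
    out: list[RawMolecule] = []
    removed = 0
    for feature, group in sorted(by_feature.items()):
        if len(group) < min_group:
            out.extend(group)
            continue
        split = dbec_split_threshold([m.depth for m in group])
        if split is None:
            out.extend(group)
            continue
        t, mean_low, mean_high = split
        if mean_low > 0 and mean_high / mean_low >= min_fold_separation:
            survivors = [m for m in group if m.depth > t]
            removed += len(group) - len(survivors)
            report.per_feature_dbec_threshold[feature] = t
            out.extend(survivors)
        else:
            out.extend(group)
    report.n_dbec_removed = removed
    return out, report
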