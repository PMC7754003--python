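"""Targeted panel reference: feature sequences plus a k-mer seed index.

A panel holds the amplicon sequences the assay targets — a block of mRNA
targets, a block of antibody-tag (AbSeq) sequences — together with decoy
sequences (e.g. a phiX174 fragment) used only to discard contaminating
reads.  Decoys participate in alignment but never appear in count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam

VALID_FEATURE_TYPES = ("mrna", "abtag", "decoy")

#: Shortest alignment the downstream validity rule can accept is >60 matched
#: or mismatched columns, so countable features must be at least 61 nt.
MIN_COUNTABLE_LENGTH = 61

_ALLOWED = set("ACGTN")


@dataclass(frozen=True)
class PanelFeature:
    """One reference sequence in the panel."""

    name: str
    sequence: str
    feature_type: str = "mrna"

    def __post_init__(self) -> None:
        if self.feature_type not in VALID_FEATURE_TYPES:
            raise ValueError(
                f"feature_type must be one of {VALID_FEATURE_TYPES}, "
                f"got {self.feature_type!r}"
            )
        seq = self.sequence.upper()
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(f"{self.name}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.feature_type != "decoy" and len(seq) < MIN_COUNTABLE_LENGTH:
            raise ValueError(
                f"{self.name}: countable features must be >= "
                f"{MIN_COUNTABLE_LENGTH} nt (got {len(seq)})"
            )

    @property
    def countable(self) -> bool:
        return self.feature_type != "decoy"


class PanelReference:
    """Ordered panel features plus an exact k-mer index for seeding.

    The index maps every k-mer of every feature to ``(feature_idx, offset)``
    postings.  k-mers containing N are never indexed and never match.
    """

    def __init__(self, features: Iterable[PanelFeature]):
        self.features: list[PanelFeature] = list(features)
        if not self.features:
            raise ValueError("empty panel")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dup}")
        self.k: int | None = None
        self._index: dict[str, list[tuple[int, int]]] = {}

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, i: int) -> PanelFeature:
        return self.features[i]

    @property
    def countable_features(self) -> list[PanelFeature]:
        return [f for f in self.features if f.countable]

    def feature_by_name(self, name: str) -> PanelFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    # -- indexing -----------------------------------------------------------

    def build_index(self, k: int = 18) -> "PanelReference":
        if not 8 <= k <= 32:
            raise ValueError(f"k must be in [8, 32], got {k}")
        shortest = min(len(f.sequence) for f in self.features)
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds shortest feature length {shortest}"
            )
        index: dict[str, list[tuple[int, int]]] = {}
        for fi, feat in enumerate(self.features):
            seq = feat.sequence
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((fi, off))
        self.k = k
        self._index = index
        return self

    @property
    def indexed(self) -> bool:
        return self.k is not None

    def query(self, kmer: str) -> list[tuple[int, int]]:
        """Postings ``(feature_idx, offset)`` for an exact k-mer."""
        if not self.indexed:
            raise RuntimeError("panel index not built; call build_index()")
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        return self._index.get(kmer, [])

    def n_postings(self, feature_idx: int) -> int:
        return sum(
            1
            for posts in self._index.values()
            for fi, _ in posts
            if fi == feature_idx
        )


def load_panel(
    fasta_path: str | Path,
    feature_type_map: Mapping[str, str] | None = None,
    default_type: str = "mrna",
) -> PanelReference:
    """Read a multi-record FASTA into a :class:`PanelReference`.

    ``feature_type_map`` assigns each record name a type in
    {mrna, abtag, decoy}; unmapped records get ``default_type``.
    Sequences are uppercased; characters outside A/C/G/T/N are rejected.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    feature_type_map = dict(feature_type_map or {})
    features = []
    with pysam.FastxFile(str(fasta_path)) as fh:
        for rec in fh:
            ftype = feature_type_map.get(rec.name, default_type)
            features.append(
                PanelFeature(name=rec.name, sequence=rec.sequence, feature_type=ftype)
            )
    return PanelReference(features)


def load_feature_type_map(tsv_path: str | Path) -> dict[str, str]:
    """Two-column TSV ``name<TAB>type`` -> mapping."""
    out: dict[str, str] = {}
    for line in Path(tsv_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, ftype = line.split("\t")[:2]
        out[name] = ftype
    return out


def build_kmer_index(panel: PanelReference, k: int = 18) -> PanelReference:
    """Functional alias for :meth:`PanelReference.build_index`."""
    return panel.build_index(k)
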