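"""R1 annotation: cell-label recovery, UMI extraction, poly(T) check.

Annotation runs three passes of increasing leniency:

1. *perfect* — all three CLS windows match their whitelist verbatim at the
   designed offsets;
2. *substitution* — each unmatched window is assigned to the unique
   whitelist entry within Hamming distance 1 (the distance-3 whitelist
   design makes this unambiguous; ties or distance >= 2 leave the section
   unresolved and the read invalid — never guess);
3. *indel* — exactly one single-base insertion or deletion somewhere in
   the label region is hypothesized: both +-1 shifted frames are re-tested
   from each of the five segment boundaries, and a frame in which all
   three sections resolve at Hamming <= 1 is a candidate.  The UMI is
   then read from the eight bases immediately after the shifted CLS3.

Passes 2 and 3 are scored jointly: every resolving hypothesis (the
unshifted frame or any shifted frame) is costed by its total implied
error count (substitutions + indels) and the cheapest wins.  When
hypotheses naming *different* label triples tie at minimal cost the read
is dropped rather than guessed — a shifted window is effectively a
random 9-mer and occasionally falls inside some entry's Hamming-1 ball,
so accepting the first resolving frame would misassign a small fraction
of indel reads.

A read with a recovered label is only *valid* if its UMI contains no N
and the poly(T) check passes (more than 6 of the 8 bases after the UMI
are T, i.e. at least 7 of 8; the window shrinks on short reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .whitelists import (
    CLS1_START,
    CLS2_START,
    CLS3_START,
    CLS_LEN,
    MIN_R1_LEN,
    UMI_LEN,
    UMI_START,
    Whitelists,
)

SECTION_STARTS = (CLS1_START, CLS2_START, CLS3_START)

# Boundaries between the five label segments (CLS1|L1|CLS2|L2|CLS3); a
# one-base indel at or after a boundary shifts all downstream offsets.
SEGMENT_BOUNDARIES = (9, 21, 30, 43, 52)

AMBIGUOUS = -1


@dataclass
class R1Annotation:
    """Result of label recovery on one R1 read."""

    cls_indices: Optional[tuple[int, int, int]]
    umi: Optional[str]
    polyt_pass: bool
    status: str  # perfect | substitution_corrected | indel_corrected | invalid
    umi_start: Optional[int] = None
    reason: Optional[str] = None

    @property
    def valid(self) -> bool:
        return (
            self.status != "invalid"
            and self.umi is not None
            and "N" not in self.umi
            and self.polyt_pass
        )


class _SectionMatcher:
    """O(1) lookup of a 9-mer against one whitelist at Hamming distance <= 1.

    Exploits the distance >= 3 design: the radius-1 Hamming balls around
    entries are disjoint, so a single dict of every entry plus its 27
    one-substitution variants resolves any query uniquely.
    """

    def __init__(self, entries: list[str]):
        self.exact = {s: i for i, s in enumerate(entries)}
        ball: dict[str, int] = dict(self.exact)
        for i, s in enumerate(entries):
            for pos in range(len(s)):
                for b in "ACGT":
                    if b == s[pos]:
                        continue
                    variant = s[:pos] + b + s[pos + 1 :]
                    prev = ball.setdefault(variant, i)
                    if prev != i:  # unreachable for distance >= 3 lists
                        ball[variant] = AMBIGUOUS
        self.ball = ball

    def match(self, window: str) -> tuple[Optional[int], int]:
        """Return (whitelist index or None, distance 0/1)."""
        hit = self.exact.get(window)
        if hit is not None:
            return hit, 0
        hit = self.ball.get(window)
        if hit is None or hit == AMBIGUOUS:
            return None, 2
        return hit, 1


class BarcodeAnnotator:
    """Reusable annotator; builds the per-whitelist matchers once."""

    def __init__(self, wl: Whitelists, polyt_max_non_t: int = 1):
        self.wl = wl
        self.matchers = tuple(_SectionMatcher(lst) for lst in wl.lists)
        self.polyt_max_non_t = polyt_max_non_t

    # -- passes --------------------------------------------------------------

    def _match_frame(
        self, seq: str, starts: tuple[int, int, int]
    ) -> tuple[Optional[tuple[int, int, int]], int]:
        """Match all three sections at the given starts; (triple, n_subs)."""
        idxs = []
        n_subs = 0
        for start, matcher in zip(starts, self.matchers):
            window = seq[start : start + CLS_LEN]
            if len(window) < CLS_LEN:
                return None, 0
            hit, dist = matcher.match(window)
            if hit is None:
                return None, 0
            idxs.append(hit)
            n_subs += dist
        return (idxs[0], idxs[1], idxs[2]), n_subs

    def annotate(self, seq: str) -> R1Annotation:
        if len(seq) < MIN_R1_LEN:
            raise ValueError(f"R1 shorter than {MIN_R1_LEN} nt: {len(seq)}")
        seq = seq.upper()

        # Pass 1: perfect matches at the designed offsets
        triple = tuple(
            m.exact.get(seq[s : s + CLS_LEN])
            for s, m in zip(SECTION_STARTS, self.matchers)
        )
        if None not in triple:
            return self._finish(seq, triple, UMI_START, "perfect")

        # Passes 2+3: score every resolving hypothesis by implied error
        # count (substitutions + indels) and keep the cheapest.
        # hypotheses: (cost, triple, umi_start, status)
        hypotheses: list[tuple[int, tuple, int, str]] = []
        triple2, n_subs = self._match_frame(seq, SECTION_STARTS)
        if triple2 is not None:
            hypotheses.append((n_subs, triple2, UMI_START, "substitution_corrected"))
        for shift in (1, -1):
            for boundary in SEGMENT_BOUNDARIES:
                starts = tuple(
                    s + shift if s >= boundary else s for s in SECTION_STARTS
                )
                triple3, n_subs3 = self._match_frame(seq, starts)
                if triple3 is not None:
                    hypotheses.append(
                        (1 + n_subs3, triple3, UMI_START + shift, "indel_corrected")
                    )
        if hypotheses:
            best_cost = min(h[0] for h in hypotheses)
            best = [h for h in hypotheses if h[0] == best_cost]
            triples = {h[1] for h in best}
            if len(triples) == 1:
                _, triple_b, umi_start, status = best[0]
                return self._finish(seq, triple_b, umi_start, status)
            return R1Annotation(
                cls_indices=None,
                umi=None,
                polyt_pass=False,
                status="invalid",
                reason="cls_ambiguous",
            )

        return R1Annotation(
            cls_indices=None,
            umi=None,
            polyt_pass=False,
            status="invalid",
            reason="cls_unresolved",
        )

    def _finish(
        self, seq: str, triple: tuple, umi_start: int, status: str
    ) -> R1Annotation:
        umi = seq[umi_start : umi_start + UMI_LEN]
        if len(umi) < UMI_LEN or "N" in umi:
            return R1Annotation(
                cls_indices=triple,
                umi=umi or None,
                polyt_pass=False,
                status="invalid",
                umi_start=umi_start,
                reason="umi_n" if umi and "N" in umi else "umi_truncated",
            )
        ptpass = check_polyt(seq, umi_start + UMI_LEN, max_non_t=self.polyt_max_non_t)
        return R1Annotation(
            cls_indices=triple,
            umi=umi,
            polyt_pass=ptpass,
            status=status,
            umi_start=umi_start,
            reason=None if ptpass else "polyt",
        )


def check_polyt(seq: str, umi_end: int, max_non_t: int = 1) -> bool:
    """Poly(T) verdict on the window after the UMI.

    With the full 8-base window the default requires at least 7 Ts
    ("over 6 out of 8").  Shorter windows (truncated reads) shrink
    proportionally but windows under 6 bases always fail.
    """
    if umi_end > len(seq):
        raise ValueError("umi_end beyond end of read")
    window = seq[umi_end : umi_end + 8]
    w = len(window)
    if w < 6:
        return False
    return (w - window.count("T")) <= max_non_t


_annotator_cache: dict[int, BarcodeAnnotator] = {}


def annotate_r1(seq: str, wl: Whitelists) -> R1Annotation:
    """Annotate one R1 read (convenience wrapper; caches the matcher)."""
    key = id(wl)
    ann = _annotator_cache.get(key)
    if ann is None or ann.wl is not wl:
        ann = BarcodeAnnotator(wl)
        _annotator_cache.clear()
        _annotator_cache[key] = ann
    return ann.annotate(seq)
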