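"""R2 panel alignment: seed-and-extend, ungapped, with validity rules.

Seeds of length k are taken at read offsets 0..4 (so an alignment that
begins within the first five read bases is always seedable) and at every
k/2 stride thereafter.  Each (feature, diagonal) candidate is extended
ungapped over the full read/feature overlap; the score is
matches - mismatches, and a candidate is viable when its mismatch
fraction over the aligned span is at most ``max_mismatch_frac``.

A read is *valid* only if (in fixed order): it has no viable decoy
alignment; exactly one panel feature scores within ``margin`` of the
best; the alignment starts within the first five read bases (0-based
offset <= 4); and the aligned span exceeds 60 columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .panel import PanelFeature, PanelReference


@dataclass
class AlignmentResult:
    feature: Optional[PanelFeature]
    read_start: int
    aln_len: int
    score: int
    n_candidates: int
    decoy_hit: bool
    valid: bool = False
    reason: Optional[str] = None


def _extend(seq: str, feat_seq: str, diag: int) -> tuple[int, int, int, int]:
    """Ungapped extension on one diagonal (feature_off - read_off).

    Returns (read_start, aln_len, mismatches, score); aln_len may be 0
    when the diagonal has no overlap.
    """
    rs = max(0, -diag)
    re = min(len(seq), len(feat_seq) - diag)
    if re <= rs:
        return rs, 0, 0, 0
    sub_r = seq[rs:re]
    sub_f = feat_seq[rs + diag : re + diag]
    mism = sum(a != b or a == "N" for a, b in zip(sub_r, sub_f))
    aln_len = re - rs
    return rs, aln_len, mism, aln_len - 2 * mism


def align_r2(
    seq: str,
    panel: PanelReference,
    max_mismatch_frac: float = 0.1,
    margin: int = 3,
) -> AlignmentResult:
    """Align one R2 read against the indexed panel."""
    if not panel.indexed:
        raise RuntimeError("panel index not built; call build_index() first")
    seq = seq.upper()
    k = panel.k
    assert k is not None

    offsets = [o for o in range(5) if o + k <= len(seq)]
    o = 4 + k // 2
    while o + k <= len(seq):
        offsets.append(o)
        o += k // 2

    candidates: set[tuple[int, int]] = set()
    for off in offsets:
        for fi, f_off in panel.query(seq[off : off + k]):
            candidates.add((fi, f_off - off))

    # best viable alignment per feature
    best_per_feature: dict[int, tuple[int, int, int]] = {}  # fi -> (score, rs, aln_len)
    decoy_hit = False
    for fi, diag in sorted(candidates):
        feat = panel[fi]
        rs, aln_len, mism, score = _extend(seq, feat.sequence, diag)
        if aln_len == 0 or mism / aln_len > max_mismatch_frac:
            continue
        if not feat.countable:
            decoy_hit = True
            continue
        prev = best_per_feature.get(fi)
        # deterministic tie-break: higher score, then earlier read start
        if prev is None or (score, -rs) > (prev[0], -prev[1]):
            best_per_feature[fi] = (score, rs, aln_len)

    if not best_per_feature:
        res = AlignmentResult(
            feature=None,
            read_start=0,
            aln_len=0,
            score=0,
            n_candidates=0,
            decoy_hit=decoy_hit,
        )
        return validate(res)

    best_fi = min(
        best_per_feature, key=lambda fi: (-best_per_feature[fi][0], fi)
    )
    best_score, rs, aln_len = best_per_feature[best_fi]
    n_candidates = sum(
        1 for s, _, _ in best_per_feature.values() if s >= best_score - margin
    )
    res = AlignmentResult(
        feature=panel[best_fi],
        read_start=rs,
        aln_len=aln_len,
        score=best_score,
        n_candidates=n_candidates,
        decoy_hit=decoy_hit,
    )
    return validate(res)


def validate(
    aln: AlignmentResult, max_start: int = 4, min_aln_len: int = 61
) -> AlignmentResult:
    """Apply the four validity rules in fixed order; sets valid/reason.

    Order: decoy, uniqueness, start position, alignment length.  A viable
    decoy alignment invalidates the read outright, even if a panel
    feature scores higher.
    """
    if aln.decoy_hit:
        aln.valid, aln.reason = False, "decoy"
    elif aln.n_candidates == 0:
        aln.valid, aln.reason = False, "no_alignment"
    elif aln.n_candidates > 1:
        aln.valid, aln.reason = False, "not_unique"
    elif aln.read_start > max_start:
        aln.valid, aln.reason = False, "start"
    elif aln.aln_len < min_aln_len:
        aln.valid, aln.reason = False, "aln_len"
    else:
        aln.valid, aln.reason = True, None
    return aln
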