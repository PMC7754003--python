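"""Cell-label whitelists and the R1 read anatomy.

An R1 read encodes its cell of origin in three 9-nt cell label sections
(CLS1/CLS2/CLS3), each drawn from a 96-entry whitelist, separated by two
fixed linkers (L1, 12 nt; L2, 13 nt) so the sections land at 1-based
positions 1-9, 22-30 and 44-52.  The 8-nt UMI follows CLS3 at 53-60, then
a poly(T) tail.  Whitelists keep a minimum intra-list Hamming distance of
3 so a single substitution is always unambiguously correctable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

CLS_LEN = 9
L1_LEN = 12
L2_LEN = 13
UMI_LEN = 8
N_ENTRIES = 96
MIN_INTRA_DISTANCE = 3

# 0-based half-open section offsets (1-based 1-9, 22-30, 44-52, UMI 53-60)
CLS1_START = 0
CLS2_START = CLS1_START + CLS_LEN + L1_LEN      # 21
CLS3_START = CLS2_START + CLS_LEN + L2_LEN      # 43
UMI_START = CLS3_START + CLS_LEN                # 52
UMI_END = UMI_START + UMI_LEN                   # 60
MIN_R1_LEN = 66

_BASES = "ACGT"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class Whitelists:
    """Three 96-entry CLS whitelists plus the two fixed linkers."""

    cls1: list[str]
    cls2: list[str]
    cls3: list[str]
    linker1: str
    linker2: str

    def __post_init__(self) -> None:
        for name, lst in (("cls1", self.cls1), ("cls2", self.cls2), ("cls3", self.cls3)):
            if len(lst) != N_ENTRIES:
                raise ValueError(f"{name}: expected {N_ENTRIES} entries, got {len(lst)}")
            if any(len(s) != CLS_LEN for s in lst):
                raise ValueError(f"{name}: all entries must be {CLS_LEN} nt")
        if len(self.linker1) != L1_LEN or len(self.linker2) != L2_LEN:
            raise ValueError(f"linkers must be {L1_LEN} and {L2_LEN} nt")

    @property
    def lists(self) -> tuple[list[str], list[str], list[str]]:
        return (self.cls1, self.cls2, self.cls3)

    def min_intra_distance(self) -> int:
        """Smallest pairwise Hamming distance within any of the three lists."""
        best = CLS_LEN
        for lst in self.lists:
            arr = np.frombuffer("".join(lst).encode(), dtype=np.uint8)
            arr = arr.reshape(N_ENTRIES, CLS_LEN)
            d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
            np.fill_diagonal(d, CLS_LEN)
            best = min(best, int(d.min()))
        return best

    def label_sequence(self, triple: tuple[int, int, int]) -> str:
        """The 52-nt label region for a (cls1, cls2, cls3) index triple."""
        i, j, k = triple
        return (
            self.cls1[i] + self.linker1 + self.cls2[j] + self.linker2 + self.cls3[k]
        )

    # -- persistence: three 96-line text files -------------------------------

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, lst in zip(("cls1", "cls2", "cls3"), self.lists):
            p = outdir / f"{name}.txt"
            p.write_text("\n".join(lst) + "\n")
            paths.append(p)
        (outdir / "linkers.txt").write_text(f"{self.linker1}\n{self.linker2}\n")
        paths.append(outdir / "linkers.txt")
        return paths

    @classmethod
    def read(cls, indir: str | Path) -> "Whitelists":
        indir = Path(indir)
        lists = [
            (indir / f"{name}.txt").read_text().split()
            for name in ("cls1", "cls2", "cls3")
        ]
        l1, l2 = (indir / "linkers.txt").read_text().split()
        return cls(*lists, linker1=l1, linker2=l2)


def _sample_distant_set(rng: np.random.Generator, max_attempts: int = 200_000) -> list[str]:
    """Rejection-sample 96 9-mers at pairwise Hamming distance >= 3."""
    chosen: list[str] = []
    for _ in range(max_attempts):
        cand = "".join(_BASES[b] for b in rng.integers(0, 4, CLS_LEN))
        if all(_hamming(cand, c) >= MIN_INTRA_DISTANCE for c in chosen):
            chosen.append(cand)
            if len(chosen) == N_ENTRIES:
                return chosen
    raise RuntimeError(
        f"failed to sample {N_ENTRIES} sequences at distance "
        f">= {MIN_INTRA_DISTANCE} in {max_attempts} attempts"
    )


def generate_whitelists(seed: int) -> Whitelists:
    """Deterministically generate the three whitelists and linkers.

    The vendor's actual 96-sequence lists are proprietary, so lists
    satisfying the same design constraints are synthesized from the seed.
    """
    rng = np.random.default_rng(seed)
    lists = [_sample_distant_set(rng) for _ in range(3)]
    linker1 = "".join(_BASES[b] for b in rng.integers(0, 4, L1_LEN))
    linker2 = "".join(_BASES[b] for b in rng.integers(0, 4, L2_LEN))
    return Whitelists(*lists, linker1=linker1, linker2=linker2)
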