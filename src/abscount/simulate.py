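"""Synthetic paired-read generator with ground truth.

Emulates the bead-based single-cell multi-omics library: every R1 is
CLS1+L1+CLS2+L2+CLS3 (52 nt) + 8-nt UMI + poly(T), every R2 a substring
of a panel feature.  Two label populations are simulated — true cells
with lognormal read depth and ambient "noise" labels at much lower
depth — so the downstream knee-calling step has a real inflection to
find.  Configurable error processes corrupt reads after synthesis:

* CLS substitutions (one random base inside one of the three CLS windows),
* single-base insertions/deletions inside the linker regions — the
  oligo-synthesis error the frame-shift recovery pass is designed for,
* single UMI substitutions (matching RSEC's Hamming-1 repair model),
* single R2 substitutions, ambient decoy-origin R2s, and a low-quality
  read fraction (constant Q15) to exercise the mean-quality filter.

Every injected error is logged in the ground-truth ledger together with
the read's true origin, so recovery rates are measurable exactly.  UMIs
are drawn uniformly from the 4^8 space but without replacement within a
(cell, feature) group: a within-group collision is indistinguishable
from a single molecule and would make even an error-free run ambiguous.

A cohort wrapper simulates a case and a control group sharing whitelists
and panel but with shifted subpopulation proportions; subpopulation
membership is the truth "cluster" column consumed by the proportion
statistics.
"""

from __future__ import annotations

import gzip
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import serialize_label
from .panel import PanelReference
from .whitelists import (
    CLS1_START,
    CLS2_START,
    CLS3_START,
    CLS_LEN,
    N_ENTRIES,
    UMI_LEN,
    UMI_START,
    Whitelists,
    generate_whitelists,
)

_BASES = "ACGT"

# linker regions on R1, where indels are injected
_L1_SPAN = (CLS1_START + CLS_LEN, CLS2_START)   # [9, 21)
_L2_SPAN = (CLS2_START + CLS_LEN, CLS3_START)   # [30, 43)
_CLS_POSITIONS = [
    p
    for start in (CLS1_START, CLS2_START, CLS3_START)
    for p in range(start, start + CLS_LEN)
]
_LINKER_POSITIONS = list(range(*_L1_SPAN)) + list(range(*_L2_SPAN))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sequencing run."""

    n_cells: int = 200
    n_noise_labels: int = 2000
    #: (mu, sigma) of reads per true cell, natural-log scale
    cell_depth_lognormal: tuple[float, float] = (math.log(250.0), 0.25)
    #: (mu, sigma) of reads per ambient noise label
    noise_depth_lognormal: tuple[float, float] = (math.log(10.0), 0.5)
    reads_per_molecule: int = 5
    #: per-feature relative expression; None = uniform over countable features
    expression_rates: Optional[dict[str, float]] = None
    subpop_proportions: dict[str, float] = field(default_factory=lambda: {"0": 1.0})
    cls_substitution_rate: float = 0.0
    cls_indel_rate: float = 0.0
    umi_substitution_rate: float = 0.0
    r2_substitution_rate: float = 0.0
    ambient_decoy_rate: float = 0.0
    bad_read_fraction: float = 0.0
    quality_phred: int = 30
    bad_quality_phred: int = 15
    r1_length: int = 70   # 52 label + 8 UMI + 10 poly(T)
    r2_length: int = 70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for name in (
            "cls_substitution_rate",
            "cls_indel_rate",
            "umi_substitution_rate",
            "r2_substitution_rate",
            "ambient_decoy_rate",
            "bad_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = sum(self.subpop_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subpopulation proportions sum to {total}, not 1")
        if self.reads_per_molecule < 1:
            raise ValueError("reads_per_molecule must be >= 1")
        if self.r1_length < UMI_START + UMI_LEN + 6:
            raise ValueError("r1_length too short for a poly(T) window")


@dataclass
class GroundTruth:
    """Simulator truth: cell set, molecule counts, injected-error ledger."""

    group: str
    true_cell_labels: list[tuple[int, int, int]]
    noise_labels: list[tuple[int, int, int]]
    truth_matrix: pd.DataFrame          # true cells x countable features
    subpop_of_cell: dict[str, str]      # serialized label -> subpopulation
    error_ledger: list[dict] = field(default_factory=list)
    n_reads: int = 0

    @property
    def true_label_set(self) -> set:
        return set(self.true_cell_labels)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cells": outdir / f"{self.group}.truth_cells.tsv",
            "counts": outdir / f"{self.group}.truth_counts.tsv",
            "ledger": outdir / f"{self.group}.error_ledger.json",
        }
        with open(paths["cells"], "w") as fh:
            fh.write("cell_id\tsubpop\n")
            for label in self.true_cell_labels:
                cid = serialize_label(label)
                fh.write(f"{cid}\t{self.subpop_of_cell[cid]}\n")
        self.truth_matrix.to_csv(paths["counts"], sep="\t")
        with open(paths["ledger"], "w") as fh:
            json.dump(self.error_ledger, fh)
        return paths


def _random_triples(
    rng: np.random.Generator, n: int, exclude: set[tuple[int, int, int]]
) -> list[tuple[int, int, int]]:
    chosen: list[tuple[int, int, int]] = []
    seen = set(exclude)
    while len(chosen) < n:
        t = tuple(int(x) for x in rng.integers(0, N_ENTRIES, 3))
        if t not in seen:
            seen.add(t)
            chosen.append(t)
    return chosen


def _random_umi(rng: np.random.Generator) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, UMI_LEN))


def _substitute(rng: np.random.Generator, seq: str, pos: int) -> str:
    old = seq[pos]
    choices = [b for b in _BASES if b != old]
    return seq[:pos] + choices[rng.integers(0, 3)] + seq[pos + 1 :]


def simulate_run(
    config: SimulationConfig,
    whitelists: Whitelists,
    panel: PanelReference,
    outdir: str | Path,
    group: str = "sample",
    emit_fastq: bool = True,
) -> tuple[Optional[Path], Optional[Path], GroundTruth]:
    """Simulate one run; returns (r1_fastq, r2_fastq, truth).

    FASTQ output is gzipped and byte-identical for identical
    config+seed.  With ``emit_fastq=False`` only the ground truth is
    generated (useful when only truth-level quantities are needed).
    """
    countable = panel.countable_features
    if not countable:
        raise ValueError("panel has no countable features")
    decoys = [f for f in panel.features if not f.countable]
    if config.ambient_decoy_rate > 0 and not decoys:
        raise ValueError("ambient_decoy_rate > 0 but the panel has no decoys")

    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    feat_names = [f.name for f in countable]
    if config.expression_rates is None:
        weights = np.full(len(countable), 1.0 / len(countable))
    else:
        w = np.array([config.expression_rates.get(n, 0.0) for n in feat_names])
        if w.sum() <= 0:
            raise ValueError("expression_rates assign zero weight to the panel")
        weights = w / w.sum()

    true_labels = _random_triples(rng, config.n_cells, exclude=set())
    noise_labels = _random_triples(
        rng, config.n_noise_labels, exclude=set(true_labels)
    )
    subpops = sorted(config.subpop_proportions)
    probs = np.array([config.subpop_proportions[s] for s in subpops])
    assign = rng.choice(len(subpops), size=config.n_cells, p=probs)
    subpop_of_cell = {
        serialize_label(lab): subpops[a] for lab, a in zip(true_labels, assign)
    }

    truth = np.zeros((config.n_cells, len(countable)), dtype=np.int64)
    ledger: list[dict] = []
    rpm = config.reads_per_molecule

    r1_path = outdir / f"{group}_R1.fastq.gz" if emit_fastq else None
    r2_path = outdir / f"{group}_R2.fastq.gz" if emit_fastq else None
    def _open_det(path: Path):
        # mtime=0 keeps same-seed reruns byte-identical
        return io.TextIOWrapper(
            gzip.GzipFile(str(path), "wb", mtime=0), encoding="ascii"
        )

    r1_fh = _open_det(r1_path) if emit_fastq else None
    r2_fh = _open_det(r2_path) if emit_fastq else None

    qual_good_r1 = chr(config.quality_phred + 33) * config.r1_length
    qual_bad_r1 = chr(config.bad_quality_phred + 33) * config.r1_length
    serial = 0
    try:
        populations = [
            (true_labels, config.cell_depth_lognormal, True),
            (noise_labels, config.noise_depth_lognormal, False),
        ]
        for labels, (mu, sigma), is_cell in populations:
            for li, label in enumerate(labels):
                depth = float(rng.lognormal(mu, sigma))
                n_mol = max(1, int(round(depth / rpm)))
                feats = rng.choice(len(countable), size=n_mol, p=weights)
                if is_cell:
                    truth[li] += np.bincount(feats, minlength=len(countable))
                if not emit_fastq:
                    continue
                label_seq = whitelists.label_sequence(label)
                used_umis: dict[int, set[str]] = {}
                for fi in feats:
                    fi = int(fi)
                    used = used_umis.setdefault(fi, set())
                    umi = _random_umi(rng)
                    while umi in used:
                        umi = _random_umi(rng)
                    used.add(umi)
                    feat = countable[fi]
                    for _ in range(rpm):
                        serial += 1
                        read_id = f"{group}:{serial:08d}"
                        errors: list[str] = []
                        r1 = label_seq + umi
                        r1 = r1 + "T" * (config.r1_length - len(r1))
                        umi_obs = umi

                        if (
                            config.cls_substitution_rate > 0
                            and rng.random() < config.cls_substitution_rate
                        ):
                            pos = _CLS_POSITIONS[
                                rng.integers(0, len(_CLS_POSITIONS))
                            ]
                            r1 = _substitute(rng, r1, pos)
                            errors.append("cls_substitution")
                        if (
                            config.umi_substitution_rate > 0
                            and rng.random() < config.umi_substitution_rate
                        ):
                            pos = UMI_START + int(rng.integers(0, UMI_LEN))
                            r1 = _substitute(rng, r1, pos)
                            umi_obs = r1[UMI_START : UMI_START + UMI_LEN]
                            errors.append("umi_substitution")
                        if (
                            config.cls_indel_rate > 0
                            and rng.random() < config.cls_indel_rate
                        ):
                            pos = _LINKER_POSITIONS[
                                rng.integers(0, len(_LINKER_POSITIONS))
                            ]
                            if rng.random() < 0.5:
                                base = _BASES[rng.integers(0, 4)]
                                r1 = (r1[:pos] + base + r1[pos:])[: config.r1_length]
                                errors.append("cls_insertion")
                            else:
                                r1 = r1[:pos] + r1[pos + 1 :] + "T"
                                errors.append("cls_deletion")

                        # R2: substring of the feature (or a decoy, at the
                        # ambient rate), starting at a random valid offset
                        if (
                            config.ambient_decoy_rate > 0
                            and rng.random() < config.ambient_decoy_rate
                        ):
                            src = decoys[rng.integers(0, len(decoys))]
                            errors.append("ambient_decoy")
                        else:
                            src = feat
                        r2_len = min(config.r2_length, len(src.sequence))
                        max_off = len(src.sequence) - r2_len
                        off = int(rng.integers(0, max_off + 1)) if max_off else 0
                        r2 = src.sequence[off : off + r2_len]
                        if (
                            config.r2_substitution_rate > 0
                            and rng.random() < config.r2_substitution_rate
                        ):
                            r2 = _substitute(rng, r2, int(rng.integers(0, len(r2))))
                            errors.append("r2_substitution")

                        bad = (
                            config.bad_read_fraction > 0
                            and rng.random() < config.bad_read_fraction
                        )
                        if bad:
                            errors.append("low_quality")
                        q1 = qual_bad_r1 if bad else qual_good_r1
                        q2 = (
                            chr(
                                (
                                    config.bad_quality_phred
                                    if bad
                                    else config.quality_phred
                                )
                                + 33
                            )
                            * len(r2)
                        )
                        r1_fh.write(f"@{read_id}\n{r1}\n+\n{q1}\n")
                        r2_fh.write(f"@{read_id}\n{r2}\n+\n{q2}\n")
                        if errors:
                            ledger.append(
                                {
                                    "read_id": read_id,
                                    "errors": errors,
                                    "cell_label": list(label),
                                    "is_cell": is_cell,
                                    "umi_true": umi,
                                    "umi_observed": umi_obs,
                                    "feature": feat.name,
                                }
                            )
    finally:
        if r1_fh:
            r1_fh.close()
        if r2_fh:
            r2_fh.close()

    truth_df = pd.DataFrame(
        truth,
        index=[serialize_label(l) for l in true_labels],
        columns=feat_names,
    ).sort_index()
    gt = GroundTruth(
        group=group,
        true_cell_labels=true_labels,
        noise_labels=noise_labels,
        truth_matrix=truth_df,
        subpop_of_cell=subpop_of_cell,
        error_ledger=ledger,
        n_reads=serial,
    )
    return r1_path, r2_path, gt


# Default cohort conditions mirror the two-group design with a large
# case-enriched subpopulation (30.35% vs 9.38%) and a small one
# (2.11% vs 0.62%), remainder in a background pool.
CASE_SUBPOPS = {"0": 0.3035, "11": 0.0211, "rest": 0.6754}
CONTROL_SUBPOPS = {"0": 0.0938, "11": 0.0062, "rest": 0.9000}


def simulate_cohort(
    config_case: SimulationConfig,
    config_control: SimulationConfig,
    whitelists: Whitelists,
    panel: PanelReference,
    outdir: str | Path,
    emit_fastq: bool = True,
) -> dict:
    """Simulate a case and a control run sharing whitelists and panel.

    Returns ``{"case": (r1, r2, truth), "control": ..., "assignments": df}``
    where the assignment table has one row per true cell with its group
    and truth subpopulation (the "cluster" column downstream statistics
    consume).
    """
    results = {}
    frames = []
    for group, cfg in (("case", config_case), ("control", config_control)):
        r1, r2, gt = simulate_run(
            cfg, whitelists, panel, outdir, group=group, emit_fastq=emit_fastq
        )
        results[group] = (r1, r2, gt)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{group}:{c}" for c in gt.subpop_of_cell],
                    "group": group,
                    "cluster": list(gt.subpop_of_cell.values()),
                }
            )
        )
    results["assignments"] = pd.concat(frames, ignore_index=True)
    return results


def simulate_label_depths(
    n_cells: int,
    cell_depth_lognormal: tuple[float, float],
    n_noise_labels: int,
    noise_depth_lognormal: tuple[float, float],
    seed: int,
) -> tuple[dict[str, int], set[str]]:
    """Reads-per-label draw only (for knee-calling studies).

    Returns (label -> read count, set of true-cell labels); counts are
    lognormal draws rounded to at least one read.
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    true_set = set()
    mu, sigma = cell_depth_lognormal
    for i, d in enumerate(rng.lognormal(mu, sigma, n_cells)):
        lab = f"cell{i:05d}"
        counts[lab] = max(1, int(round(d)))
        true_set.add(lab)
    mu, sigma = noise_depth_lognormal
    for i, d in enumerate(rng.lognormal(mu, sigma, n_noise_labels)):
        counts[f"noise{i:05d}"] = max(1, int(round(d)))
    return counts, true_set


__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_run",
    "simulate_cohort",
    "simulate_label_depths",
    "generate_whitelists",
    "Whitelists",
    "CASE_SUBPOPS",
    "CONTROL_SUBPOPS",
]
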