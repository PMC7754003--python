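"""End-to-end pipeline: FASTQ pair -> corrected count matrix.

Stage order is fixed: read QC -> R1 label annotation -> R2 panel
alignment -> pair validity -> molecule collapse -> RSEC -> DBEC -> knee
cell calling -> matrix export.  A pair is retained only when the R1 is
valid (recovered label, N-free UMI, poly(T) pass) and the R2 is valid
(unique panel alignment starting within the first five bases, span >60,
no decoy hit).  Every stage's in/out counts and drop reasons accumulate
into a metrics dict, and rerunning with an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pysam
import yaml

from . import __version__
from .align import align_r2
from .barcode import BarcodeAnnotator
from .cellcalling import KneeCurve, build_knee_curve, call_cells, knee_table
from .matrix import CountMatrix, build_matrix, parse_label, write_matrix
from .molecules import (
    CorrectionReport,
    RawMolecule,
    collapse_to_molecules,
    dbec_filter,
    rsec_correct,
)
from .panel import load_feature_type_map, load_panel
from .qc import QcMetrics, QcThresholds, ReadPair, filter_read_pair
from .whitelists import Whitelists


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run (YAML/JSON round-trip)."""

    r1_fastq: str = ""
    r2_fastq: str = ""
    panel_fasta: str = ""
    feature_type_tsv: Optional[str] = None
    whitelist_dir: str = ""
    outdir: str = "out"
    # QC
    min_r1_len: int = 66
    min_r2_len: int = 64
    min_mean_qual: float = 20.0
    max_r1_snf: float = 0.55
    max_r2_snf: float = 0.80
    # annotation
    polyt_max_non_t: int = 1
    # aligner
    k: int = 18
    max_mismatch_frac: float = 0.1
    uniqueness_margin: int = 3
    # correction
    dbec_min_group: int = 20
    dbec_min_fold_separation: float = 4.0
    # calling
    smooth_window: int = 15
    derivative_mode: str = "second"
    seed: int = 0

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            min_r1_len=self.min_r1_len,
            min_r2_len=self.min_r2_len,
            min_mean_qual=self.min_mean_qual,
            max_r1_snf=self.max_r1_snf,
            max_r2_snf=self.max_r2_snf,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        data = yaml.safe_load(path.read_text())  # YAML is a JSON superset
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    matrix: CountMatrix
    metrics: dict
    molecules: list[RawMolecule]
    report: CorrectionReport
    knee: KneeCurve
    valid_records: list = field(default_factory=list)


def run_pipeline(
    config: RunConfig, write_outputs: bool = True
) -> PipelineResult:
    """Run every stage; see module docstring for the fixed order."""
    # -- inputs --------------------------------------------------------------
    for name in ("r1_fastq", "r2_fastq", "panel_fasta"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise PipelineError("config", f"missing input {name}: {p!r}")
    if not Path(config.whitelist_dir).is_dir():
        raise PipelineError(
            "config", f"missing whitelist directory: {config.whitelist_dir!r}"
        )
    ftype_map = (
        load_feature_type_map(config.feature_type_tsv)
        if config.feature_type_tsv
        else None
    )
    panel = load_panel(config.panel_fasta, feature_type_map=ftype_map)
    panel.build_index(config.k)
    wl = Whitelists.read(config.whitelist_dir)
    annotator = BarcodeAnnotator(wl, polyt_max_non_t=config.polyt_max_non_t)
    th = config.qc_thresholds()

    qc_metrics = QcMetrics()
    r1_drops: dict[str, int] = {}
    r2_drops: dict[str, int] = {}
    valid_records: list[tuple] = []
    reads_per_label: dict[tuple, int] = {}
    ann_status: dict[str, int] = {}

    # -- per-read stages: QC, R1 annotation, R2 alignment, pair validity -----
    try:
        with pysam.FastxFile(config.r1_fastq) as f1, pysam.FastxFile(
            config.r2_fastq
        ) as f2:
            for rec1, rec2 in zip(f1, f2):
                pair = ReadPair(
                    read_id=rec1.name,
                    r1_seq=rec1.sequence,
                    r2_seq=rec2.sequence,
                    r1_qual=rec1.get_quality_array(),
                    r2_qual=rec2.get_quality_array(),
                )
                kept, _ = filter_read_pair(pair, th, qc_metrics)
                if not kept:
                    continue
                ann = annotator.annotate(pair.r1_seq)
                ann_status[ann.status] = ann_status.get(ann.status, 0) + 1
                if not ann.valid:
                    reason = ann.reason or "cls_unresolved"
                    r1_drops[reason] = r1_drops.get(reason, 0) + 1
                    continue
                aln = align_r2(
                    pair.r2_seq,
                    panel,
                    max_mismatch_frac=config.max_mismatch_frac,
                    margin=config.uniqueness_margin,
                )
                if not aln.valid:
                    r2_drops[aln.reason] = r2_drops.get(aln.reason, 0) + 1
                    continue
                label = tuple(ann.cls_indices)
                valid_records.append((label, ann.umi, aln.feature.name))
                reads_per_label[label] = reads_per_label.get(label, 0) + 1
    except OSError as exc:
        raise PipelineError("read_io", str(exc)) from exc

    if not valid_records:
        raise PipelineError("pair_validity", "no valid read pairs survived")

    # -- molecules -----------------------------------------------------------
    raw = collapse_to_molecules(valid_records)
    report = CorrectionReport(n_molecules_in=len(raw))
    post_rsec, report = rsec_correct(raw, report)
    post_dbec, report = dbec_filter(
        post_rsec,
        min_group=config.dbec_min_group,
        min_fold_separation=config.dbec_min_fold_separation,
        report=report,
    )

    # -- cell calling (on per-label read counts of retained pairs) -----------
    try:
        curve = build_knee_curve(reads_per_label)
    except ValueError as exc:
        raise PipelineError("cell_calling", str(exc)) from exc
    curve = call_cells(
        curve, smooth_window=config.smooth_window, mode=config.derivative_mode
    )
    if not curve.called:
        raise PipelineError("cell_calling", "degenerate knee curve: no cells called")

    # -- matrix --------------------------------------------------------------
    provenance = {"tool": "abscount", "version": __version__, "config": asdict(config)}
    cm, matrix_metrics = build_matrix(post_dbec, curve.called, panel, provenance)

    n_valid = len(valid_records)
    metrics = {
        "qc": qc_metrics.as_dict(),
        "r1_annotation": {"status": ann_status, "dropped": r1_drops},
        "r2_alignment": {"dropped": r2_drops},
        "valid_pairs": n_valid,
        "conservation_ok": qc_metrics.reads_in
        == sum(qc_metrics.dropped.values())
        + sum(r1_drops.values())
        + sum(r2_drops.values())
        + n_valid,
        "correction": report.as_dict(),
        "cell_calling": {
            "n_labels": curve.n_labels,
            "inflection_rank": curve.inflection_rank,
            "n_called": len(curve.called),
            "degenerate": curve.degenerate,
        },
        "matrix": matrix_metrics,
    }

    result = PipelineResult(
        matrix=cm,
        metrics=metrics,
        molecules=post_dbec,
        report=report,
        knee=curve,
        valid_records=valid_records,
    )
    if write_outputs:
        _write_outputs(config, result, raw, post_rsec, post_dbec)
    return result


def _write_outputs(config, result, raw, post_rsec, post_dbec) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(result.matrix, outdir / "matrix")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True)
    config.write(outdir / "config.resolved.yaml")
    knee_table(result.knee).to_csv(outdir / "knee.tsv", sep="\t", index=False)

    final_keys = {m.key() for m in post_dbec}
    rsec_keys = {m.key() for m in post_rsec}
    with open(outdir / "molecules.tsv", "w") as fh:
        fh.write("cell\tumi\tfeature\tdepth\tfate\n")
        for m in post_rsec:
            fate = "kept" if m.key() in final_keys else "dbec_removed"
            cell = "_".join(map(str, m.cell_label))
            fh.write(f"{cell}\t{m.umi}\t{m.feature}\t{m.depth}\t{fate}\n")
        for m in raw:
            if m.key() not in rsec_keys:
                cell = "_".join(map(str, m.cell_label))
                fh.write(
                    f"{cell}\t{m.umi}\t{m.feature}\t{m.depth}\trsec_merged\n"
                )
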