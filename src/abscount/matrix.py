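"""Count-matrix assembly and MatrixMarket serialization.

The terminal product of the pipeline: a called-cells x features sparse
matrix of corrected molecule counts, with mRNA and antibody-tag features
side by side in a single matrix tagged by feature type (a CellRanger-like
``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` triplet).  Decoy
features never appear.  Barcodes serialize as whitelist index triples
``i_j_k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .molecules import CellLabel, RawMolecule
from .panel import PanelReference


def serialize_label(label: CellLabel) -> str:
    return "_".join(str(i) for i in label)


def parse_label(s: str) -> CellLabel:
    i, j, k = (int(x) for x in s.split("_"))
    return (i, j, k)


@dataclass
class CountMatrix:
    cell_ids: list[str]            # serialized label triples, row order
    feature_ids: list[str]         # panel order, countable only
    feature_types: list[str]       # mrna | abtag, parallel to feature_ids
    counts: sp.csr_matrix          # cells x features, non-negative ints
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError("matrix dimensions inconsistent with labels")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def feature_block(self, feature_type: str) -> sp.csr_matrix:
        cols = [i for i, t in enumerate(self.feature_types) if t == feature_type]
        return self.counts[:, cols]

    def to_anndata(self):
        """Convert to an AnnData (requires the anndata package)."""
        import anndata
        import pandas as pd

        return anndata.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(
                {"feature_type": self.feature_types}, index=self.feature_ids
            ),
            uns={"provenance": self.provenance},
        )


def build_matrix(
    mols: Sequence[RawMolecule],
    called: Iterable[CellLabel],
    panel: PanelReference,
    provenance: dict | None = None,
) -> tuple[CountMatrix, dict]:
    """Assemble the matrix from surviving molecules of called cells.

    Returns (matrix, metrics); metrics counts molecules excluded because
    their label was not called.  Cells are ordered by label triple,
    features in panel order (decoys dropped).  Called cells with zero
    surviving molecules keep their (all-zero) row.
    """
    called_set = {tuple(c) for c in called}
    if not called_set:
        raise ValueError("empty called cell set")
    features = panel.countable_features
    feat_idx = {f.name: i for i, f in enumerate(features)}
    cell_order = sorted(called_set)
    cell_idx = {c: i for i, c in enumerate(cell_order)}

    rows, cols, vals = [], [], []
    excluded = 0
    for m in mols:
        ci = cell_idx.get(tuple(m.cell_label))
        if ci is None:
            excluded += 1
            continue
        fi = feat_idx.get(m.feature)
        if fi is None:
            raise KeyError(f"molecule feature {m.feature!r} not in panel")
        rows.append(ci)
        cols.append(fi)
        vals.append(1)
    counts = sp.coo_matrix(
        (vals, (rows, cols)),
        shape=(len(cell_order), len(features)),
        dtype=np.int64,
    ).tocsr()
    counts.sum_duplicates()
    cm = CountMatrix(
        cell_ids=[serialize_label(c) for c in cell_order],
        feature_ids=[f.name for f in features],
        feature_types=[f.feature_type for f in features],
        counts=counts,
        provenance=dict(provenance or {}),
    )
    metrics = {
        "molecules_in": len(mols),
        "molecules_counted": cm.total,
        "molecules_excluded_uncalled": excluded,
    }
    return cm, metrics


def write_matrix(m: CountMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write the MTX triplet plus provenance JSON; see :func:`read_matrix`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "provenance": outdir / "provenance.json",
    }
    scipy.io.mmwrite(str(paths["matrix"]), m.counts.tocoo(), field="integer")
    with open(paths["features"], "w") as fh:
        for name, ftype in zip(m.feature_ids, m.feature_types):
            fh.write(f"{name}\t{ftype}\n")
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(m.cell_ids) + "\n")
    with open(paths["provenance"], "w") as fh:
        json.dump(m.provenance, fh, indent=2, sort_keys=True)
    return paths


def read_matrix(indir: str | Path) -> CountMatrix:
    """Read a matrix written by :func:`write_matrix` (bit-exact round trip)."""
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"), dtype=np.int64)
    feature_ids, feature_types = [], []
    for line in (indir / "features.tsv").read_text().splitlines():
        name, ftype = line.split("\t")
        feature_ids.append(name)
        feature_types.append(ftype)
    cell_ids = (indir / "barcodes.tsv").read_text().split()
    prov_path = indir / "provenance.json"
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return CountMatrix(
        cell_ids=cell_ids,
        feature_ids=feature_ids,
        feature_types=feature_types,
        counts=counts,
        provenance=provenance,
    )
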