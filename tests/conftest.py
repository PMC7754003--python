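"""Shared fixtures: a deterministic toy panel and whitelists.

Everything is generated programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from abscount.panel import PanelFeature, PanelReference
from abscount.whitelists import Whitelists, generate_whitelists

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def whitelists() -> Whitelists:
    return generate_whitelists(3)


@pytest.fixture(scope="session")
def toy_panel() -> PanelReference:
    """Five features: three mRNA, one antibody tag, one decoy."""
    rng = np.random.default_rng(17)
    feats = [
        PanelFeature(f"GENE{i}", random_seq(rng, 150), "mrna") for i in range(3)
    ]
    feats.append(PanelFeature("AB0", random_seq(rng, 80), "abtag"))
    feats.append(PanelFeature("phiX174", random_seq(rng, 300), "decoy"))
    return PanelReference(feats).build_index(18)


@pytest.fixture(scope="session")
def sim_panel() -> PanelReference:
    """Thirty-feature mRNA panel for simulator runs."""
    rng = np.random.default_rng(5)
    feats = [
        PanelFeature(f"G{i:03d}", random_seq(rng, 150), "mrna") for i in range(30)
    ]
    return PanelReference(feats).build_index(18)


def write_panel_fasta(panel: PanelReference, path, types_path=None) -> None:
    with open(path, "w") as fh:
        for f in panel.features:
            fh.write(f">{f.name}\n{f.sequence}\n")
    if types_path is not None:
        with open(types_path, "w") as fh:
            for f in panel.features:
                fh.write(f"{f.name}\t{f.feature_type}\n")
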