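"""Case/control cluster-proportion comparison demo.

First the two published worked examples: cluster proportions of 30.35%
vs 9.38% give a 3.2-fold increase, and 2.11% vs 0.62% give 3.4-fold.
Then a simulated 2000-cell-per-group cohort with those same
subpopulation shifts is pushed through the proportion test to show the
full table (counts, percentages, fold change, two-proportion z-test).
"""

import tempfile

from abscount.panel import PanelFeature, PanelReference
from abscount.simulate import (
    CASE_SUBPOPS,
    CONTROL_SUBPOPS,
    SimulationConfig,
    simulate_cohort,
)
from abscount.stats import compare_groups, fold_change
from abscount.whitelists import generate_whitelists

import numpy as np


def main():
    print("printed worked examples:")
    print(f"  30.35% vs 9.38%  -> {fold_change(30.35, 9.38)}-fold")
    print(f"  2.11% vs 0.62%   -> {fold_change(2.11, 0.62)}-fold")

    rng = np.random.default_rng(0)
    feats = [
        PanelFeature(f"G{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, 150)))
        for i in range(5)
    ]
    panel = PanelReference(feats).build_index(18)
    wl = generate_whitelists(0)
    case = SimulationConfig(
        n_cells=2000, n_noise_labels=0,
        subpop_proportions=dict(CASE_SUBPOPS), seed=1,
    )
    ctrl = SimulationConfig(
        n_cells=2000, n_noise_labels=0,
        subpop_proportions=dict(CONTROL_SUBPOPS), seed=2,
    )
    with tempfile.TemporaryDirectory() as tmp:
        res = simulate_cohort(case, ctrl, wl, panel, tmp, emit_fastq=False)
    tab = compare_groups(res["assignments"])
    print("\nsimulated cohort (2000 cells/group):")
    print(tab.to_string(index=False))
    # Cluster "0" is simulated at 30.35% in cases vs 9.38% in controls, so
    # its fold change lands near 3.2 up to multinomial sampling noise, with
    # a vanishing p-value; the "rest" background pool differs modestly.


if __name__ == "__main__":
    main()
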