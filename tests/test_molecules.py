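"""Molecule collapsing, RSEC and DBEC behaviour against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from abscount.molecules import (
    CorrectionReport,
    RawMolecule,
    collapse_to_molecules,
    dbec_filter,
    dbec_split_threshold,
    rsec_correct,
    rsec_merge_group,
)

CELL = (1, 2, 3)


def mol(umi, depth, feature="G1", cell=CELL):
    return RawMolecule(cell_label=cell, umi=umi, feature=feature, depth=depth)


class TestCollapse:
    def test_five_reads_one_molecule(self):
        mols = collapse_to_molecules([(CELL, "AAAACCCC", "G1")] * 5)
        assert len(mols) == 1
        assert mols[0].depth == 5

    def test_distinct_umis_stay_separate(self):
        mols = collapse_to_molecules(
            [(CELL, "AAAACCCC", "G1"), (CELL, "GGGGTTTT", "G1")]
        )
        assert len(mols) == 2

    def test_empty_stream(self):
        assert collapse_to_molecules([]) == []

    def test_depth_sums_to_input_reads(self):
        rng = np.random.default_rng(0)
        umis = ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG"]
        records = [
            (CELL, umis[rng.integers(0, 3)], f"G{rng.integers(0, 2)}")
            for _ in range(200)
        ]
        mols = collapse_to_molecules(records)
        assert sum(m.depth for m in mols) == 200


def enumerate_rsec_outcomes(depths: dict) -> set:
    """All final states over every legal merge order.  Oracle for RSEC.

    The merge rule is ordered: the child must be a *lowest-depth* UMI
    with a strictly deeper Hamming-1 neighbor (otherwise a deep chain
    A-B-C could strand its tail: merging B into A first leaves C with no
    deeper neighbor).  Depth ties on the child are enumerated
    exhaustively; the parent is fixed by the deepest-neighbor rule."""

    def h1(a, b):
        return sum(x != y for x, y in zip(a, b)) == 1

    outcomes = set()

    def step(state: dict):
        candidates = [
            u
            for u in state
            if any(h1(u, v) and state[v] > state[u] for v in state)
        ]
        if not candidates:
            outcomes.add(frozenset(state.items()))
            return
        dmin = min(state[u] for u in candidates)
        children = [u for u in candidates if state[u] == dmin]
        for child in children:
            parents = [
                v for v in state if h1(child, v) and state[v] > state[child]
            ]
            parent = min(parents, key=lambda v: (-state[v], v))
            nxt = dict(state)
            nxt[parent] += nxt.pop(child)
            step(nxt)

    step(dict(depths))
    return outcomes


class TestRsec:
    def test_single_child_merges_into_parent(self):
        depths = {"AAAAAAAA": 10, "AAAAAAAC": 1}
        assert rsec_merge_group(depths) == {"AAAAAAAA": 11}
        assert enumerate_rsec_outcomes(depths) == {
            frozenset({("AAAAAAAA", 11)})
        }

    def test_distance_two_untouched(self):
        depths = {"AAAAAAAA": 10, "AAAAAACC": 3}
        assert rsec_merge_group(depths) == depths

    def test_chain_merges_recursively(self):
        # C -> B -> A along Hamming-1 edges; d(A, C) = 2
        depths = {"AAAAAAAA": 10, "AAAAAAAC": 2, "AAAAAACC": 1}
        assert rsec_merge_group(depths) == {"AAAAAAAA": 13}
        assert enumerate_rsec_outcomes(depths) == {
            frozenset({("AAAAAAAA", 13)})
        }

    def test_equal_depth_pair_unmerged(self):
        depths = {"AAAAAAAA": 5, "AAAAAAAC": 5}
        assert rsec_merge_group(depths) == depths

    def test_agrees_with_merge_order_enumeration(self):
        """On random <=4-UMI groups the implementation's outcome is among
        (and usually the unique element of) all legal merge orders."""
        rng = np.random.default_rng(7)
        bases = "ACGT"
        for _ in range(200):
            n = rng.integers(2, 5)
            # short UMIs make Hamming-1 neighbours likely
            umis = list({
                "".join(bases[b] for b in rng.integers(0, 2, 3))
                for _ in range(n)
            })
            depths = {u: int(rng.integers(1, 12)) for u in umis}
            result = rsec_merge_group(depths)
            outcomes = enumerate_rsec_outcomes(depths)
            assert frozenset(result.items()) in outcomes
            # conservation and monotonicity
            assert sum(result.values()) == sum(depths.values())
            assert len(result) <= len(depths)

    def test_report_counts(self):
        mols = [mol("AAAAAAAA", 10), mol("AAAAAAAC", 1), mol("GGGGGGGG", 4)]
        out, report = rsec_correct(mols)
        assert report.n_molecules_in == 3
        assert report.n_rsec_merged == 1
        assert len(out) == 2
        assert sum(m.depth for m in out) == 15

    def test_groups_isolated_by_cell_and_feature(self):
        mols = [
            mol("AAAAAAAA", 10, feature="G1"),
            mol("AAAAAAAC", 1, feature="G2"),  # different gene: no merge
            mol("AAAAAAAC", 1, feature="G1", cell=(9, 9, 9)),  # other cell
        ]
        out, report = rsec_correct(mols)
        assert report.n_rsec_merged == 0
        assert len(out) == 3


def dbec_threshold_oracle(depths):
    """Exhaustive likelihood search with an independent geometric pmf."""
    best = None
    for t in sorted(set(depths))[:-1]:
        low = [d for d in depths if d <= t]
        high = [d for d in depths if d > t]
        ll = 0.0
        for side in (low, high):
            m = sum(side) / len(side)
            p = 1.0 if m <= 1 else 1.0 / m
            ll += float(np.sum(sps.geom.logpmf(side, p)))
        if best is None or ll > best[1]:
            best = (t, ll)
    return best[0] if best else None


class TestDbec:
    def test_clear_bimodal_removes_error_tail(self):
        depths = [1, 1, 1, 1, 48, 50, 52]
        mols = [mol(f"AAAAAAA{b}", d) for b, d in zip("ACGTACG", depths)]
        out, report = dbec_filter(mols, min_group=5)
        assert len(out) == 3
        assert report.n_dbec_removed == 4
        assert report.per_feature_dbec_threshold == {"G1": 1}
        assert dbec_split_threshold(depths)[0] == dbec_threshold_oracle(depths)

    def test_threshold_matches_oracle_on_random_mixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_err = int(rng.integers(3, 15))
            n_sig = int(rng.integers(3, 15))
            depths = list(rng.geometric(0.8, n_err)) + list(
                rng.geometric(0.05, n_sig) + 10
            )
            t_impl = dbec_split_threshold(depths)
            t_orac = dbec_threshold_oracle(depths)
            assert t_impl[0] == t_orac

    def test_all_equal_no_removal(self):
        mols = [mol(f"AAAAAA{a}{b}", 7) for a in "ACGT" for b in "ACGT"]
        out, report = dbec_filter(mols, min_group=5)
        assert len(out) == len(mols)
        assert report.n_dbec_removed == 0

    def test_below_min_group_passes_through(self):
        mols = [mol(f"AAAAAAA{b}", d) for b, d in zip("ACGTA", [1, 1, 40, 40, 40])]
        out, report = dbec_filter(mols, min_group=20)
        assert len(out) == 5
        assert report.n_dbec_removed == 0

    def test_weak_separation_no_removal(self):
        # means differ by < 4-fold -> treated as unimodal
        depths = [5, 6, 7, 8, 10, 11, 12, 13]
        mols = [mol(f"AAAAAA{a}{b}", d) for (a, b), d in zip(
            itertools.product("ACGT", "AC"), depths
        )]
        out, report = dbec_filter(mols, min_group=5)
        assert len(out) == len(mols)
        assert report.n_dbec_removed == 0

    def test_survivor_depths_untouched(self):
        depths = [1, 1, 1, 1, 48, 50, 52]
        mols = [mol(f"AAAAAAA{b}", d) for b, d in zip("ACGTACG", depths)]
        out, _ = dbec_filter(mols, min_group=5)
        assert sorted(m.depth for m in out) == [48, 50, 52]


class TestReportInvariant:
    def test_out_equals_in_minus_merged_minus_removed(self):
        mols = [
            mol("AAAAAAAA", 30),
            mol("AAAAAAAC", 1),   # rsec-merged
            mol("CCCCCCCC", 30),
            mol("GGGGGGGG", 30),
            mol("TTTTTTTT", 1),   # dbec-removed
            mol("TTTTTTAA", 30),
        ]
        post_rsec, report = rsec_correct(mols)
        out, report = dbec_filter(post_rsec, min_group=5, report=report)
        assert report.n_molecules_out == len(out)
        assert (
            report.n_molecules_in
            - report.n_rsec_merged
            - report.n_dbec_removed
            == len(out)
        )
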