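import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oncoprofiler import simulate
from oncoprofiler.formats import MethylationTable, parse_barcode
from oncoprofiler.methylation import (
    bh_adjust,
    build_pairing,
    delta_histogram,
    differential_methylation,
    wilcoxon_paired,
    wilcoxon_unpaired,
)

from oracles import bh_stepup, rank_sum_exact_p, signed_rank_exact_p


class TestBuildPairing:
    def test_basic_matching(self):
        samples = [
            parse_barcode("TCGA-AA-0001-01A"),
            parse_barcode("TCGA-AA-0001-11A"),
            parse_barcode("TCGA-AA-0002-01A"),
        ]
        pairing = build_pairing(samples, "E")
        assert pairing.pairs == (("TCGA-AA-0001-01", "TCGA-AA-0001-11"),)
        assert pairing.unpaired_tumors == ("TCGA-AA-0002-01",)
        assert pairing.unpaired_normals == ()

    def test_multiple_tumor_vials_deterministic(self):
        samples = [
            parse_barcode("TCGA-AA-0001-02A"),
            parse_barcode("TCGA-AA-0001-01A"),
            parse_barcode("TCGA-AA-0001-11A"),
        ]
        pairing = build_pairing(samples, "E")
        assert pairing.pairs == (("TCGA-AA-0001-01", "TCGA-AA-0001-11"),)

    def test_no_normals_no_pairs(self):
        samples = [parse_barcode("TCGA-AA-0001-01A")]
        pairing = build_pairing(samples, "E")
        assert pairing.pairs == ()


class TestWilcoxonPaired:
    def test_five_positive_distinct_differences(self):
        """All-positive signs put W at its maximum 15: p = 2/32."""
        p, degenerate, underpowered = wilcoxon_paired([1, 2, 3, 4, 5])
        assert p == pytest.approx(2 / 32)
        assert not degenerate and not underpowered

    def test_symmetric_differences_land_in_null_center(self):
        # mirrored pairs tie in |d|, so this goes through the approximate
        # branch; balanced signs must sit deep in the null
        p, _, _ = wilcoxon_paired([0.1, -0.1, 0.22, -0.22, 0.31, -0.31])
        assert p >= 0.5
        # a tie-free near-balanced set goes through the exact branch and
        # must agree with sign-flip enumeration
        diffs = [0.1, -0.11, 0.22, -0.23, 0.31, -0.32]
        p2, _, _ = wilcoxon_paired(diffs)
        assert p2 >= 0.5
        assert p2 == pytest.approx(signed_rank_exact_p(diffs))

    def test_all_zero_differences_degenerate(self):
        p, degenerate, _ = wilcoxon_paired([0.0, 0.0, 0.0])
        assert p == 1.0 and degenerate

    def test_zero_differences_dropped_before_ranking(self):
        p_with, _, _ = wilcoxon_paired([0.0, 1, 2, 3, 4, 5])
        p_without, _, _ = wilcoxon_paired([1, 2, 3, 4, 5])
        assert p_with == pytest.approx(p_without)

    def test_underpowered_flag_below_five(self):
        _, _, underpowered = wilcoxon_paired([1, 2, 3])
        assert underpowered

    @pytest.mark.parametrize("n", range(1, 9))
    def test_exact_branch_matches_signflip_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.standard_normal(n)
            while np.unique(np.abs(d)).size < n or (d == 0).any():
                d = rng.standard_normal(n)
            p, _, _ = wilcoxon_paired(d)
            assert p == pytest.approx(signed_rank_exact_p(d), abs=1e-12)


class TestWilcoxonUnpaired:
    def test_fully_separated_groups(self):
        """{10,11,12} vs {1,2,3}: the most extreme of C(6,3)=20 assignments,
        two-sided p = 2/20."""
        assert wilcoxon_unpaired([10, 11, 12], [1, 2, 3]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert wilcoxon_unpaired([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_one_observation_per_group(self):
        assert wilcoxon_unpaired([2.0], [1.0]) == pytest.approx(
            rank_sum_exact_p([2.0], [1.0])
        )
        assert wilcoxon_unpaired([2.0], [1.0]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_unpaired([], [1.0])

    @pytest.mark.parametrize("m,n", [(m, n) for m in range(1, 6) for n in range(1, 6)])
    def test_exact_branch_matches_assignment_enumeration(self, m, n):
        rng = np.random.default_rng(100 * m + n)
        for _ in range(15):
            pooled = rng.standard_normal(m + n)
            while np.unique(pooled).size < m + n:
                pooled = rng.standard_normal(m + n)
            x, y = pooled[:m], pooled[m:]
            assert wilcoxon_unpaired(x, y) == pytest.approx(
                rank_sum_exact_p(x, y), abs=1e-12
            )


class TestBhAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.2], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            m = int(rng.integers(1, 201))
            p = rng.uniform(1e-12, 1.0, size=m)
            np.testing.assert_allclose(
                bh_adjust(p), bh_stepup(p), rtol=0, atol=1e-12
            )

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1, max_size=40),
        st.floats(0.5, 1.0),
    )
    def test_adding_larger_p_never_decreases_adjusted(self, ps, extra):
        """Monotonicity of the step-up family under growth."""
        extra = max(extra, max(ps))
        base = bh_adjust(ps)
        grown = bh_adjust(ps + [extra])[: len(ps)]
        assert (np.asarray(grown) >= np.asarray(base) - 1e-12).all()


def _tiny_table(betas_by_row, tumor_n, normal_n, entity="E"):
    cols = [f"TCGA-AA-{i:04d}-01A" for i in range(tumor_n)] + [
        f"TCGA-AA-{i:04d}-11A" for i in range(normal_n)
    ]
    frame = pd.DataFrame(
        betas_by_row.values(),
        index=pd.MultiIndex.from_tuples(betas_by_row.keys(), names=["gene", "region"]),
        columns=cols,
    )
    return MethylationTable(entity=entity, betas=frame, samples=[parse_barcode(c) for c in cols])


class TestDifferentialMethylation:
    def test_planted_shift_recovered(self, small_cohort):
        results = differential_methylation(small_cohort.methylation, mode="paired")
        hit = next(r for r in results if r.gene == "TP53" and r.region == "Body")
        assert hit.p_adj < 0.05
        assert hit.direction == "hyper"
        assert hit.delta_beta == pytest.approx(0.3, abs=0.1)

    def test_direction_follows_delta_not_p(self):
        table = _tiny_table(
            {("G", "Body"): [0.1, 0.15, 0.12, 0.6, 0.62, 0.61]}, 3, 3
        )
        results = differential_methylation(table, mode="unpaired")
        assert results[0].delta_beta < 0
        assert results[0].direction == "hypo"

    def test_row_missing_everywhere_reported_without_p(self):
        table = _tiny_table(
            {
                ("G", "Body"): [0.1, 0.2, 0.3, 0.5, 0.6, 0.7],
                ("G", "TSS200"): [np.nan] * 6,
            },
            3, 3,
        )
        results = differential_methylation(table, mode="unpaired")
        missing = next(r for r in results if r.region == "TSS200")
        assert missing.p_raw is None and missing.p_adj is None
        tested = next(r for r in results if r.region == "Body")
        # BH family is only the testable rows
        assert tested.p_adj == pytest.approx(tested.p_raw)

    def test_paired_mode_without_pairs_is_error(self):
        cols = ["TCGA-AA-0001-01A", "TCGA-AA-0002-01A"]
        frame = pd.DataFrame(
            [[0.1, 0.2]],
            index=pd.MultiIndex.from_tuples([("G", "Body")], names=["gene", "region"]),
            columns=cols,
        )
        table = MethylationTable("E", frame, [parse_barcode(c) for c in cols])
        with pytest.raises(ValueError, match="no tumor/normal pairs"):
            differential_methylation(table, mode="paired")

    def test_p_adj_never_below_p_raw(self, small_cohort):
        for r in differential_methylation(small_cohort.methylation, mode="unpaired"):
            if r.p_raw is not None:
                assert r.p_adj >= r.p_raw - 1e-12

    def test_permuting_p_leaves_directions_unchanged(self, small_cohort):
        results = differential_methylation(small_cohort.methylation, mode="paired")
        directions = {(r.gene, r.region): r.direction for r in results}
        # directions recomputed from deltas alone must agree
        for r in results:
            want = "hyper" if (r.delta_beta or 0) > 0 else (
                "hypo" if (r.delta_beta or 0) < 0 else "none"
            )
            assert directions[(r.gene, r.region)] == want


class TestDeltaHistogram:
    def test_point_mass_single_bin(self):
        n = 10
        rows = {("G", "Body"): [0.52] * n + [0.40] * n}
        table = _tiny_table(rows, n, n)
        edges, counts = delta_histogram(table, "G", "Body")
        assert counts.sum() == n
        bin_idx = np.nonzero(counts)[0]
        assert len(bin_idx) == 1
        left = edges[bin_idx[0]]
        assert left == pytest.approx(0.10)

    def test_symmetric_differences_two_mirrored_bins(self):
        tumor = [0.7, 0.7, 0.3, 0.3]
        normal = [0.5, 0.5, 0.5, 0.5]
        table = _tiny_table({("G", "Body"): tumor + normal}, 4, 4)
        edges, counts = delta_histogram(table, "G", "Body")
        nz = np.nonzero(counts)[0]
        assert counts.sum() == 4
        assert len(nz) == 2
        assert counts[nz[0]] == counts[nz[1]] == 2

    def test_counts_sum_to_informative_pairs(self, small_cohort):
        edges, counts = delta_histogram(small_cohort.methylation, "TP53", "Body")
        n_pairs = len(build_pairing(small_cohort.methylation.samples).pairs)
        assert counts.sum() == n_pairs

    def test_no_pairs_is_error(self):
        table = _tiny_table({("G", "Body"): [0.1, 0.2]}, 2, 0)
        with pytest.raises(ValueError, match="no tumor/normal pairs"):
            delta_histogram(table, "G", "Body")


def test_null_tables_control_false_discovery_rate():
    """On all-null cohorts the average false-discovery proportion at
    q < 0.05 over 200 seeded replicates stays at or below 0.075."""
    rng = np.random.default_rng(2024)
    n_pairs = 20
    n_features = 60
    fdps = []
    for _ in range(200):
        tumor = rng.beta(6, 14, size=(n_features, n_pairs))
        normal = rng.beta(6, 14, size=(n_features, n_pairs))
        ps = []
        for i in range(n_features):
            p, _, _ = wilcoxon_paired(tumor[i] - normal[i])
            ps.append(p)
        q = bh_adjust(ps)
        discoveries = int((q < 0.05).sum())
        fdps.append(1.0 if discoveries else 0.0)
    assert float(np.mean(fdps)) <= 0.075
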