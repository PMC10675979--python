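"""ChIP filter, co-expression consensus, HEG screen, intersection, verification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metascreen.io import ChipTargetTable
from metascreen.screen import (
    ceg_consensus,
    chip_candidate_filter,
    heg_screen,
    intersect_targets,
    pearson_vs_gene,
    verify_bulk_correlation,
    verify_single_cell,
)
from metascreen.simulate import SimSpec, simulate_single_cell


def chip_table(rows):
    return ChipTargetTable(pd.DataFrame(rows, columns=["gene", "score", "dataset_id"]))


class TestChipFilter:
    def test_boundary_score_inclusive(self):
        t = chip_table([("A", 0.4, "d1"), ("A", 1.0, "d2")])
        assert chip_candidate_filter(t) == {"A"}

    def test_below_boundary_dropped(self):
        t = chip_table([("A", 0.99, "d1"), ("A", 0.5, "d2")])
        assert chip_candidate_filter(t) == set()

    def test_empty_table_list_rejected(self):
        with pytest.raises(ValueError):
            chip_candidate_filter([])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            chip_candidate_filter(chip_table([("A", 1.0, "d")]), score_min=-1)


class TestPearson:
    def test_hand_example_fails_p_despite_r(self, cohort_factory):
        cm = cohort_factory({"GOI": [1, 2, 3], "G1": [1, 2, 4]}, n_tumor=2)
        df = pearson_vs_gene(cm, "GOI").set_index("gene")
        r_ref, p_ref = stats.pearsonr([1, 2, 3], [1, 2, 4])
        assert df.loc["G1", "r"] == pytest.approx(r_ref, abs=1e-9)
        assert df.loc["G1", "r"] == pytest.approx(0.982, abs=1e-3)
        assert df.loc["G1", "p"] == pytest.approx(p_ref, abs=1e-9)
        assert df.loc["G1", "p"] == pytest.approx(0.121, abs=1e-3)
        assert not (df.loc["G1", "r"] >= 0.30 and df.loc["G1", "p"] < 0.05)

    def test_perfect_correlation_passes(self, cohort_factory):
        x = list(np.linspace(0, 5, 50))
        cm = cohort_factory({"GOI": x, "G1": x}, n_tumor=25)
        df = pearson_vs_gene(cm, "GOI").set_index("gene")
        assert df.loc["G1", "r"] == pytest.approx(1.0)
        assert df.loc["G1", "p"] == 0.0

    def test_matches_scipy_on_random_data(self, cohort_factory):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        cm = cohort_factory({"GOI": list(x), "G1": list(y)}, n_tumor=15)
        df = pearson_vs_gene(cm, "GOI").set_index("gene")
        r_ref, p_ref = stats.pearsonr(x, y)
        assert df.loc["G1", "r"] == pytest.approx(r_ref, abs=1e-10)
        assert df.loc["G1", "p"] == pytest.approx(p_ref, rel=1e-6)


class TestCegConsensus:
    @staticmethod
    def _build(n_pass_a, n_pass_b, k=39):
        from conftest import make_cohort

        rng = np.random.default_rng(42)
        cohorts = []
        for i in range(k):
            goi = rng.normal(size=30)
            ga = goi.copy() if i < n_pass_a else rng.normal(size=30)
            gb = goi.copy() if i < n_pass_b else rng.normal(size=30)
            cohorts.append(
                make_cohort(
                    {"GOI": list(goi), "GA": list(ga), "GB": list(gb)},
                    n_tumor=15,
                    cohort_id=f"P{i}",
                )
            )
        return cohorts

    def test_platform_count_boundary(self):
        cohorts = self._build(20, 19)
        consensus, counts = ceg_consensus(cohorts, "GOI")
        assert "GA" in consensus
        assert "GB" not in consensus
        assert counts["GA"] >= 20 and counts["GB"] < 20

    def test_goi_excluded_and_order_invariant(self):
        cohorts = self._build(25, 5, k=30)
        c1, _ = ceg_consensus(cohorts, "GOI", min_platforms=10)
        c2, _ = ceg_consensus(cohorts[::-1], "GOI", min_platforms=10)
        assert c1 == c2
        assert "GOI" not in c1

    def test_threshold_monotonicity(self):
        cohorts = self._build(22, 15, k=30)
        strict, _ = ceg_consensus(cohorts, "GOI", r_min=0.5, p_max=0.01, min_platforms=15)
        loose, _ = ceg_consensus(cohorts, "GOI", r_min=0.3, p_max=0.05, min_platforms=15)
        assert strict <= loose


class TestHegScreen:
    @staticmethod
    def _cohorts(k=6, n=40, seed=0):
        from conftest import make_cohort

        rng = np.random.default_rng(seed)
        cohorts = []
        for i in range(k):
            up = np.concatenate([rng.normal(1.5, 1, n // 2), rng.normal(0, 1, n // 2)])
            null = rng.normal(0, 1, n)
            down = np.concatenate([rng.normal(-1.5, 1, n // 2), rng.normal(0, 1, n // 2)])
            cohorts.append(
                make_cohort(
                    {"UP": list(up), "NULL": list(null), "DOWN": list(down)},
                    n_tumor=n // 2,
                    cohort_id=f"P{i}",
                )
            )
        return cohorts

    def test_rule_membership(self):
        heg, table = heg_screen(self._cohorts())
        assert "UP" in heg
        assert "DOWN" not in heg  # pooled SMD < 0
        t = table.set_index("gene")
        assert t.loc["UP", "pooled_smd"] > 0
        assert t.loc["DOWN", "pooled_smd"] < 0

    def test_nonsignificant_positive_excluded(self):
        heg, table = heg_screen(self._cohorts(), p_max=1e-30)
        assert "UP" not in heg  # rule complement: p too strict

    def test_needs_two_cohorts(self):
        with pytest.raises(ValueError, match="2 cohorts"):
            heg_screen(self._cohorts(k=1))

    def test_order_invariance(self):
        cohorts = self._cohorts()
        h1, _ = heg_screen(cohorts)
        h2, _ = heg_screen(cohorts[::-1])
        assert h1 == h2


class TestIntersection:
    def test_set_algebra_example(self):
        res = intersect_targets({"A", "B", "C"}, {"B", "C", "D"}, {"C", "B"})
        assert res.intersection == {"B", "C"}
        ev = res.evidence.set_index("gene")
        assert bool(ev.loc["D", "in_ceg"]) and not bool(ev.loc["D", "in_intersection"])

    def test_empty_input_gives_empty_intersection(self):
        assert intersect_targets(set(), {"A"}, {"A"}).intersection == set()

    def test_permutation_invariance(self):
        a, b, c = {"A", "B"}, {"B", "C"}, {"B", "D"}
        results = {
            frozenset(intersect_targets(x, y, z).intersection)
            for x, y, z in [(a, b, c), (b, c, a), (c, a, b)]
        }
        assert results == {frozenset({"B"})}

    def test_subset_invariant(self):
        res = intersect_targets({"A", "B"}, {"B", "C"}, {"B"})
        assert res.intersection <= res.chip_candidates
        assert res.intersection <= res.ceg_consensus
        assert res.intersection <= res.heg


class TestVerification:
    def test_bulk_self_correlation_is_one(self, cohort_factory):
        rng = np.random.default_rng(7)
        cohorts = [
            cohort_factory(
                {"GOI": list(rng.normal(size=20)), "G1": list(rng.normal(size=20))},
                n_tumor=10, cohort_id=f"P{i}",
            )
            for i in range(3)
        ]
        rows = verify_bulk_correlation(cohorts, "GOI", ["GOI"])
        assert (rows["r"] == pytest.approx(1.0)) if len(rows) == 1 else (rows["r"] > 0.999).all()

    def test_bulk_missing_symbol_row(self, cohort_factory):
        cm = cohort_factory({"GOI": [1.0, 2, 3, 4], "G1": [1.0, 2, 3, 5]}, n_tumor=2)
        rows = verify_bulk_correlation([cm], "GOI", ["ABSENT"])
        assert (rows["status"] == "missing").all()

    def test_bulk_decoy_rarely_flagged(self, cohort_factory):
        rng = np.random.default_rng(23)
        cohorts = [
            cohort_factory(
                {"GOI": list(rng.normal(size=60)), "DEC": list(rng.normal(size=60))},
                n_tumor=30, cohort_id=f"P{i}",
            )
            for i in range(20)
        ]
        rows = verify_bulk_correlation(cohorts, "GOI", ["DEC"])
        assert rows["passes"].mean() <= 0.05

    def test_sc_identical_counts(self):
        spec = SimSpec(rng_seed=3, sc_cells=400, n_genes=20, n_true_targets=3,
                       dropout_rate=0.3)
        sc = simulate_single_cell(spec)
        rows = verify_single_cell(sc, "FOXM1", ["FOXM1"], "malignant")
        mal = rows[rows["compartment"] == "malignant"].iloc[0]
        x = sc.gene_counts("FOXM1")[sc.cluster_mask("malignant")]
        assert mal["both_positive_fraction"] == pytest.approx(np.mean(x > 0))
        assert mal["spearman_r"] == pytest.approx(1.0)

    def test_sc_true_target_coexpresses_in_malignant(self):
        spec = SimSpec(rng_seed=3, sc_cells=1200, n_genes=30, n_true_targets=3)
        sc = simulate_single_cell(spec)
        rows = verify_single_cell(sc, "FOXM1", ["TGT001"], "malignant")
        mal = rows[rows["compartment"] == "malignant"]["both_positive_fraction"].iloc[0]
        other = rows[rows["compartment"] == "other"]["both_positive_fraction"].iloc[0]
        assert mal > other

    def test_sc_empty_cluster_rejected(self):
        spec = SimSpec(rng_seed=3, sc_cells=100, n_genes=15, n_true_targets=2)
        sc = simulate_single_cell(spec)
        with pytest.raises(ValueError, match="empty cluster"):
            verify_single_cell(sc, "FOXM1", ["TGT001"], "nonexistent")
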