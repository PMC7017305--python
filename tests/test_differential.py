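import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicenet.design import STUDY_CONTRASTS
from splicenet.differential import (
    benjamini_hochberg,
    deg_sets,
    pairwise_fold_changes,
    select_degs,
    two_way_anova,
    venn_partition,
)


def bh_step_up_brute(p):
    """Independent step-up: sort, scale by m/rank, enforce monotonicity from the top."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestTwoWayAnova:
    def test_worked_balanced_2x2_example(self, toy_2x2_matrix):
        values, metadata = toy_2x2_matrix
        res = two_way_anova(values, metadata)
        row = res.loc["g1"]
        assert row["F_tissue"] == pytest.approx(64.0, abs=1e-9)
        assert row["F_state"] == pytest.approx(16.0, abs=1e-9)
        assert row["F_interaction"] == pytest.approx(0.0, abs=1e-9)
        assert row["residual_df"] == 4

    def test_constant_gene_flagged_degenerate(self, toy_2x2_matrix):
        values, metadata = toy_2x2_matrix
        values = pd.concat([values, pd.DataFrame(
            [[5.0] * 8], index=["flat"], columns=values.columns)])
        res = two_way_anova(values, metadata)
        assert bool(res.loc["flat", "degenerate"])
        assert res.loc["flat", "F_state"] == 0.0
        assert res.loc["flat", "p_state"] == 1.0
        assert not bool(res.loc["g1", "degenerate"])

    def test_exact_fit_gene_reports_limiting_p(self, toy_2x2_matrix):
        _, metadata = toy_2x2_matrix
        # noiseless tissue effect: zero residual variance, nonzero effect SS
        values = pd.DataFrame([[0.0] * 4 + [1.0] * 4], index=["g"],
                              columns=metadata.index)
        res = two_way_anova(values, metadata)
        assert bool(res.loc["g", "degenerate"])
        assert res.loc["g", "p_tissue"] == 0.0
        assert np.isinf(res.loc["g", "F_tissue"])

    def test_pure_interaction_pattern_maximizes_interaction_F(self, toy_2x2_matrix):
        _, metadata = toy_2x2_matrix
        rng = np.random.default_rng(0)
        cell = {("t1", "a"): 0.0, ("t1", "b"): 1.0, ("t2", "a"): 1.0, ("t2", "b"): 0.0}
        y = np.array([cell[(t, s)] for t, s in
                      zip(metadata["tissue"], metadata["state"])])
        y = y + rng.normal(0, 0.01, size=y.size)
        values = pd.DataFrame([y], index=["g"], columns=metadata.index)
        res = two_way_anova(values, metadata)
        assert res.loc["g", "F_interaction"] > res.loc["g", "F_tissue"]
        assert res.loc["g", "F_interaction"] > res.loc["g", "F_state"]

    def test_matches_statsmodels_type3_on_unbalanced_design(self, unbalanced_2x3):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        values, metadata = unbalanced_2x3
        res = two_way_anova(values, metadata, ss_type=3)
        for gene in values.index:
            frame = pd.DataFrame({
                "y": values.loc[gene].to_numpy(),
                "tissue": metadata["tissue"].to_numpy(),
                "state": metadata["state"].to_numpy(),
            })
            fit = smf.ols("y ~ C(tissue, Sum) * C(state, Sum)", frame).fit()
            table = anova_lm(fit, typ=3)
            assert res.loc[gene, "F_tissue"] == pytest.approx(
                table.loc["C(tissue, Sum)", "F"], rel=1e-8)
            assert res.loc[gene, "F_state"] == pytest.approx(
                table.loc["C(state, Sum)", "F"], rel=1e-8)
            assert res.loc[gene, "F_interaction"] == pytest.approx(
                table.loc["C(tissue, Sum):C(state, Sum)", "F"], rel=1e-8)
            assert res.loc[gene, "p_interaction"] == pytest.approx(
                table.loc["C(tissue, Sum):C(state, Sum)", "PR(>F)"], rel=1e-8)

    def test_type1_equals_type3_on_balanced_design(self):
        rng = np.random.default_rng(11)
        tissue = ["t1"] * 6 + ["t2"] * 6
        state = (["a", "b", "c"] * 2) * 2
        cols = [f"s{i}" for i in range(12)]
        values = pd.DataFrame(rng.normal(size=(8, 12)),
                              index=[f"g{i}" for i in range(8)], columns=cols)
        metadata = pd.DataFrame({"tissue": tissue, "state": state}, index=cols)
        r1 = two_way_anova(values, metadata, ss_type=1)
        r3 = two_way_anova(values, metadata, ss_type=3)
        for eff in ("state", "tissue", "interaction"):
            np.testing.assert_allclose(r1[f"F_{eff}"], r3[f"F_{eff}"], rtol=1e-9)

    def test_empty_cell_rejected(self, toy_2x2_matrix):
        values, metadata = toy_2x2_matrix
        broken = metadata.copy()
        broken.loc[broken.index[:2], "state"] = "b"  # removes cell (t1, a)
        with pytest.raises(ValueError, match="empty factorial cell"):
            two_way_anova(values, broken)

    def test_q_values_dominate_p_and_are_monotone(self, unbalanced_2x3):
        values, metadata = unbalanced_2x3
        res = two_way_anova(values, metadata)
        for eff in ("state", "tissue", "interaction"):
            assert (res[f"q_{eff}"] >= res[f"p_{eff}"] - 1e-12).all()
            ordered = res.sort_values(f"p_{eff}")
            assert ordered[f"q_{eff}"].is_monotonic_increasing


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.3], [0.3]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([-0.1])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                benjamini_hochberg(p), bh_step_up_brute(list(p)), atol=1e-12
            )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_property_clipped_order_preserving(self, p):
        q = benjamini_hochberg(p)
        assert (q <= 1 + 1e-12).all() and (q >= np.asarray(p) - 1e-12).all()
        np.testing.assert_allclose(q, bh_step_up_brute(p), atol=1e-12)


class TestPairwiseAndSelection:
    def frame(self, lfc_by_gene):
        """One-sample-per-cell gene matrix realizing given cortex SALS1-CTRL log2FCs."""
        cols, tissue, state = [], [], []
        from splicenet.design import STATES, TISSUES
        for t in TISSUES:
            for s in STATES:
                cols.append(f"{t}_{s}")
                tissue.append(t)
                state.append(s)
        metadata = pd.DataFrame({"tissue": tissue, "state": state}, index=cols)
        values = pd.DataFrame(0.0, index=list(lfc_by_gene), columns=cols)
        for gene, lfc in lfc_by_gene.items():
            values.loc[gene, "motor_cortex_SALS1"] = lfc
        return values, metadata

    def test_log2fc_direction_and_magnitude(self):
        values, metadata = self.frame({"g_up": 2.0, "g_null": 0.0, "g_dn": -1.5})
        pw = pairwise_fold_changes(values, metadata)
        rec = pw.set_index(["gene_id", "contrast_id"])
        up = rec.loc[("g_up", "cortex_SALS1_vs_cortex_CTRL")]
        assert up["log2_fc"] == pytest.approx(2.0)
        assert up["direction"] == "up"
        assert up["linear_fc_magnitude"] == pytest.approx(4.0)
        null = rec.loc[("g_null", "cortex_SALS1_vs_cortex_CTRL")]
        assert null["log2_fc"] == 0.0
        dn = rec.loc[("g_dn", "cortex_SALS1_vs_cortex_CTRL")]
        assert dn["direction"] == "down"
        assert dn["linear_fc_magnitude"] == pytest.approx(2 ** 1.5)

    def anova_stub(self, genes, q=0.01):
        cols = {}
        for eff in ("state", "tissue", "interaction"):
            cols[f"F_{eff}"] = 1.0
            cols[f"p_{eff}"] = q
            cols[f"q_{eff}"] = q
        stub = pd.DataFrame(cols, index=list(genes))
        stub["residual_df"] = 10
        stub["degenerate"] = False
        return stub

    def pairwise_stub(self, rows):
        frame = pd.DataFrame(rows, columns=["gene_id", "contrast_id", "kind", "log2_fc"])
        frame["linear_fc_magnitude"] = 2.0 ** frame["log2_fc"].abs()
        frame["direction"] = np.where(frame["log2_fc"] > 0, "up", "down")
        return frame

    def test_selection_thresholds_are_strict(self):
        pw = self.pairwise_stub([
            ("g1", "c", "state", 1.5),
            ("g2", "c", "state", 3.0),
            ("g3", "c", "state", 1.0),   # linear FC exactly 2
        ])
        anova = self.anova_stub(["g1", "g2", "g3"])
        anova.loc["g2", ["q_state", "q_interaction"]] = 0.06  # fails p gate
        sel = select_degs(anova, pw)
        got = dict(zip(sel["gene_id"], sel["passes_threshold"]))
        assert got == {"g1": True, "g2": False, "g3": False}

    def test_gating_uses_relevant_effect(self):
        pw = self.pairwise_stub([
            ("g1", "cs", "state", 2.0),
            ("g1", "ct", "tissue", 2.0),
        ])
        anova = self.anova_stub(["g1"], q=0.5)
        anova.loc["g1", "q_state"] = 0.01  # only the state effect is significant
        sel = select_degs(anova, pw).set_index("contrast_id")["passes_threshold"]
        assert bool(sel["cs"]) and not bool(sel["ct"])
        sel_any = select_degs(anova, pw, gating="any")
        assert sel_any["passes_threshold"].all()

    def test_selection_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        anova = self.anova_stub(genes)
        for eff in ("state", "tissue", "interaction"):
            anova[f"q_{eff}"] = rng.uniform(size=30)
        pw = self.pairwise_stub(
            [(g, "c", "state", rng.normal(0, 2)) for g in genes])
        strict = deg_sets(select_degs(anova, pw, alpha=0.03, fc_cut=3.0))["c"]
        relaxed = deg_sets(select_degs(anova, pw, alpha=0.10, fc_cut=2.0))["c"]
        assert strict <= relaxed


class TestVenn:
    def test_three_region_partition(self):
        part = venn_partition({"X": {"A", "B"}, "Y": {"B", "C"}})
        assert part.region("X") == {"A"}
        assert part.region("Y") == {"C"}
        assert part.region("X", "Y") == {"B"}

    def test_identical_sets_single_region(self):
        part = venn_partition({"X": {1, 2}, "Y": {1, 2}})
        assert part.region("X", "Y") == {1, 2}
        assert not part.region("X")

    def test_disjoint_sets(self):
        part = venn_partition({"X": {1}, "Y": {2}})
        assert not part.region("X", "Y")
        assert part.region("X") == {1}

    def test_counts_sum_to_union_and_regions_disjoint(self):
        rng = np.random.default_rng(9)
        sets = {name: set(rng.choice(50, size=20)) for name in "ABC"}
        part = venn_partition(sets)
        union = set().union(*sets.values())
        assert sum(part.counts.values()) == len(union)
        seen = set()
        for members in part.regions.values():
            assert not (seen & members)
            seen |= members

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            venn_partition([("X", {1}), ("X", {2})])
        with pytest.raises(ValueError, match="two sets"):
            venn_partition({"X": {1}})


def test_study_contrasts_cover_seven_comparisons():
    assert len(STUDY_CONTRASTS) == 7
    kinds = [c.kind for c in STUDY_CONTRASTS]
    assert kinds.count("state") == 4 and kinds.count("tissue") == 3
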