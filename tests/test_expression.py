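"""Expression classification, fold changes, 2^-ΔΔCt, Duncan's MRT."""

import numpy as np
import pandas as pd
import pytest

from hdzipkit.expression import (analyze_qpcr, classify_expression, ddct,
                                 duncan_mrt, duncan_q, fold_change,
                                 fold_change_table)


def _matrix(rows, samples=("s1", "s2", "s3")):
    return pd.DataFrame(rows, columns=list(samples)).rename_axis("gene_id")


class TestClassifyExpression:
    def test_constitutive(self):
        m = _matrix({"g": [5.0, 5.0, 5.0]}.values() and
                    pd.DataFrame({"s1": [5.0], "s2": [5.0], "s3": [5.0]},
                                 index=["g"]))
        (c,) = classify_expression(m)
        assert c.label == "constitutive"

    def test_boundary_value_not_expressed(self):
        # FPKM exactly 1.0 everywhere: strictly-greater rule -> silent
        m = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["g"])
        (c,) = classify_expression(m)
        assert c.label == "non_expressed"

    def test_tissue_specific_requires_configured_group(self):
        m = pd.DataFrame({"leaf": [9.0], "r1": [0.2], "r2": [0.1]},
                         index=["g"])
        (c,) = classify_expression(m, tissue_groups={"leaf": ["leaf"]})
        assert c.label == "tissue_specific" and c.tissue_group == "leaf"
        (c2,) = classify_expression(m)  # no groups configured
        assert c2.label == "partial"

    def test_negative_fpkm_rejected(self):
        m = pd.DataFrame({"s1": [-1.0]}, index=["g"])
        with pytest.raises(ValueError):
            classify_expression(m)

    def test_noiseless_truth_recovered(self, noiseless_scenario):
        from hdzipkit.synthetic import generate_expression
        fpkm, _, truth = generate_expression(noiseless_scenario)
        plan = noiseless_scenario.expression_plan
        classes = classify_expression(fpkm[plan.samples],
                                      tissue_groups=plan.tissue_groups)
        for c in classes:
            assert c.label == truth.true_expression_class[c.gene_id]


class TestFoldChange:
    def test_equal_values_unchanged(self):
        r = fold_change(5.0, 5.0, pseudocount=0.0)
        assert r.log2_fc == 0.0 and not r.changed

    def test_fourfold_is_changed(self):
        r = fold_change(4.0, 1.0, pseudocount=0.0)
        assert r.log2_fc == pytest.approx(2.0) and r.changed

    def test_twofold_boundary_not_changed(self):
        r = fold_change(2.0, 1.0, pseudocount=0.0)
        assert not r.changed  # strict > 2 rule

    def test_zero_control_with_pseudocount(self):
        r = fold_change(10.0, 0.0, pseudocount=0.1)
        assert r.log2_fc == pytest.approx(np.log2(10.1 / 0.1), abs=1e-9)
        assert r.log2_fc == pytest.approx(6.66, abs=0.01)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 1.0)

    def test_noiseless_changed_sets_recovered(self, noiseless_scenario):
        from hdzipkit.synthetic import generate_expression
        fpkm, _, truth = generate_expression(noiseless_scenario)
        for tissue, planted in truth.true_fold_changed.items():
            fc = fold_change_table(fpkm, f"{tissue}_drought",
                                   f"{tissue}_ctrl")
            assert sorted(fc[fc.changed].gene_id) == planted


class TestDdct:
    def test_calibrator_gives_unity(self):
        assert ddct([20, 20, 20], [18, 18, 18], [22, 22], [20, 20]) == \
            pytest.approx(1.0)

    def test_two_cycle_difference_is_fourfold(self):
        assert ddct([20], [18], [22], [18]) == pytest.approx(4.0)

    def test_constant_shift_invariance(self):
        base = ddct([21.3, 21.5], [18.2, 18.1], [23.0, 22.8], [18.0, 18.2])
        c = 3.7
        shifted = ddct([21.3 + c, 21.5 + c], [18.2 + c, 18.1 + c],
                       [23.0 + c, 22.8 + c], [18.0 + c, 18.2 + c])
        assert shifted == pytest.approx(base)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            ddct([], [18], [22], [18])


class TestDuncanQuantiles:
    @pytest.mark.parametrize("p,df,expected", [
        # Duncan's significant-range table, alpha = 0.05
        (2, 6, 3.46), (3, 6, 3.59),
        (2, 9, 3.20), (3, 9, 3.34),
    ])
    def test_matches_published_tables(self, p, df, expected):
        assert duncan_q(0.05, p, df) == pytest.approx(expected, abs=5e-3)

    def test_increasing_in_p(self):
        qs = [duncan_q(0.05, p, 12) for p in range(2, 8)]
        assert all(b > a for a, b in zip(qs, qs[1:]))

    def test_decreasing_in_df(self):
        qs = [duncan_q(0.05, 3, df) for df in (4, 8, 16, 32)]
        assert all(b < a for a, b in zip(qs, qs[1:]))


class TestDuncanMRT:
    def test_identical_groups_share_letter(self):
        letters = duncan_mrt([("a", [5.0, 5.1, 4.9]),
                              ("b", [5.0, 5.1, 4.9]),
                              ("c", [5.0, 5.1, 4.9])])
        assert len(set(letters.values())) == 1

    def test_widely_separated_groups_all_distinct(self):
        letters = duncan_mrt([("a", [0, 0.01, -0.01]),
                              ("b", [100, 100.01, 99.99]),
                              ("c", [200, 200.01, 199.99])])
        assert len(set(letters.values())) == 3

    def test_zero_variance_unequal_means_distinct(self):
        letters = duncan_mrt([("a", [1.0, 1.0, 1.0]),
                              ("b", [2.0, 2.0, 2.0])])
        assert letters["a"] != letters["b"]

    def test_zero_variance_equal_means_share(self):
        letters = duncan_mrt([("a", [2.0, 2.0]), ("b", [2.0, 2.0])])
        assert letters["a"] == letters["b"]

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            duncan_mrt([("a", [1, 2, 3]), ("b", [1, 2])])

    def test_letter_groups_contiguous_in_mean_order(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            groups = [(f"g{i}", list(rng.normal(rng.uniform(0, 6), 1.0, 3)))
                      for i in range(5)]
            letters = duncan_mrt(groups)
            means = {lab: np.mean(v) for lab, v in groups}
            ordered = sorted(letters, key=lambda l: -means[l])
            for letter in set("".join(letters.values())):
                idx = [i for i, lab in enumerate(ordered)
                       if letter in letters[lab]]
                assert idx == list(range(min(idx), max(idx) + 1))


class TestAnalyzeQpcr:
    def test_noiseless_ratios_recovered(self, noiseless_scenario):
        from hdzipkit.synthetic import generate_expression
        _, ct, truth = generate_expression(noiseless_scenario)
        res = analyze_qpcr(ct, "NTC")
        for r in res:
            assert r.relative_expression == pytest.approx(
                truth.true_qpcr_ratio[r.gene_id][r.sample], rel=1e-3)

    def test_missing_calibrator_rejected(self, noiseless_scenario):
        from hdzipkit.synthetic import generate_expression
        _, ct, _ = generate_expression(noiseless_scenario)
        with pytest.raises(ValueError, match="calibrator"):
            analyze_qpcr(ct, "no_such_sample")
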