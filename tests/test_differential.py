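import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lipsite.differential import (
    DEFAULT_FC_THRESHOLD,
    DEFAULT_Q_THRESHOLD,
    adjust_fdr,
    differential_table,
    differential_test,
    filter_candidates,
    log2_fold_change,
    median_center,
)


def _quant_frame(groups):
    """Build a minimal quant table from {peptide: {dose: [replicate values]}}."""
    rows = []
    for pep, by_dose in groups.items():
        for dose, values in by_dose.items():
            for i, v in enumerate(values):
                rows.append(("P", pep, pep, dose, f"R{i+1}", v))
    return pd.DataFrame(
        rows,
        columns=["protein_id", "modified_sequence", "stripped_sequence",
                 "dose", "replicate", "quantity"],
    )


#: flat majority peptides so the per-sample median is a constant anchor and
#: centering does not distort the peptide under test
_ANCHORS = {
    "XK": {0.0: [1000, 1000, 1000], 2e-6: [1000, 1000, 1000]},
    "YK": {0.0: [1000, 1000, 1000], 2e-6: [1000, 1000, 1000]},
    "ZK": {0.0: [1000, 1000, 1000], 2e-6: [1000, 1000, 1000]},
}


class TestLog2FoldChange:
    def test_identical_groups_give_zero(self):
        q = _quant_frame({"AK": {0.0: [100, 100, 100], 2e-6: [100, 100, 100]}, **_ANCHORS})
        assert log2_fold_change(q, "AK", 2e-6) == pytest.approx(0.0)

    def test_exact_doubling_gives_one(self):
        q = _quant_frame({"AK": {0.0: [50, 50, 50], 2e-6: [100, 100, 100]}, **_ANCHORS})
        assert log2_fold_change(q, "AK", 2e-6) == pytest.approx(1.0)

    def test_hand_computed_fixture_after_centering(self):
        # (100,110,90) vs (50,55,45): exactly 2x at every replicate rank
        q = _quant_frame(
            {"AK": {2e-6: [100, 110, 90], 0.0: [50, 55, 45]}, **_ANCHORS}
        )
        lfc = log2_fold_change(q, "AK", 2e-6)
        expected = np.mean(np.log2([100, 110, 90])) - np.mean(np.log2([50, 55, 45]))
        assert lfc == pytest.approx(expected, abs=1e-6)
        assert lfc == pytest.approx(1.0, abs=0.01)

    def test_missing_condition_marks_nan(self):
        q = _quant_frame({"AK": {0.0: [50, 50]}, **_ANCHORS})
        assert np.isnan(log2_fold_change(q, "AK", 2e-6))


class TestWelchTest:
    def test_identical_groups_give_p_one(self):
        q = _quant_frame({"AK": {0.0: [100, 100, 100], 2e-6: [100, 100, 100]}, **_ANCHORS})
        assert differential_test(q, "AK", 2e-6) == 1.0

    def test_zero_variance_different_means_give_p_zero(self):
        q = _quant_frame({"AK": {0.0: [100, 100, 100], 2e-6: [200, 200, 200]}, **_ANCHORS})
        assert differential_test(q, "AK", 2e-6) == 0.0

    def test_matches_reference_welch_formula(self):
        """Hand-rolled Welch-Satterthwaite oracle on a fixed fixture."""
        a_raw = [10.01, 9.98, 10.03]
        b_raw = [13.02, 12.97, 13.00]
        q = _quant_frame(
            {
                "AK": {2e-6: [2.0**v for v in a_raw], 0.0: [2.0**v for v in b_raw]},
                **_ANCHORS,
            }
        )
        centered = median_center(q)
        rows = centered[centered["modified_sequence"] == "AK"]
        a = rows.loc[rows["dose"] == 2e-6, "log2_centered"].to_numpy()
        b = rows.loc[rows["dose"] == 0.0, "log2_centered"].to_numpy()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert differential_test(q, "AK", 2e-6) == pytest.approx(p_oracle, abs=1e-10)

    def test_single_replicate_marks_nan(self):
        q = _quant_frame({"AK": {0.0: [100.0], 2e-6: [120, 130]}, **_ANCHORS})
        assert np.isnan(differential_test(q, "AK", 2e-6))


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.04]) == pytest.approx([0.04])

    def test_worked_step_up_case(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_matches_brute_force_step_up(self, p_list):
        """BH step-up oracle: q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
        p = np.array(p_list)
        m = p.size
        order = np.argsort(p, kind="stable")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(adjust_fdr(p), oracle, atol=1e-12)

    def test_monotone_on_sorted_input(self):
        q = adjust_fdr(np.linspace(0.001, 0.9, 20))
        assert (np.diff(q) >= -1e-12).all()


class TestCandidateFilter:
    @staticmethod
    def _results(rows):
        return pd.DataFrame(rows, columns=["peptide", "dose", "log2_fc", "p_value", "q_value"])

    def test_flat_peptide_excluded(self):
        res = self._results([("AK", 2e-6, 0.0, 1e-6, 1e-6)])
        assert filter_candidates(res) == set()

    def test_hand_applied_thresholds_on_five_peptide_fixture(self):
        # survivors: BK (q and fc pass), EK (passes at one comparison: rule any)
        res = self._results(
            [
                ("AK", 2e-6, 0.30, 1e-5, 1e-4),   # fc too small
                ("BK", 2e-6, 1.20, 1e-6, 1e-5),   # passes
                ("CK", 2e-6, -0.80, 0.02, 0.05),  # q too big
                ("DK", 2e-6, 0.10, 0.9, 0.95),    # fails both
                ("EK", 2e-6, 0.20, 0.5, 0.6),     # fails here...
                ("EK", 2e-5, -0.90, 1e-7, 1e-6),  # ...passes here
            ]
        )
        assert filter_candidates(res) == {"BK", "EK"}

    def test_all_rule_requires_every_comparison(self):
        res = self._results(
            [("EK", 2e-6, 0.20, 0.5, 0.6), ("EK", 2e-5, -0.90, 1e-7, 1e-6)]
        )
        assert filter_candidates(res, rule="all") == set()

    def test_default_thresholds_are_published_values(self):
        assert DEFAULT_Q_THRESHOLD == 0.01
        assert DEFAULT_FC_THRESHOLD == 0.46

    def test_raising_thresholds_never_grows_candidates(self):
        rng = np.random.default_rng(0)
        res = self._results(
            [
                (f"P{i}K", 2e-6, rng.normal(0, 1), p, q)
                for i, (p, q) in enumerate(
                    zip(rng.uniform(0, 0.1, 40), rng.uniform(0, 0.1, 40))
                )
            ]
        )
        base = filter_candidates(res, q_threshold=0.02, fc_threshold=0.46)
        stricter_q = filter_candidates(res, q_threshold=0.005, fc_threshold=0.46)
        stricter_fc = filter_candidates(res, q_threshold=0.02, fc_threshold=1.0)
        assert stricter_q <= base and stricter_fc <= base


class TestDifferentialTable:
    def test_three_default_comparisons(self, noiseless_experiment):
        quant, _, _ = noiseless_experiment
        table = differential_table(median_center(quant))
        assert set(table["dose"].unique()) == {2e-6, 2e-5, 1e-4}

    def test_candidate_set_invariant_under_row_permutation(self, noiseless_experiment):
        quant, _, _ = noiseless_experiment
        shuffled = quant.sample(frac=1.0, random_state=5).reset_index(drop=True)
        c1 = filter_candidates(differential_table(median_center(quant)))
        c2 = filter_candidates(differential_table(median_center(shuffled)))
        assert c1 == c2

    def test_noiseless_filter_returns_exactly_planted_set(self, noiseless_experiment):
        quant, _, truth = noiseless_experiment
        table = differential_table(median_center(quant))
        assert filter_candidates(table) == set(truth.responsive_peptides)
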