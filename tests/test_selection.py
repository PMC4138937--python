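import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import restdecode as rd
from restdecode.selection import MIN_PAIRS, SelectionCriterion, _signed_rank_z


# ----------------------------------------------------------- exact oracle

def exact_signed_rank_distribution(magnitudes):
    """Exact W+ distribution by enumerating all 2^n sign patterns.

    Uses midranks of the given magnitudes, so ties are honoured.
    Returns (support, probabilities).
    """
    mags = np.asarray(magnitudes, dtype=float)
    n = len(mags)
    ranks = scipy.stats.rankdata(mags)
    ws = {}
    for signs in itertools.product((0, 1), repeat=n):
        w = float(np.dot(signs, ranks))
        ws[w] = ws.get(w, 0) + 1
    support = np.array(sorted(ws))
    probs = np.array([ws[w] for w in support]) / 2.0**n
    return support, probs


def exact_two_sided_p(diffs):
    """Exact two-sided p of W+ for the observed signs."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    support, probs = exact_signed_rank_distribution(np.abs(d))
    mu = len(d) * (len(d) + 1) / 4.0
    return probs[np.abs(support - mu) >= abs(w_obs - mu) - 1e-9].sum()


class TestWilcoxonZ:
    def test_all_positive_n5_matches_enumeration(self):
        """diffs [1..5]: W+ = 15, Z = 7.5/sqrt(13.75)."""
        z = rd.wilcoxon_signed_rank_z([1, 2, 3, 4, 5])
        assert z == pytest.approx(7.5 / np.sqrt(13.75), abs=1e-12)
        # the exact distribution puts W+=15 at its maximum
        support, probs = exact_signed_rank_distribution([1, 2, 3, 4, 5])
        assert support[-1] == 15.0
        assert exact_two_sided_p([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)

    def test_antisymmetric_diffs_give_zero(self):
        assert rd.wilcoxon_signed_rank_z([-3, -1, 1, 3, -2, 2]) == pytest.approx(0.0)

    def test_sign_convention_positive_when_ec_larger(self):
        assert rd.wilcoxon_signed_rank_z([1, 2, 3, 4, 5, 6]) > 0
        assert rd.wilcoxon_signed_rank_z([-1, -2, -3, -4, -5, -6]) < 0

    def test_all_zero_is_degenerate_zero(self):
        z, n, degen = _signed_rank_z(np.zeros(8))
        assert z == 0.0 and degen and n == 0

    def test_too_few_nonzero_pairs_rejected(self):
        with pytest.raises(ValueError, match="non-zero pairs"):
            rd.wilcoxon_signed_rank_z([0, 0, 0, 0, 1, 2, 3])

    def test_zero_diffs_dropped_before_ranking(self):
        with_zeros = rd.wilcoxon_signed_rank_z([0.0, 1, 2, 3, 4, 5, 0.0])
        assert with_zeros == pytest.approx(rd.wilcoxon_signed_rank_z([1, 2, 3, 4, 5]))

    @pytest.mark.parametrize("n", [7, 8])
    def test_normal_p_matches_exact_enumeration_per_pattern(self, n):
        """Continuity-corrected normal p agrees with exact p within 0.03
        for |Z| <= 2.5, checked pattern by pattern at small n (the full
        n <= 12 sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(n)
        mags = rng.uniform(0.5, 3.0, size=n)
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        for signs in itertools.product((-1, 1), repeat=n):
            d = mags * np.array(signs)
            z = rd.wilcoxon_signed_rank_z(d)
            if abs(z) > 2.5:
                continue
            p_cc = 2 * scipy.stats.norm.sf(max(abs(z) * sigma - 0.5, 0.0) / sigma)
            assert abs(p_cc - exact_two_sided_p(d)) < 0.03

    def test_small_n_lattice_gap_near_centre(self):
        """At n = 5 the uncorrected two-sided normal p undershoots the
        exact p near the centre of the W+ lattice (worst gap > 0.1) —
        why the approximation is only trusted at tail thresholds."""
        support, probs = exact_signed_rank_distribution([1, 2, 3, 4, 5])
        mu, sigma = 7.5, np.sqrt(13.75)
        worst = max(
            abs(2 * scipy.stats.norm.sf(abs(w - mu) / sigma)
                - probs[np.abs(support - mu) >= abs(w - mu) - 1e-9].sum())
            for w in support)
        assert worst > 0.1

    def test_tied_magnitudes_match_scipy_approx(self):
        """Midranks + tie-corrected variance agree with scipy's |z|."""
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0, -3.0, 4.0])
        res = scipy.stats.wilcoxon(d, method="approx", correction=False)
        assert abs(rd.wilcoxon_signed_rank_z(d)) == pytest.approx(
            abs(res.zstatistic), abs=1e-10)

    @given(st.lists(st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-3),
                    min_size=MIN_PAIRS, max_size=24))
    @settings(deadline=None, max_examples=50)
    def test_matches_scipy_magnitude_on_random_diffs(self, diffs):
        d = np.array(diffs)
        res = scipy.stats.wilcoxon(d, method="approx", correction=False)
        assert abs(rd.wilcoxon_signed_rank_z(d)) == pytest.approx(
            abs(res.zstatistic), abs=1e-9)


class TestScoreAllRois:
    def _tables(self, rng, n_sub=8, n_roi=6, shift=0.0):
        ec = pd.DataFrame(rng.standard_normal((n_sub, n_roi)) + shift,
                          index=[f"s{i}" for i in range(n_sub)],
                          columns=[f"r{j}" for j in range(n_roi)])
        eo = pd.DataFrame(rng.standard_normal((n_sub, n_roi)),
                          index=ec.index, columns=ec.columns)
        return ec, eo

    def test_identical_tables_all_degenerate_zero(self):
        rng = np.random.default_rng(0)
        ec, _ = self._tables(rng)
        scores = rd.score_all_rois(ec, ec.copy())
        assert np.all(scores.z == 0.0) and np.all(scores.degenerate)

    def test_label_swap_negates_z_exactly(self):
        rng = np.random.default_rng(1)
        ec, eo = self._tables(rng, shift=0.4)
        z1 = rd.score_all_rois(ec, eo).z
        z2 = rd.score_all_rois(eo, ec).z
        np.testing.assert_allclose(z2, -z1, atol=1e-12)

    def test_subject_mismatch_names_discrepancy(self):
        rng = np.random.default_rng(2)
        ec, eo = self._tables(rng)
        eo = eo.rename(index={"s0": "sX"})
        with pytest.raises(ValueError, match="sX"):
            rd.score_all_rois(ec, eo)

    def test_subjects_paired_by_id_not_position(self):
        rng = np.random.default_rng(3)
        ec, eo = self._tables(rng, shift=0.5)
        shuffled = eo.sample(frac=1, random_state=0)
        np.testing.assert_allclose(rd.score_all_rois(ec, shuffled).z,
                                   rd.score_all_rois(ec, eo).z)

    def test_planted_effect_rois_carry_top_z(self, d160, small_cohort_tables):
        cfg, tables = small_cohort_tables
        scores = rd.score_all_rois(tables["EC"], tables["EO"], d160)
        eff = set(rd.default_effect_rois(d160))
        top = set(np.argsort(-scores.z)[: len(eff)])
        assert len(eff & top) >= 8  # 10 planted, allow 2 swaps


class TestCriteriaAndPatterns:
    def test_study_criteria_are_the_four_published_rules(self):
        labels = [c.label for c in rd.study_criteria()]
        assert labels == ["|Z| > 1.96", "Z > 1.96", "Z > 2.25", "Z < -1.96"]

    def test_table1_pattern_sizes(self, table1):
        scores = rd.RoiZScores.from_template(table1)
        sizes = [len(rd.select_pattern(scores, c)) for c in rd.study_criteria()]
        assert sizes == [28, 21, 13, 7]

    def test_threshold_is_strict(self):
        scores = rd.RoiZScores(z=[1.96, 1.9601, -1.96, -2.0], n_pairs=10,
                               roi_names=list("abcd"), degenerate=[False] * 4)
        sel = rd.select_pattern(scores, SelectionCriterion("abs_gt", 1.96))
        assert set(sel.roi_names) == {"b", "d"}  # exactly-1.96 rows excluded

    def test_pattern_ordered_by_descending_abs_z(self, table1):
        scores = rd.RoiZScores.from_template(table1)
        pat = rd.select_pattern(scores, SelectionCriterion("abs_gt", 1.96))
        assert np.all(np.diff(np.abs(pat.z_values)) <= 1e-12)
        # ties broken by template order
        ties = pat.roi_indices[np.abs(pat.z_values) == 2.92]
        assert list(ties) == sorted(ties)

    def test_empty_selection_warns(self):
        scores = rd.RoiZScores(z=[0.1, -0.2], n_pairs=10, roi_names=["a", "b"],
                               degenerate=[False, False])
        with pytest.warns(UserWarning, match="selects no ROI"):
            pat = rd.select_pattern(scores, SelectionCriterion("pos_gt", 1.96))
        assert len(pat) == 0

    @given(st.lists(st.floats(min_value=-4, max_value=4), min_size=5, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_nesting_and_disjoint_union(self, zs):
        scores = rd.RoiZScores(z=zs, n_pairs=24,
                               roi_names=[f"r{i}" for i in range(len(zs))],
                               degenerate=[False] * len(zs))
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            pats = {c.name: set(rd.select_pattern(scores, c).roi_indices)
                    for c in rd.study_criteria()}
        assert pats["pos_gt_strict"] <= pats["pos_gt"] <= pats["abs_gt"]
        assert pats["abs_gt"] == pats["pos_gt"] | pats["neg_lt"]
        assert not pats["pos_gt"] & pats["neg_lt"]

    def test_antisymmetry_maps_pos_pattern_to_neg(self):
        rng = np.random.default_rng(4)
        z = rng.normal(0, 1.5, 40)
        mk = lambda zz: rd.RoiZScores(z=zz, n_pairs=24,
                                      roi_names=[f"r{i}" for i in range(40)],
                                      degenerate=[False] * 40)
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            pos = rd.select_pattern(mk(z), SelectionCriterion("pos_gt", 1.96))
            neg = rd.select_pattern(mk(-z), SelectionCriterion("neg_lt", 1.96))
        assert set(pos.roi_indices) == set(neg.roi_indices)

    def test_fdr_flag_only_shrinks_selection(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1.5, 100)
        scores = rd.RoiZScores(z=z, n_pairs=24,
                               roi_names=[f"r{i}" for i in range(100)],
                               degenerate=[False] * 100)
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            plain = rd.select_pattern(scores, SelectionCriterion("abs_gt", 1.96))
            fdr = rd.select_pattern(scores, SelectionCriterion("abs_gt", 1.96),
                                    fdr_alpha=0.05)
        assert set(fdr.roi_indices) <= set(plain.roi_indices)


class TestModuleComposition:
    def test_table1_positive_pattern_is_86pct_sensorimotor(self, table1):
        scores = rd.RoiZScores.from_template(table1)
        pat = rd.select_pattern(scores, SelectionCriterion("pos_gt", 1.96))
        comp = rd.module_composition(pat)
        assert int(comp.loc["sensorimotor", "count"]) == 18
        assert round(comp.loc["sensorimotor", "percent"]) == 86

    def test_counts_sum_to_pattern_size_percentages_to_100(self, table1):
        scores = rd.RoiZScores.from_template(table1)
        pat = rd.select_pattern(scores, SelectionCriterion("abs_gt", 1.96))
        comp = rd.module_composition(pat)
        assert comp["count"].sum() == 28
        assert comp["percent"].sum() == pytest.approx(100.0)

    def test_single_roi_pattern_is_100pct_its_module(self, table1):
        scores = rd.RoiZScores.from_template(table1)
        pat = rd.select_pattern(scores, SelectionCriterion("pos_gt_strict", 3.0))
        assert len(pat) == 1
        comp = rd.module_composition(pat)
        assert comp["percent"].iloc[0] == 100.0


class TestSelectorEstimator:
    def test_selector_fits_on_differences_and_transforms(self):
        rng = np.random.default_rng(6)
        D = rng.standard_normal((24, 30))
        D[:, 3] += 1.5
        sel = rd.PairedWilcoxonSelector(criterion="pos_gt", threshold=1.96).fit(D)
        assert sel.support_[3]
        out = sel.transform(D)
        assert out.shape[1] == sel.support_.sum()
        # first output column is the largest-|Z| ROI
        assert sel.order_[0] == np.argmax(np.abs(sel.z_))

    def test_selector_clonable(self):
        from sklearn.base import clone

        clone(rd.PairedWilcoxonSelector(criterion="neg_lt", threshold=2.25))
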