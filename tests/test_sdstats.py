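"""Exact contingency tests (with a brute-force enumeration oracle),
inheritance-model goodness of fit, Hardy-Weinberg deviation, association
scanning and one-way ANOVA."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wzkit.sdstats import (AlleleFreqs, anova_oneway, association_scan,
                           fisher_exact_2x2, fisher_exact_rxc, gof_pearson,
                           hwe_deviation_test, hwe_expected, model_expected)
from wzkit.simulate import MarkerDef, SimConfig, gen_cohort
from tests.conftest import MARKER_POSITIONS_KBP, MARKER_TABLES


def brute_force_exact_p(table):
    """Independent oracle: enumerate every margins-fixed table with exact
    rational arithmetic and sum probabilities <= the observed one."""
    t = np.asarray(table)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()

    def prob(cells):
        num = (np.prod([factorial(int(r)) for r in rows], dtype=object)
               * np.prod([factorial(int(c)) for c in cols], dtype=object))
        den = factorial(int(n))
        for c in cells:
            den *= factorial(int(c))
        return Fraction(int(num), int(den))

    observed = prob(t.ravel())
    total = Fraction(0)
    ranges = [range(int(r) + 1) for r in rows]
    for col1 in itertools.product(*ranges):
        if sum(col1) != cols[0]:
            continue
        cells = [x for a, r in zip(col1, rows) for x in (a, r - a)]
        p = prob(cells)
        if p <= observed:
            total += p
    return float(total)


class TestFisher2x2:
    def test_near_perfect_marker_table(self):
        assert fisher_exact_2x2(MARKER_TABLES["Banf2_w"]) == pytest.approx(
            1.5e-26, rel=0.05)

    def test_flat_table_has_no_association(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_hand_enumerated_value(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_empty_margin_warns_p1(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0


class TestFreemanHalton:
    @pytest.mark.parametrize("marker, expected", [
        ("Paics_long", 3.9e-3),
        ("M1_like", 6.8e-3),
        ("UNH168", 6e-12),
    ])
    def test_published_marker_tables(self, marker, expected):
        assert fisher_exact_rxc(MARKER_TABLES[marker]) == pytest.approx(
            expected, rel=0.05)

    def test_rows_proportional_to_margins(self):
        assert fisher_exact_rxc([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_hand_enumerated_3x2(self):
        assert fisher_exact_rxc([[2, 0], [0, 2], [1, 1]]) == pytest.approx(0.6)

    def test_agrees_with_2x2_fisher(self):
        for table in ([[48, 1], [0, 47]], [[3, 1], [1, 3]], [[10, 2], [4, 9]]):
            assert fisher_exact_rxc(table) == pytest.approx(
                fisher_exact_2x2(table), abs=1e-12)

    def test_matches_brute_force_on_small_tables(self, rng):
        # all 3x2 shapes with N <= 12, random sample plus known corner cases
        tables = [[[2, 0], [0, 2], [1, 1]], [[4, 0], [0, 4], [2, 2]],
                  [[1, 1], [1, 1], [1, 1]], [[3, 0], [0, 3], [3, 3]]]
        for _ in range(40):
            t = rng.integers(0, 3, size=(3, 2))
            if t.sum() == 0 or np.any(t.sum(axis=0) == 0):
                continue
            if np.all(t.sum(axis=1) > 0):
                tables.append(t.tolist())
        for table in tables:
            assert fisher_exact_rxc(table) == pytest.approx(
                brute_force_exact_p(table), rel=1e-9)

    def test_capability_bound(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, 1]] * 9)


class TestInheritanceModels:
    def test_hwe_expected_counts(self):
        np.testing.assert_allclose(
            hwe_expected(AlleleFreqs(0.5, 0.5), 48), [12, 24, 12])
        np.testing.assert_allclose(
            hwe_expected(AlleleFreqs(1.0, 0.0), 10), [10, 0, 0])
        np.testing.assert_allclose(
            hwe_expected(AlleleFreqs(0.75, 0.25), 96), [54, 36, 6])

    def test_model_expected_counts(self):
        half = AlleleFreqs(0.5, 0.5)
        np.testing.assert_allclose(
            model_expected("lethal_ww", half, 48), [16, 32, 0])
        np.testing.assert_allclose(
            model_expected("female_w", AlleleFreqs(0.3, 0.7), 48), [0, 48, 0])
        np.testing.assert_allclose(
            model_expected("autosomal", AlleleFreqs(1.0, 0.0), 5), [5, 0, 0])
        with pytest.raises(ValueError):
            model_expected("dominant_y", half, 10)

    def test_model_totals_are_conserved(self):
        half = AlleleFreqs(0.5, 0.5)
        for name in ("autosomal", "lethal_ww", "female_w"):
            assert model_expected(name, half, 48).sum() == pytest.approx(48)

    def test_autosomal_model_rejected_for_all_heterozygotes(self):
        res = gof_pearson([0, 48, 0], [12, 24, 12], "autosomal")
        assert res.chi2 == pytest.approx(48.0)
        assert res.df == 2
        assert res.p == pytest.approx(3.8e-11, rel=0.05)

    def test_obligate_heterozygote_model_fits_exactly(self):
        res = gof_pearson([0, 48, 0], [0, 48, 0], "female_w")
        assert res.chi2 == 0.0 and res.df == 0 and res.p == 1.0

    def test_lethal_ww_model_pearson_value(self):
        # defined Pearson value on the lethal-WW expectation (16, 32, 0):
        # chi2 = 24 on 1 df
        res = gof_pearson([0, 48, 0], [16, 32, 0], "lethal_ww")
        assert res.chi2 == pytest.approx(24.0)
        assert res.df == 1
        assert res.p == pytest.approx(9.6e-7, rel=0.05)

    def test_observation_in_structural_zero_rejects_outright(self):
        res = gof_pearson([0, 40, 8], [16, 32, 0], "lethal_ww")
        assert res.p == 0.0

    def test_invariant_to_cell_order(self):
        a = gof_pearson([5, 10, 33], [8, 12, 28])
        b = gof_pearson([33, 5, 10], [28, 8, 12])
        assert a.chi2 == pytest.approx(b.chi2) and a.p == pytest.approx(b.p)

    def test_p_decreases_with_chi2_at_fixed_df(self):
        ps = [gof_pearson([k, 48 - k, 0], [16, 32, 0]).p for k in (8, 4, 0)]
        assert ps[0] > ps[1] > ps[2]


class TestHweDeviation:
    def test_no_ww_individuals_deviate(self):
        res = hwe_deviation_test((48, 48, 0))
        np.testing.assert_allclose(res.expected, [54, 36, 6])
        assert res.chi2 == pytest.approx(32 / 3, rel=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(1.07e-3, rel=0.05)
        assert res.p <= 4.2e-3  # the published bound

    def test_perfect_hwe(self):
        res = hwe_deviation_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0) and res.p == 1.0

    def test_maximal_deviation(self):
        res = hwe_deviation_test((10, 0, 10))
        assert res.chi2 == pytest.approx(20.0)
        assert res.p < 1e-4

    def test_monomorphic_sample_fits(self):
        assert hwe_deviation_test((30, 0, 0)).p == 1.0


def _cohort_from_tables():
    """Rebuild a long-format cohort from the published genotype-by-sex
    tables (rows align across markers by construction of the counts)."""
    genotypes = {
        "UNH168": ["N/N", "N/W", "N/Z", "Z/W", "Z/Z"],
        "Paics_long": ["F/F", "F/S", "S/S"],
        "Banf2_del": ["F/S", "S/S"],
        "Banf2_w": ["W/Z", "Z/Z"],
        "Paics_short": ["P", "A"],
        "M1_like": ["F/F", "F/S", "S/S"],
    }
    rows = []
    for sex_idx, sex, n in ((0, "F", 48), (1, "M", 48)):
        for k in range(n):
            rows.append({"id": f"{sex}{k}", "sex": sex})
    # assign genotypes marker by marker, filling each sex column in order
    for marker, labels in genotypes.items():
        for sex_idx, sex in ((0, "F"), (1, "M")):
            values = []
            for label, counts in zip(labels, MARKER_TABLES[marker]):
                values.extend([label] * counts[sex_idx])
            target = [r for r in rows if r["sex"] == sex]
            assert len(values) == len(target)
            for r, v in zip(target, values):
                r[marker] = v
    return pd.DataFrame(rows)


class TestAssociationScan:
    def test_published_cohort_reproduces_interval(self):
        cohort = _cohort_from_tables()
        markers = [MarkerDef(name, pos) for name, pos in
                   MARKER_POSITIONS_KBP.items()]
        scan = association_scan(cohort, markers)
        by_name = {r.marker: r for r in scan.results}
        for top in ("Banf2_w", "Banf2_del", "Paics_short"):
            assert by_name[top].p == pytest.approx(1.5e-26, rel=0.05)
        assert by_name["Paics_long"].p == pytest.approx(3.9e-3, rel=0.05)
        assert by_name["M1_like"].p == pytest.approx(6.8e-3, rel=0.05)
        assert by_name["UNH168"].p == pytest.approx(6e-12, rel=0.1)
        assert scan.interval_kbp == (73159.0, 73394.0)
        assert scan.span_kbp == pytest.approx(235.0)

    def test_simulated_near_perfect_marker(self):
        config = SimConfig(seed=17, n_females=48, n_males=48,
                           sex_reversal_rate=1 / 96)
        markers = [MarkerDef("sd", 100.0, 0.0)]
        cohort = gen_cohort(config, markers)
        scan = association_scan(cohort, markers)
        assert scan.results[0].p < 1e-20

    def test_dominant_marker_collapses_to_presence_absence(self):
        config = SimConfig(seed=2, n_females=20, n_males=20)
        markers = [MarkerDef("dom", 50.0, 0.0, dominant=True,
                             dominant_allele="W")]
        cohort = gen_cohort(config, markers)
        scan = association_scan(cohort, markers)
        assert scan.results[0].table.row_labels == ["A", "P"]

    def test_type_one_error_at_most_nominal(self):
        # unlinked marker: exact-test false-positive rate <= alpha (the test
        # is conservative by discreteness)
        markers = [MarkerDef("null", 0.0, 0.5)]
        rejections = 0
        n_sim = 200
        for seed in range(n_sim):
            config = SimConfig(seed=seed, n_females=12, n_males=12)
            scan = association_scan(gen_cohort(config, markers), markers)
            rejections += scan.results[0].p <= 0.05
        bound = 0.05 * n_sim + 3 * np.sqrt(n_sim * 0.05 * 0.95)
        assert rejections <= bound

    def test_single_sex_cohort_warns_p1(self):
        config = SimConfig(seed=1, n_females=10, n_males=0)
        markers = [MarkerDef("m", 0.0, 0.0)]
        cohort = gen_cohort(config, markers)
        with pytest.warns(UserWarning):
            scan = association_scan(cohort, markers)
        assert scan.results[0].p == 1.0


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([[1.0, 2.0], [1.0, 2.0]])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_f(self):
        f, p = anova_oneway([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0)
        assert p == pytest.approx(0.1056, abs=1e-3)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(4)
        ps = [anova_oneway([rng.normal(size=6), rng.normal(size=6)])[1]
              for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 1.0], [1.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0]])
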