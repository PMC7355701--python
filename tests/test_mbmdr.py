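from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from tp53axis import (
    categorize_cells,
    enumerate_cells,
    mbmdr_report,
    permutation_correct,
    preset,
    scan_combinations,
    simulate_cohort,
    step2_test,
    wald_to_p,
)
from tp53axis.mbmdr import MIN_CELL_SIZE, P_THRESHOLD, _ComboData, logistic_irls

PAIR = ("MDM2_rs2279744", "TP53_rs1042522")

# published Wald statistics, their printed chi-square(1) upper-tail
# p-values, and the number of printed decimals; both W and p are printed
# rounded, so agreement is to within 1.5 printed ulp of p
PUBLISHED_W_P = [(3.09, 0.078, 3), (2.97, 0.085, 3), (2.80, 0.094, 3),
                 (10.70, 0.001, 3), (3.49, 0.062, 3), (7.15, 0.008, 3),
                 (2.85, 0.092, 3), (2.75, 0.097, 3), (8.39, 0.004, 3),
                 (16.79, 0.00004, 5)]


@pytest.mark.parametrize("w,p,decimals", PUBLISHED_W_P,
                         ids=[str(w) for w, _, _ in PUBLISHED_W_P])
def test_wald_to_p_matches_published_pairs(w, p, decimals):
    assert wald_to_p(w) == pytest.approx(p, abs=1.5 * 10 ** -decimals)


class TestEnumerate:
    def test_two_locus_cells_partition_cohort(self, replica_cohort):
        cells = enumerate_cells(replica_cohort, PAIR)
        assert len(cells) <= 9
        assert sum(c.n_case + c.n_control for c in cells) == 809

    def test_four_locus_cells_partition_cohort(self, replica_cohort):
        cells = enumerate_cells(replica_cohort, tuple(replica_cohort.locus_ids))
        assert len(cells) <= 81
        assert sum(c.n_case + c.n_control for c in cells) == 809

    def test_counts_match_groupby_recount(self, replica_cohort):
        cells = enumerate_cells(replica_cohort, PAIR)
        df = replica_cohort.data
        for cell in cells:
            d = [list(replica_cohort.locus(l).genotype_labels).index(g)
                 for l, g in zip(cell.combo, cell.genotypes)]
            mask = (df[PAIR[0]] == d[0]) & (df[PAIR[1]] == d[1])
            assert cell.n_case == int((mask & (df["status"] == 1)).sum())
            assert cell.n_control == int((mask & (df["status"] == 0)).sum())

    def test_duplicate_or_bad_order_rejected(self, replica_cohort):
        with pytest.raises(ValueError):
            enumerate_cells(replica_cohort, (PAIR[0], PAIR[0]))
        with pytest.raises(ValueError):
            enumerate_cells(replica_cohort, (PAIR[0],))


class TestCategorize:
    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0, 1)),
                    min_size=1, max_size=30))
    def test_rule_is_pure_sign_and_threshold(self, cells):
        beta = np.array([b for b, _ in cells])
        p = np.array([q for _, q in cells])
        cat = _ComboData.categorize(beta, p)
        for b, q, c in zip(beta, p, cat):
            if q < P_THRESHOLD and b > 0:
                assert c == "H"
            elif q < P_THRESHOLD and b < 0:
                assert c == "L"
            else:
                assert c == "O"

    def test_boundary_p_is_no_evidence(self):
        cat = _ComboData.categorize(np.array([2.0, -2.0]),
                                    np.array([0.2, P_THRESHOLD]))
        assert list(cat) == ["O", "O"]

    def test_step1_beta_matches_glm(self, replica_cohort):
        """The closed-form per-cell log-OR equals a logistic regression of
        status on the cell indicator."""
        cells = categorize_cells(replica_cohort, PAIR)
        data = _ComboData(replica_cohort, PAIR)
        target = max(range(len(cells)),
                     key=lambda i: cells[i].n_case + cells[i].n_control)
        ind = (data.cell_idx == target).astype(float)
        X = np.column_stack([np.ones(data.n), ind])
        fit = sm.GLM(data.y.astype(float), X,
                     family=sm.families.Binomial()).fit()
        assert cells[target].beta == pytest.approx(fit.params[1], abs=1e-6)
        w = (fit.params[1] / fit.bse[1]) ** 2
        assert cells[target].p_step1 == pytest.approx(wald_to_p(w), abs=1e-4)

    def test_small_cells_forced_no_evidence(self, replica_cohort):
        cells = categorize_cells(replica_cohort, PAIR)
        for c in cells:
            if c.n_case + c.n_control < MIN_CELL_SIZE:
                assert c.category == "O"
                assert "below_min_cell_size" in c.flags

    def test_balanced_cell_is_no_evidence(self):
        from tp53axis.synthetic_cohort import cohort_from_marginal_counts
        counts = {"TP53_rs1042522": (100, 60, 40),
                  "MDM2_rs2279744": (120, 50, 30)}
        c = cohort_from_marginal_counts(counts, counts)
        cells = categorize_cells(c, PAIR)
        for cell in cells:
            if np.isfinite(cell.beta):
                assert abs(cell.beta) < 1e-9
            assert cell.category == "O"

    def test_planted_high_risk_cell_recovered(self):
        """A cell-specific odds ratio of 3 on the double-variant cell is
        categorized H in most seeds at n = 800."""
        hits = 0
        for s in range(10):
            cfg = replace(
                preset("null", seed=60 + s), n_cases=400, n_controls=400,
                betas={"recessive(MDM2_rs2279744)*recessive(TP53_rs1042522)":
                       np.log(3.0) + 0.8})
            cells = categorize_cells(simulate_cohort(cfg), PAIR)
            for cell in cells:
                if cell.genotypes == ("G/G", "Pro/Pro") and cell.category == "H":
                    hits += 1
        assert hits >= 6


class TestStep2:
    def test_na_convention_when_no_high_risk_cells(self):
        from tp53axis.synthetic_cohort import cohort_from_marginal_counts
        counts = {"TP53_rs1042522": (100, 60, 40),
                  "MDM2_rs2279744": (120, 50, 30)}
        c = cohort_from_marginal_counts(counts, counts)
        res = step2_test(c, PAIR)
        assert res.n_h == 0 and res.n_l == 0
        assert np.isnan(res.beta_h) and np.isnan(res.w_h) and np.isnan(res.p_h)

    def test_step2_wald_matches_statsmodels(self, replica_cohort):
        """The in-package IRLS reproduces the statsmodels GLM coefficient
        and Wald statistic for the merged-group model."""
        data = _ComboData(replica_cohort, PAIR)
        a, b, beta, p, _ = data.step1(data.y)
        cat = data.categorize(beta, p)
        res = step2_test(replica_cohort, PAIR)
        for grp, (b_ours, w_ours) in (("H", (res.beta_h, res.w_h)),
                                      ("L", (res.beta_l, res.w_l))):
            member = np.isin(data.cell_idx, np.where(cat == grp)[0])
            if not member.any():
                continue
            X = np.column_stack([np.ones(data.n), member.astype(float),
                                 data.X_tail])
            fit = sm.GLM(data.y.astype(float), X,
                         family=sm.families.Binomial()).fit()
            assert b_ours == pytest.approx(fit.params[1], abs=1e-6)
            assert w_ours == pytest.approx((fit.params[1] / fit.bse[1]) ** 2,
                                           abs=1e-4)

    def test_min_p_is_min_of_group_ps(self, replica_cohort):
        res = step2_test(replica_cohort, PAIR)
        ps = [p for p in (res.p_h, res.p_l) if np.isfinite(p)]
        assert res.min_p == pytest.approx(min(ps))


def test_logistic_irls_matches_statsmodels_on_random_designs():
    rng = np.random.default_rng(3)
    for _ in range(5):
        X = np.column_stack([np.ones(400), rng.random((400, 3))])
        beta_true = rng.normal(0, 0.8, 4)
        y = (rng.random(400) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        beta, se, ok = logistic_irls(X, y)
        assert ok
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, fit.params, atol=1e-6)
        np.testing.assert_allclose(se, fit.bse, atol=1e-6)


class TestPermutation:
    def test_perm_p_floor_and_determinism(self, replica_cohort):
        r1 = permutation_correct(replica_cohort, PAIR, n_perm=99, seed=7)
        r2 = permutation_correct(replica_cohort, PAIR, n_perm=99, seed=7)
        assert r1.perm_p == r2.perm_p
        assert r1.perm_p >= 1 / 100

    def test_no_risk_groups_gives_p_one(self):
        from tp53axis.synthetic_cohort import cohort_from_marginal_counts
        counts = {"TP53_rs1042522": (100, 60, 40),
                  "MDM2_rs2279744": (120, 50, 30)}
        c = cohort_from_marginal_counts(counts, counts)
        r = permutation_correct(c, PAIR, n_perm=20, seed=1)
        assert r.perm_p == 1.0
        assert "no_H_no_L" in r.flags

    def test_monte_carlo_stability_across_seeds(self, replica_cohort):
        r1 = permutation_correct(replica_cohort, PAIR, n_perm=200, seed=11)
        r2 = permutation_correct(replica_cohort, PAIR, n_perm=200, seed=12)
        se = np.sqrt(0.5 * 0.5 / 200)  # worst-case binomial MC error
        assert abs(r1.perm_p - r2.perm_p) <= 4 * se

    def test_n_perm_validation(self, replica_cohort):
        with pytest.raises(ValueError):
            permutation_correct(replica_cohort, PAIR, n_perm=0, seed=1)


def test_scan_combinations_row_count_and_report(replica_cohort):
    results = scan_combinations(replica_cohort, orders=(2, 3, 4),
                                n_perm=19, seed=5)
    assert len(results) == 6 + 4 + 1
    rep = mbmdr_report(results)
    assert list(rep["order"]) == [2] * 6 + [3] * 4 + [4] * 1
    assert {"N_H", "beta_H", "W_H", "p_H", "N_L", "perm_p"} <= set(rep.columns)
    # rows are independently reproducible from their spawned seeds
    again = scan_combinations(replica_cohort, orders=(2, 3, 4),
                              n_perm=19, seed=5)
    assert [r.perm_p for r in results] == [r.perm_p for r in again]
    assert all(0 <= r.seed < 2 ** 31 for r in results)
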