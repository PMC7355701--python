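from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tp53axis import (
    DEFAULT_LOCI,
    Cohort,
    associate_locus,
    association_table,
    bh_adjust,
    coding_design,
    crude_or_from_counts,
    fit_interaction_model,
    fit_locus,
    preset,
    simulate_cohort,
    stratum_odds_ratio,
)
from tp53axis.synthetic_cohort import cohort_from_marginal_counts

# published crude odds ratios: (a, b, c, d) with a/b exposed cases/controls
# and c/d reference cases/controls -> OR (lo, hi) to 2 decimals
PUBLISHED_CRUDE_ORS = [
    ("tp53 codominant Pro/Pro", (68, 37, 225, 217), 1.77, (1.14, 2.76)),
    ("tp53 recessive", (68, 37, 335, 369), 2.02, (1.32, 3.10)),
    ("tp53 overdominant", (110, 152, 293, 254), 0.63, (0.47, 0.84)),
    ("mdm4 codominant AC", (144, 114, 57, 83), 1.84, (1.21, 2.79)),
    ("mdm4 dominant", (346, 323, 57, 83), 1.56, (1.08, 2.26)),
    ("mdm2 309 dominant", (268, 265, 135, 141), 1.06, (0.79, 1.41)),
    ("mdm2 del1518 recessive", (50, 58, 353, 348), 0.85, (0.57, 1.28)),
]


@pytest.mark.parametrize("label,cells,or_exp,ci_exp", PUBLISHED_CRUDE_ORS,
                         ids=[x[0] for x in PUBLISHED_CRUDE_ORS])
def test_crude_or_reproduces_published_values(label, cells, or_exp, ci_exp):
    or_, (lo, hi), corrected = crude_or_from_counts(*cells)
    assert not corrected
    assert round(or_, 2) == pytest.approx(or_exp, abs=0.005)
    assert round(lo, 2) == pytest.approx(ci_exp[0], abs=0.005)
    assert round(hi, 2) == pytest.approx(ci_exp[1], abs=0.005)


def test_crude_or_symmetric_table_is_one():
    or_, _, _ = crude_or_from_counts(10, 10, 10, 10)
    assert or_ == pytest.approx(1.0)


def test_crude_or_zero_cell_uses_haldane_correction():
    or_, (lo, hi), corrected = crude_or_from_counts(5, 0, 10, 10)
    assert corrected
    assert np.isfinite(or_) and np.isfinite(hi)
    with pytest.raises(ValueError):
        crude_or_from_counts(-1, 2, 3, 4)


def test_coding_designs():
    d = np.array([0, 1, 2])
    labels = ("A/A", "A/B", "B/B")
    X, lv, ref = coding_design("codominant", d, labels)
    assert X.shape == (3, 2) and lv == ["A/B", "B/B"] and ref == "A/A"
    assert X.tolist() == [[0, 0], [1, 0], [0, 1]]
    X, lv, ref = coding_design("dominant", d, labels)
    assert X.ravel().tolist() == [0, 1, 1] and ref == "A/A"
    X, lv, ref = coding_design("recessive", d, labels)
    assert X.ravel().tolist() == [0, 0, 1] and ref == "A/A + A/B"
    X, lv, ref = coding_design("overdominant", d, labels)
    assert X.ravel().tolist() == [0, 1, 0] and ref == "A/A + B/B"
    with pytest.raises(ValueError):
        coding_design("additive!", d, labels)


class TestFitLocus:
    def test_glm_equals_closed_form_on_published_counts(self,
                                                        printed_counts_cohort):
        """For 1-column codings the GLM odds ratio and Wald CI coincide
        with the 2×2 cross-product closed form."""
        r = fit_locus(printed_counts_cohort, "TP53_rs1042522", "recessive")
        lev = r.levels[0]
        or_, (lo, hi), _ = crude_or_from_counts(
            lev.n_case, lev.n_control, *r.reference_counts[::-1])
        assert lev.odds_ratio == pytest.approx(or_, abs=1e-6)
        assert lev.ci_low == pytest.approx(lo, abs=1e-6)
        assert lev.ci_high == pytest.approx(hi, abs=1e-6)
        assert round(lev.odds_ratio, 2) == 2.02
        assert (round(lev.ci_low, 2), round(lev.ci_high, 2)) == (1.32, 3.10)

    def test_codominant_levels_equal_crossproduct_ratios(self,
                                                         printed_counts_cohort):
        r = fit_locus(printed_counts_cohort, "MDM4_rs4245739", "codominant")
        for lev in r.levels:
            or_, _, _ = crude_or_from_counts(lev.n_case, lev.n_control,
                                             *r.reference_counts[::-1])
            assert lev.odds_ratio == pytest.approx(or_, abs=1e-6)
        assert round(r.levels[0].odds_ratio, 2) == 1.84

    def test_published_model_pvalues_reproduced(self, printed_counts_cohort):
        """The four crude LRT p-values and their BH column at the TP53
        locus equal the published values at printed precision."""
        res = associate_locus(printed_counts_cohort, "TP53_rs1042522")
        p = {r.coding: r.p for r in res}
        q = {r.coding: r.p_fdr for r in res}
        assert round(p["codominant"], 4) == 0.0003
        assert round(p["dominant"], 4) == 0.4960
        assert round(p["recessive"], 4) in (0.0009, 0.0010)
        assert round(p["overdominant"], 4) == 0.0020
        assert round(q["codominant"], 4) == 0.0012
        assert round(q["dominant"], 4) == 0.4960

    def test_proportional_cohort_gives_null_fit(self):
        counts = {"TP53_rs1042522": (100, 60, 40)}
        c = cohort_from_marginal_counts(counts, {"TP53_rs1042522": (50, 30, 20)})
        for coding in ("dominant", "recessive", "codominant"):
            r = fit_locus(c, "TP53_rs1042522", coding)
            assert r.p == pytest.approx(1.0, abs=1e-9)
            for lev in r.levels:
                assert lev.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_close_to_crude_under_null(self, null_cohort):
        """With covariates independent of genotype and status, adjustment
        barely moves the estimate."""
        crude = fit_locus(null_cohort, "TP53_rs1042522", "dominant")
        adj = fit_locus(null_cohort, "TP53_rs1042522", "dominant", adjust=True)
        assert abs(adj.levels[0].beta - crude.levels[0].beta) < 0.05

    def test_empty_level_flagged_not_crashed(self):
        counts_ctrl = {"TP53_rs1042522": (50, 50, 0)}
        counts_case = {"TP53_rs1042522": (50, 50, 0)}
        c = cohort_from_marginal_counts(counts_ctrl, counts_case)
        r = fit_locus(c, "TP53_rs1042522", "recessive")
        assert "empty_level" in r.flags or "separation" in r.flags
        assert np.isnan(r.p)

    def test_refit_oracle_agreement(self):
        """GLM coefficients agree with an independent direct optimisation
        of the binomial log-likelihood from a different start."""
        from scipy.optimize import minimize

        for seed in range(5):
            cfg = replace(preset("study_replica", seed=30 + seed),
                          n_cases=300, n_controls=300)
            c = simulate_cohort(cfg)
            r = fit_locus(c, "TP53_rs1042522", "dominant", adjust=True)
            df = c.data
            y = df["status"].to_numpy(float)
            X = np.column_stack([
                np.ones(len(df)),
                (df["TP53_rs1042522"].astype(int) >= 1).astype(float),
                df["age_ge60"].astype(float), df["sex"].astype(float)])

            def nll(b):
                eta = X @ b
                return -(y * eta - np.log1p(np.exp(eta))).sum()

            opt = minimize(nll, x0=np.full(4, 0.5), method="BFGS",
                           options={"gtol": 1e-10})
            assert r.levels[0].beta == pytest.approx(opt.x[1], abs=1e-5)


class TestBHAdjust:
    def test_reproduces_published_fdr_column(self):
        adj = bh_adjust([0.0003, 0.0009, 0.0020, 0.4960])
        published = np.array([0.0012, 0.0019, 0.0027, 0.4960])
        assert np.abs(adj - published).max() <= 2e-4

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.05] * 4) == pytest.approx([0.05] * 4)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_step_up_properties(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestInteractionModel:
    def test_or_equals_exp_beta_and_derived_strata(self, replica_cohort):
        fit = fit_interaction_model(replica_cohort)
        for t in fit.terms:
            assert t.odds_ratio == pytest.approx(np.exp(t.beta), rel=1e-9)
        inter = "recessive(MDM2_rs2279744)*recessive(TP53_rs1042522)"
        manual = np.exp(fit.term("recessive(TP53_rs1042522)").beta
                        + fit.term(inter).beta)
        assert fit.stratum_or("recessive(TP53_rs1042522)", inter) == \
            pytest.approx(manual, rel=1e-12)

    def test_published_coefficient_arithmetic(self):
        """exp(0.51 + 1.22) = 5.64 for the doubly-variant stratum and
        exp(-0.92) = 0.40 for the second interaction term."""
        assert round(stratum_odds_ratio(0.51, 1.22), 2) == 5.64
        assert round(stratum_odds_ratio(-0.92), 2) == 0.40

    def test_codominant_rejected(self, replica_cohort):
        with pytest.raises(ValueError):
            fit_interaction_model(replica_cohort, coding="codominant")

    def test_term_layout(self, replica_cohort):
        fit = fit_interaction_model(replica_cohort)
        names = [t.name for t in fit.terms]
        assert names[0] == "intercept"
        assert sum("*" in n for n in names) == 2
        assert {"age_ge60", "male"} <= set(names)
        assert fit.n == 809


def test_association_table_shape(replica_cohort):
    tab = association_table(replica_cohort)
    # 4 loci × (codominant 3 rows + 3 codings × 2 rows)
    assert len(tab) == 4 * 9
    assert set(tab["coding"]) == {"codominant", "dominant", "recessive",
                                  "overdominant"}
    ref_rows = tab[tab["ci_crude"] == "Reference"]
    assert len(ref_rows) == 16
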