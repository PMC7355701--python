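"""Per-locus genetic-model logistic regression and the joint interaction fit.

Each biallelic locus is tested under four inheritance codings of the
variant-allele dosage d ∈ {0, 1, 2}:

* codominant — two dummies (d = 1, d = 2) against the d = 0 reference;
* dominant — one indicator 1{d >= 1};
* recessive — one indicator 1{d = 2};
* overdominant — one indicator 1{d = 1} (heterozygote vs both homozygotes).

Fits are maximum-likelihood logistic regressions (binomial GLM, logit
link), crude or adjusted for age group (>= 60 years) and sex.  Odds ratios
and 95% CIs are Wald; the single per-coding model p-value is a likelihood-
ratio test against the nested null (2 df for codominant, 1 df otherwise) —
with covariates, both models contain the covariates.  Within each locus the
four coding p-values are Benjamini–Hochberg adjusted (crude and adjusted
families kept separate).

The joint gene–gene interaction model fits all four recessive-coded main
effects, two product terms (rs2279744 × rs1042522 and rs4245739 ×
rs3730485) and the covariates in one logistic model; stratum odds ratios
are derived as exp of summed coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core_data_io import Cohort

Z95 = 1.959964  # two-sided 95% normal quantile

CODING_NAMES = ("codominant", "dominant", "recessive", "overdominant")

#: Default interaction pairs of the joint model (modifier locus first).
DEFAULT_INTERACTION_PAIRS = (
    ("MDM2_rs2279744", "TP53_rs1042522"),
    ("MDM4_rs4245739", "MDM2_rs3730485"),
)


# ---------------------------------------------------------------------------
# codings
# ---------------------------------------------------------------------------

def coding_design(coding: str, dosage: np.ndarray,
                  labels: tuple[str, str, str]
                  ) -> tuple[np.ndarray, list[str], str]:
    """Design columns for one coding.

    Returns (columns of shape (n, k), per-column level labels, reference
    label).  Codominant yields k = 2, the others k = 1; the reference
    category maps to an all-zero row.
    """
    d = np.asarray(dosage, dtype=int)
    l0, l1, l2 = labels
    if coding == "codominant":
        return (np.column_stack([(d == 1), (d == 2)]).astype(float),
                [l1, l2], l0)
    if coding == "dominant":
        return (d >= 1).astype(float)[:, None], [f"{l1} + {l2}"], l0
    if coding == "recessive":
        return (d == 2).astype(float)[:, None], [l2], f"{l0} + {l1}"
    if coding == "overdominant":
        return (d == 1).astype(float)[:, None], [l1], f"{l0} + {l2}"
    raise ValueError(f"unknown coding {coding!r}")


# ---------------------------------------------------------------------------
# closed-form 2×2 odds ratio
# ---------------------------------------------------------------------------

def crude_or_from_counts(a: int, b: int, c: int, d: int
                         ) -> tuple[float, tuple[float, float], bool]:
    """Cross-product odds ratio with Wald 95% CI from a 2×2 table.

    Orientation: ``a`` exposed cases, ``b`` exposed controls, ``c``
    reference cases, ``d`` reference controls, so OR = (a·d)/(b·c).
    Any zero cell triggers the Haldane–Anscombe +0.5 correction, signalled
    by the returned flag.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell count")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = float(np.sqrt((1 / cells).sum()))
    lo, hi = np.exp(np.log(or_) + np.array([-Z95, Z95]) * se)
    return float(or_), (float(lo), float(hi)), corrected


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class LevelEffect:
    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    n_control: int
    n_case: int


@dataclass
class AssociationResult:
    locus_id: str
    coding: str
    adjusted: bool
    reference_label: str
    reference_counts: tuple[int, int]   # (controls, cases)
    levels: list[LevelEffect]
    p: float                            # LRT model p (NaN when degenerate)
    df: int
    p_fdr: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class TermEffect:
    name: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float                            # Wald


@dataclass
class InteractionFit:
    terms: list[TermEffect]
    cov: np.ndarray                     # coefficient covariance (term order)
    n: int
    loglik: float
    flags: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermEffect:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def stratum_or(self, *term_names: str) -> float:
        """exp of the summed fitted coefficients — e.g. the odds ratio of
        the exposed stratum of an interaction (main effect + product)."""
        return float(np.exp(sum(self.term(n).beta for n in term_names)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": [t.name for t in self.terms],
             "beta": [t.beta for t in self.terms],
             "se": [t.se for t in self.terms],
             "OR": [t.odds_ratio for t in self.terms],
             "ci_low": [t.ci_low for t in self.terms],
             "ci_high": [t.ci_high for t in self.terms],
             "p": [t.p for t in self.terms]})


def stratum_odds_ratio(*betas: float) -> float:
    """exp of summed log-odds coefficients (derived stratum OR)."""
    return float(np.exp(np.sum(betas)))


# ---------------------------------------------------------------------------
# GLM machinery
# ---------------------------------------------------------------------------

def _fit_glm(y: np.ndarray, X: np.ndarray):
    """Binomial-logit GLM fit; returns (result, flag) where flag names a
    degeneracy ('separation' / 'non_convergence') or is None."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-8)
    except PerfectSeparationError:
        return None, "separation"
    except Exception:
        return None, "non_convergence"
    if not res.converged:
        return res, "non_convergence"
    if np.abs(res.params).max() > 15:
        return res, "separation"
    return res, None


def _covariate_matrix(df: pd.DataFrame) -> np.ndarray:
    return np.column_stack([df["age_ge60"].to_numpy(float),
                            df["sex"].to_numpy(float)])


def fit_locus(cohort: Cohort, locus_id: str, coding: str,
              adjust: bool = False) -> AssociationResult:
    """Single-locus logistic association under one inheritance coding.

    Complete-case on the locus (and covariates when ``adjust``); the LRT
    compares against the intercept(+covariate) null.  Degenerate fits are
    returned flagged with NaN p rather than raising.
    """
    locus = cohort.locus(locus_id)
    df = cohort.complete_cases([locus_id])
    y = df["status"].to_numpy(float)
    dosage = df[locus_id].astype(int).to_numpy()
    cols, level_labels, ref_label = coding_design(coding, dosage,
                                                  locus.genotype_labels)
    flags: list[str] = []
    # per-level counts
    ref_mask = cols.sum(axis=1) == 0
    ref_counts = (int(((y == 0) & ref_mask).sum()), int(((y == 1) & ref_mask).sum()))
    level_counts = [(int(((y == 0) & (cols[:, j] == 1)).sum()),
                     int(((y == 1) & (cols[:, j] == 1)).sum()))
                    for j in range(cols.shape[1])]
    if ref_mask.sum() == 0 or any(cols[:, j].sum() == 0 for j in range(cols.shape[1])):
        flags.append("empty_level")

    X_null = np.ones((len(y), 1))
    if adjust:
        X_null = np.column_stack([X_null, _covariate_matrix(df)])
    X_full = np.column_stack([X_null[:, :1], cols, X_null[:, 1:]])

    res_full, f1 = _fit_glm(y, X_full)
    res_null, f2 = _fit_glm(y, X_null)
    for f in (f1, f2):
        if f:
            flags.append(f)

    levels: list[LevelEffect] = []
    p = float("nan")
    dfree = cols.shape[1]
    if res_full is not None:
        beta = res_full.params[1:1 + cols.shape[1]]
        se = res_full.bse[1:1 + cols.shape[1]]
        for j, label in enumerate(level_labels):
            or_ = float(np.exp(beta[j]))
            lo, hi = np.exp(beta[j] + np.array([-Z95, Z95]) * se[j])
            levels.append(LevelEffect(label, or_, float(lo), float(hi),
                                      float(beta[j]), float(se[j]),
                                      *level_counts[j]))
        if not flags and res_null is not None:
            lrt = max(0.0, 2.0 * (res_full.llf - res_null.llf))
            p = float(stats.chi2.sf(lrt, dfree))
    return AssociationResult(locus_id, coding, adjust, ref_label, ref_counts,
                             levels, p, dfree, flags=flags)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        out = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            out[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return out
    return multipletests(p, method="fdr_bh")[1]


def associate_locus(cohort: Cohort, locus_id: str,
                    adjust: bool = False) -> list[AssociationResult]:
    """All four codings at one locus, with the BH family = those four
    model p-values (the published multiple-testing convention)."""
    results = [fit_locus(cohort, locus_id, c, adjust) for c in CODING_NAMES]
    adj = bh_adjust([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q) if not np.isnan(q) else None
    return results


def association_table(cohort: Cohort) -> pd.DataFrame:
    """Genotype-distribution-shaped report: per locus and coding, counts,
    percentages, crude and adjusted OR (95% CI), LRT p and BH-FDR p."""
    rows = []
    for locus in cohort.loci:
        crude = associate_locus(cohort, locus.locus_id, adjust=False)
        adjusted = associate_locus(cohort, locus.locus_id, adjust=True)
        for rc, ra in zip(crude, adjusted):
            n_ctrl = rc.reference_counts[0] + sum(l.n_control for l in rc.levels)
            n_case = rc.reference_counts[1] + sum(l.n_case for l in rc.levels)
            rows.append({"locus_id": locus.locus_id, "coding": rc.coding,
                         "genotype": rc.reference_label,
                         "controls_n": rc.reference_counts[0],
                         "controls_pct": round(100 * rc.reference_counts[0] / n_ctrl, 1),
                         "cases_n": rc.reference_counts[1],
                         "cases_pct": round(100 * rc.reference_counts[1] / n_case, 1),
                         "OR_crude": None, "ci_crude": "Reference",
                         "p_crude": rc.p, "p_fdr_crude": rc.p_fdr,
                         "OR_adj": None, "ci_adj": "Reference",
                         "p_adj": ra.p, "p_fdr_adj": ra.p_fdr})
            for lc, la in zip(rc.levels, ra.levels):
                rows.append({"locus_id": locus.locus_id, "coding": rc.coding,
                             "genotype": lc.label,
                             "controls_n": lc.n_control,
                             "controls_pct": round(100 * lc.n_control / n_ctrl, 1),
                             "cases_n": lc.n_case,
                             "cases_pct": round(100 * lc.n_case / n_case, 1),
                             "OR_crude": round(lc.odds_ratio, 2),
                             "ci_crude": f"{lc.ci_low:.2f}-{lc.ci_high:.2f}",
                             "p_crude": None, "p_fdr_crude": None,
                             "OR_adj": round(la.odds_ratio, 2),
                             "ci_adj": f"{la.ci_low:.2f}-{la.ci_high:.2f}",
                             "p_adj": None, "p_fdr_adj": None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# joint interaction model
# ---------------------------------------------------------------------------

def fit_interaction_model(cohort: Cohort,
                          pairs=DEFAULT_INTERACTION_PAIRS,
                          coding: str = "recessive",
                          adjust: bool = True) -> InteractionFit:
    """One logistic model: all loci coded under ``coding`` (single-column
    codings only) as main effects, one product term per pair in ``pairs``,
    plus age-group and sex covariates when ``adjust``."""
    if coding == "codominant":
        raise ValueError("joint interaction model requires a 1-column coding")
    locus_ids = list(cohort.locus_ids)
    for a, b in pairs:
        cohort.locus(a), cohort.locus(b)
    df = cohort.complete_cases(locus_ids)
    y = df["status"].to_numpy(float)

    names = ["intercept"]
    columns = [np.ones(len(df))]
    main_col: dict[str, np.ndarray] = {}
    for lid in locus_ids:
        locus = cohort.locus(lid)
        col, _, _ = coding_design(coding, df[lid].astype(int).to_numpy(),
                                  locus.genotype_labels)
        main_col[lid] = col[:, 0]
        names.append(f"{coding}({lid})")
        columns.append(col[:, 0])
    for a, b in pairs:
        names.append(f"{coding}({a})*{coding}({b})")
        columns.append(main_col[a] * main_col[b])
    if adjust:
        names += ["age_ge60", "male"]
        columns += [df["age_ge60"].to_numpy(float), df["sex"].to_numpy(float)]
    X = np.column_stack(columns)

    res, flag = _fit_glm(y, X)
    flags = [flag] if flag else []
    if res is None:
        raise RuntimeError(f"interaction model failed: {flag}")
    terms = []
    for j, name in enumerate(names):
        b, s = float(res.params[j]), float(res.bse[j])
        with np.errstate(over="ignore"):
            lo, hi = np.exp(b + np.array([-Z95, Z95]) * s)
        w = (b / s) ** 2 if s > 0 else float("inf")
        terms.append(TermEffect(name, b, s, float(np.exp(b)),
                                float(lo), float(hi),
                                float(stats.chi2.sf(w, 1))))
    return InteractionFit(terms, np.asarray(res.cov_params()), len(df),
                          float(res.llf), flags=flags)
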