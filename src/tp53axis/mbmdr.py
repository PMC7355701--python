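"""Model-based multifactor dimensionality reduction (MB-MDR) for binary traits.

MB-MDR screens multi-locus genotype combinations for gene–gene interaction
signal in two steps, followed by a permutation correction:

1. *Cell categorization.*  Under the codominant model every k-locus combo
   partitions subjects into up to 3^k genotype cells.  Each observed cell is
   tested by a logistic regression of disease status on the cell-membership
   indicator (against all remaining subjects).  Cells with beta > 0 and
   p < 0.10 become "high-risk" (H), beta < 0 and p < 0.10 "low-risk" (L),
   everything else "no-evidence" (O).  Cells below a minimum size, or with
   a degenerate (all-case / all-control) 2×2, are forced to O and flagged.

2. *Merged-group testing.*  The H cells are merged and tested against the
   remaining subjects by logistic regression adjusted for the additive main
   effects of the combo's loci plus age group and sex, giving beta_H and the
   Wald statistic W_H = (beta_H / SE)² with a 1-df chi-square p-value p_H;
   likewise for L.  min(p_H, p_L) summarizes the combo.

3. *Permutation correction.*  Case/control labels are permuted (genotypes
   and covariates stay with subjects), both steps re-run, and max(W_H, W_L)
   recorded; the corrected p-value is (1 + #{perm_max >= observed_max}) /
   (n_perm + 1).

The unadjusted step-1 regression on a membership indicator is a saturated
2×2 logistic model, so its MLE is the closed-form log odds ratio — used
directly, which keeps the permutation loop cheap.  Step-2 fits use an
in-package IRLS Newton solver; it is cross-checked against statsmodels in
the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data_io import Cohort

#: step-1 significance threshold for H/L assignment
P_THRESHOLD = 0.10
#: cells smaller than this are forced to the no-evidence category
MIN_CELL_SIZE = 5

_CHI2_1 = stats.chi2(1)


# ---------------------------------------------------------------------------
# logistic IRLS (used in the permutation hot loop)
# ---------------------------------------------------------------------------

def logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                  tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares.

    Returns (beta, se, ok); ``ok`` is False on non-convergence, a singular
    information matrix, or quasi-separation (|beta| > 15).
    """
    n, k = X.shape
    beta = np.zeros(k)
    ok = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            break
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        beta = beta + step
        if np.abs(step).max() < tol:
            ok = True
            break
    if np.abs(beta).max() > 15:
        ok = False
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X
    try:
        se = np.sqrt(np.diag(np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        ok = False
    return beta, se, ok


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class MBMDRCell:
    combo: tuple[str, ...]
    genotypes: tuple[str, ...]
    n_case: int
    n_control: int
    beta: float = float("nan")
    p_step1: float = float("nan")
    category: str = "O"
    flags: list[str] = field(default_factory=list)


@dataclass
class MBMDRResult:
    combo: tuple[str, ...]
    n_h: int
    n_l: int
    genotypes_h: list[tuple[str, ...]]
    genotypes_l: list[tuple[str, ...]]
    beta_h: float
    w_h: float
    p_h: float
    beta_l: float
    w_l: float
    p_l: float
    min_p: float
    perm_p: float | None = None
    n_perm: int = 0
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def observed_max_w(self) -> float:
        ws = [w for w in (self.w_h, self.w_l) if np.isfinite(w)]
        return max(ws) if ws else 0.0


# ---------------------------------------------------------------------------
# combo workspace
# ---------------------------------------------------------------------------

class _ComboData:
    """Precomputed, permutation-invariant view of one locus combination:
    cell membership of every complete-case subject and the fixed columns of
    the step-2 design (intercept, additive dosages, covariates)."""

    def __init__(self, cohort: Cohort, combo: tuple[str, ...]):
        if len(set(combo)) != len(combo):
            raise ValueError("combo contains duplicate loci")
        if not 2 <= len(combo) <= 4:
            raise ValueError("combo order must be 2-4")
        loci = [cohort.locus(lid) for lid in combo]
        df = cohort.complete_cases(list(combo))
        self.n = len(df)
        self.y = df["status"].to_numpy(np.int64)
        dos = np.column_stack([df[lid].astype(int).to_numpy() for lid in combo])
        # cell index = base-3 code of the dosage vector
        code = np.zeros(self.n, dtype=np.int64)
        for j in range(dos.shape[1]):
            code = code * 3 + dos[:, j]
        observed = np.unique(code)
        remap = {c: i for i, c in enumerate(observed)}
        self.cell_idx = np.array([remap[c] for c in code])
        self.n_cells = len(observed)
        self.combo = combo
        self.genotypes = []
        for c in observed:
            digits = []
            for _ in range(len(combo)):
                digits.append(c % 3)
                c //= 3
            digits.reverse()
            self.genotypes.append(tuple(
                loci[j].genotype_labels[d] for j, d in enumerate(digits)))
        self.X_tail = np.column_stack(
            [dos.astype(float),
             df["age_ge60"].to_numpy(float), df["sex"].to_numpy(float)])
        self.ones = np.ones((self.n, 1))

    # -- step 1 -------------------------------------------------------------

    def step1(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                            np.ndarray, list[list[str]]]:
        """Closed-form per-cell 2×2 logistic stats under outcome ``y``.

        Returns (n_case, n_control, beta, p, flags-per-cell)."""
        a = np.bincount(self.cell_idx[y == 1], minlength=self.n_cells).astype(float)
        b = np.bincount(self.cell_idx[y == 0], minlength=self.n_cells).astype(float)
        c = y.sum() - a
        d = (len(y) - y.sum()) - b
        flags: list[list[str]] = [[] for _ in range(self.n_cells)]
        small = (a + b) < MIN_CELL_SIZE
        degenerate = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        valid = ~(small | degenerate)
        beta = np.full(self.n_cells, np.nan)
        p = np.full(self.n_cells, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta[valid] = np.log((a[valid] * d[valid]) / (b[valid] * c[valid]))
            se = np.sqrt(1 / a[valid] + 1 / b[valid] + 1 / c[valid] + 1 / d[valid])
            p[valid] = _CHI2_1.sf((beta[valid] / se) ** 2)
        for i in range(self.n_cells):
            if small[i]:
                flags[i].append("below_min_cell_size")
            elif degenerate[i]:
                flags[i].append("degenerate_cell")
        return a, b, beta, p, flags

    @staticmethod
    def categorize(beta: np.ndarray, p: np.ndarray) -> np.ndarray:
        """H/L/O per cell from the sign-and-threshold rule."""
        cat = np.full(len(beta), "O", dtype=object)
        sig = np.isfinite(p) & (p < P_THRESHOLD)
        cat[sig & (beta > 0)] = "H"
        cat[sig & (beta < 0)] = "L"
        return cat

    # -- step 2 -------------------------------------------------------------

    def step2(self, y: np.ndarray, cat: np.ndarray
              ) -> tuple[float, float, float, float, float, float, list[str]]:
        """(beta_H, W_H, p_H, beta_L, W_L, p_L, flags) for merged groups."""
        out = []
        flags: list[str] = []
        member = {g: np.isin(self.cell_idx, np.where(cat == g)[0])
                  for g in ("H", "L")}
        for g in ("H", "L"):
            if not member[g].any():
                out += [float("nan")] * 3
                continue
            X = np.column_stack([self.ones, member[g].astype(float), self.X_tail])
            beta, se, ok = logistic_irls(X, y.astype(float))
            if not ok or not np.isfinite(se[1]) or se[1] == 0:
                flags.append(f"step2_{g}_degenerate")
                out += [float("nan")] * 3
                continue
            w = (beta[1] / se[1]) ** 2
            out += [float(beta[1]), float(w), float(_CHI2_1.sf(w))]
        return (*out, flags)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def enumerate_cells(cohort: Cohort, combo: tuple[str, ...]) -> list[MBMDRCell]:
    """Observed multi-locus genotype cells with status counts (step 1
    input; unobserved combinations are omitted)."""
    data = _ComboData(cohort, tuple(combo))
    a, b, _, _, _ = data.step1(data.y)
    return [MBMDRCell(data.combo, data.genotypes[i], int(a[i]), int(b[i]))
            for i in range(data.n_cells)]


def categorize_cells(cohort: Cohort, combo: tuple[str, ...]) -> list[MBMDRCell]:
    """Step 1: per-cell membership regressions and H/L/O assignment."""
    data = _ComboData(cohort, tuple(combo))
    a, b, beta, p, flags = data.step1(data.y)
    cat = data.categorize(beta, p)
    return [MBMDRCell(data.combo, data.genotypes[i], int(a[i]), int(b[i]),
                      float(beta[i]), float(p[i]), str(cat[i]), flags[i])
            for i in range(data.n_cells)]


def _result_from(data: _ComboData, y: np.ndarray) -> MBMDRResult:
    a, b, beta, p, _ = data.step1(y)
    cat = data.categorize(beta, p)
    beta_h, w_h, p_h, beta_l, w_l, p_l, flags = data.step2(y, cat)
    ps = [v for v in (p_h, p_l) if np.isfinite(v)]
    return MBMDRResult(
        combo=data.combo,
        n_h=int((cat == "H").sum()), n_l=int((cat == "L").sum()),
        genotypes_h=[data.genotypes[i] for i in np.where(cat == "H")[0]],
        genotypes_l=[data.genotypes[i] for i in np.where(cat == "L")[0]],
        beta_h=beta_h, w_h=w_h, p_h=p_h,
        beta_l=beta_l, w_l=w_l, p_l=p_l,
        min_p=min(ps) if ps else float("nan"), flags=flags)


def step2_test(cohort: Cohort, combo: tuple[str, ...]) -> MBMDRResult:
    """Steps 1+2 for one combination (no permutation correction)."""
    data = _ComboData(cohort, tuple(combo))
    return _result_from(data, data.y)


def permutation_correct(cohort: Cohort, combo: tuple[str, ...],
                        n_perm: int = 1000,
                        seed: int | np.random.SeedSequence = 0) -> MBMDRResult:
    """Steps 1+2 plus the max-Wald permutation correction.

    Outcome labels are permuted against (genotypes + covariates) retained
    jointly per subject; perm_p uses the add-one convention and therefore
    never falls below 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    data = _ComboData(cohort, tuple(combo))
    result = _result_from(data, data.y)
    rng = np.random.default_rng(seed)
    obs = result.observed_max_w
    if not (np.isfinite(result.w_h) or np.isfinite(result.w_l)):
        result.flags.append("no_H_no_L")
        result.perm_p, result.n_perm = 1.0, n_perm
        return result
    n_ge = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(data.y)
        a, b, beta, p, _ = data.step1(y_perm)
        cat = data.categorize(beta, p)
        _, w_h, _, _, w_l, _, _ = data.step2(y_perm, cat)
        ws = [w for w in (w_h, w_l) if np.isfinite(w)]
        if (max(ws) if ws else 0.0) >= obs:
            n_ge += 1
    result.perm_p = (1 + n_ge) / (n_perm + 1)
    result.n_perm = n_perm
    if isinstance(seed, int):
        result.seed = seed
    return result


def scan_combinations(cohort: Cohort, orders=(2, 3, 4),
                      n_perm: int = 1000, seed: int = 0) -> list[MBMDRResult]:
    """All locus combinations of the requested orders, each with the full
    two-step + permutation analysis.

    Per-combination child seeds are spawned deterministically from the
    master seed, so any row is reproducible in isolation via its recorded
    seed index.
    """
    ids = cohort.locus_ids
    if len(ids) < max(orders):
        raise ValueError("not enough loci for the requested orders")
    combos = [c for k in orders for c in itertools.combinations(ids, k)]
    results = []
    for i, combo in enumerate(combos):
        child = np.random.SeedSequence(seed, spawn_key=(i,))
        res = permutation_correct(cohort, combo, n_perm=n_perm, seed=child)
        res.seed = int(child.generate_state(1)[0] % (2 ** 31))
        results.append(res)
    return results


def mbmdr_report(results: list[MBMDRResult]) -> pd.DataFrame:
    """Tabular report mirroring the published layout: combo, N_H, H
    genotypes (joined by '+'), beta_H, W_H, p_H, the L analogues, and the
    permutation-corrected p."""
    def join(genos: list[tuple[str, ...]]) -> str:
        return "; ".join(" + ".join(g) for g in genos) or "Na"

    rows = []
    for r in results:
        rows.append({
            "interaction_model": " + ".join(r.combo), "order": len(r.combo),
            "N_H": r.n_h, "genotypes_H": join(r.genotypes_h),
            "beta_H": r.beta_h, "W_H": r.w_h, "p_H": r.p_h,
            "N_L": r.n_l, "genotypes_L": join(r.genotypes_l),
            "beta_L": r.beta_l, "W_L": r.w_l, "p_L": r.p_l,
            "min_p": r.min_p, "perm_p": r.perm_p, "n_perm": r.n_perm})
    return pd.DataFrame(rows)


def wald_to_p(w: float) -> float:
    """Upper-tail chi-square(1) p for a Wald statistic."""
    return float(_CHI2_1.sf(w))
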