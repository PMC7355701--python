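"""Pairwise epistasis matrices of likelihood-ratio p-values.

For each inheritance coding, the report is a loci × loci matrix with three
semantics (all logistic models include the age-group and sex covariates):

* upper triangle — interaction LRT: the two-locus model with genotype ×
  genotype product term(s) against the additive two-locus model;
* diagonal — single-locus LRT: the locus against the covariate-only null;
* lower triangle — the additive two-locus model against the better
  (higher log-likelihood) of the two single-locus models, ties broken by
  row-locus order.

Degrees of freedom follow parameter counts: 1 for single-column codings,
4 for codominant interactions (2 × 2 product dummies); product columns
that are constant in the sample are dropped, reducing the df, and cells
whose fits degenerate are reported as NaN with a warning flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association_models import CODING_NAMES, _covariate_matrix, _fit_glm, coding_design
from .core_data_io import Cohort

logger = logging.getLogger("tp53axis")

LEGEND = ("upper: interaction LRT (pair + product vs additive pair); "
          "diagonal: locus vs covariate-only LRT; "
          "lower: additive pair vs best single-locus LRT; "
          "all models adjusted for age group and sex")


@dataclass
class EpistasisMatrix:
    coding: str
    locus_ids: tuple[str, ...]
    pvalues: pd.DataFrame                 # square, index/columns = locus_ids
    legend: str = LEGEND
    flags: dict = field(default_factory=dict)

    def _ordered(self, a: str, b: str) -> tuple[str, str]:
        if a == b or a not in self.locus_ids or b not in self.locus_ids:
            raise KeyError((a, b))
        i, j = self.locus_ids.index(a), self.locus_ids.index(b)
        return (a, b) if i < j else (b, a)

    def interaction_p(self, a: str, b: str) -> float:
        """Upper-triangle cell: interaction LRT p for the pair (order of
        arguments irrelevant)."""
        a, b = self._ordered(a, b)
        return float(self.pvalues.loc[a, b])

    def pair_vs_best_single_p(self, a: str, b: str) -> float:
        """Lower-triangle cell: additive pair vs best single-locus LRT p."""
        a, b = self._ordered(a, b)
        return float(self.pvalues.loc[b, a])


def _loglik(y, X):
    res, flag = _fit_glm(y, X)
    if res is None or flag:
        return None
    return float(res.llf)


def _lrt_p(ll_full, ll_reduced, df):
    if ll_full is None or ll_reduced is None or df <= 0:
        return float("nan")
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(stat, df))


def epistasis_matrix(cohort: Cohort, coding: str) -> EpistasisMatrix:
    """The pairwise LRT p-value matrix for one coding (see module docs)."""
    if coding not in CODING_NAMES:
        raise ValueError(f"unknown coding {coding!r}")
    ids = cohort.locus_ids
    if len(ids) < 2:
        raise ValueError("need at least two loci")
    p = pd.DataFrame(np.full((len(ids), len(ids)), np.nan),
                     index=ids, columns=ids)
    flags: dict = {}

    # complete cases across all loci so every cell shares one sample
    df = cohort.complete_cases(list(ids))
    y = df["status"].to_numpy(float)
    cov = _covariate_matrix(df)
    ones = np.ones((len(df), 1))
    X_cov = np.column_stack([ones, cov])
    ll_cov = _loglik(y, X_cov)

    design: dict[str, np.ndarray] = {}
    ll_single: dict[str, float | None] = {}
    for lid in ids:
        locus = cohort.locus(lid)
        cols, _, _ = coding_design(coding, df[lid].astype(int).to_numpy(),
                                   locus.genotype_labels)
        design[lid] = cols
        ll_single[lid] = _loglik(y, np.column_stack([ones, cols, cov]))
        p.loc[lid, lid] = _lrt_p(ll_single[lid], ll_cov, cols.shape[1])

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ca, cb = design[a], design[b]
            X_add = np.column_stack([ones, ca, cb, cov])
            ll_add = _loglik(y, X_add)
            # product columns; drop those constant in the sample
            prods = [ca[:, j] * cb[:, k]
                     for j in range(ca.shape[1]) for k in range(cb.shape[1])]
            kept = [c for c in prods if np.ptp(c) > 0]
            dropped = len(prods) - len(kept)
            if dropped:
                flags[(a, b)] = f"{dropped} empty joint class(es) dropped"
                logger.warning("epistasis %s×%s (%s): %s", a, b, coding,
                               flags[(a, b)])
            if kept:
                X_full = np.column_stack([X_add[:, :1 + ca.shape[1] + cb.shape[1]],
                                          np.column_stack(kept), cov])
                ll_full = _loglik(y, X_full)
                p.loc[a, b] = _lrt_p(ll_full, ll_add, len(kept))
            # lower triangle: additive pair vs best single locus
            lls = [ll_single[a], ll_single[b]]
            if all(l is not None for l in lls):
                best = max(lls)  # tie -> same value either way
                k_best = ca.shape[1] if lls[0] >= lls[1] else cb.shape[1]
                df_lower = (ca.shape[1] + cb.shape[1]) - k_best
                p.loc[b, a] = _lrt_p(ll_add, best, df_lower)
    return EpistasisMatrix(coding, ids, p, flags=flags)


def epistasis_report(cohort: Cohort,
                     codings=CODING_NAMES) -> pd.DataFrame:
    """Stacked per-coding matrices (one block per coding)."""
    blocks = []
    for coding in codings:
        m = epistasis_matrix(cohort, coding)
        block = m.pvalues.copy()
        block.insert(0, "coding", coding)
        block.insert(0, "locus_id", list(m.locus_ids))
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)
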