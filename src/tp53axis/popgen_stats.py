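"""Hardy–Weinberg testing and two-locus LD estimation from unphased genotypes.

HWE is tested per locus (and usually per study group) with a 1-df Pearson
chi-square against expectations from the estimated allele frequency.  Two-
locus linkage disequilibrium is estimated by an EM algorithm over the 3×3
unphased genotype table: only the double-heterozygote cell has ambiguous
phase, and EM splits it between the cis (wt-wt / var-var) and trans
(wt-var / var-wt) haplotype resolutions at each iteration.  The standardized
coefficient D' is reported as an absolute value, the field's convention;
signed D is retained.  Significance of D ≠ 0 comes from a 1-df likelihood-
ratio test against the independence (D = 0) haplotype distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data_io import Cohort

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# Hardy–Weinberg
# ---------------------------------------------------------------------------

def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for HWE.

    Parameters
    ----------
    counts : (n_wtwt, n_het, n_varvar)

    Returns
    -------
    (chi2, p); a monomorphic sample returns (0.0, 1.0) by convention.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype count")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("empty genotype sample")
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p * p])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def hwe_table(cohort: Cohort, group: str = "all") -> pd.DataFrame:
    """HWE chi-square and p per locus for ``group`` in {case, control, all}."""
    from .core_data_io import tabulate

    rows = []
    for locus in cohort.loci:
        gc = tabulate(cohort, locus.locus_id)
        if group == "case":
            counts = tuple(gc.counts[1])
        elif group == "control":
            counts = tuple(gc.counts[0])
        elif group == "all":
            counts = tuple(gc.counts.sum(axis=0))
        else:
            raise ValueError("group must be 'case', 'control' or 'all'")
        chi2, p = hwe_test(counts)
        rows.append({"locus_id": locus.locus_id, "group": group,
                     "n": int(sum(counts)), "chi2": chi2, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EM haplotype frequencies and D'
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeEstimate:
    """EM-estimated two-locus haplotype distribution and LD summaries.

    ``freqs`` orders haplotypes (wt-wt, wt-var, var-wt, var-var) with
    respect to the two loci's variant-allele orientations.
    """

    locus_pair: tuple[str, str]
    freqs: tuple[float, float, float, float]
    D: float
    D_prime: float       # |D'|
    r2: float
    loglik: float
    n_iter: int
    p_value: float       # LRT p for D = 0
    loglik_trace: tuple[float, ...] = ()

    @property
    def signed_D_prime(self) -> float:
        return math.copysign(self.D_prime, self.D)


def _genotype_table(cohort: Cohort, locus_a: str, locus_b: str) -> np.ndarray:
    df = cohort.complete_cases([locus_a, locus_b])
    table = np.zeros((3, 3), dtype=np.int64)
    a = df[locus_a].astype(int).to_numpy()
    b = df[locus_b].astype(int).to_numpy()
    for i, j in zip(a, b):
        table[i, j] += 1
    return table


def _hap_loglik(freqs: np.ndarray, table: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3×3 unphased genotype table under
    haplotype frequencies (f_00, f_01, f_10, f_11)."""
    f00, f01, f10, f11 = freqs
    probs = np.array([
        [f00 * f00, 2 * f00 * f01, f01 * f01],
        [2 * f00 * f10, 2 * f00 * f11 + 2 * f01 * f10, 2 * f01 * f11],
        [f10 * f10, 2 * f10 * f11, f11 * f11],
    ])
    with np.errstate(divide="ignore"):
        logp = np.where(table > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float((table * logp).sum())


def _ld_summaries(freqs: np.ndarray) -> tuple[float, float, float]:
    f00, f01, f10, f11 = freqs
    p_a0 = f00 + f01      # wt freq at locus a
    p_b0 = f00 + f10      # wt freq at locus b
    d = f00 - p_a0 * p_b0
    if d >= 0:
        dmax = min(p_a0 * (1 - p_b0), (1 - p_a0) * p_b0)
    else:
        dmax = min(p_a0 * p_b0, (1 - p_a0) * (1 - p_b0))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    denom = p_a0 * (1 - p_a0) * p_b0 * (1 - p_b0)
    r2 = d * d / denom if denom > 0 else 0.0
    return d, dprime, r2


def em_haplotypes_from_table(table: np.ndarray,
                             tol: float = _EM_TOL,
                             max_iter: int = _EM_MAX_ITER,
                             locus_pair: tuple[str, str] = ("a", "b"),
                             ) -> HaplotypeEstimate:
    """EM over a 3×3 unphased genotype count table (rows = dosage at the
    first locus, columns = dosage at the second)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (3, 3) or table.min() < 0:
        raise ValueError("expected a nonnegative 3x3 genotype count table")
    n = table.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    a_counts = np.array([table[i].sum() * (2 - i) for i in range(3)]).sum()
    b_counts = np.array([table[:, j].sum() * (2 - j) for j in range(3)]).sum()
    p_a0 = a_counts / (2 * n)   # wt allele freq, locus a
    p_b0 = b_counts / (2 * n)
    if p_a0 in (0.0, 1.0) or p_b0 in (0.0, 1.0):
        raise ValueError("LD undefined: monomorphic locus")

    # unambiguous haplotype counts contributed by each cell; the double
    # heterozygote (1,1) contributes 2 haplotypes of unknown phase
    base = np.zeros(4)  # (00, 01, 10, 11)
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            c = table[i, j]
            # each subject carries haplotypes determined by (i, j)
            a_hap = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[i]
            b_hap = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[j]
            # for single-locus heterozygotes phase is irrelevant to counts:
            # dosage i=1, j=0 -> haplotypes (0,0) and (1,0), etc.
            for k in range(2):
                base[2 * a_hap[k] + b_hap[k]] += c

    n_dh = int(table[1, 1])
    freqs = np.array([p_a0 * p_b0, p_a0 * (1 - p_b0),
                      (1 - p_a0) * p_b0, (1 - p_a0) * (1 - p_b0)])
    trace = [_hap_loglik(freqs, table)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: split double heterozygotes between cis (00/11) and
        # trans (01/10) resolutions
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        counts = base.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        new = counts / (2 * n)
        delta = np.abs(new - freqs).max()
        freqs = new
        trace.append(_hap_loglik(freqs, table))
        if delta < tol:
            break

    ll_full = trace[-1]
    ll_indep = _hap_loglik(np.array([p_a0 * p_b0, p_a0 * (1 - p_b0),
                                     (1 - p_a0) * p_b0,
                                     (1 - p_a0) * (1 - p_b0)]), table)
    lrt = max(0.0, 2.0 * (ll_full - ll_indep))
    p = float(stats.chi2.sf(lrt, 1))
    d, dprime, r2 = _ld_summaries(freqs)
    return HaplotypeEstimate(locus_pair, tuple(freqs), d, dprime, r2,
                             ll_full, n_iter, p, tuple(trace))


def em_haplotypes(cohort: Cohort, locus_a: str, locus_b: str,
                  tol: float = _EM_TOL,
                  max_iter: int = _EM_MAX_ITER) -> HaplotypeEstimate:
    """EM haplotype-frequency and D' estimate for one locus pair."""
    table = _genotype_table(cohort, locus_a, locus_b)
    return em_haplotypes_from_table(table, tol=tol, max_iter=max_iter,
                                    locus_pair=(locus_a, locus_b))


def ld_table(cohort: Cohort,
             pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """D, |D'|, r² and LRT p for the requested (default: all) locus pairs."""
    if pairs is None:
        ids = cohort.locus_ids
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    rows = []
    for a, b in pairs:
        est = em_haplotypes(cohort, a, b)
        rows.append({"locus_a": a, "locus_b": b, "D": est.D,
                     "D_prime": est.D_prime, "r2": est.r2,
                     "p": est.p_value, "n_iter": est.n_iter})
    return pd.DataFrame(rows)
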