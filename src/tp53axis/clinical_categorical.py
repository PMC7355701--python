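"""Categorical association tests for clinical features.

Omnibus r×c association is tested by Pearson chi-square, switching to
Fisher's exact test whenever any expected cell count falls below 5 (the
classical validity rule): exact for 2×2 tables, Monte-Carlo (sampling
tables with fixed margins, seeded) otherwise.  When the omnibus test is
significant on a table larger than 2×2, post-hoc pairwise contrasts are
formed — by default each row level vs the rest crossed with each column
level vs the rest — and Benjamini–Hochberg adjusted within the family of
contrasts for that feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .association_models import bh_adjust

EXPECTED_MIN = 5.0
POSTHOC_ALPHA = 0.05


@dataclass
class Contrast:
    label: str
    table: np.ndarray
    test_used: str
    p: float
    p_fdr: float | None = None


@dataclass
class ContingencyResult:
    table: np.ndarray
    test_used: str               # "pearson" or "fisher"
    statistic: float
    p: float
    posthoc: list[Contrast] = field(default_factory=list)


def _expected(table: np.ndarray) -> np.ndarray:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    return rows * cols / table.sum()


def _fisher_mc(table: np.ndarray, n_mc: int, seed) -> float:
    """Monte-Carlo Fisher p for an r×c table: probability-ordering over
    tables sampled with the observed margins."""
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    logp_obs = dist.logpmf(table)
    samples = dist.rvs(n_mc, random_state=rng)
    logp = dist.logpmf(samples)
    n_le = int((logp <= logp_obs + 1e-9).sum())
    return (1 + n_le) / (1 + n_mc)


def contingency_test(table, force: str | None = None, seed: int = 0,
                     n_mc: int = 10000, posthoc: bool = True,
                     row_labels=None, col_labels=None) -> ContingencyResult:
    """Omnibus r×c test with automatic chi-square/Fisher selection.

    ``force`` pins the branch to "pearson" or "fisher"; selection otherwise
    follows the minimum-expected-count rule.  Post-hoc level-vs-rest
    contrasts (BH-adjusted) are attached when the omnibus p < 0.05 and the
    table exceeds 2×2.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if (table < 0).any():
        raise ValueError("negative counts")
    margins_r, margins_c = table.sum(axis=1), table.sum(axis=0)
    if (margins_r == 0).any():
        raise ValueError(f"zero row margin at row {int(np.argmin(margins_r))}")
    if (margins_c == 0).any():
        raise ValueError(f"zero column margin at column {int(np.argmin(margins_c))}")

    use = force
    if use is None:
        use = "fisher" if (_expected(table) < EXPECTED_MIN).any() else "pearson"
    if use == "pearson":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        statistic, p = float(chi2), float(p)
    elif use == "fisher":
        if table.shape == (2, 2):
            statistic, p = (float(x) for x in stats.fisher_exact(table))
        else:
            p = _fisher_mc(table, n_mc, seed)
            statistic = float("nan")
    else:
        raise ValueError("force must be 'pearson', 'fisher' or None")

    result = ContingencyResult(table, use, statistic, float(p))
    if posthoc and p < POSTHOC_ALPHA and table.shape != (2, 2):
        result.posthoc = posthoc_pairwise(table, seed=seed, n_mc=n_mc,
                                          row_labels=row_labels,
                                          col_labels=col_labels)
    return result


def _collapse(table: np.ndarray, i: int, j: int) -> np.ndarray:
    """2×2 collapsing: row i vs rest × column j vs rest."""
    a = table[i, j]
    b = table[i].sum() - a
    c = table[:, j].sum() - a
    d = table.sum() - a - b - c
    return np.array([[a, b], [c, d]], dtype=np.int64)


def posthoc_pairwise(table, mode: str = "level_vs_rest", seed: int = 0,
                     n_mc: int = 10000, row_labels=None,
                     col_labels=None) -> list[Contrast]:
    """Post-hoc 2×2 contrasts with BH adjustment within the family.

    ``level_vs_rest`` (default) collapses each row level vs the rest
    against each column level vs the rest; ``pairwise`` tests every row
    pair × column pair sub-table.
    """
    table = np.asarray(table, dtype=np.int64)
    r, c = table.shape
    row_labels = row_labels or [f"r{i}" for i in range(r)]
    col_labels = col_labels or [f"c{j}" for j in range(c)]
    contrasts: list[Contrast] = []

    def add(label: str, sub: np.ndarray) -> None:
        if (sub.sum(axis=1) == 0).any() or (sub.sum(axis=0) == 0).any():
            return
        use = "fisher" if (_expected(sub) < EXPECTED_MIN).any() else "pearson"
        if use == "pearson":
            _, p, _, _ = stats.chi2_contingency(sub, correction=False)
        else:
            _, p = stats.fisher_exact(sub)
        contrasts.append(Contrast(label, sub, use, float(p)))

    if mode == "level_vs_rest":
        row_sets = [(i,) for i in range(r)] if r > 2 else [(0,)]
        col_sets = [(j,) for j in range(c)] if c > 2 else [(0,)]
        for (i,) in row_sets:
            for (j,) in col_sets:
                add(f"{row_labels[i]} vs rest × {col_labels[j]} vs rest",
                    _collapse(table, i, j))
    elif mode == "pairwise":
        for i1 in range(r):
            for i2 in range(i1 + 1, r):
                for j1 in range(c):
                    for j2 in range(j1 + 1, c):
                        sub = table[np.ix_([i1, i2], [j1, j2])]
                        add(f"{row_labels[i1]}|{row_labels[i2]} × "
                            f"{col_labels[j1]}|{col_labels[j2]}", sub)
    else:
        raise ValueError("mode must be 'level_vs_rest' or 'pairwise'")

    adj = bh_adjust([ct.p for ct in contrasts])
    for ct, q in zip(contrasts, adj):
        ct.p_fdr = float(q)
    return contrasts
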