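"""Clinical scoring and correlation: P.A.I.N.S., Spearman, BH-FDR, Table-1 tests.

P.A.I.N.S. (pain area and intensity number summation) scores a 220-cell
craniofacial grid with per-cell intensities 0-3, cumulative range 0-660,
reported as a percentage of the maximum.  The 3D head-grid geometry is not
reproduced; cells are an ordered vector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PainsRecord",
    "pains_score",
    "spearman",
    "bh_fdr",
    "correlate_family",
    "demographic_tests",
    "N_PAINS_CELLS",
    "MAX_PAINS_SCORE",
]

N_PAINS_CELLS = 220
MAX_PAINS_SCORE = 3 * N_PAINS_CELLS  # 660


@dataclass(frozen=True)
class PainsRecord:
    cells: tuple
    score: int
    percent: float


def pains_score(cells) -> PainsRecord:
    """Cumulative P.A.I.N.S. score and percentage from 220 cell intensities."""
    cells = np.asarray(cells)
    if cells.shape != (N_PAINS_CELLS,):
        raise ValueError(f"expected exactly {N_PAINS_CELLS} cells, got shape {cells.shape}")
    if not np.issubdtype(cells.dtype, np.integer):
        as_int = cells.astype(int)
        if not np.array_equal(as_int, cells):
            raise ValueError("cell intensities must be integers")
        cells = as_int
    if cells.min() < 0 or cells.max() > 3:
        raise ValueError("cell intensities must be in {0, 1, 2, 3}")
    score = int(cells.sum())
    return PainsRecord(
        cells=tuple(int(c) for c in cells),
        score=score,
        percent=100.0 * score / MAX_PAINS_SCORE,
    )


def spearman(x, y, exact: bool = False, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p value.

    rho is the Pearson correlation of mid-ranks (average ranks for ties);
    the default p uses the t approximation t = rho sqrt((n-2)/(1-rho^2)).
    ``exact=True`` enumerates the permutation null instead (all n!
    arrangements), practical up to ``exact_max_n``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rho undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > exact_max_n:
            raise ValueError(
                f"exact permutation p limited to n <= {exact_max_n} ({math.factorial(n)} arrangements)"
            )
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def bh_fdr(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Rejects the largest i with p_(i) <= i q / m and all smaller; adjusted
    q_(i) = min_{j >= i} m p_(j) / j, capped at 1.

    Returns
    -------
    (q_adjusted, reject) : arrays aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    q_adj = np.empty(m)
    q_adj[order] = q
    thresh = np.arange(1, m + 1) * q_level / m
    passing = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing.max() + 1]] = True
    return q_adj, reject


def correlate_family(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]], q_level: float = 0.05
) -> pd.DataFrame:
    """Spearman correlations for one BH family, with adjusted q values.

    ``pairs`` maps a label to an (x, y) pair; the family is the set of
    correlations corrected together (declared by the caller, not inferred).
    """
    rows = []
    for label, (x, y) in pairs.items():
        rho, p = spearman(x, y)
        rows.append({"pair": label, "rho": rho, "p": p, "n": len(x)})
    df = pd.DataFrame(rows)
    q, reject = bh_fdr(df["p"].to_numpy(), q_level)
    df["q"] = q
    df["significant"] = reject
    return df


def demographic_tests(
    table: pd.DataFrame,
    group_col: str = "group",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    welch: bool = False,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Group-comparison table: two-sample t for continuous, chi-square for categorical.

    Pooled-variance t by default (``welch=True`` for unequal variances);
    Pearson chi-square without continuity correction for 2x2 by default.
    """
    groups = table[group_col].unique()
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    rows = []
    for col in continuous or []:
        t, p = stats.ttest_ind(
            ga[col].dropna(), gb[col].dropna(), equal_var=not welch
        )
        rows.append({"variable": col, "test": "t", "statistic": float(t), "p": float(p)})
    for col in categorical or []:
        ct = pd.crosstab(table[group_col], table[col])
        if (ct.to_numpy() == 0).any():
            raise ValueError(f"empty cells in the {col!r} contingency table:\n{ct}")
        chi2, p, _, _ = stats.chi2_contingency(ct, correction=continuity_correction)
        rows.append({"variable": col, "test": "chi2", "statistic": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)
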