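"""The raw coherence statistic: a through-origin regression slope.

For each gene g in a phenotype's degree table let x_g = sqrt(k_int(g)) and
y_g = sqrt(k_ext(g)). The coherence statistic is the least-squares slope of
the no-intercept regression of y on x,

    beta = sum(x_g * y_g) / sum(x_g ** 2),

so a tightly knit set with few outside edges lies near the horizontal
(beta ~ 0) and a random-like set with mostly outside edges has a steep
slope. The square-root transform tames the heavy-tailed PPI degree
distribution; both axes are transformed so a set whose genes have
k_int == k_ext sits exactly on beta = 1.

Genes with k_int = 0 are part of the data (they were kept for their
external degrees) but contribute nothing to the slope algebraically; they
only enter the residual degrees of freedom.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateSlopeError
from .types import DegreeTable, SlopeFit


def fit_origin_slope(table: DegreeTable, ci_level: float = 0.95) -> SlopeFit:
    """Fit the through-origin slope of sqrt(external) on sqrt(internal) degree.

    Parameters
    ----------
    table:
        Degree table of one gene set; must contain at least one gene with
        k_int > 0 (enforce eligibility first).
    ci_level:
        Coverage of the normal-theory confidence interval. The interval is
        beta +/- t_{1-(1-ci_level)/2, n-1} * se with
        se^2 = RSS / ((n - 1) * sum(x^2)), the standard no-intercept
        regression interval.

    Raises
    ------
    DegenerateSlopeError
        If every internal degree is zero (the regressor is identically 0).
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    x = np.sqrt(table.table["k_int"].to_numpy(dtype=float))
    y = np.sqrt(table.table["k_ext"].to_numpy(dtype=float))
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise DegenerateSlopeError(
            f"{table.set_id or 'gene set'}: all internal degrees are zero; slope undefined"
        )
    beta = float(np.dot(x, y)) / sxx
    n = len(x)
    df = n - 1
    if df > 0:
        rss = float(np.sum((y - beta * x) ** 2))
        se = np.sqrt(rss / (df * sxx))
        tq = stats.t.ppf(1.0 - (1.0 - ci_level) / 2.0, df)
        ci_low, ci_high = beta - tq * se, beta + tq * se
    else:
        ci_low = ci_high = beta
    return SlopeFit(beta=beta, ci_low=float(ci_low), ci_high=float(ci_high), n_points=n, residual_df=max(df, 0))


def slope_size_diagnostic(fits: Sequence[tuple[int, SlopeFit]]) -> float:
    """Pearson correlation between network size and raw slope.

    Raw slopes shrink as networks grow (larger sets accumulate internal
    edges), so on panels of random or pathway sets this correlation is
    substantially negative — the size artifact that min-max normalization
    removes. Requires at least 3 fits and non-constant inputs.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 fits for a size-slope correlation")
    sizes = np.array([s for s, _ in fits], dtype=float)
    betas = np.array([f.beta for _, f in fits], dtype=float)
    if np.ptp(sizes) == 0 or np.ptp(betas) == 0:
        raise ValueError("size-slope correlation undefined for constant input")
    return float(stats.pearsonr(sizes, betas).statistic)
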