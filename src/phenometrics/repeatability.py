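"""Absolute-agreement repeatability of paired measurement series.

The statistic is the single-measure, two-way, absolute-agreement intraclass
correlation ICC(A,1) of McGraw & Wong, computed from the two-way ANOVA mean
squares.  Absolute agreement penalizes systematic offsets between the paired
instruments, which rank- or consistency-based coefficients ignore: two traps
that always differ by a constant have Pearson r = 1 but ICC(A,1) < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = ["ICCResult", "icc_absolute"]


@dataclass
class ICCResult:
    r: float
    p: float
    n: int
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_absolute(m1, m2, variant: str = "agreement") -> ICCResult:
    """Intraclass correlation of two measurement columns over the same units.

    Parameters
    ----------
    m1, m2 : array-like
        The two measurements, aligned by unit (tree or timepoint).
    variant : {"agreement", "consistency"}
        ICC(A,1) (default) or ICC(C,1).

    Returns
    -------
    ICCResult with the coefficient, F-test p-value, n, and the ANOVA mean
    squares it was computed from.
    """
    x = np.asarray(m1, dtype=float)
    y = np.asarray(m2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("m1 and m2 must be one-dimensional and aligned")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite cells are not allowed; drop "
                         "incomplete units first")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired units")
    data = np.column_stack([x, y])
    k = 2

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(np.sum((data - grand) ** 2))
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_total <= 1e-300:
        raise ValueError("zero total variance: agreement is undefined when "
                         "every measurement is identical")

    if variant == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        model = "two-way, single measures, absolute agreement (ICC(A,1))"
    elif variant == "consistency":
        denom = msr + (k - 1) * mse
        model = "two-way, single measures, consistency (ICC(C,1))"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom <= 0:
        raise ValueError("degenerate variance decomposition; ICC undefined")
    r = (msr - mse) / denom

    # F-test of ICC = 0 (shared by the agreement and consistency variants)
    if mse <= 0:
        p = 0.0
    else:
        F = msr / mse
        p = float(f_dist.sf(F, n - 1, (n - 1) * (k - 1)))
    return ICCResult(float(r), p, n, model, msr, msc, mse)
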