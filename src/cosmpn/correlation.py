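"""Power-law relation between cell density and COS degradation rate.

Across environmental samples the per-gram rate constant scales with the
density of COS degraders roughly as ``y = a * x^b``.  The fit is ordinary
least squares of ``log10 y`` on ``log10 x`` (the relation is reported as a
correlation among logarithms, and the noise on both axes is multiplicative),
so ``a = 10^intercept`` and ``b = slope``, with the Pearson correlation of
the logs and its two-sided t-test p-value (n-2 df).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError


@dataclass(frozen=True)
class PowerLawFit:
    """y = a*x^b fitted in log10 space, with log-space correlation statistics."""

    a: float
    b: float
    r_squared_log: float
    pearson_r_log: float
    p_value: float
    n: int

    def predict(self, x):
        return self.a * np.asarray(x, float) ** self.b


def fit_power_law(
    x: Sequence[float], y: Sequence[float]
) -> PowerLawFit:
    """Fit ``y = a*x^b`` by OLS of log10 y on log10 x.

    Pairs with a non-positive member (e.g. below-range MPN estimates of
    zero) are excluded with a warning — their logarithm is undefined and
    only detected samples enter the relation.  Requires >=3 usable pairs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    if np.any(~ok):
        warnings.warn(
            f"excluding {int(np.sum(~ok))} pair(s) with non-positive or "
            "non-finite values from the log-log fit",
            stacklevel=2,
        )
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need >=3 positive pairs, have {n}")
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    r = float(res.rvalue)
    return PowerLawFit(
        a=float(10.0 ** res.intercept),
        b=float(res.slope),
        r_squared_log=r * r,
        pearson_r_log=r,
        p_value=float(res.pvalue) if not math.isnan(res.pvalue) else 1.0,
        n=n,
    )
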