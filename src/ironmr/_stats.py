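"""Small closed-form regression helpers for tight simulation loops.

These implement textbook simple linear regression (one predictor plus
intercept) directly from sums of squares, avoiding model-object overhead in
replicate loops where millions of fits may be needed.  The full association
module (statsmodels-backed) is the general-purpose surface; tests verify the
two agree.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def simple_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Slope, SE and two-sided t-test p-value of y ~ 1 + x.

    Requires n >= 3 and var(x) > 0.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need n >= 3 for simple OLS inference")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0.0:
        raise ValueError("zero-variance predictor")
    beta = (xc @ y) / sxx
    resid = y - y.mean() - beta * xc
    sigma2 = (resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        return float(beta), 0.0, 0.0
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(beta), se, float(p)
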