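"""Descriptive trend-line fits for figure-data tables.

Latitude profiles get order-6 polynomial least-squares trends; depth
profiles get logarithmic trends y = a + b·ln x. These are descriptive
overlays, not inferential models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TrendFit:
    kind: str                   # "polynomial" or "logarithmic"
    degree: int
    coefficients: np.ndarray    # polynomial: ascending powers; log: (a, b)
    r_squared: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "polynomial":
            return np.polynomial.polynomial.polyval(x, self.coefficients)
        a, b = self.coefficients
        return a + b * np.log(x)


def fit_trend(x, y, kind: str = "polynomial", degree: int = 6) -> TrendFit:
    """Ordinary least-squares trend fit.

    polynomial: needs at least degree+1 distinct x values.
    logarithmic: y = a + b·ln x, needs x > 0 and >= 2 distinct x values.
    Constant y yields R² = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "polynomial":
        if degree < 1:
            raise ValueError("degree must be >= 1")
        if len(np.unique(x)) < degree + 1:
            raise ValueError(f"need at least {degree + 1} distinct x values")
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
        yhat = np.polynomial.polynomial.polyval(x, coeffs)
    elif kind == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic trend requires x > 0")
        if len(np.unique(x)) < 2:
            raise ValueError("need at least 2 distinct x values")
        A = np.column_stack([np.ones_like(x), np.log(x)])
        coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
        yhat = A @ coeffs
        degree = 1
    else:
        raise ValueError(f"unknown trend kind {kind!r}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 0.0 if ss_tot <= 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return TrendFit(kind=kind, degree=degree, coefficients=np.asarray(coeffs),
                    r_squared=r2)
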