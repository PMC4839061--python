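"""Goodness-of-fit metrics for surface-tension regressions.

Seven residual-based metrics are computed between experimental and
calculated tensions, with r_i = gamma_exp,i - gamma_cal,i:

========  =======================================  ============
metric    definition                               units
========  =======================================  ============
RMSE      sqrt( sum r^2 / (n - 2) )                mN/m
SSE       sum r^2                                  (mN/m)^2
CFEF      sum r^2 / gamma_exp                      mN/m
MPSD      sum (r / gamma_exp)^2                    dimensionless
ARE       sum |r / gamma_exp|                      dimensionless
EABS      sum |r|                                  mN/m
APE       100 * ARE / n                            percent
========  =======================================  ============

ARE and MPSD are plain sums over the points, not means, and RMSE always
divides by n - 2 regardless of the number of fitted parameters; both are
deliberate so that reported numbers are comparable across models.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = ["ErrorSuite", "error_suite"]


@dataclass(frozen=True)
class ErrorSuite:
    rmse: float
    sse: float
    cfef: float
    mpsd: float
    are: float
    eabs: float
    ape: float
    n: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def error_suite(gamma_exp, gamma_cal) -> ErrorSuite:
    """Compute all seven metrics from experimental and calculated tensions.

    Requires n >= 3 (the RMSE divisor is n - 2) and strictly positive
    experimental tensions (the relative metrics divide by them). All metrics
    are zero iff the two inputs coincide.
    """
    exp = np.asarray(gamma_exp, dtype=float)
    cal = np.asarray(gamma_cal, dtype=float)
    if exp.shape != cal.shape or exp.ndim != 1:
        raise ValueError("gamma_exp and gamma_cal must be 1-D of equal length")
    n = exp.size
    if n < 3:
        raise ValueError("need at least 3 points (RMSE divides by n - 2)")
    if np.any(exp <= 0):
        raise ValueError("experimental tensions must be > 0")
    r = exp - cal
    sse = float(np.sum(r**2))
    are = float(np.sum(np.abs(r / exp)))
    return ErrorSuite(
        rmse=float(np.sqrt(sse / (n - 2))),
        sse=sse,
        cfef=float(np.sum(r**2 / exp)),
        mpsd=float(np.sum((r / exp) ** 2)),
        are=are,
        eabs=float(np.sum(np.abs(r))),
        ape=100.0 * are / n,
        n=n,
    )
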