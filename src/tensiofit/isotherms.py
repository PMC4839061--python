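"""Forward adsorption models and unit conversions.

The equations of state and isotherms implemented here describe equilibrium
surfactant adsorption at a liquid-air interface:

* the Gibbs adsorption equation, which turns the slope of gamma^e vs ln C
  into a maximum adsorption density Gamma_inf;
* the Langmuir-Szyszkowski equation of state,
  gamma^e = gamma0 - R T Gamma_inf ln(1 + K C);
* the Frumkin equation of state / isotherm pair, which adds a dimensionless
  lateral-interaction parameter beta between the adsorbed molecules
  (beta > 0: net attraction, beta < 0: net repulsion);
* an anchored ("two-region") variant of each, rebased at a reference point
  (C_12, gamma_12) where the premicellar gamma-lnC curve changes slope, so
  that only data above that point constrain the fit.

Internally tensions are mN/m, concentrations mol/m^3, adsorption densities
mol/m^2; ``R T Gamma_inf`` (N/m) is converted to mN/m where it meets a
tension.

The Frumkin isotherm C(Gamma^e) is strictly increasing in the coverage only
for beta < 4 (d lnC/d theta = 1/theta + 1/(1-theta) - beta); the coverage
solver therefore refuses beta >= BETA_MAX, where the inverse would be
ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import N_A, R

__all__ = [
    "IsothermParams",
    "RegionAnchor",
    "BETA_MIN",
    "BETA_MAX",
    "area_per_molecule",
    "format_area",
    "gibbs_gamma_inf",
    "langmuir_tension",
    "frumkin_tension",
    "frumkin_concentration",
    "solve_coverage",
    "modified_frumkin_tension",
    "modified_frumkin_concentration",
    "solve_coverage_anchored",
    "modified_langmuir_tension",
]

#: Default admissible range for the lateral interaction parameter.
BETA_MIN = -10.0
BETA_MAX = 4.0

_THETA_CAP = 1.0 - 1e-12


@dataclass(frozen=True)
class IsothermParams:
    """Parameter bundle shared by all adsorption models.

    Parameters
    ----------
    gamma_inf : float
        Maximum adsorption density Gamma_inf in mol/m^2.
    K : float
        Adsorption equilibrium constant, m^3/mol (reciprocal of the internal
        concentration unit).
    beta : float
        Dimensionless lateral interaction parameter; 0 recovers the
        Langmuir-Szyszkowski model. Must lie below the monotone-isotherm
        bound ``BETA_MAX``.
    n : float
        Gibbs prefactor (dissociation / counter-ion factor); 1 for nonionic
        surfactants and for ionic ones at high counter-ion excess.
    """

    gamma_inf: float
    K: float = np.nan
    beta: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_inf > 0:
            raise ValueError("gamma_inf must be > 0")
        if not (np.isnan(self.K) or self.K > 0):
            raise ValueError("K must be > 0")
        if self.n < 1:
            raise ValueError("Gibbs prefactor n must be >= 1")
        if not self.beta < BETA_MAX:
            raise ValueError(
                f"beta={self.beta} >= {BETA_MAX}: isotherm non-monotone, "
                "inverse ill-defined"
            )


@dataclass(frozen=True)
class RegionAnchor:
    """Intersection of premicellar regions 1 and 2 on a gamma-lnC curve.

    ``coverage_12`` (the equilibrium surface coverage at the intersection,
    mol/m^2) is usually unknown from the data and left to the fitter.
    """

    c_12: float
    gamma_12: float
    coverage_12: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.c_12 > 0:
            raise ValueError("anchor concentration c_12 must be > 0")
        if not self.gamma_12 > 0:
            raise ValueError("anchor tension gamma_12 must be > 0")
        if self.coverage_12 is not None and not 0 <= self.coverage_12:
            raise ValueError("anchor coverage must be >= 0")


def area_per_molecule(gamma_inf: float) -> float:
    """Interfacial area per adsorbed molecule, in Angstrom^2.

    ``A = 1e20 / (Gamma_inf * N_A)`` for ``gamma_inf`` in mol/m^2
    (1 m^2 = 1e20 A^2).
    """
    if not gamma_inf > 0:
        raise ValueError("gamma_inf must be > 0")
    return 1e20 / (gamma_inf * N_A)


def format_area(area: float) -> str:
    """Round an area (A^2) for reporting.

    Nearest integer, except one decimal place is kept when the first decimal
    digit is a 5 (61.5 stays 61.5 instead of collapsing to 62), matching
    common tabulation practice for values that sit on a half-integer.
    """
    if int(area * 10.0) % 10 == 5:
        return f"{round(area * 10.0) / 10.0:.1f}"
    return f"{round(area):d}"


def gibbs_gamma_inf(slope: float, n: float, temperature: float) -> float:
    """Maximum adsorption density from the gamma^e vs lnC slope.

    ``(d gamma^e / d lnC)_T = -n R T Gamma_inf``, so
    ``Gamma_inf = -slope / (n R T)`` with the slope given in mN/m per ln
    unit (converted to N/m internally). Returns mol/m^2.
    """
    if n < 1:
        raise ValueError("Gibbs prefactor n must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    if slope >= 0:
        raise ValueError(
            "gamma^e must decrease with lnC (slope < 0) for an adsorbing "
            "surfactant"
        )
    return -slope * 1e-3 / (n * R * temperature)


def langmuir_tension(params: IsothermParams, C, gamma0: float, temperature: float):
    """Langmuir-Szyszkowski equation of state, gamma^e(C) in mN/m.

    ``gamma^e = gamma0 - R T Gamma_inf ln(1 + K C)``; strictly decreasing
    in C.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    rtg = R * temperature * params.gamma_inf * 1e3  # mN/m
    out = gamma0 - rtg * np.log1p(params.K * C)
    return out if out.ndim else float(out)


def _theta(params: IsothermParams, coverage) -> np.ndarray:
    theta = np.asarray(coverage, dtype=float) / params.gamma_inf
    if np.any(theta < 0) or np.any(theta >= 1.0):
        raise ValueError("coverage must satisfy 0 <= coverage < gamma_inf")
    return theta


def frumkin_tension(params: IsothermParams, coverage, gamma0: float, temperature: float):
    """Frumkin equation of state, gamma^e(Gamma^e) in mN/m.

    ``gamma^e = gamma0 + (R T Gamma_inf / 2) (2 ln(1 - theta) + beta theta^2)``
    with ``theta = Gamma^e / Gamma_inf``. Zero coverage returns gamma0; the
    log diverges as coverage approaches saturation.
    """
    theta = _theta(params, coverage)
    half_rtg = R * temperature * params.gamma_inf * 1e3 / 2.0  # mN/m
    out = gamma0 + half_rtg * (2.0 * np.log1p(-theta) + params.beta * theta**2)
    return out if out.ndim else float(out)


def frumkin_concentration(params: IsothermParams, coverage):
    """Frumkin isotherm, bulk concentration C(Gamma^e) in mol/m^3.

    ``C = Gamma^e exp(-beta theta) / (K (Gamma_inf - Gamma^e))``; strictly
    increasing in the coverage for beta < 4, with C(0) = 0.
    """
    theta = _theta(params, coverage)
    out = theta * np.exp(-params.beta * theta) / (params.K * (1.0 - theta))
    return out if out.ndim else float(out)


def _log_c_of_theta(theta: float, params: IsothermParams) -> float:
    # ln C(theta); strictly increasing in theta for beta < BETA_MAX
    return (
        np.log(theta)
        - params.beta * theta
        - np.log1p(-theta)
        - np.log(params.K)
    )


def solve_coverage(params: IsothermParams, C) -> np.ndarray | float:
    """Invert the Frumkin isotherm: the unique Gamma^e with C(Gamma^e) = C.

    Bracketed root finding on ln C(theta) over theta in (0, 1); monotone for
    beta < 4 so the root is unique. Round-trips with
    :func:`frumkin_concentration` to ~1e-12 relative.
    """
    if not params.beta < BETA_MAX:  # pragma: no cover - params enforce this
        raise ValueError("beta >= 4: non-monotone isotherm, unsupported regime")
    C_arr = np.atleast_1d(np.asarray(C, dtype=float))
    if np.any(C_arr < 0):
        raise ValueError("concentration must be >= 0")
    out = np.empty_like(C_arr)
    for i, c in enumerate(C_arr):
        if c == 0.0:
            out[i] = 0.0
            continue
        target = np.log(c)
        f = lambda th: _log_c_of_theta(th, params) - target  # noqa: E731
        lo = 1e-300
        if f(_THETA_CAP) < 0:  # pragma: no cover - needs C beyond ~1e288/K
            out[i] = params.gamma_inf * _THETA_CAP
            continue
        theta = brentq(f, lo, _THETA_CAP, xtol=1e-300, rtol=1e-15, maxiter=300)
        out[i] = theta * params.gamma_inf
    return out if np.ndim(C) else float(out[0])


def _require_anchor_coverage(anchor: RegionAnchor) -> float:
    if anchor.coverage_12 is None:
        raise ValueError("anchor coverage_12 is required for the two-region model")
    return anchor.coverage_12


def modified_frumkin_tension(
    params: IsothermParams, coverage, anchor: RegionAnchor, temperature: float
):
    """Frumkin equation of state rebased at the region-1/region-2 anchor.

    ``gamma_2^e = gamma_12 + (R T Gamma_inf / 2) (2 ln((Gamma_inf - Gamma^e)
    / (Gamma_inf - Gamma_12)) + beta (theta^2 - theta_12^2))``.
    Equals gamma_12 exactly at the anchor coverage; reduces to the plain
    Frumkin equation when the anchor itself lies on the plain curve.
    """
    cov12 = _require_anchor_coverage(anchor)
    theta12 = cov12 / params.gamma_inf
    theta = _theta(params, coverage)
    if np.any(theta < theta12 - 1e-15):
        raise ValueError("coverage below the anchor coverage (region-2 model)")
    half_rtg = R * temperature * params.gamma_inf * 1e3 / 2.0  # mN/m
    out = anchor.gamma_12 + half_rtg * (
        2.0 * (np.log1p(-theta) - np.log1p(-theta12))
        + params.beta * (theta**2 - theta12**2)
    )
    return out if out.ndim else float(out)


def modified_frumkin_concentration(params: IsothermParams, coverage, anchor: RegionAnchor):
    """Frumkin isotherm rebased at the anchor: C_2(Gamma^e) in mol/m^3.

    ``C_2 = C_12 + (1/K) (theta e^{-beta theta}/(1-theta)
    - theta_12 e^{-beta theta_12}/(1-theta_12))``; equals C_12 at the anchor
    coverage and is strictly increasing for beta < 4.
    """
    cov12 = _require_anchor_coverage(anchor)
    theta12 = cov12 / params.gamma_inf
    theta = _theta(params, coverage)
    if np.any(theta < theta12 - 1e-15):
        raise ValueError("coverage below the anchor coverage (region-2 model)")

    def h(t):
        return t * np.exp(-params.beta * t) / (1.0 - t)

    out = anchor.c_12 + (h(theta) - h(theta12)) / params.K
    return out if out.ndim else float(out)


def solve_coverage_anchored(params: IsothermParams, C, anchor: RegionAnchor):
    """Invert the anchored isotherm: Gamma^e with C_2(Gamma^e) = C.

    Same contract as :func:`solve_coverage`, restricted to coverages at or
    above the anchor coverage (so C >= C_12).
    """
    cov12 = _require_anchor_coverage(anchor)
    theta12 = cov12 / params.gamma_inf
    C_arr = np.atleast_1d(np.asarray(C, dtype=float))
    if np.any(C_arr < anchor.c_12 * (1.0 - 1e-12)):
        raise ValueError("concentration below the anchor concentration c_12")

    def h(t):
        return t * np.exp(-params.beta * t) / (1.0 - t)

    h12 = h(theta12)
    out = np.empty_like(C_arr)
    for i, c in enumerate(C_arr):
        target = h12 + params.K * (c - anchor.c_12)  # h(theta) at the root
        f = lambda th: h(th) - target  # noqa: E731
        if f(theta12) >= 0:
            out[i] = cov12
            continue
        if f(_THETA_CAP) < 0:  # pragma: no cover - astronomically large C
            out[i] = params.gamma_inf * _THETA_CAP
            continue
        theta = brentq(f, theta12, _THETA_CAP, xtol=1e-300, rtol=1e-15, maxiter=300)
        out[i] = theta * params.gamma_inf
    return out if np.ndim(C) else float(out[0])


def modified_langmuir_tension(
    params: IsothermParams, C, anchor: RegionAnchor, temperature: float
):
    """Langmuir-Szyszkowski equation rebased at the anchor.

    ``gamma_2^e = gamma_12 - R T Gamma_inf ln((1 + K C)/(1 + K C_12))``;
    equals gamma_12 at C = C_12 and reduces to the plain equation with
    gamma0 = gamma_12 as C_12 -> 0.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < anchor.c_12 * (1.0 - 1e-12)):
        raise ValueError("concentration below the anchor concentration c_12")
    rtg = R * temperature * params.gamma_inf * 1e3  # mN/m
    out = anchor.gamma_12 - rtg * (
        np.log1p(params.K * C) - np.log1p(params.K * anchor.c_12)
    )
    return out if out.ndim else float(out)
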