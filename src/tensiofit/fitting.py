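"""Model objects fitting adsorption isotherms to surface-tension data.

The API follows the model/results convention of statistical modelling
packages: a model object is built from a :class:`~tensiofit.dataset.TensionDataset`
(plus, for the two-region variants, a :class:`~tensiofit.isotherms.RegionAnchor`),
its ``fit()`` runs a deterministic multi-start nonlinear least squares and
returns a :class:`FitResult` carrying the estimates, per-point predictions,
the seven-metric error suite and the derived area per molecule, with a
``summary()`` table.

Fitting minimises the unweighted sum of squared tension residuals
``sum (gamma_exp - gamma_cal)^2`` in mN/m. For the Frumkin models each trial
parameter vector requires an inner inversion of the isotherm (bulk
concentration -> equilibrium coverage) at every data point; a failed inner
solve penalises that trial instead of aborting the fit. Positivity of
Gamma_inf and K is enforced by optimising their logarithms; the lateral
interaction parameter beta is box-constrained to (-10, 4), inside which the
isotherm is invertible.

Multi-start grid (fixed, so fits are reproducible run to run):
Gamma_inf in {0.5, 1, 2, 4} umol/m^2; K from matching the mid-curve point
under the Langmuir-Szyszkowski form at each trial Gamma_inf; beta in
{-2, 0, 2}; anchored coverage fraction theta_12 in {0.3, 0.6}. The start
with the lowest final objective wins; near-ties go to the smallest |beta|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .constants import R
from .dataset import TensionDataset
from .errors import ErrorSuite, error_suite
from .isotherms import (
    BETA_MAX,
    BETA_MIN,
    IsothermParams,
    RegionAnchor,
    area_per_molecule,
    frumkin_tension,
    gibbs_gamma_inf,
    langmuir_tension,
    modified_frumkin_tension,
    modified_langmuir_tension,
    solve_coverage,
    solve_coverage_anchored,
)

__all__ = [
    "FitResult",
    "FitFailure",
    "GibbsAdsorptionModel",
    "LangmuirSzyszkowskiModel",
    "FrumkinModel",
    "TwoRegionFrumkinModel",
    "TwoRegionLangmuirModel",
    "fit_gibbs",
    "fit_langmuir",
    "fit_frumkin",
    "fit_modified_frumkin",
    "fit_modified_langmuir",
]

_GAMMA_INF_STARTS = np.array([0.5e-6, 1e-6, 2e-6, 4e-6])  # mol/m^2
_BETA_STARTS = (-2.0, 0.0, 2.0)
_THETA12_STARTS = (0.3, 0.6)
_MAX_NFEV = 500
_TOL = 1e-14
_PENALTY = 1e6


class FitFailure(RuntimeError):
    """Raised when no optimizer start converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class FitResult:
    """Results object returned by every model's ``fit()``.

    Attributes
    ----------
    model_id : str
        One of gibbs, langmuir, frumkin, modified_frumkin, modified_langmuir.
    params : IsothermParams
        Fitted parameter bundle (K is NaN for the Gibbs fit).
    anchor : RegionAnchor or None
        Anchor used by the two-region models, with the fitted coverage_12.
    predicted_tensions : ndarray
        Calculated gamma^e per fitted point, mN/m.
    predicted_coverage : ndarray or None
        Equilibrium coverage Gamma^e per point, mol/m^2 (None for Gibbs).
    area : float
        Interfacial area per molecule implied by Gamma_inf, Angstrom^2.
    errors : ErrorSuite
        The seven goodness-of-fit metrics on the fitted points.
    converged : bool
    n_points : int
    objective : float
        Final sum of squared residuals, (mN/m)^2.
    """

    model_id: str
    params: IsothermParams
    anchor: Optional[RegionAnchor]
    predicted_tensions: np.ndarray
    predicted_coverage: Optional[np.ndarray]
    area: float
    errors: ErrorSuite
    converged: bool
    n_points: int
    objective: float
    dataset: Optional[TensionDataset] = None

    def summary(self) -> str:
        lines = [
            f"{'Model:':<22}{self.model_id}",
            f"{'No. observations:':<22}{self.n_points}",
            f"{'Converged:':<22}{self.converged}",
            f"{'Gamma_inf (umol/m2):':<22}{self.params.gamma_inf * 1e6:.4g}",
            f"{'Area per molecule:':<22}{self.area:.4g} A^2",
        ]
        if np.isfinite(self.params.K):
            lines.append(f"{'K (m3/mol):':<22}{self.params.K:.4g}")
        if self.model_id in ("frumkin", "modified_frumkin"):
            lines.append(f"{'beta (-):':<22}{self.params.beta:.4g}")
            kind = "attractive" if self.params.beta > 0 else (
                "repulsive" if self.params.beta < 0 else "none")
            lines.append(f"{'Lateral interaction:':<22}{kind}")
        if self.anchor is not None:
            lines.append(f"{'Anchor C_12:':<22}{self.anchor.c_12:.6g} mol/m3")
            lines.append(f"{'Anchor gamma_12:':<22}{self.anchor.gamma_12:.6g} mN/m")
        lines.append(
            f"{'RMSE / SSE:':<22}{self.errors.rmse:.4g} mN/m / "
            f"{self.errors.sse:.4g} (mN/m)^2"
        )
        width = max(len(s) for s in lines)
        rule = "=" * width
        return "\n".join([rule, *lines, rule])

    def plot(self, ax=None):
        """Measured tensions and the fitted curve on a semilog-C axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.dataset is not None:
            ax.semilogx(self.dataset.concentrations, self.dataset.tensions,
                        "o", label="measured")
            ax.semilogx(self.dataset.concentrations, self.predicted_tensions,
                        "-", label=f"{self.model_id} fit")
        ax.set_xlabel("C (mol/m$^3$)")
        ax.set_ylabel(r"$\gamma^e$ (mN/m)")
        ax.legend()
        return ax


def _make_result(model_id, params, anchor, dataset, gamma_cal, coverage,
                 converged, extra_objective=None) -> FitResult:
    gamma_exp = dataset.tensions
    errs = error_suite(gamma_exp, gamma_cal)
    return FitResult(
        model_id=model_id,
        params=params,
        anchor=anchor,
        predicted_tensions=np.asarray(gamma_cal, dtype=float),
        predicted_coverage=None if coverage is None else np.asarray(coverage, dtype=float),
        area=area_per_molecule(params.gamma_inf),
        errors=errs,
        converged=bool(converged),
        n_points=len(gamma_exp),
        objective=errs.sse if extra_objective is None else extra_objective,
        dataset=dataset,
    )


def _k_start(gamma_inf: float, c_mid: float, drop_mid: float, temperature: float) -> float:
    """K matching the mid-curve tension drop under the Langmuir form."""
    rtg = R * temperature * gamma_inf * 1e3  # mN/m
    ratio = np.exp(min(drop_mid / rtg, 500.0))
    k = (ratio - 1.0) / c_mid
    return k if k > 0 else 1.0 / c_mid


def _multistart(residual_fn, starts, bounds) -> tuple[np.ndarray, float, bool]:
    """Run least_squares from each start; best objective wins, ties -> min |beta|.

    ``bounds`` is a (lb, ub) pair; the beta coordinate, when present, is
    assumed to be the third parameter.
    """
    candidates = []
    for x0 in starts:
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            res = least_squares(
                residual_fn, x0, bounds=bounds, method="trf",
                ftol=_TOL, xtol=_TOL, gtol=_TOL, max_nfev=_MAX_NFEV,
            )
        except Exception:
            continue
        obj = float(2.0 * res.cost)
        candidates.append((obj, res.x, res.status > 0))
    if not candidates:
        raise FitFailure("all optimizer starts failed", {"n_starts": len(starts)})
    best_obj = min(c[0] for c in candidates)
    near = [c for c in candidates if c[0] <= best_obj * (1.0 + 1e-9) + 1e-300]
    if len(near) > 1 and len(near[0][1]) >= 3:
        near.sort(key=lambda c: abs(c[1][2]))
    obj, x, ok = near[0]
    return x, obj, ok


class GibbsAdsorptionModel:
    """Gamma_inf from the slope of gamma^e vs lnC (Gibbs adsorption equation).

    Ordinary least squares of the tensions on the log concentrations;
    ``Gamma_inf = -slope / (n R T)``. All points must be premicellar.
    """

    model_id = "gibbs"

    def __init__(self, dataset: TensionDataset, n: float = 1.0):
        if len(dataset) < 3:
            raise ValueError("need at least 3 premicellar points")
        if n < 1:
            raise ValueError("Gibbs prefactor n must be >= 1")
        self.dataset = dataset
        self.n = float(n)

    def fit(self) -> FitResult:
        x, y = self.dataset.log_concentrations, self.dataset.tensions
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            raise FitFailure(
                "non-adsorbing input: gamma^e does not decrease with lnC",
                {"slope": float(slope)},
            )
        gamma_inf = gibbs_gamma_inf(float(slope), self.n, self.dataset.temperature)
        params = IsothermParams(gamma_inf=gamma_inf, K=np.nan, beta=0.0, n=self.n)
        gamma_cal = slope * x + intercept
        return _make_result(
            self.model_id, params, None, self.dataset, gamma_cal, None, converged=True
        )


class LangmuirSzyszkowskiModel:
    """Langmuir-Szyszkowski fit over (Gamma_inf, K)."""

    model_id = "langmuir"

    def __init__(self, dataset: TensionDataset):
        if len(dataset) < 4:
            raise ValueError("need at least 4 points")
        self.dataset = dataset

    def _predict(self, gamma_inf: float, k: float) -> np.ndarray:
        p = IsothermParams(gamma_inf=gamma_inf, K=k)
        return langmuir_tension(
            p, self.dataset.concentrations, self.dataset.gamma0,
            self.dataset.temperature,
        )

    def fit(self) -> FitResult:
        ds = self.dataset
        y = ds.tensions
        mid = len(ds) // 2
        drop_mid = max(ds.gamma0 - y[mid], 1e-6)

        def resid(x):
            return self._predict(np.exp(x[0]), np.exp(x[1])) - y

        starts = [
            np.array([np.log(g), np.log(_k_start(g, ds.concentrations[mid], drop_mid, ds.temperature))])
            for g in _GAMMA_INF_STARTS
        ]
        bounds = (np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf]))
        x, obj, ok = _multistart(resid, starts, bounds)
        gamma_inf, k = float(np.exp(x[0])), float(np.exp(x[1]))
        params = IsothermParams(gamma_inf=gamma_inf, K=k)
        gamma_cal = self._predict(gamma_inf, k)
        # flag non-adsorbing data: fitted curve is essentially flat
        span = abs(gamma_cal[0] - gamma_cal[-1])
        converged = ok and span > 1e-6 * ds.gamma0
        coverage = gamma_inf * k * ds.concentrations / (1.0 + k * ds.concentrations)
        return _make_result(
            self.model_id, params, None, self.dataset, gamma_cal, coverage, converged
        )


class FrumkinModel:
    """Frumkin fit over (Gamma_inf, K, beta) with the inner coverage solve."""

    model_id = "frumkin"

    def __init__(self, dataset: TensionDataset):
        if len(dataset) < 5:
            raise ValueError("need at least 5 points")
        self.dataset = dataset

    def _predict(self, params: IsothermParams) -> tuple[np.ndarray, np.ndarray]:
        cov = solve_coverage(params, self.dataset.concentrations)
        return frumkin_tension(
            params, cov, self.dataset.gamma0, self.dataset.temperature
        ), cov

    def fit(self) -> FitResult:
        ds = self.dataset
        y = ds.tensions
        mid = len(ds) // 2
        drop_mid = max(ds.gamma0 - y[mid], 1e-6)

        def resid(x):
            try:
                p = IsothermParams(np.exp(x[0]), np.exp(x[1]), x[2])
                gamma_cal, _ = self._predict(p)
            except (ValueError, OverflowError):
                return np.full(len(ds), _PENALTY)
            return gamma_cal - y

        starts = [
            np.array([np.log(g), np.log(_k_start(g, ds.concentrations[mid], drop_mid, ds.temperature)), b])
            for g in _GAMMA_INF_STARTS
            for b in _BETA_STARTS
        ]
        bounds = (
            np.array([-np.inf, -np.inf, BETA_MIN]),
            np.array([np.inf, np.inf, BETA_MAX - 1e-9]),
        )
        x, obj, ok = _multistart(resid, starts, bounds)
        params = IsothermParams(float(np.exp(x[0])), float(np.exp(x[1])), float(x[2]))
        gamma_cal, cov = self._predict(params)
        return _make_result(self.model_id, params, None, self.dataset, gamma_cal, cov, ok)


class TwoRegionFrumkinModel:
    """Frumkin fit rebased at the region-1/region-2 anchor.

    Fits (Gamma_inf, K, beta, Gamma_12) to region-2 data only; the anchor
    coordinates (C_12, gamma_12) are fixed inputs and the anchor coverage is
    a bounded free parameter (0 < Gamma_12 < Gamma_inf), estimated because it
    is not observable from the tension curve.
    """

    model_id = "modified_frumkin"

    def __init__(self, dataset_region2: TensionDataset, anchor: RegionAnchor):
        if len(dataset_region2) < 5:
            raise ValueError("need at least 5 region-2 points")
        if np.any(dataset_region2.concentrations < anchor.c_12 * (1.0 - 1e-9)):
            raise ValueError("region-2 points must all have C >= anchor C_12")
        self.dataset = dataset_region2
        self.anchor = anchor

    def _predict(self, params: IsothermParams, theta12: float):
        anchor = RegionAnchor(
            self.anchor.c_12, self.anchor.gamma_12, theta12 * params.gamma_inf
        )
        cov = solve_coverage_anchored(params, self.dataset.concentrations, anchor)
        gamma_cal = modified_frumkin_tension(
            params, cov, anchor, self.dataset.temperature
        )
        return gamma_cal, cov, anchor

    def fit(self) -> FitResult:
        ds = self.dataset
        y = ds.tensions
        mid = len(ds) // 2
        drop_mid = max(self.anchor.gamma_12 - y[mid], 1e-6)

        def resid(x):
            try:
                p = IsothermParams(np.exp(x[0]), np.exp(x[1]), x[2])
                theta12 = 1.0 / (1.0 + np.exp(-x[3]))  # logistic -> (0, 1)
                gamma_cal, _, _ = self._predict(p, theta12)
            except (ValueError, OverflowError):
                return np.full(len(ds), _PENALTY)
            return gamma_cal - y

        starts = [
            np.array([
                np.log(g),
                np.log(_k_start(g, ds.concentrations[mid], drop_mid, ds.temperature)),
                b,
                np.log(t / (1.0 - t)),
            ])
            for g in _GAMMA_INF_STARTS
            for b in _BETA_STARTS
            for t in _THETA12_STARTS
        ]
        bounds = (
            np.array([-np.inf, -np.inf, BETA_MIN, -np.inf]),
            np.array([np.inf, np.inf, BETA_MAX - 1e-9, np.inf]),
        )
        x, obj, ok = _multistart(resid, starts, bounds)
        params = IsothermParams(float(np.exp(x[0])), float(np.exp(x[1])), float(x[2]))
        theta12 = float(1.0 / (1.0 + np.exp(-x[3])))
        gamma_cal, cov, anchor = self._predict(params, theta12)
        return _make_result(self.model_id, params, anchor, self.dataset, gamma_cal, cov, ok)


class TwoRegionLangmuirModel:
    """Langmuir-Szyszkowski fit rebased at the anchor.

    ``gamma_2^e = gamma_12 - R T Gamma_inf ln((1 + K C)/(1 + K C_12))`` over
    (Gamma_inf, K) on region-2 data.
    """

    model_id = "modified_langmuir"

    def __init__(self, dataset_region2: TensionDataset, anchor: RegionAnchor):
        if len(dataset_region2) < 4:
            raise ValueError("need at least 4 region-2 points")
        if np.any(dataset_region2.concentrations < anchor.c_12 * (1.0 - 1e-9)):
            raise ValueError("region-2 points must all have C >= anchor C_12")
        self.dataset = dataset_region2
        self.anchor = anchor

    def _predict(self, gamma_inf: float, k: float) -> np.ndarray:
        p = IsothermParams(gamma_inf=gamma_inf, K=k)
        return modified_langmuir_tension(
            p, self.dataset.concentrations, self.anchor, self.dataset.temperature
        )

    def fit(self) -> FitResult:
        ds = self.dataset
        y = ds.tensions
        mid = len(ds) // 2
        drop_mid = max(self.anchor.gamma_12 - y[mid], 1e-6)

        def resid(x):
            return self._predict(np.exp(x[0]), np.exp(x[1])) - y

        starts = [
            np.array([np.log(g), np.log(_k_start(g, ds.concentrations[mid], drop_mid, ds.temperature))])
            for g in _GAMMA_INF_STARTS
        ]
        bounds = (np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf]))
        x, obj, ok = _multistart(resid, starts, bounds)
        gamma_inf, k = float(np.exp(x[0])), float(np.exp(x[1]))
        params = IsothermParams(gamma_inf=gamma_inf, K=k)
        gamma_cal = self._predict(gamma_inf, k)
        coverage = gamma_inf * k * ds.concentrations / (1.0 + k * ds.concentrations)
        return _make_result(
            self.model_id, params, self.anchor, self.dataset, gamma_cal, coverage, ok
        )


def fit_gibbs(dataset: TensionDataset, n: float = 1.0) -> FitResult:
    return GibbsAdsorptionModel(dataset, n=n).fit()


def fit_langmuir(dataset: TensionDataset) -> FitResult:
    return LangmuirSzyszkowskiModel(dataset).fit()


def fit_frumkin(dataset: TensionDataset) -> FitResult:
    return FrumkinModel(dataset).fit()


def fit_modified_frumkin(dataset_region2: TensionDataset, anchor: RegionAnchor) -> FitResult:
    return TwoRegionFrumkinModel(dataset_region2, anchor).fit()


def fit_modified_langmuir(dataset_region2: TensionDataset, anchor: RegionAnchor) -> FitResult:
    return TwoRegionLangmuirModel(dataset_region2, anchor).fit()
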