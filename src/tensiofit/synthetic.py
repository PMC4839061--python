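"""Synthetic equilibrium surface-tension curves with known ground truth.

Emulates pendant-bubble tensiometry of a surfactant dilution series: a
premicellar branch generated by one of the forward adsorption models
(optionally with the two-slope structure seen for highly surface-active
solutes, where depletion of the dilute solutions steepens the gamma-lnC
curve below the region-1/region-2 intersection), an optional post-CMC
plateau, and multiplicative run-to-run noise.

Noise is multiplicative Gaussian on the tension with coefficient of
variation ``noise_cv``, truncated at +/- 3 sigma so that no generated point
exceeds ``gamma0 * (1 + 3 * noise_cv)`` — the generator's reading of a
tensiometric reproducibility bound of a few percent. ``noise_cv`` is capped
at 0.03 accordingly.

The region-1 branch is a log-linear graft: a straight line in (lnC, gamma)
through the anchor whose slope is a configurable multiple (> 1) of the
region-2 tangent slope at the anchor. No physical model of the depletion is
attempted — only region 2 is ever fitted — but the graft gives segmentation
something real to find. A slope multiple of exactly 1 degenerates the whole
premicellar curve to a single log-linear branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import R
from .dataset import TensionDataset
from .isotherms import (
    IsothermParams,
    RegionAnchor,
    frumkin_concentration,
    frumkin_tension,
    langmuir_tension,
    modified_frumkin_concentration,
    modified_frumkin_tension,
    modified_langmuir_tension,
)

__all__ = ["SyntheticSpec", "generate", "two_region_curve"]

_NOISE_CV_CAP = 0.03


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic gamma-C dataset.

    ``coverage_range`` is the interval of fractional coverage
    theta = Gamma^e/Gamma_inf sampled (log-spaced); for the anchored models
    sampling starts no lower than the anchor coverage. ``plateau`` adds that
    many post-CMC points at constant tension above the last premicellar
    concentration.
    """

    model_id: str
    true_params: IsothermParams
    anchor: Optional[RegionAnchor] = None
    gamma0: float = 72.0
    temperature: float = 298.15
    n_points: int = 15
    coverage_range: tuple = (0.2, 0.97)
    noise_cv: float = 0.01
    plateau: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in (
            "langmuir", "frumkin", "modified_frumkin", "modified_langmuir"
        ):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not 0 <= self.noise_cv <= _NOISE_CV_CAP:
            raise ValueError(f"noise_cv must lie in [0, {_NOISE_CV_CAP}]")
        if self.n_points < 5:
            raise ValueError("n_points must be >= 5")
        lo, hi = self.coverage_range
        if not (0 < lo < hi < 1):
            raise ValueError("coverage_range must satisfy 0 < lo < hi < 1")
        if self.model_id.startswith("modified") and self.anchor is None:
            raise ValueError("anchored models require an anchor")


def _anchor_theta(spec: SyntheticSpec) -> float:
    """Fractional coverage at the anchor under the spec's model."""
    if spec.anchor.coverage_12 is not None:
        return spec.anchor.coverage_12 / spec.true_params.gamma_inf
    # Langmuir-type anchored model: coverage follows from the isotherm
    kc = spec.true_params.K * spec.anchor.c_12
    return kc / (1.0 + kc)


def _theta_grid(spec: SyntheticSpec) -> np.ndarray:
    lo, hi = spec.coverage_range
    if spec.model_id.startswith("modified"):
        lo = max(lo, _anchor_theta(spec))
    return np.geomspace(lo, hi, spec.n_points)


def _forward(spec: SyntheticSpec, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map a coverage grid to (C, gamma) under the spec's model."""
    p = spec.true_params
    cov = theta * p.gamma_inf
    if spec.model_id == "langmuir":
        conc = theta / (p.K * (1.0 - theta))
        gamma = langmuir_tension(p, conc, spec.gamma0, spec.temperature)
    elif spec.model_id == "frumkin":
        conc = frumkin_concentration(p, cov)
        gamma = frumkin_tension(p, cov, spec.gamma0, spec.temperature)
    elif spec.model_id == "modified_frumkin":
        conc = modified_frumkin_concentration(p, cov, spec.anchor)
        gamma = modified_frumkin_tension(p, cov, spec.anchor, spec.temperature)
    else:  # modified_langmuir: theta = KC/(1+KC) inverted for C
        conc = theta / (p.K * (1.0 - theta))
        conc = np.maximum(conc, spec.anchor.c_12)
        gamma = modified_langmuir_tension(p, conc, spec.anchor, spec.temperature)
    return np.asarray(conc, dtype=float), np.asarray(gamma, dtype=float)


def _apply_noise(gamma: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_cv == 0:
        return gamma
    eps = rng.normal(0.0, spec.noise_cv, size=gamma.shape)
    eps = np.clip(eps, -3.0 * spec.noise_cv, 3.0 * spec.noise_cv)
    return gamma * (1.0 + eps)


def generate(spec: SyntheticSpec) -> tuple[TensionDataset, dict]:
    """Generate one dataset plus the generating ground truth.

    Returns ``(dataset, truth)`` where ``truth`` records the parameters,
    model, anchor and (when a plateau is appended) the CMC used. The same
    spec (same seed) always yields the identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    theta = _theta_grid(spec)
    conc, gamma = _forward(spec, theta)
    cmc = None
    if spec.plateau > 0:
        cmc = conc[-1]
        c_plateau = np.geomspace(cmc * 1.4, cmc * 5.0, spec.plateau)
        conc = np.concatenate([conc, c_plateau])
        gamma = np.concatenate([gamma, np.full(spec.plateau, gamma[-1])])
    gamma = _apply_noise(gamma, spec, rng)
    ds = TensionDataset(
        conc, gamma, spec.temperature, spec.gamma0,
        label=f"synthetic-{spec.model_id}",
    )
    truth = {
        "model_id": spec.model_id,
        "params": spec.true_params,
        "anchor": spec.anchor,
        "cmc": cmc,
        "coverage": theta * spec.true_params.gamma_inf,
        "seed": spec.seed,
    }
    return ds, truth


def region2_tangent_slope(spec: SyntheticSpec) -> float:
    """d gamma / d lnC of the region-2 branch at the anchor, mN/m per ln unit."""
    p = spec.true_params
    anchor = spec.anchor
    theta12 = anchor.coverage_12 / p.gamma_inf
    # d gamma / d theta (mN/m) and d C / d theta at the anchor
    dgamma_dtheta = R * spec.temperature * p.gamma_inf * 1e3 * (
        p.beta * theta12 - 1.0 / (1.0 - theta12)
    )
    h12 = theta12 * np.exp(-p.beta * theta12) / (1.0 - theta12)
    dh_dtheta = h12 * (1.0 / theta12 + 1.0 / (1.0 - theta12) - p.beta)
    dlnc_dtheta = dh_dtheta / (p.K * anchor.c_12)
    return float(dgamma_dtheta / dlnc_dtheta)


def two_region_curve(
    spec: SyntheticSpec,
    slope_multiple: float = 2.0,
    n_region1: int = 6,
) -> TensionDataset:
    """Premicellar curve with the two-slope (region-1 / region-2) structure.

    Region 2 follows the spec's anchored model above the anchor; region 1 is
    a log-linear branch through the anchor with slope ``slope_multiple``
    times the region-2 tangent slope there. ``slope_multiple == 1`` produces
    a single log-linear curve (no two-slope structure).
    """
    if spec.anchor is None:
        raise ValueError("two_region_curve requires an anchor in the spec")
    if spec.anchor.coverage_12 is None:
        raise ValueError("the anchor must carry its coverage (coverage_12)")
    if slope_multiple < 1:
        raise ValueError("slope_multiple must be >= 1")
    rng = np.random.default_rng(spec.seed)
    m2 = region2_tangent_slope(spec)
    m1 = slope_multiple * m2
    ln_c12 = np.log(spec.anchor.c_12)

    # region-1 extent: at most one decade, clipped so gamma stays <= gamma0
    span = np.log(10.0)
    headroom = (spec.gamma0 - spec.anchor.gamma_12) / (-m1)
    span = min(span, 0.95 * headroom)
    ln_c1 = np.linspace(ln_c12 - span, ln_c12, n_region1, endpoint=False)
    gamma1 = spec.anchor.gamma_12 + m1 * (ln_c1 - ln_c12)

    if slope_multiple == 1.0:
        # single-slope curve: continue the same line above the anchor too
        theta = _theta_grid(spec)
        conc2, _ = _forward(spec, theta)
        gamma2 = spec.anchor.gamma_12 + m1 * (np.log(conc2) - ln_c12)
    else:
        theta = _theta_grid(spec)
        conc2, gamma2 = _forward(spec, theta)

    conc = np.concatenate([np.exp(ln_c1), conc2])
    gamma = np.concatenate([gamma1, gamma2])
    gamma = _apply_noise(gamma, spec, rng)
    return TensionDataset(
        conc, gamma, spec.temperature, spec.gamma0,
        label=f"synthetic-two-region-{spec.model_id}",
    )
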