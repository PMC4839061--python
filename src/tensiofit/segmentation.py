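"""Segmentation of gamma-lnC curves.

Premicellar surface-tension curves of highly surface-active molecules can
show two distinct log-linear slopes (a steep dilute branch, attributed to
depletion of the surfactant from the bulk, followed by the branch that
actually reflects interfacial saturation), and above the critical micelle
concentration (CMC) the tension plateaus. This module partitions a dataset
into those segments and locates:

* the region-1/region-2 intersection anchor (C_12, gamma_12) used by the
  anchored (two-region) models, and
* the CMC, as the meeting point of the region-2 branch with the plateau
  line when a third segment is requested.

Estimator
---------
The anchor is the knot of a continuous segmented ("hinge") regression in
(lnC, gamma): gamma = gamma* + m1 min(x-k, 0) + m2 max(x-k, 0), optionally
with a quadratic term a max(x-k, 0)^2 that absorbs the curvature of the
region-2 branch (an adsorption isotherm is not exactly log-linear below
saturation). The knot k is located in two deterministic stages:

1. a global scan — the plain-hinge residual is minimised within every
   admissible inter-point interval (>= 3 points per side) and the best
   interval wins;
2. a local refinement — the quadratic-hinge residual is minimised with the
   knot confined to one median point-spacing around the stage-1 knot.

Fitting two unconstrained lines and intersecting them is simpler but
systematically biased: the region-2 curvature drags both the breakpoint
placement and the fitted line, and the bias survives at zero noise.
Requiring continuity at the knot and modelling the curvature removes it.
The plateau boundary (three-segment fits) is still found by exhaustive
search, with the plateau fitted as an independent line whose slope
magnitude must be the smallest of the three.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dataset import TensionDataset
from .isotherms import RegionAnchor

__all__ = [
    "RegionSplit",
    "fit_piecewise_loglinear",
    "split_at_breakpoints",
    "premicellar_subset",
    "hinge_sse",
    "MIN_SEGMENT_POINTS",
]

MIN_SEGMENT_POINTS = 3

# relative slope difference below which two segments count as one line
_COLLINEAR_RTOL = 1e-6
_XATOL = 1e-12


@dataclass(frozen=True)
class RegionSplit:
    """Partition of a tension dataset into up to three segments.

    ``slopes`` are d gamma / d lnC (mN/m per ln unit): the region-1 slope,
    the region-2 slope at the anchor, and — when present — the plateau
    slope. ``sse`` is the total squared residual of the piecewise fit.
    """

    region1_indices: np.ndarray
    region2_indices: np.ndarray
    postcmc_indices: np.ndarray
    anchor: Optional[RegionAnchor]
    cmc: Optional[float]
    slopes: tuple
    curvature: float  # quadratic coefficient of the region-2 branch
    sse: float
    degenerate: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.slopes)


def _hinge_design(x: np.ndarray, k: float, quad: bool) -> np.ndarray:
    cols = [np.ones_like(x), np.minimum(x - k, 0.0), np.maximum(x - k, 0.0)]
    if quad:
        cols.append(np.maximum(x - k, 0.0) ** 2)
    return np.column_stack(cols)


def hinge_sse(x: np.ndarray, y: np.ndarray, knot: float, quad: bool = False):
    """Least-squares continuous segmented fit with the knot at ``knot``.

    Returns ``(sse, coef)`` with ``coef = (gamma*, m1, m2[, a])``.
    """
    A = _hinge_design(x, knot, quad)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


# how many leading plain-hinge candidates the curvature-aware stage re-judges
_N_REFINE = 3


def _best_knot(x: np.ndarray, y: np.ndarray, min_pts: int) -> float:
    """Two-stage knot search.

    Stage 1 minimises the plain-hinge residual within every admissible
    inter-point interval. Stage 2 re-fits the leading candidates with the
    region-2 quadratic term, the knot confined to one median point-spacing,
    and lets the curvature-aware residual adjudicate: the plain model is
    misspecified on a curved region-2 branch, so its near-tied candidates
    are best separated by the richer model.
    """
    n = x.size
    candidates = []
    for j in range(min_pts, n - min_pts + 1):
        res = minimize_scalar(
            lambda k: hinge_sse(x, y, k)[0],
            bounds=(x[j - 1], x[j]), method="bounded",
            options={"xatol": _XATOL},
        )
        candidates.append((float(res.fun), float(res.x)))
    candidates.sort()
    window = float(np.median(np.diff(x)))
    best_k, best_sse = None, np.inf
    for _, k0 in candidates[:_N_REFINE]:
        res = minimize_scalar(
            lambda k: hinge_sse(x, y, k, quad=True)[0],
            bounds=(k0 - window, k0 + window), method="bounded",
            options={"xatol": _XATOL},
        )
        if res.fun < best_sse:
            best_k, best_sse = float(res.x), float(res.fun)
    return best_k


def _two_segment(x: np.ndarray, y: np.ndarray, min_pts: int):
    """Fit the premicellar two-slope structure; returns (knot, coef, sse)."""
    k = _best_knot(x, y, min_pts)
    sse, coef = hinge_sse(x, y, k, quad=True)
    return k, coef, sse


def _degenerate_split(dataset: TensionDataset) -> RegionSplit:
    x, y = dataset.log_concentrations, dataset.tensions
    m, b = np.polyfit(x, y, 1)
    resid = y - (m * x + b)
    return RegionSplit(
        region1_indices=np.arange(len(dataset)),
        region2_indices=np.arange(0),
        postcmc_indices=np.arange(0),
        anchor=None,
        cmc=None,
        slopes=(float(m),),
        curvature=0.0,
        sse=float(resid @ resid),
        degenerate=True,
    )


def fit_piecewise_loglinear(dataset: TensionDataset, n_segments: int = 2) -> RegionSplit:
    """Segment a gamma-C curve and locate the region anchor (and CMC).

    With ``n_segments=2`` the whole dataset is treated as premicellar and
    split into regions 1 and 2 at the fitted knot. With ``n_segments=3``
    every admissible plateau start index is tried: the points before it get
    the continuous two-slope fit, the plateau gets its own line (smallest
    slope magnitude of the three, by construction of a plateau), and the
    total squared residual decides. The CMC is where the region-2 branch
    (including its curvature) meets the plateau line.

    Collinear input yields a degenerate single-segment split with no anchor.
    """
    if n_segments not in (2, 3):
        raise ValueError("n_segments must be 2 or 3")
    n = len(dataset)
    if n < MIN_SEGMENT_POINTS * n_segments:
        raise ValueError(
            f"need at least {MIN_SEGMENT_POINTS * n_segments} points for "
            f"{n_segments} segments, got {n}"
        )
    x = dataset.log_concentrations
    y = dataset.tensions
    if np.any(np.diff(x) <= 0):
        raise ValueError("concentrations must be strictly increasing")

    if n_segments == 2:
        k, coef, sse = _two_segment(x, y, MIN_SEGMENT_POINTS)
        return _build_split(dataset, x, y, k, coef, sse, plateau_start=None,
                            plateau_line=None)

    best = None
    for j in range(2 * MIN_SEGMENT_POINTS, n - MIN_SEGMENT_POINTS + 1):
        k, coef, sse_pre = _two_segment(x[:j], y[:j], MIN_SEGMENT_POINTS)
        m3, b3 = np.polyfit(x[j:], y[j:], 1)
        resid3 = y[j:] - (m3 * x[j:] + b3)
        m2_end = coef[2] + 2.0 * coef[3] * (x[j - 1] - k)  # region-2 slope at plateau
        if abs(m3) > min(abs(coef[1]), abs(m2_end)):
            continue  # plateau must be the flattest segment
        total = sse_pre + float(resid3 @ resid3)
        if best is None or total < best[0]:
            best = (total, j, k, coef, (float(m3), float(b3)))
    if best is None:
        raise ValueError("no admissible plateau segment (slope constraint)")
    total, j, k, coef, plateau_line = best
    return _build_split(dataset, x, y, k, coef, total, plateau_start=j,
                        plateau_line=plateau_line)


def _build_split(dataset, x, y, k, coef, sse, plateau_start, plateau_line) -> RegionSplit:
    n = len(dataset)
    m1, m2, a2 = float(coef[1]), float(coef[2]), float(coef[3])
    if abs(m2 - m1) <= _COLLINEAR_RTOL * max(1e-12, abs(m1)) and plateau_start is None:
        return _degenerate_split(dataset)
    # single-line fit cannot beat the hinge unless the hinge adds nothing
    m_all, b_all = np.polyfit(x, y, 1)
    resid_all = y - (m_all * x + b_all)
    if plateau_start is None and float(resid_all @ resid_all) <= sse * (1 + 1e-9) + 1e-12:
        return _degenerate_split(dataset)

    anchor = RegionAnchor(c_12=float(np.exp(k)), gamma_12=float(coef[0]))
    pre_end = n if plateau_start is None else plateau_start
    split_idx = int(np.searchsorted(x[:pre_end], k))
    cmc = None
    slopes = (m1, m2)
    if plateau_start is not None:
        m3, b3 = plateau_line
        gamma_at = lambda z: coef[0] + m2 * (z - k) + a2 * (z - k) ** 2  # noqa: E731
        f = lambda z: gamma_at(z) - (m3 * z + b3)  # noqa: E731
        lo, hi = k, x[-1] + 5.0
        try:
            ln_cmc = brentq(f, lo, hi) if f(lo) * f(hi) < 0 else None
        except ValueError:  # pragma: no cover
            ln_cmc = None
        if ln_cmc is None:
            # fall back to the straight-line intersection
            ln_cmc = (coef[0] - m2 * k - b3) / (m3 - m2)
        cmc = float(np.exp(ln_cmc))
        slopes = (m1, m2, m3)
    return RegionSplit(
        region1_indices=np.arange(0, split_idx),
        region2_indices=np.arange(split_idx, pre_end),
        postcmc_indices=np.arange(pre_end, n) if plateau_start is not None else np.arange(0),
        anchor=anchor,
        cmc=cmc,
        slopes=slopes,
        curvature=a2,
        sse=float(sse),
        degenerate=False,
    )


def split_at_breakpoints(dataset: TensionDataset, breakpoints: Sequence[int]) -> RegionSplit:
    """Manual override: segment at user-chosen breakpoint indices.

    ``breakpoints`` are 1 or 2 indices marking the first point of region 2
    (and, optionally, of the post-CMC plateau). The knot is fitted within
    the interval just below the first breakpoint.
    """
    n = len(dataset)
    breaks = tuple(int(b) for b in breakpoints)
    if not breaks or len(breaks) > 2 or list(breaks) != sorted(set(breaks)):
        raise ValueError("breakpoints must be 1 or 2 strictly increasing indices")
    bounds = (0, *breaks, n)
    if any(b - a < MIN_SEGMENT_POINTS for a, b in zip(bounds[:-1], bounds[1:])):
        raise ValueError(f"each segment needs >= {MIN_SEGMENT_POINTS} points")
    x, y = dataset.log_concentrations, dataset.tensions
    i = breaks[0]
    pre_end = breaks[1] if len(breaks) == 2 else n
    res = minimize_scalar(
        lambda k: hinge_sse(x[:pre_end], y[:pre_end], k, quad=True)[0],
        bounds=(x[i - 1], x[i]), method="bounded", options={"xatol": _XATOL},
    )
    k = float(res.x)
    sse_pre, coef = hinge_sse(x[:pre_end], y[:pre_end], k, quad=True)
    if abs(coef[2] - coef[1]) <= _COLLINEAR_RTOL * max(1e-12, abs(coef[1])):
        raise ValueError("segments are collinear; no anchor exists")
    plateau_line = None
    total = sse_pre
    if len(breaks) == 2:
        j = breaks[1]
        m3, b3 = np.polyfit(x[j:], y[j:], 1)
        resid3 = y[j:] - (m3 * x[j:] + b3)
        plateau_line = (float(m3), float(b3))
        total = sse_pre + float(resid3 @ resid3)
    return _build_split(
        dataset, x, y, k, coef, total,
        plateau_start=breaks[1] if len(breaks) == 2 else None,
        plateau_line=plateau_line,
    )


def premicellar_subset(dataset: TensionDataset, split: RegionSplit) -> TensionDataset:
    """Points below the CMC (all points if no plateau was detected)."""
    if split.postcmc_indices.size == 0:
        return dataset
    keep = np.concatenate([split.region1_indices, split.region2_indices])
    return dataset.subset(np.sort(keep))
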