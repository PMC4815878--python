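"""Beam-center refinement via Friedel symmetry.

Elastic scattering from a real-valued density satisfies I(q) = I(-q), so
within the flat region of the Ewald sphere (where out-of-plane curvature is
negligible) a pattern is centrosymmetric about the true beam center. The
center is refined by a grid search minimizing a Poisson-aware squared
difference between Friedel-pair intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .simulate import DetectorGeometry, ScatteringPattern

#: minimum number of valid Friedel pairs for a meaningful score
MIN_PAIRS = 50


def flat_cutoff_angle(flat_tol: float = 0.01) -> float:
    """Scattering half-angle (rad) at which the Ewald sphere departs from its
    tangent plane by the fraction ``flat_tol``.

    The fractional departure along the beam axis at full scattering angle
    alpha is 1 - cos(alpha), so the cutoff half-angle is arccos(1 - tol) / 2;
    at the default 1% tolerance this is about 0.07 rad.
    """
    if not 0 < flat_tol < 1:
        raise InvalidInputError("flat_tol must be in (0, 1)")
    return float(np.arccos(1.0 - flat_tol) / 2.0)


def flat_region_mask(geometry: DetectorGeometry, flat_tol: float = 0.01) -> np.ndarray:
    """Boolean mask of unmasked pixels within the flat Ewald region.

    A pixel is included iff 1 - cos(alpha) <= flat_tol, with alpha its full
    scattering angle, and it is usable in the geometry mask. ``flat_tol = 1``
    degenerates to the whole (unmasked) detector.
    """
    if not 0 < flat_tol <= 1:
        raise InvalidInputError("flat_tol must be in (0, 1]")
    alpha = geometry.scattering_angles()
    return (1.0 - np.cos(alpha) <= flat_tol) & geometry.mask


@dataclass
class CenterSearchSpec:
    """Grid-search configuration around an initial beam-center guess."""

    initial_center: tuple[float, float]
    half_width: float = 5.0
    step: float = 1.0
    flat_tol: float = 0.01

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise InvalidInputError("step must be positive")
        if self.half_width < self.step:
            raise InvalidInputError("half_width must be >= step")
        if not 0 < self.flat_tol < 1:
            raise InvalidInputError("flat_tol must be in (0, 1)")


@dataclass
class CenterResult:
    """Refined center plus the full diagnostic score surface."""

    center: tuple[float, float]
    score: float
    grid_cx: np.ndarray
    grid_cy: np.ndarray
    surface: np.ndarray  # score[iy, ix] over (grid_cy, grid_cx)


def friedel_score(pattern: ScatteringPattern, trial_center: tuple[float, float],
                  flat_mask: np.ndarray | None = None,
                  flat_tol: float = 0.01) -> float:
    """Mean count-normalized squared Friedel-pair difference at a trial center.

    For every flat-region pixel p whose reflection p' through the trial
    center (nearest-pixel rounding) is also a valid flat-region pixel, the
    contribution is (I(p) - I(p'))^2 / max(I(p) + I(p'), 1); the score is the
    mean over pairs. The denominator is the Poisson variance of the
    difference, floored at one count.
    """
    geo = pattern.geometry
    cx, cy = trial_center
    if not (0 <= cx < geo.n_fast and 0 <= cy < geo.n_slow):
        raise InvalidInputError("trial center outside detector")
    if flat_mask is None:
        flat_mask = flat_region_mask(geo, flat_tol)
    valid = flat_mask & pattern.valid
    ii, jj = np.nonzero(valid)
    # Friedel partner: reflection through the trial center
    pi = np.rint(2.0 * cy - ii).astype(np.int64)
    pj = np.rint(2.0 * cx - jj).astype(np.int64)
    ok = (pi >= 0) & (pi < geo.n_slow) & (pj >= 0) & (pj < geo.n_fast)
    ii, jj, pi, pj = ii[ok], jj[ok], pi[ok], pj[ok]
    ok = valid[pi, pj]
    ii, jj, pi, pj = ii[ok], jj[ok], pi[ok], pj[ok]
    if len(ii) < MIN_PAIRS:
        raise InsufficientDataError(
            f"only {len(ii)} valid Friedel pairs (need >= {MIN_PAIRS})")
    a = pattern.counts[ii, jj].astype(float)
    b = pattern.counts[pi, pj].astype(float)
    return float(np.mean((a - b) ** 2 / np.maximum(a + b, 1.0)))


def optimize_center(pattern: ScatteringPattern, spec: CenterSearchSpec,
                    refine: bool = False) -> CenterResult:
    """Grid-search the beam center minimizing :func:`friedel_score`.

    Ties are broken by smallest Euclidean distance to the initial center,
    then lexicographically on (cx, cy). With ``refine=True`` a second pass at
    a quarter of the step runs around the first-pass optimum.
    """
    geo = pattern.geometry
    flat0 = flat_region_mask(geo, spec.flat_tol)
    result = _grid_pass(pattern, spec.initial_center, spec.half_width, spec.step,
                        flat0, spec.initial_center)
    if refine:
        fine = _grid_pass(pattern, result.center, spec.step, spec.step / 4.0,
                          flat0, spec.initial_center)
        if fine.score <= result.score:
            result = fine
    return result


def _grid_pass(pattern, around, half_width, step, flat_mask, initial) -> CenterResult:
    geo = pattern.geometry
    n = int(round(half_width / step))
    offsets = step * np.arange(-n, n + 1)
    grid_cx = around[0] + offsets
    grid_cy = around[1] + offsets
    surface = np.full((len(grid_cy), len(grid_cx)), np.nan)
    best = None
    for iy, cy in enumerate(grid_cy):
        for ix, cx in enumerate(grid_cx):
            if not (0 <= cx < geo.n_fast and 0 <= cy < geo.n_slow):
                continue
            s = friedel_score(pattern, (cx, cy), flat_mask)
            surface[iy, ix] = s
            key = (s, np.hypot(cx - initial[0], cy - initial[1]), cx, cy)
            if best is None or key < best[0]:
                best = (key, (float(cx), float(cy)), s)
    if best is None:
        raise InsufficientDataError("no trial center inside the detector")
    return CenterResult(best[1], best[2], grid_cx, grid_cy, surface)


def optimize_centers(patterns, spec: CenterSearchSpec, refine: bool = False):
    """Per-pattern center refinement; returns a list of CenterResult."""
    return [optimize_center(p, spec, refine=refine) for p in patterns]
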