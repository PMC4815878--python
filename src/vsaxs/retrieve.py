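"""Shape retrieval: chi scoring, golden-section radius search, ranking,
clustering and averaging of the retrieved models.

A query SAXS profile is compared against every database shape scaled to a
trial radius; agreement is a reduced chi with the multiplicative scale c
solved in closed form by least squares. The radius enters only as an
argument rescaling of the stored dimensionless profiles, so a 1D
golden-section search over the radius (bracketed around a user-supplied
guess) finds the best size cheaply. The top-K models are rendered as voxel
maps, clustered by real-space overlap, and averaged per class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import map_coordinates

from .errors import (DegenerateModelError, InsufficientDataError,
                     InvalidInputError, RangeError)
from .models import VoxelMap, model_to_voxels
from .profiles import SAXSProfile
from .shapedb import ShapeDatabase, model_profile_at_radius

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0  # bracket contraction per iteration

#: default radius bracket and tolerance, as fractions of the user radius r0
BRACKET_LO, BRACKET_HI, RADIUS_TOL = 0.8, 1.25, 0.01


# ---------------------------------------------------------------------------
# chi score
# ---------------------------------------------------------------------------

@dataclass
class ChiFit:
    """Least-squares scale c and reduced chi of one model-vs-data fit."""

    c: float
    chi: float
    n_points: int


def chi_score(exp: SAXSProfile, model_I: np.ndarray,
              sigma_mode: str = "auto") -> ChiFit:
    """Reduced chi between an experimental profile and a model intensity.

    c = [sum I_e I_m / s^2] / [sum I_m^2 / s^2] and
    chi = sqrt( (1/N) sum ((I_e - c I_m) / s)^2 ), over bins where both
    profiles are defined. ``sigma_mode``: 'experimental' uses the profile's
    sigma, 'relative' uses s_i = I_e(q_i) (unweighted relative residuals),
    'auto' picks 'experimental' when every fitted sigma is positive.
    """
    model_I = np.asarray(model_I, dtype=float)
    if model_I.shape != exp.q.shape:
        raise InvalidInputError("model intensity must be on the profile's q grid")
    m = exp.valid & np.isfinite(exp.I) & np.isfinite(model_I)
    if m.sum() < 3:
        raise InsufficientDataError("need >= 3 shared points for a chi fit")
    Ie, Im = exp.I[m], model_I[m]
    if not np.any(Im != 0):
        raise DegenerateModelError("model profile is identically zero")
    if sigma_mode == "auto":
        sigma_mode = "experimental" if np.all(exp.sigma[m] > 0) else "relative"
    if sigma_mode == "experimental":
        s = exp.sigma[m]
        if np.any(s <= 0):
            raise InvalidInputError("sigma must be positive for experimental weighting")
    elif sigma_mode == "relative":
        s = np.abs(Ie)
        s[s == 0] = 1.0
    else:
        raise InvalidInputError(f"unknown sigma_mode {sigma_mode!r}")
    w = 1.0 / s**2
    c = float(np.sum(w * Ie * Im) / np.sum(w * Im * Im))
    chi = float(np.sqrt(np.mean(((Ie - c * Im) / s) ** 2)))
    return ChiFit(c=c, chi=chi, n_points=int(m.sum()))


# ---------------------------------------------------------------------------
# golden-section search
# ---------------------------------------------------------------------------

@dataclass
class RadiusSearch:
    """Outcome of a 1D golden-section minimization over the radius."""

    r0: float | None
    bracket: tuple[float, float]
    tolerance: float
    r_star: float
    n_iterations: int
    evaluations: list = field(default_factory=list)  # (r, f(r)) log


def golden_section_minimize(f, bracket: tuple[float, float], tolerance: float,
                            r0: float | None = None) -> RadiusSearch:
    """Standard golden-section minimization of a scalar function.

    Each iteration evaluates one new interior point and shrinks the bracket
    by the golden ratio (sqrt(5)-1)/2 ~ 0.618; iteration stops once the
    bracket width is <= ``tolerance`` and the midpoint of the final bracket
    is returned. A monotone objective drives the result to the corresponding
    endpoint neighborhood.
    """
    lo, hi = bracket
    if not lo < hi:
        raise InvalidInputError("bracket must satisfy r_lo < r_hi")
    if not tolerance > 0:
        raise InvalidInputError("tolerance must be positive")
    log: list = []

    def ev(r):
        v = f(r)
        log.append((r, v))
        return v

    x1 = hi - GOLDEN * (hi - lo)
    x2 = lo + GOLDEN * (hi - lo)
    f1, f2 = ev(x1), ev(x2)
    n_iter = 0
    while hi - lo > tolerance:
        n_iter += 1
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - GOLDEN * (hi - lo)
            f1 = ev(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + GOLDEN * (hi - lo)
            f2 = ev(x2)
    return RadiusSearch(r0=r0, bracket=(float(bracket[0]), float(bracket[1])),
                        tolerance=float(tolerance), r_star=float(0.5 * (lo + hi)),
                        n_iterations=n_iter, evaluations=log)


def _seeded_minimize(f, bracket: tuple[float, float], tolerance: float,
                     r0: float | None = None, n_grid: int = 13) -> RadiusSearch:
    """Coarse grid scan to locate the best basin, golden-section within it,
    and a final argmin over every evaluated point (including r0).

    Chi-vs-radius landscapes of profiles with deep minima are not unimodal
    over a +-25% bracket; the scan keeps the golden section from discarding
    the global basin, and evaluating r0 guarantees the result is never worse
    than the user's guess when it lies inside the bracket.
    """
    lo, hi = bracket
    grid = list(np.linspace(lo, hi, n_grid))
    if r0 is not None and lo <= r0 <= hi:
        grid = sorted(set(grid + [float(r0)]))
    vals = [f(r) for r in grid]
    k = int(np.argmin(vals))
    sub = (grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)])
    gs = golden_section_minimize(f, sub, tolerance, r0=r0)
    evals = list(zip(grid, vals)) + gs.evaluations + [(gs.r_star, f(gs.r_star))]
    r_best, f_best = min(evals, key=lambda t: (t[1], t[0]))
    return RadiusSearch(r0=r0, bracket=(float(lo), float(hi)),
                        tolerance=float(tolerance), r_star=float(r_best),
                        n_iterations=gs.n_iterations, evaluations=evals)


def default_bracket(r0: float) -> tuple[tuple[float, float], float]:
    """Default radius bracket [0.8 r0, 1.25 r0] (symmetric on a log scale)
    and tolerance 0.01 r0, giving 8 golden-section iterations."""
    if not r0 > 0:
        raise InvalidInputError("r0 must be positive")
    return (BRACKET_LO * r0, BRACKET_HI * r0), RADIUS_TOL * r0


# ---------------------------------------------------------------------------
# database search
# ---------------------------------------------------------------------------

@dataclass
class RankedModel:
    model_id: str
    chi: float
    c: float
    r: float


@dataclass
class RetrievalResult:
    """Ranked models with per-model fits, class labels and averaged maps."""

    ranked: list[RankedModel]
    radius_search: RadiusSearch
    class_labels: np.ndarray | None = None
    maps: list[VoxelMap] | None = None
    class_maps: dict[int, VoxelMap] | None = None
    q_range: tuple[float, float] | None = None

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.ranked]


def _chi_at_radius(db: ShapeDatabase, exp: SAXSProfile, r: float,
                   sigma_mode: str) -> list[tuple[float, str, ChiFit]]:
    """(chi, id, fit) for every model at one radius, coverage-checked."""
    out = []
    n_valid = int(np.sum(exp.valid & np.isfinite(exp.I)))
    for e in db.entries:
        Im = model_profile_at_radius(e, r, exp.q)
        if np.sum(np.isfinite(Im) & exp.valid) < 0.5 * n_valid:
            raise RangeError(
                "q*r exceeds the database s_max over more than half of the "
                "profile; rebuild the database with a larger s_max")
        fit = chi_score(exp, Im, sigma_mode=sigma_mode)
        out.append((fit.chi, e.model_id, fit))
    return out


def search(db: ShapeDatabase, exp: SAXSProfile, r0: float,
           mode: str = "global", K: int = 10, sigma_mode: str = "auto",
           q_range: tuple[float, float] | None = None,
           bracket: tuple[float, float] | None = None,
           tolerance: float | None = None,
           with_maps: bool = True,
           overlap_threshold: float = 0.75,
           refine_top: int = 50) -> RetrievalResult:
    """Retrieve the K database models that best match a SAXS profile.

    mode='global': one golden-section search over the radius with objective
    J(r) = min over models of chi(exp, model at r), after which the top
    ``refine_top`` candidates each get an independent per-model radius
    refinement before the final ranking. mode='per_model': independent
    golden-section per model from the start. Ties in chi break
    lexicographically on model id.
    """
    if len(db) == 0:
        raise InvalidInputError("empty database")
    if not r0 > 0:
        raise InvalidInputError("r0 must be positive")
    if K < 1:
        raise InvalidInputError("K must be >= 1")
    if q_range is not None:
        exp = _restrict(exp, q_range)
    if bracket is None or tolerance is None:
        dflt_bracket, dflt_tol = default_bracket(r0)
        bracket = bracket or dflt_bracket
        tolerance = tolerance or dflt_tol

    if mode == "global":
        gs = _seeded_minimize(
            lambda r: min(c for c, _, _ in _chi_at_radius(db, exp, r, sigma_mode)),
            bracket, tolerance, r0=r0)
        at_star = sorted(_chi_at_radius(db, exp, gs.r_star, sigma_mode),
                         key=lambda t: (t[0], t[1]))
        candidates = at_star[:max(refine_top, K)]
        ranked = []
        for _, mid, _ in candidates:
            entry = db[mid]
            sub = _seeded_minimize(
                lambda r, e=entry: chi_score(
                    exp, model_profile_at_radius(e, r, exp.q), sigma_mode).chi,
                bracket, tolerance, r0=r0)
            fit = chi_score(exp, model_profile_at_radius(entry, sub.r_star, exp.q),
                            sigma_mode)
            ranked.append(RankedModel(mid, fit.chi, fit.c, sub.r_star))
    elif mode == "per_model":
        gs = None
        best_chi = np.inf
        ranked = []
        for e in db.entries:
            sub = _seeded_minimize(
                lambda r, e=e: chi_score(
                    exp, model_profile_at_radius(e, r, exp.q), sigma_mode).chi,
                bracket, tolerance, r0=r0)
            fit = chi_score(exp, model_profile_at_radius(e, sub.r_star, exp.q),
                            sigma_mode)
            ranked.append(RankedModel(e.model_id, fit.chi, fit.c, sub.r_star))
            if fit.chi < best_chi:
                best_chi, gs = fit.chi, sub
    else:
        raise InvalidInputError(f"unknown search mode {mode!r}")

    ranked.sort(key=lambda rm: (rm.chi, rm.model_id))
    ranked = ranked[:min(K, len(ranked))]
    result = RetrievalResult(ranked=ranked, radius_search=gs,
                             q_range=(float(exp.q[0]), float(exp.q[-1])))
    if with_maps and db.geometry:
        voxel = ranked[0].r / 20.0
        maps = []
        for rm in ranked:
            unit = db.geometry[rm.model_id]
            maps.append(model_to_voxels(unit.rescaled(rm.r), voxel_size=voxel))
        result.maps = maps
        result.class_labels = cluster_top_models(maps, overlap_threshold)
        result.class_maps = {}
        for label in _classes_in_rank_order(result.class_labels):
            members = [m for m, l in zip(maps, result.class_labels) if l == label]
            result.class_maps[int(label)] = average_models(members)
    return result


def _restrict(exp: SAXSProfile, q_range) -> SAXSProfile:
    m = (exp.q >= q_range[0]) & (exp.q <= q_range[1])
    if m.sum() < 3:
        raise InsufficientDataError("fewer than 3 bins in the requested q range")
    return SAXSProfile(exp.q[m], exp.I[m], exp.sigma[m],
                       n_patterns=exp.n_patterns, n_pix=exp.n_pix[m])


def _classes_in_rank_order(labels) -> list[int]:
    seen, out = set(), []
    for l in labels:
        if l not in seen:
            seen.add(l)
            out.append(int(l))
    return out


# ---------------------------------------------------------------------------
# map alignment, clustering, averaging
# ---------------------------------------------------------------------------

def _principal_frame(vmap: VoxelMap) -> tuple[np.ndarray, np.ndarray]:
    """Center of mass and right-handed principal-axes matrix (rows = axes),
    ordered by decreasing variance, sign fixed by the third central moment
    (ties resolve to the identity orientation of the eigenvector basis)."""
    x, y, z = vmap.voxel_centers()
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    w = vmap.values.ravel()
    total = w.sum()
    if total <= 0:
        return np.zeros(3), np.eye(3)
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    com = (w[:, None] * pts).sum(axis=0) / total
    d = pts - com
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / total
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows
    for k in range(3):
        m3 = np.sum(w * (d @ axes[k]) ** 3)
        if m3 < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return com, axes


def _resample_aligned(vmap: VoxelMap, com: np.ndarray, axes: np.ndarray,
                      grid_axes: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Sample a map on an aligned grid: grid point u (principal-frame
    coordinates) maps to com + axes^T u in the original frame."""
    gx, gy, gz = grid_axes
    U, V, W = np.meshgrid(gx, gy, gz, indexing="ij")
    pts = np.stack([U.ravel(), V.ravel(), W.ravel()], axis=1) @ axes + com
    idx = (pts - vmap.origin) / vmap.voxel_size
    vals = map_coordinates(vmap.values, idx.T, order=1, mode="constant", cval=0.0)
    return vals.reshape(U.shape)


def _common_grid(maps, voxel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-frame grid covering the largest aligned bounding box."""
    half = 0.0
    for m in maps:
        x, y, z = m.voxel_centers()
        ext = np.array([x[-1] - x[0], y[-1] - y[0], z[-1] - z[0]])
        half = max(half, 0.5 * float(np.linalg.norm(ext)))
    ax = np.arange(-half, half + voxel_size, voxel_size)
    return ax, ax, ax


def _mass_support(v: np.ndarray, frac: float = 0.9) -> np.ndarray:
    """Smallest voxel set holding ``frac`` of the map's mass — an iso-level
    robust to interpolation smoothing, analogous to contouring a density
    map at its molecular volume."""
    if v.sum() <= 0:
        return v > 0
    order = np.sort(v.ravel())[::-1]
    cum = np.cumsum(order)
    t = order[np.searchsorted(cum, frac * v.sum())]
    return v >= max(t, 1e-12)


def map_overlap(a: VoxelMap, b: VoxelMap) -> float:
    """Jaccard overlap of the 90%-mass supports after centroid +
    principal-axes alignment on a common grid."""
    voxel = min(a.voxel_size, b.voxel_size)
    grid = _common_grid([a, b], voxel)
    va = _resample_aligned(a, *_principal_frame(a), grid)
    vb = _resample_aligned(b, *_principal_frame(b), grid)
    ta, tb = _mass_support(va), _mass_support(vb)
    inter = np.logical_and(ta, tb).sum()
    union = np.logical_or(ta, tb).sum()
    return float(inter / union) if union else 0.0


def cluster_top_models(maps, overlap_threshold: float = 0.75) -> np.ndarray:
    """Single-linkage clustering of maps at a pairwise overlap threshold.

    Labels are integers renumbered in rank order of each class's best
    (earliest) member: the class of the top-ranked map is 0. A threshold of
    0 merges everything; a threshold above 1 leaves singletons.
    """
    n = len(maps)
    if n == 0:
        raise InvalidInputError("no maps to cluster")
    if n == 1:
        return np.zeros(1, dtype=int)
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            dist.append(1.0 - map_overlap(maps[i], maps[j]))
    if overlap_threshold <= 0:
        raw = np.ones(n, dtype=int)
    elif overlap_threshold > 1:
        raw = np.arange(1, n + 1)
    else:
        Z = linkage(np.asarray(dist), method="single")
        raw = fcluster(Z, t=1.0 - overlap_threshold + 1e-12, criterion="distance")
    # renumber in rank order of best member
    out = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def average_models(members) -> VoxelMap:
    """Voxel-wise mean of maps after deterministic principal-axes alignment
    and resampling onto a common grid covering the union bounding box."""
    members = list(members)
    if not members:
        raise InvalidInputError("need at least one map to average")
    if len(members) == 1:
        return members[0]
    voxel = min(m.voxel_size for m in members)
    grid = _common_grid(members, voxel)
    acc = np.zeros((len(grid[0]), len(grid[1]), len(grid[2])))
    for m in members:
        acc += _resample_aligned(m, *_principal_frame(m), grid)
    acc /= len(members)
    origin = np.array([grid[0][0], grid[1][0], grid[2][0]])
    return VoxelMap(acc, voxel, origin)
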