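"""Radial intensity profiles and the merged virtual SAXS profile.

Each centered pattern is azimuthally integrated onto a common q grid to give
an "intensity profile"; summing many profiles over uniformly random particle
orientations converges to the spherically averaged SAXS profile of the
particle. Convergence is monitored by the Pearson correlation of the
cumulative profile against a reference (typically the full-set merge), and
by split-half consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (EmptyProfileError, GridMismatchError, InsufficientDataError,
                     InvalidInputError)
from .simulate import DetectorGeometry, ScatteringPattern


@dataclass
class SAXSProfile:
    """1D scattering profile on a fixed q grid.

    ``q`` holds bin centers (nm^-1, strictly increasing), ``I`` the mean
    intensity per bin scaled by the number of merged patterns, ``sigma`` the
    propagated Poisson uncertainty, ``n_pix`` the cumulative number of
    contributing pixels per bin. Bins with ``n_pix == 0`` carry NaN in ``I``.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    n_patterns: int = 1
    n_pix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise InvalidInputError("q, I, sigma must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise InvalidInputError("q must be strictly increasing")
        if self.n_pix is None:
            self.n_pix = np.where(np.isfinite(self.I), 1, 0)
        self.n_pix = np.asarray(self.n_pix)

    @property
    def valid(self) -> np.ndarray:
        """Bins with at least one contributing pixel."""
        return self.n_pix > 0

    def __len__(self) -> int:
        return len(self.q)


def default_q_bins(geometry: DetectorGeometry, n_bins: int = 200,
                   q_min: float | None = None, q_max: float | None = None) -> np.ndarray:
    """Linear bin edges from about one pixel off the beam center out to the
    detector corner, the default working range of the integration."""
    k = geometry.k
    if q_min is None:
        q_min = 2 * k * np.sin(0.5 * np.arctan2(geometry.pixel_mm, geometry.distance_mm))
    if q_max is None:
        cx, cy = geometry.beam_center
        corners = [(0, 0), (0, geometry.n_fast - 1),
                   (geometry.n_slow - 1, 0), (geometry.n_slow - 1, geometry.n_fast - 1)]
        r = max(np.hypot(j - cx, i - cy) for i, j in corners) * geometry.pixel_mm
        q_max = 2 * k * np.sin(0.5 * np.arctan2(r, geometry.distance_mm))
    return np.linspace(q_min, q_max, n_bins + 1)


def azimuthal_integrate(pattern: ScatteringPattern,
                        center: tuple[float, float] | None = None,
                        q_bins: np.ndarray | None = None) -> SAXSProfile:
    """Radially average a pattern into 1D.

    Every usable pixel is assigned to the half-open bin [e_k, e_{k+1})
    containing its |q| (computed from ``center``, defaulting to the
    geometry's beam center); the bin value is the MEAN of the counts, sigma
    the Poisson error of that mean: sqrt(sum counts) / n_pix.
    """
    geo = pattern.geometry
    if q_bins is None:
        q_bins = default_q_bins(geo)
    q_bins = np.asarray(q_bins, dtype=float)
    if np.any(np.diff(q_bins) <= 0):
        raise InvalidInputError("bin edges must be strictly increasing")
    if center is not None and not (0 <= center[0] < geo.n_fast
                                   and 0 <= center[1] < geo.n_slow):
        raise InvalidInputError("center outside detector")
    valid = pattern.valid
    if not valid.any():
        raise EmptyProfileError("all pixels masked")
    qmag = geo.pixel_q_magnitudes(center)[valid]
    counts = pattern.counts[valid].astype(float)
    idx = np.digitize(qmag, q_bins) - 1  # [e_k, e_{k+1}) half-open
    inside = (idx >= 0) & (idx < len(q_bins) - 1)
    idx, counts = idx[inside], counts[inside]
    n = len(q_bins) - 1
    n_pix = np.bincount(idx, minlength=n)
    tot = np.bincount(idx, weights=counts, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = np.where(n_pix > 0, tot / np.maximum(n_pix, 1), np.nan)
        sigma = np.where(n_pix > 0, np.sqrt(np.maximum(tot, 0.0)) / np.maximum(n_pix, 1), 0.0)
    centers = 0.5 * (q_bins[:-1] + q_bins[1:])
    return SAXSProfile(centers, I, sigma, n_patterns=1, n_pix=n_pix)


def _check_grids(profiles) -> np.ndarray:
    q0 = profiles[0].q
    for p in profiles[1:]:
        if len(p.q) != len(q0) or not np.allclose(p.q, q0, rtol=1e-10, atol=0.0):
            raise GridMismatchError("profiles are on different q grids")
    return q0


def accumulate(profiles) -> SAXSProfile:
    """Merge profiles into a cumulative virtual SAXS profile.

    Per bin the pooled photon total and pixel total are added across inputs
    and the cumulative intensity is ``n_patterns x pooled mean``, so N copies
    of one profile sum to N times that profile and the operation is
    associative. Uncertainties combine in quadrature with the same count
    weights. Bins empty in every input stay empty.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("nothing to accumulate")
    q0 = _check_grids(profiles)
    n = len(q0)
    tot_counts = np.zeros(n)
    tot_var = np.zeros(n)
    tot_pix = np.zeros(n, dtype=np.int64)
    n_patterns = 0
    for p in profiles:
        m = p.valid
        # per-profile pooled photon total per bin: I * n_pix / n_patterns
        tot_counts[m] += p.I[m] * p.n_pix[m] / p.n_patterns
        tot_var[m] += (p.sigma[m] * p.n_pix[m] / p.n_patterns) ** 2
        tot_pix += p.n_pix
        n_patterns += p.n_patterns
    with np.errstate(invalid="ignore", divide="ignore"):
        I = np.where(tot_pix > 0, n_patterns * tot_counts / np.maximum(tot_pix, 1), np.nan)
        sigma = np.where(tot_pix > 0,
                         n_patterns * np.sqrt(tot_var) / np.maximum(tot_pix, 1), 0.0)
    return SAXSProfile(q0, I, sigma, n_patterns=n_patterns, n_pix=tot_pix)


def pearson_correlation(a: SAXSProfile, b: SAXSProfile,
                        q_range: tuple[float, float] | None = None) -> float:
    """Pearson correlation of two profiles over their shared non-empty bins."""
    _check_grids([a, b])
    m = a.valid & b.valid & np.isfinite(a.I) & np.isfinite(b.I)
    if q_range is not None:
        m &= (a.q >= q_range[0]) & (a.q <= q_range[1])
    if m.sum() < 3:
        raise InsufficientDataError("need >= 3 shared non-empty bins")
    return float(stats.pearsonr(a.I[m], b.I[m]).statistic)


@dataclass
class ConvergenceTrace:
    """Pearson correlation of the cumulative profile vs a reference, as
    patterns are added one stride at a time."""

    n_included: np.ndarray
    r_p: np.ndarray

    def __post_init__(self) -> None:
        self.n_included = np.asarray(self.n_included)
        self.r_p = np.asarray(self.r_p, dtype=float)
        if np.any(np.diff(self.n_included) <= 0):
            raise InvalidInputError("n_included must be strictly increasing")


def convergence_trace(profiles, reference: SAXSProfile | None = None,
                      stride: int = 1,
                      q_range: tuple[float, float] | None = None) -> ConvergenceTrace:
    """Trace the convergence of the cumulative profile.

    ``reference`` defaults to the merge of the whole sequence, matching the
    practice of correlating against the final full-set SAXS profile.
    """
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")
    profiles = list(profiles)
    if reference is None:
        reference = accumulate(profiles)
    q0 = _check_grids([reference] + profiles)
    n = len(q0)
    tot_counts = np.zeros(n)
    tot_pix = np.zeros(n, dtype=np.int64)
    n_inc, r_p = [], []
    n_patterns = 0
    for i, p in enumerate(profiles):
        m = p.valid
        tot_counts[m] += p.I[m] * p.n_pix[m] / p.n_patterns
        tot_pix += p.n_pix
        n_patterns += p.n_patterns
        if (i + 1) % stride == 0 or i == len(profiles) - 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                I = np.where(tot_pix > 0,
                             n_patterns * tot_counts / np.maximum(tot_pix, 1), np.nan)
            cum = SAXSProfile(q0, I, np.zeros(n), n_patterns=n_patterns,
                              n_pix=tot_pix.copy())
            n_inc.append(i + 1)
            r_p.append(pearson_correlation(cum, reference, q_range))
    return ConvergenceTrace(np.asarray(n_inc), np.asarray(r_p))


def split_half_consistency(profiles, seed: int | np.random.Generator = 0,
                           q_range: tuple[float, float] | None = None):
    """Randomly split the profiles into halves, merge each, and correlate.

    Returns ``(profile_A, profile_B, r_p)``. For an odd count the halves
    differ in size by one. The partition is reproducible from ``seed``.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise InvalidInputError("need at least 2 profiles to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(profiles))
    half = len(profiles) // 2
    a = accumulate([profiles[i] for i in order[:half]])
    b = accumulate([profiles[i] for i in order[half:]])
    return a, b, pearson_correlation(a, b, q_range)


# ---------------------------------------------------------------------------
# 3-column ASCII profile I/O
# ---------------------------------------------------------------------------

def write_dat(profile: SAXSProfile, path, header: str = "") -> None:
    """Write q / I / sigma as whitespace-separated ASCII with '#' headers;
    empty bins are omitted."""
    m = profile.valid & np.isfinite(profile.I)
    with open(path, "w") as f:
        if header:
            for line in header.splitlines():
                f.write(f"# {line}\n")
        f.write("# q[nm^-1]  I[arb]  sigma\n")
        for q, i, s in zip(profile.q[m], profile.I[m], profile.sigma[m]):
            f.write(f"{q:.8e} {i:.8e} {s:.8e}\n")


def read_dat(path) -> SAXSProfile:
    """Read a 3-column (or 2-column, sigma absent) ASCII profile."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise InvalidInputError("profile file needs at least 2 columns (q, I)")
    q, I = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else np.zeros_like(q)
    return SAXSProfile(q, I, sigma, n_patterns=1, n_pix=np.ones(len(q), dtype=int))
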