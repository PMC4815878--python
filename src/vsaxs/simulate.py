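"""Synthetic single-particle scattering data.

Generates 2D detector patterns with the statistical structure the downstream
pipeline assumes: a monodisperse particle (one bead model) at uniform random
orientations on SO(3), intensities sampled on the Ewald sphere, Poisson photon
noise, per-shot beam-center jitter, and an optional admixture of false-positive
patterns produced from a different (non-sample) model.

Units: lengths attached to the particle and to momentum transfer are in nm
(q in nm^-1); detector distances and pixel pitch are in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np

from .errors import InvalidInputError

#: sentinel stored in masked pixels of a pattern's count array
MASKED = -1


def sphere_form_amplitude(q, radius: float):
    """Normalized scattering amplitude of a uniform sphere,
    3 (sin x - x cos x) / x^3 with x = q * radius; equal to 1 at q = 0."""
    x = np.asarray(q, dtype=float) * radius
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    xs = x[nz]
    out[nz] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BeadModel:
    """A 3D shape as a set of identical spheres ("beads").

    Parameters
    ----------
    centers : (n, 3) array, nm
        Bead center coordinates. The centroid may be anywhere; operations
        that need a centered model recenter explicitly.
    bead_radius : float, nm
        Common radius of all beads.
    weights : (n,) array, optional
        Scattering weight per bead (default 1 each).
    label : str
        Identifier used in databases and rankings.
    """

    centers: np.ndarray
    bead_radius: float
    weights: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.ndim != 2 or self.centers.shape[1] != 3 or len(self.centers) == 0:
            raise InvalidInputError("centers must be a non-empty (n, 3) array")
        if not self.bead_radius > 0:
            raise InvalidInputError("bead_radius must be positive")
        if self.weights is None:
            self.weights = np.ones(len(self.centers))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.centers),):
                raise InvalidInputError("weights must have one entry per bead")
            if np.any(self.weights <= 0):
                raise InvalidInputError("weights must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.centers)

    @property
    def centroid(self) -> np.ndarray:
        w = self.weights
        return (w[:, None] * self.centers).sum(axis=0) / w.sum()

    def recentered(self) -> "BeadModel":
        """Copy with the weighted centroid moved to the origin."""
        return replace(self, centers=self.centers - self.centroid)

    def rescaled(self, factor: float) -> "BeadModel":
        """Uniformly rescale coordinates and bead radius by ``factor``."""
        if not factor > 0:
            raise InvalidInputError("scale factor must be positive")
        return replace(self, centers=self.centers * factor,
                       bead_radius=self.bead_radius * factor)


@dataclass
class DetectorGeometry:
    """Flat area detector downstream of the interaction point.

    ``beam_center`` is ``(cx, cy)`` in fractional pixel units, ``cx`` along
    the fast axis (columns) and ``cy`` along the slow axis (rows); pixel
    centers sit at integer coordinates, 0-based.
    """

    wavelength_nm: float
    distance_mm: float
    pixel_mm: float
    n_fast: int
    n_slow: int
    beam_center: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None  # True = usable

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "distance_mm", "pixel_mm"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")
        cx, cy = self.beam_center
        if not (0 <= cx < self.n_fast and 0 <= cy < self.n_slow):
            raise InvalidInputError("beam center must lie on the detector")
        if self.mask is None:
            self.mask = np.ones((self.n_slow, self.n_fast), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_slow, self.n_fast):
                raise InvalidInputError("mask shape must be (n_slow, n_fast)")

    @property
    def k(self) -> float:
        """Wavenumber 2*pi/lambda in nm^-1 (derived, never stored)."""
        return 2.0 * np.pi / self.wavelength_nm

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_slow, self.n_fast)

    # -- per-pixel geometry --------------------------------------------------

    def pixel_radii_mm(self, center: tuple[float, float] | None = None) -> np.ndarray:
        """In-plane distance of each pixel center from the beam center (mm)."""
        cx, cy = self.beam_center if center is None else center
        jj, ii = np.meshgrid(np.arange(self.n_fast), np.arange(self.n_slow))
        return self.pixel_mm * np.hypot(jj - cx, ii - cy)

    def scattering_angles(self, center: tuple[float, float] | None = None) -> np.ndarray:
        """Full scattering angle alpha = atan(r/D) per pixel (rad)."""
        return np.arctan2(self.pixel_radii_mm(center), self.distance_mm)

    def pixel_q_vectors(self, center: tuple[float, float] | None = None) -> np.ndarray:
        """Momentum transfer q = k (s_hat - z_hat) per pixel, shape (n_slow, n_fast, 3), nm^-1.

        s_hat points from the sample to the pixel center; the z axis is the
        incident beam. The out-of-plane component k (cos(alpha) - 1) carries
        the Ewald-sphere curvature.
        """
        cx, cy = self.beam_center if center is None else center
        jj, ii = np.meshgrid(np.arange(self.n_fast), np.arange(self.n_slow))
        x = (jj - cx) * self.pixel_mm
        y = (ii - cy) * self.pixel_mm
        z = np.full_like(x, self.distance_mm, dtype=float)
        norm = np.sqrt(x * x + y * y + z * z)
        q = np.empty((self.n_slow, self.n_fast, 3))
        q[..., 0] = self.k * x / norm
        q[..., 1] = self.k * y / norm
        q[..., 2] = self.k * (z / norm - 1.0)
        return q

    def pixel_q_magnitudes(self, center: tuple[float, float] | None = None) -> np.ndarray:
        """|q| = 2 k sin(alpha/2) per pixel (nm^-1)."""
        return 2.0 * self.k * np.sin(0.5 * self.scattering_angles(center))


def pixel_q_vector(geometry: DetectorGeometry, pixel: tuple[int, int]) -> np.ndarray:
    """q vector (nm^-1) of one pixel ``(i, j)`` = (slow, fast) index."""
    i, j = pixel
    if not (0 <= i < geometry.n_slow and 0 <= j < geometry.n_fast):
        raise InvalidInputError("pixel outside detector bounds")
    cx, cy = geometry.beam_center
    x = (j - cx) * geometry.pixel_mm
    y = (i - cy) * geometry.pixel_mm
    z = geometry.distance_mm
    norm = np.sqrt(x * x + y * y + z * z)
    k = geometry.k
    return np.array([k * x / norm, k * y / norm, k * (z / norm - 1.0)])


@dataclass
class ScatteringPattern:
    """One detector frame of photon counts.

    ``counts`` has shape ``(n_slow, n_fast)``; masked pixels hold the sentinel
    :data:`MASKED` and are excluded from every statistic. For noiseless
    (pre-Poisson) patterns the array is float-valued.
    """

    counts: np.ndarray
    geometry: DetectorGeometry
    true_orientation: np.ndarray | None = None
    is_false_positive: bool = False
    center_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.geometry.shape:
            raise InvalidInputError("counts shape must equal (n_slow, n_fast)")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of usable pixels (geometry mask AND not sentinel)."""
        return self.geometry.mask & (self.counts != MASKED)


# ---------------------------------------------------------------------------
# shape construction
# ---------------------------------------------------------------------------

def _lattice(extent: np.ndarray, spacing: float) -> np.ndarray:
    """Cubic lattice (origin on a node) covering [-extent, extent] per axis."""
    axes = []
    for e in extent:
        n = int(np.floor(e / spacing + 1e-9))
        axes.append(np.arange(-n, n + 1) * spacing)
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def _volume_match(pts: np.ndarray, spacing: float, v_target: float) -> float:
    """Scale factor making the lattice-enclosed volume (n * spacing^3) equal
    the analytic solid volume.

    The leading-order error of a lattice fill is a small bias of the
    effective size (fraction of a spacing); matching volumes removes it, so
    profile minima land where the continuum solid puts them.
    """
    v_lattice = len(pts) * spacing**3
    return float((v_target / v_lattice) ** (1.0 / 3.0))


def make_shape(kind: str, *, radius: float | None = None,
               semi_axes: tuple[float, float] | None = None,
               separation: float | None = None,
               edge: float | None = None,
               spacing: float = 1.0,
               path: str | None = None,
               label: str | None = None) -> BeadModel:
    """Build a bead model of a canonical solid filled on a cubic lattice.

    Kinds: ``sphere`` (radius), ``prolate`` (semi_axes (a, b) -> ellipsoid
    with semi-axes a, b, b, a >= b), ``dumbbell`` (two spheres of ``radius``
    with center separation ``separation``), ``cube`` (edge length), and
    ``beads_from_file`` (PDB path, via :func:`vsaxs.models.read_bead_pdb`).

    ``spacing`` is the lattice constant in nm; bead radius is spacing / 2.
    The returned model is recentered to its centroid.
    """
    if not spacing > 0:
        raise InvalidInputError("spacing must be positive")
    r_bead = spacing / 2.0

    if kind == "sphere":
        if radius is None or radius <= 0:
            raise InvalidInputError("sphere needs a positive radius")
        pts = _lattice(np.array([radius] * 3), spacing)
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= radius**2 + 1e-12]
        v_target = 4.0 / 3.0 * np.pi * radius**3
        default_label = f"sphere_R{radius:g}"
    elif kind == "prolate":
        if semi_axes is None:
            raise InvalidInputError("prolate needs semi_axes (a, b)")
        a, b = semi_axes
        if not (a > 0 and b > 0):
            raise InvalidInputError("semi-axes must be positive")
        if a < b:
            raise InvalidInputError("prolate requires a >= b")
        pts = _lattice(np.array([a, b, b]), spacing)
        s = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / b) ** 2
        pts = pts[s <= 1.0 + 1e-12]
        v_target = 4.0 / 3.0 * np.pi * a * b * b
        default_label = f"prolate_a{a:g}_b{b:g}"
    elif kind == "dumbbell":
        if radius is None or radius <= 0 or separation is None or separation < 0:
            raise InvalidInputError("dumbbell needs positive radius and separation >= 0")
        if separation > 20 * radius:
            warnings.warn("dumbbell lobes separated by more than 20 bead-sphere radii",
                          stacklevel=2)
        half = separation / 2.0
        pts = _lattice(np.array([half + radius, radius, radius]), spacing)
        d1 = (pts[:, 0] - half) ** 2 + pts[:, 1] ** 2 + pts[:, 2] ** 2
        d2 = (pts[:, 0] + half) ** 2 + pts[:, 1] ** 2 + pts[:, 2] ** 2
        pts = pts[(d1 <= radius**2 + 1e-12) | (d2 <= radius**2 + 1e-12)]
        v_target = 2.0 * 4.0 / 3.0 * np.pi * radius**3
        if separation < 2 * radius:  # subtract the lens-shaped overlap
            d = separation
            v_target -= np.pi * (4 * radius + d) * (2 * radius - d) ** 2 / 12.0
        default_label = f"dumbbell_R{radius:g}_d{separation:g}"
    elif kind == "cube":
        if edge is None or edge <= 0:
            raise InvalidInputError("cube needs a positive edge")
        h = edge / 2.0
        pts = _lattice(np.array([h] * 3), spacing)
        pts = pts[np.all(np.abs(pts) <= h + 1e-12, axis=1)]
        v_target = edge**3
        default_label = f"cube_L{edge:g}"
    elif kind == "beads_from_file":
        if path is None:
            raise InvalidInputError("beads_from_file needs a path")
        from .models import read_bead_pdb
        model = read_bead_pdb(path)
        if label is not None:
            model = replace(model, label=label)
        return model.recentered()
    else:
        raise InvalidInputError(f"unknown shape kind {kind!r}")

    if len(pts) == 0:
        raise InvalidInputError("shape too small for the requested lattice spacing")
    f = _volume_match(pts, spacing, v_target)
    model = BeadModel(pts * f, bead_radius=r_bead * f,
                      label=label if label is not None else default_label)
    return model.recentered()


# ---------------------------------------------------------------------------
# orientations
# ---------------------------------------------------------------------------

def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """One unit quaternion (w, x, y, z) uniform on SO(3).

    Uses the 3-uniform-variate construction: with u1, u2, u3 ~ U(0, 1),
    q = (sqrt(1-u1) sin 2πu2, sqrt(1-u1) cos 2πu2,
         sqrt(u1) sin 2πu3, sqrt(u1) cos 2πu3).
    """
    return random_orientations(rng, 1)[0]


def random_orientations(rng: np.random.Generator, n: int) -> np.ndarray:
    u1, u2, u3 = rng.random((3, n))
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    t2, t3 = 2.0 * np.pi * u2, 2.0 * np.pi * u3
    return np.stack([a * np.sin(t2), a * np.cos(t2),
                     b * np.sin(t3), b * np.cos(t3)], axis=1)


def uniform_orientation_set(n: int) -> np.ndarray:
    """n quasi-uniform rotations (unit quaternions, deterministic).

    Rotation axes follow a golden-spiral (Fibonacci) covering of the sphere
    of view directions while the in-plane angle advances by the golden
    angle, giving low-discrepancy coverage of SO(3). Useful where uniform
    orientation coverage matters more than randomness, e.g. checking that
    summed intensity profiles converge to the spherical average.
    """
    if n < 1:
        raise InvalidInputError("need n >= 1")
    # Halton points in the unit cube fed through the 3-variate quaternion
    # construction; mutually independent bases avoid the correlated-angle
    # bias a shared irrational increment would introduce.
    u1 = _halton(n, 2)
    u2 = _halton(n, 3)
    u3 = _halton(n, 5)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    t2, t3 = 2.0 * np.pi * u2, 2.0 * np.pi * u3
    return np.stack([a * np.sin(t2), a * np.cos(t2),
                     b * np.sin(t3), b * np.cos(t3)], axis=1)


def _halton(n: int, base: int) -> np.ndarray:
    out = np.zeros(n)
    i = np.arange(1, n + 1)
    f = 1.0
    while i.any():
        f /= base
        out += f * (i % base)
        i //= base
    return out


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = np.asarray(q, dtype=float)
    n = w * w + x * x + y * y + z * z
    if abs(n - 1.0) > 1e-8:
        raise InvalidInputError("quaternion must be unit-norm")
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# pattern simulation
# ---------------------------------------------------------------------------

def _coherent_intensity(model: BeadModel, qvecs: np.ndarray) -> np.ndarray:
    """|sum_j w_j exp(i q.x_j)|^2 / (sum w)^2 for each row of qvecs (n, 3)."""
    w = model.weights
    out = np.empty(len(qvecs))
    # chunk over pixels to bound the (pixels x beads) phase matrix
    step = max(1, int(4e6) // max(model.n_beads, 1))
    w32 = w.astype(np.float32)
    for lo in range(0, len(qvecs), step):
        phases = (qvecs[lo:lo + step] @ model.centers.T).astype(np.float32)
        re = np.cos(phases) @ w32   # float32 trig: phase quantization ~1e-6 rad
        im = np.sin(phases) @ w32
        out[lo:lo + step] = (re.astype(float))**2 + (im.astype(float))**2
    return out / w.sum() ** 2


# cache of per-geometry pixel q-vector arrays (flattened), keyed on the
# geometry values and the effective beam center
_QVEC_CACHE: dict = {}


def _qvecs_flat(geometry: DetectorGeometry,
                center: tuple[float, float] | None) -> np.ndarray:
    c = tuple(geometry.beam_center) if center is None else (float(center[0]),
                                                            float(center[1]))
    key = (geometry.wavelength_nm, geometry.distance_mm, geometry.pixel_mm,
           geometry.n_fast, geometry.n_slow, c)
    if key not in _QVEC_CACHE:
        if len(_QVEC_CACHE) > 16:
            _QVEC_CACHE.clear()
        _QVEC_CACHE[key] = geometry.pixel_q_vectors(c).reshape(-1, 3)
    return _QVEC_CACHE[key]


def simulate_pattern(model: BeadModel, geometry: DetectorGeometry,
                     orientation: np.ndarray, fluence_scale: float,
                     rng: np.random.Generator | None = None,
                     poisson: bool = True,
                     center: tuple[float, float] | None = None) -> ScatteringPattern:
    """Simulate one detector frame of a particle at a fixed orientation.

    The expected intensity at a pixel with momentum transfer q is
    ``fluence_scale * Phi_b(|q|)^2 |sum_j w_j exp(i q . R x_j)|^2 / (sum_j w_j)^2``
    with Phi_b the uniform-sphere amplitude of one bead (the same form factor
    the Debye profile of the model carries, so orientation-averaged patterns
    converge to it). The forward-scattering expectation is exactly
    ``fluence_scale``; counts are Poisson-sampled unless ``poisson=False``.
    """
    if model.n_beads == 0:
        raise InvalidInputError("empty model")
    if fluence_scale < 0:
        raise InvalidInputError("fluence_scale must be >= 0")
    R = quaternion_to_matrix(orientation)
    rotated = BeadModel(model.centers @ R.T, model.bead_radius,
                        model.weights.copy(), model.label)
    q = _qvecs_flat(geometry, center)
    qmag = np.sqrt(np.einsum("ij,ij->i", q, q))
    intensity = (fluence_scale * sphere_form_amplitude(qmag, model.bead_radius) ** 2
                 * _coherent_intensity(rotated, q))
    intensity = intensity.reshape(geometry.shape)
    if poisson:
        if rng is None:
            raise InvalidInputError("Poisson sampling needs an rng")
        counts = rng.poisson(intensity).astype(np.int64)
    else:
        counts = intensity
    counts = np.where(geometry.mask, counts, MASKED)
    off = (0.0, 0.0)
    if center is not None:
        off = (center[0] - geometry.beam_center[0], center[1] - geometry.beam_center[1])
    return ScatteringPattern(counts, geometry, true_orientation=np.asarray(orientation),
                             center_offset=off)


@dataclass
class DatasetManifest:
    """Per-pattern ground truth recorded by :func:`simulate_dataset`."""

    orientations: np.ndarray          # (n, 4)
    false_positive: np.ndarray        # (n,) bool
    center_offset: np.ndarray         # (n, 2) px, (dx, dy)
    seed: int | None = None


def simulate_dataset(model: BeadModel, geometry: DetectorGeometry,
                     n_patterns: int, fluence_scale: float,
                     center_jitter_px: float = 0.0,
                     false_positive_rate: float = 0.0,
                     false_positive_model: BeadModel | None = None,
                     false_positive_fluence: float | None = None,
                     seed: int | np.random.Generator = 0,
                     poisson: bool = True) -> tuple[list[ScatteringPattern], DatasetManifest]:
    """Simulate a stack of patterns with fresh uniform orientations.

    With probability ``false_positive_rate`` a pattern is generated from
    ``false_positive_model`` (emulating non-sample scattering) and flagged in
    the manifest. The beam center of each shot is offset uniformly within
    ``±center_jitter_px`` on both axes and the offset is recorded.
    """
    if n_patterns <= 0:
        raise InvalidInputError("n_patterns must be positive")
    if not (0 <= false_positive_rate < 1):
        raise InvalidInputError("false_positive_rate must be in [0, 1)")
    if false_positive_rate > 0 and false_positive_model is None:
        raise InvalidInputError("false_positive_rate > 0 needs a false_positive_model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    patterns: list[ScatteringPattern] = []
    quats = np.empty((n_patterns, 4))
    flags = np.zeros(n_patterns, dtype=bool)
    offsets = np.zeros((n_patterns, 2))
    cx0, cy0 = geometry.beam_center
    for i in range(n_patterns):
        quat = random_orientation(rng)
        is_fp = rng.random() < false_positive_rate
        off = rng.uniform(-center_jitter_px, center_jitter_px, size=2) \
            if center_jitter_px > 0 else np.zeros(2)
        src = false_positive_model if is_fp else model
        flu = fluence_scale
        if is_fp and false_positive_fluence is not None:
            flu = false_positive_fluence
        pat = simulate_pattern(src, geometry, quat, flu, rng=rng, poisson=poisson,
                               center=(cx0 + off[0], cy0 + off[1]))
        pat.is_false_positive = is_fp
        patterns.append(pat)
        quats[i], flags[i], offsets[i] = quat, is_fp, off
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return patterns, DatasetManifest(quats, flags, offsets, seed=seed_val)


# ---------------------------------------------------------------------------
# HDF5 pattern-stack I/O
# ---------------------------------------------------------------------------

def save_patterns(path, patterns: list[ScatteringPattern],
                  manifest: DatasetManifest | None = None) -> None:
    """Write a pattern stack to HDF5.

    Layout: ``/patterns/counts`` (uint32, N x ny x nx; masked pixels stored
    as 0 — the mask dataset is authoritative), ``/patterns/mask``,
    ``/geometry/{wavelength_nm,distance_mm,pixel_mm,center_xy}`` and an
    optional ``/truth`` group with the simulation ground truth.
    """
    if not patterns:
        raise InvalidInputError("no patterns to save")
    geo = patterns[0].geometry
    stack = np.stack([np.maximum(np.rint(p.counts).astype(np.int64), 0)
                      for p in patterns]).astype(np.uint32)
    with h5py.File(path, "w") as f:
        g = f.create_group("patterns")
        g.create_dataset("counts", data=stack, compression="gzip")
        g.create_dataset("mask", data=geo.mask.astype(np.uint8), compression="gzip")
        gg = f.create_group("geometry")
        gg.create_dataset("wavelength_nm", data=geo.wavelength_nm)
        gg.create_dataset("distance_mm", data=geo.distance_mm)
        gg.create_dataset("pixel_mm", data=geo.pixel_mm)
        gg.create_dataset("center_xy", data=np.asarray(geo.beam_center, dtype=float))
        if manifest is not None:
            t = f.create_group("truth")
            t.create_dataset("orientations", data=manifest.orientations)
            t.create_dataset("false_positive", data=manifest.false_positive.astype(np.uint8))
            t.create_dataset("center_offset", data=manifest.center_offset)
            if manifest.seed is not None:
                t.attrs["seed"] = int(manifest.seed)


def load_patterns(path) -> tuple[list[ScatteringPattern], DatasetManifest | None]:
    """Read a pattern stack written by :func:`save_patterns`."""
    with h5py.File(path, "r") as f:
        stack = f["patterns/counts"][...].astype(np.int64)
        mask = f["patterns/mask"][...].astype(bool)
        geo = DetectorGeometry(
            wavelength_nm=float(f["geometry/wavelength_nm"][()]),
            distance_mm=float(f["geometry/distance_mm"][()]),
            pixel_mm=float(f["geometry/pixel_mm"][()]),
            n_fast=stack.shape[2], n_slow=stack.shape[1],
            beam_center=tuple(f["geometry/center_xy"][...]),
            mask=mask,
        )
        manifest = None
        if "truth" in f:
            t = f["truth"]
            manifest = DatasetManifest(
                orientations=t["orientations"][...],
                false_positive=t["false_positive"][...].astype(bool),
                center_offset=t["center_offset"][...],
                seed=int(t.attrs["seed"]) if "seed" in t.attrs else None,
            )
    patterns = []
    for i in range(stack.shape[0]):
        counts = np.where(mask, stack[i], MASKED)
        pat = ScatteringPattern(counts, geo)
        if manifest is not None:
            pat.true_orientation = manifest.orientations[i]
            pat.is_false_positive = bool(manifest.false_positive[i])
            pat.center_offset = tuple(manifest.center_offset[i])
        patterns.append(pat)
    return patterns, manifest
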