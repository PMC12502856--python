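"""Experimental geometry: goniometer rotations, scan axes and probed directions.

The experiment is described in a sample-fixed voxel coordinate system that
coincides with the laboratory frame when all goniometer angles are zero.  A
two-circle goniometer (an inner "rotation" stage carried by an outer "tilt"
stage) orients the sample; the beam direction, the two raster-scan axes and
the two vectors spanning the detector azimuth are all given as unit vectors
in the laboratory frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Geometry",
    "DetectorSegments",
    "rotation_matrix",
    "probed_direction",
]

_UNIT_TOL = 1e-9


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be unit-norm (|{name}| = {norm:.12g})")
    return v


@dataclass
class Geometry:
    """Vectors, angles and offsets defining a tensor-tomography acquisition.

    Parameters
    ----------
    p_direction
        Beam (projection) direction in the laboratory frame at zero angles.
    j_direction, k_direction
        Orthogonal raster-scan axes (rows ``j`` and columns ``k`` of each
        projection image).
    detector_direction_origin, detector_direction_positive_90
        Unit vectors spanning the detector plane; the azimuth ``phi`` is
        measured from the first towards the second.
    inner_axis, outer_axis
        Rotation axes of the inner (rotation) and outer (tilt) goniometer
        stages.
    inner_angles, outer_angles
        Per-projection goniometer angles ``alpha_s`` and ``beta_s`` in
        radians; both arrays have length ``S``.
    j_offsets, k_offsets
        Per-projection alignment offsets ``dj_s``, ``dk_s`` in units of the
        scan step (sub-pixel values allowed).
    volume_shape
        Number of voxels along x, y, z.
    projection_shape
        Raster-scan dimensions ``(J, K)``.
    voxel_size, scan_step
        Edge length ``a`` of the cubic voxel grid and step ``b`` of the
        raster scan.  Typically the reconstruction is matched to the scan so
        that ``a == b`` (the default, both 1).
    """

    p_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    j_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    k_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    detector_direction_origin: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    detector_direction_positive_90: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    inner_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    outer_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    inner_angles: np.ndarray = field(default_factory=lambda: np.zeros(1))
    outer_angles: np.ndarray = field(default_factory=lambda: np.zeros(1))
    j_offsets: np.ndarray | None = None
    k_offsets: np.ndarray | None = None
    volume_shape: tuple[int, int, int] = (1, 1, 1)
    projection_shape: tuple[int, int] = (1, 1)
    voxel_size: float = 1.0
    scan_step: float = 1.0

    def __post_init__(self):
        for name in ("p_direction", "j_direction", "k_direction",
                     "detector_direction_origin", "detector_direction_positive_90",
                     "inner_axis", "outer_axis"):
            setattr(self, name, _as_unit(getattr(self, name), name))
        if abs(np.dot(self.detector_direction_origin,
                      self.detector_direction_positive_90)) > _UNIT_TOL:
            raise ValueError("detector azimuth vectors must be orthogonal")
        if abs(np.dot(self.j_direction, self.k_direction)) > _UNIT_TOL:
            raise ValueError("j_direction and k_direction must be orthogonal")
        self.inner_angles = np.atleast_1d(np.asarray(self.inner_angles, dtype=float))
        self.outer_angles = np.atleast_1d(np.asarray(self.outer_angles, dtype=float))
        S = len(self.inner_angles)
        if self.j_offsets is None:
            self.j_offsets = np.zeros(S)
        if self.k_offsets is None:
            self.k_offsets = np.zeros(S)
        self.j_offsets = np.atleast_1d(np.asarray(self.j_offsets, dtype=float))
        self.k_offsets = np.atleast_1d(np.asarray(self.k_offsets, dtype=float))
        for name in ("outer_angles", "j_offsets", "k_offsets"):
            if len(getattr(self, name)) != S:
                raise ValueError(
                    f"{name} has length {len(getattr(self, name))}, expected {S}")
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        self.projection_shape = tuple(int(n) for n in self.projection_shape)
        if any(n < 1 for n in self.volume_shape) or any(
                n < 1 for n in self.projection_shape):
            raise ValueError("volume_shape and projection_shape must be positive")

    @property
    def n_projections(self) -> int:
        return len(self.inner_angles)


@dataclass
class DetectorSegments:
    """Azimuthal segmentation of the detector at a fixed scattering angle.

    ``boundaries`` holds the ``C + 1`` strictly increasing azimuth angles
    (radians) delimiting the ``C`` segments.  ``coverage`` declares whether
    the segments span the full circle (WAXS) or a half circle (SAXS, relying
    on Friedel symmetry of the scattering).  ``two_theta`` is the scattering
    angle of the q shell; 0 selects the small-angle limit in which the
    scattering vector lies in the detector plane.
    """

    boundaries: np.ndarray
    coverage: str = "half"
    two_theta: float = 0.0

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.ndim != 1 or len(self.boundaries) < 2:
            raise ValueError("need at least 2 segment boundaries")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("segment boundaries must be strictly increasing")
        if self.coverage not in ("full", "half"):
            raise ValueError(f"unknown coverage {self.coverage!r}")
        span = self.boundaries[-1] - self.boundaries[0]
        expected = 2 * np.pi if self.coverage == "full" else np.pi
        if abs(span - expected) > _UNIT_TOL:
            raise ValueError(
                f"boundaries span {span:.9g} rad but coverage={self.coverage!r} "
                f"requires {expected:.9g}")
        if not (0.0 <= self.two_theta < np.pi):
            raise ValueError("two_theta must lie in [0, pi)")

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    @classmethod
    def evenly_spaced(cls, n_segments: int, coverage: str = "half",
                      two_theta: float = 0.0, start: float = 0.0
                      ) -> "DetectorSegments":
        span = 2 * np.pi if coverage == "full" else np.pi
        return cls(start + np.linspace(0.0, span, n_segments + 1),
                   coverage=coverage, two_theta=two_theta)

    @classmethod
    def from_centers(cls, centers, coverage: str = "half",
                     two_theta: float = 0.0) -> "DetectorSegments":
        """Reconstruct boundaries from evenly spaced segment-center angles."""
        centers = np.asarray(centers, dtype=float)
        if len(centers) < 1:
            raise ValueError("need at least one segment center")
        if len(centers) == 1:
            width = 2 * np.pi if coverage == "full" else np.pi
        else:
            steps = np.diff(centers)
            if not np.allclose(steps, steps[0], atol=1e-9):
                raise ValueError("segment centers must be evenly spaced")
            width = steps[0]
        bounds = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        return cls(bounds, coverage=coverage, two_theta=two_theta)


def rotation_matrix(geometry: Geometry, s: int) -> np.ndarray:
    """Full goniometer rotation ``R_s`` for projection ``s``.

    The outer (tilt) stage physically carries the inner (rotation) stage, so
    the composed rotation is the tilt applied after the inner rotation:
    ``R_s = R(beta_s, outer_axis) @ R(alpha_s, inner_axis)``.
    """
    S = geometry.n_projections
    if not 0 <= s < S:
        raise IndexError(f"projection index {s} out of range [0, {S})")
    r_inner = Rotation.from_rotvec(geometry.inner_angles[s] * geometry.inner_axis)
    r_outer = Rotation.from_rotvec(geometry.outer_angles[s] * geometry.outer_axis)
    return (r_outer * r_inner).as_matrix()


def probed_direction(geometry: Geometry, segments: DetectorSegments,
                     s: int, phi, tilt_sign: float = -1.0) -> np.ndarray:
    """Unit scattering direction probed at azimuth ``phi``, in sample frame.

    In the laboratory frame the normalized scattering vector at detector
    azimuth ``phi`` and scattering angle ``2 theta`` is

        q_lab(phi) = cos(theta) (cos(phi) q0 + sin(phi) q90) - sin(theta) p

    i.e. it tilts against the beam; for ``two_theta == 0`` (small-angle
    limit) it lies in the detector plane.  The sample-frame direction probed
    at goniometer setting ``s`` is ``R_s^T q_lab(phi)``.

    ``tilt_sign`` flips the out-of-plane term (``+1`` tilts the scattering
    vector along the beam instead), accommodating beamlines with the
    opposite detector-normal convention.  ``phi`` may be a scalar or an
    array; the result has shape ``phi.shape + (3,)``.
    """
    if tilt_sign not in (-1.0, 1.0):
        raise ValueError("tilt_sign must be -1 or +1")
    phi = np.asarray(phi, dtype=float)
    if segments.coverage != "full":
        # full-circle coverage is 2 pi periodic, any azimuth is meaningful
        lo, hi = segments.boundaries[0], segments.boundaries[-1]
        if np.any(phi < lo - _UNIT_TOL) or np.any(phi > hi + _UNIT_TOL):
            raise ValueError(
                f"azimuth outside declared coverage [{lo:.6g}, {hi:.6g}]")
    theta = 0.5 * segments.two_theta
    q_lab = (np.cos(theta) * (np.cos(phi)[..., None] * geometry.detector_direction_origin
                              + np.sin(phi)[..., None] * geometry.detector_direction_positive_90)
             + tilt_sign * np.sin(theta) * geometry.p_direction)
    R = rotation_matrix(geometry, s)
    return q_lab @ R  # (R.T @ q_lab.T).T
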