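"""HDF5 input/output for projection stacks and reconstruction results.

A projection-stack file stores, per q bin, the azimuthally regrouped
intensities of every projection together with the transmission (diode)
images, per-measurement weights, goniometer angles, alignment offsets and
the geometry vectors.  Layout::

    p_direction_0                   float(3)
    j_direction_0                   float(3)
    k_direction_0                   float(3)
    detector_direction_origin       float(3)
    detector_direction_positive_90  float(3)
    inner_axis                      float(3)
    outer_axis                      float(3)
    volume_shape                    int(3)
    detector_angles                 float(C + 1)   [segment boundaries, rad]
    projections/                    group
        0/                          group
            data                    float(J, K, C)
            diode                   float(J, K)
            inner_angle             float
            j_offset                float
            k_offset                float
            outer_angle             float
            weights                 float(J, K, C)
        1/ ...

``detector_angles`` holds the C + 1 segment-boundary azimuths in radians;
a loader option accepts C evenly spaced segment-center angles instead, and
``degrees=True`` converts angle fields on the way in.  Optional per-
projection fields (``weights``, ``diode``) default to ones.  All floats are
written as 64-bit; 32-bit files are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
import json

import h5py
import numpy as np

from .geometry import Geometry, DetectorSegments
from .basis_sets import basis_from_descriptor

__all__ = [
    "ProjectionStack",
    "ReconstructionOutput",
    "load_projection_stack",
    "save_projection_stack",
    "normalize_by_transmission",
    "save_reconstruction",
    "load_reconstruction",
]

_GEOMETRY_VECTOR_FIELDS = {
    "p_direction_0": "p_direction",
    "j_direction_0": "j_direction",
    "k_direction_0": "k_direction",
    "detector_direction_origin": "detector_direction_origin",
    "detector_direction_positive_90": "detector_direction_positive_90",
    "inner_axis": "inner_axis",
    "outer_axis": "outer_axis",
}


@dataclass
class ProjectionStack:
    """Measured data of one q bin: intensities, transmission and weights.

    ``data`` and ``weights`` have shape ``(S, J, K, C)`` and ``diode``
    ``(S, J, K)``.  A weight of 0 fully excludes a measurement.
    """

    data: np.ndarray
    diode: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must have shape (S, J, K, C)")
        if np.any(self.data < 0):
            raise ValueError("data must be nonnegative")
        if self.diode is None:
            self.diode = np.ones(self.data.shape[:3])
        if self.weights is None:
            self.weights = np.ones_like(self.data)
        self.diode = np.asarray(self.diode, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.diode.shape != self.data.shape[:3]:
            raise ValueError("diode shape must be (S, J, K)")
        if self.weights.shape != self.data.shape:
            raise ValueError("weights must have data's shape")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_projections(self) -> int:
        return self.data.shape[0]


@dataclass
class ReconstructionOutput:
    """A reconstructed coefficient field plus its basis and provenance."""

    coefficients: np.ndarray
    basis_descriptor: dict
    derived: "object | None" = None  # quantities.DerivedMaps
    provenance: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4:
            raise ValueError("coefficients must have shape (X, Y, Z, N)")
        n = basis_from_descriptor(self.basis_descriptor).n_coefficients
        if self.coefficients.shape[-1] != n:
            raise ValueError(
                f"coefficient count {self.coefficients.shape[-1]} does not "
                f"match basis ({n} functions)")


class FormatError(RuntimeError):
    """Raised when a projection-stack file violates the expected layout."""


def load_projection_stack(path, detector_angles_kind: str = "boundaries",
                          degrees: bool = False,
                          detector_coverage: str | None = None,
                          geometry_overrides: dict | None = None):
    """Load a projection-stack HDF5 file.

    Returns ``(stack, geometry, segments)``.  Geometry vectors missing from
    the file fall back to the standard-geometry defaults of
    :class:`~tensortomo.geometry.Geometry` and can be overridden through
    ``geometry_overrides``.  ``detector_angles_kind`` selects whether the
    ``detector_angles`` dataset holds ``C + 1`` segment boundaries or ``C``
    evenly spaced segment centers.
    """
    if detector_angles_kind not in ("boundaries", "centers"):
        raise ValueError(f"unknown detector_angles_kind {detector_angles_kind!r}")
    conv = np.pi / 180 if degrees else 1.0
    overrides = dict(geometry_overrides or {})
    with h5py.File(path, "r") as f:
        if "projections" not in f:
            raise FormatError("missing mandatory group 'projections'")
        group = f["projections"]
        S = len(group.keys())
        if S == 0:
            raise FormatError("'projections' group is empty")
        for s in range(S):
            if str(s) not in group:
                raise FormatError(
                    f"projections group is not consecutively numbered: "
                    f"missing key '{s}'")

        data, diode, weights = [], [], []
        inner, outer, joff, koff = [], [], [], []
        for s in range(S):
            g = group[str(s)]
            if "data" not in g:
                raise FormatError(f"missing mandatory dataset 'projections/{s}/data'")
            d = np.asarray(g["data"], dtype=float)
            if d.ndim != 3:
                raise FormatError(f"'projections/{s}/data' must be 3D (J, K, C)")
            data.append(d)
            diode.append(np.asarray(g["diode"], dtype=float)
                         if "diode" in g else np.ones(d.shape[:2]))
            weights.append(np.asarray(g["weights"], dtype=float)
                           if "weights" in g else np.ones_like(d))
            for name, acc in (("inner_angle", inner), ("outer_angle", outer)):
                acc.append(float(g[name][()]) * conv if name in g else 0.0)
            joff.append(float(g["j_offset"][()]) if "j_offset" in g else 0.0)
            koff.append(float(g["k_offset"][()]) if "k_offset" in g else 0.0)
        shapes = {d.shape for d in data}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent projection shapes: {sorted(shapes)}")

        geo_kwargs = {}
        for file_name, attr in _GEOMETRY_VECTOR_FIELDS.items():
            if file_name in f:
                geo_kwargs[attr] = np.asarray(f[file_name], dtype=float)
        if "volume_shape" in f:
            geo_kwargs["volume_shape"] = tuple(
                int(n) for n in np.asarray(f["volume_shape"]))
        else:
            J, K, _ = data[0].shape
            side = max(J, K)
            geo_kwargs["volume_shape"] = (side, side, side)

        if "detector_angles" in f:
            angles = np.asarray(f["detector_angles"], dtype=float) * conv
        else:
            raise FormatError("missing mandatory dataset 'detector_angles'")
        coverage = detector_coverage
        if coverage is None:
            coverage = f.attrs.get("detector_coverage", None)
        two_theta = float(f.attrs.get("two_theta", 0.0)) * conv

    if coverage is None:
        # infer from the angular span of the stored boundaries/centers
        span = angles[-1] - angles[0]
        coverage = "full" if span > 1.5 * np.pi else "half"
    if detector_angles_kind == "boundaries":
        segments = DetectorSegments(angles, coverage=coverage, two_theta=two_theta)
    else:
        segments = DetectorSegments.from_centers(angles, coverage=coverage,
                                                 two_theta=two_theta)

    stack = ProjectionStack(data=np.stack(data), diode=np.stack(diode),
                            weights=np.stack(weights))
    if stack.data.shape[3] != segments.n_segments:
        raise FormatError(
            f"data has {stack.data.shape[3]} segments but detector_angles "
            f"defines {segments.n_segments}")
    geo_kwargs.update(
        inner_angles=np.array(inner), outer_angles=np.array(outer),
        j_offsets=np.array(joff), k_offsets=np.array(koff),
        projection_shape=stack.data.shape[1:3])
    geo_kwargs.update(overrides)
    geometry = Geometry(**geo_kwargs)
    return stack, geometry, segments


def save_projection_stack(path, stack: ProjectionStack, geometry: Geometry,
                          segments: DetectorSegments) -> None:
    """Write a projection stack in the layout documented in this module."""
    if stack.n_projections != geometry.n_projections:
        raise ValueError("stack and geometry disagree on the projection count")
    with h5py.File(path, "w") as f:
        for file_name, attr in _GEOMETRY_VECTOR_FIELDS.items():
            f.create_dataset(file_name, data=np.asarray(getattr(geometry, attr),
                                                        dtype=np.float64))
        f.create_dataset("volume_shape",
                         data=np.asarray(geometry.volume_shape, dtype=np.int64))
        f.create_dataset("detector_angles",
                         data=np.asarray(segments.boundaries, dtype=np.float64))
        f.attrs["detector_coverage"] = segments.coverage
        f.attrs["two_theta"] = float(segments.two_theta)
        group = f.create_group("projections")
        for s in range(stack.n_projections):
            g = group.create_group(str(s))
            g.create_dataset("data", data=stack.data[s].astype(np.float64))
            g.create_dataset("diode", data=stack.diode[s].astype(np.float64))
            g.create_dataset("weights", data=stack.weights[s].astype(np.float64))
            g.create_dataset("inner_angle", data=float(geometry.inner_angles[s]))
            g.create_dataset("outer_angle", data=float(geometry.outer_angles[s]))
            g.create_dataset("j_offset", data=float(geometry.j_offsets[s]))
            g.create_dataset("k_offset", data=float(geometry.k_offsets[s]))


def normalize_by_transmission(stack: ProjectionStack) -> ProjectionStack:
    """Divide the scattered intensities by the transmitted intensity.

    Standard absorption correction: ``data[s,j,k,c] /= diode[s,j,k]``.
    Pixels with non-positive diode readings cannot be normalized; their
    weights are zeroed so they are excluded from reconstruction, and their
    data values are left untouched (but unused).  Returns a new stack with
    unit diode.
    """
    good = stack.diode > 0
    data = stack.data.copy()
    data[good] = data[good] / stack.diode[good][..., None]
    weights = stack.weights.copy()
    weights[~good] = 0.0
    return ProjectionStack(data=data, diode=np.ones_like(stack.diode),
                           weights=weights)


def _write_basis_descriptor(group, desc: dict) -> None:
    for key, value in desc.items():
        if isinstance(value, np.ndarray):
            group.create_dataset(key, data=value.astype(np.float64))
        else:
            group.attrs[key] = value


def _read_basis_descriptor(group) -> dict:
    desc = {key: group.attrs[key] for key in group.attrs}
    for key in group:
        desc[key] = np.asarray(group[key])
    if "kind" in desc and isinstance(desc["kind"], bytes):
        desc["kind"] = desc["kind"].decode()
    return desc


def save_reconstruction(output: ReconstructionOutput, path) -> None:
    """Write a reconstruction (coefficients, basis, derived maps, provenance).

    The coefficient array is always stored; the derived maps, when present,
    are stored under the dataset names ``mean_intensity``,
    ``second_moment_tensor``, ``eigenvalues``, ``eigenvectors``,
    ``fractional_anisotropy`` and ``main_orientation``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("coefficients",
                         data=output.coefficients.astype(np.float64))
        _write_basis_descriptor(f.create_group("basis"), output.basis_descriptor)
        f.attrs["has_derived_maps"] = output.derived is not None
        if output.derived is not None:
            d = output.derived
            f.create_dataset("mean_intensity", data=np.asarray(d.mean_intensity))
            f.create_dataset("second_moment_tensor", data=np.asarray(d.second_moment))
            f.create_dataset("eigenvalues", data=np.asarray(d.eigenvalues))
            f.create_dataset("eigenvectors", data=np.asarray(d.eigenvectors))
            f.create_dataset("fractional_anisotropy",
                             data=np.asarray(d.fractional_anisotropy))
            f.create_dataset("main_orientation", data=np.asarray(d.main_orientation))
            f.attrs["orientation_mode"] = d.orientation_mode
        if output.provenance:
            f.attrs["provenance"] = json.dumps(
                output.provenance, default=_json_fallback)


def _json_fallback(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


def load_reconstruction(path) -> ReconstructionOutput:
    """Read a reconstruction file written by :func:`save_reconstruction`."""
    from .quantities import DerivedMaps  # avoid import cycle at module load
    with h5py.File(path, "r") as f:
        coefficients = np.asarray(f["coefficients"])
        desc = _read_basis_descriptor(f["basis"])
        derived = None
        if bool(f.attrs.get("has_derived_maps", False)):
            derived = DerivedMaps(
                mean_intensity=np.asarray(f["mean_intensity"]),
                second_moment=np.asarray(f["second_moment_tensor"]),
                eigenvalues=np.asarray(f["eigenvalues"]),
                eigenvectors=np.asarray(f["eigenvectors"]),
                fractional_anisotropy=np.asarray(f["fractional_anisotropy"]),
                main_orientation=np.asarray(f["main_orientation"]),
                orientation_mode=str(f.attrs.get("orientation_mode",
                                                 "polar_peaks")),
            )
        provenance = {}
        if "provenance" in f.attrs:
            provenance = json.loads(f.attrs["provenance"])
    return ReconstructionOutput(coefficients=coefficients,
                                basis_descriptor=desc, derived=derived,
                                provenance=provenance)
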