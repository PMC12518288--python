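"""Core domain types and colored point-cloud PLY I/O.

All coordinates are centimetres in a z-up frame with the pot base near
z = 0.  Colors are 8-bit RGB.  Labels are optional per-point integers
(-1 = unlabeled) used for markers and plant organs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PointCloud",
    "RigidTransform",
    "SphereModel",
    "PlyError",
    "PlyHeaderError",
    "PlyPropertyError",
    "read_ply",
    "write_ply",
    "rotation_angle_deg",
]


class PlyError(ValueError):
    """Base class for PLY parsing problems."""


class PlyHeaderError(PlyError):
    """Malformed or unsupported PLY header."""


class PlyPropertyError(PlyError):
    """Vertex element lacks required coordinate properties."""


@dataclass
class PointCloud:
    """N colored 3D points with optional integer labels.

    Attributes
    ----------
    points : (N, 3) float64 array, centimetres.
    colors : (N, 3) integer array, each channel in [0, 255].
    labels : (N,) integer array or None; -1 means unlabeled.
    """

    points: np.ndarray
    colors: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors).reshape(-1, 3)
        if not np.issubdtype(self.colors.dtype, np.integer):
            rounded = np.rint(np.asarray(self.colors, dtype=np.float64))
            if self.colors.size and not np.allclose(self.colors, rounded):
                raise ValueError("colors must be integers")
            self.colors = rounded.astype(np.int64)
        else:
            self.colors = self.colors.astype(np.int64)
        if len(self.points) != len(self.colors):
            raise ValueError(
                f"points ({len(self.points)}) and colors ({len(self.colors)}) "
                "must have identical length"
            )
        if self.colors.size and (
            self.colors.min() < 0 or self.colors.max() > 255
        ):
            raise ValueError("color channels must lie in [0, 255]")
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must match point count")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls) -> "PointCloud":
        return cls(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))

    def select(self, index) -> "PointCloud":
        """Subset by boolean mask or integer index array, order preserved."""
        labels = self.labels[index] if self.labels is not None else None
        return PointCloud(self.points[index], self.colors[index], labels)

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        return PointCloud(transform.apply(self.points), self.colors, self.labels)

    @staticmethod
    def concatenate(clouds: "list[PointCloud]") -> "PointCloud":
        if not clouds:
            return PointCloud.empty()
        pts = np.vstack([c.points for c in clouds])
        cols = np.vstack([c.colors for c in clouds])
        if all(c.labels is not None for c in clouds):
            labels = np.concatenate([c.labels for c in clouds])
        else:
            labels = None
        return PointCloud(pts, cols, labels)


_ROT_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.linalg.norm(R.T @ R - np.eye(3))
        if err > _ROT_TOL:
            raise ValueError(f"rotation not orthonormal (‖RᵀR−I‖={err:.3e})")
        det = np.linalg.det(R)
        if abs(det - 1.0) > _ROT_TOL:
            raise ValueError(f"rotation must be proper (det={det:.12f})")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (other applied first)."""
        R = self.rotation @ other.rotation
        # re-orthonormalize to keep long chains within the invariant tolerance
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        return RigidTransform(R, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def rotation_angle_deg(a: RigidTransform, b: RigidTransform | None = None) -> float:
    """Geodesic angle (degrees) of a, or between a and b."""
    R = a.rotation if b is None else a.rotation @ b.rotation.T
    c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class SphereModel:
    """A fitted calibration sphere."""

    center: np.ndarray
    radius: float
    inlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    weight: float = 0.0
    residual_mean: float = 0.0
    residual_std: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        self.radius = float(self.radius)
        self.inlier_indices = np.asarray(self.inlier_indices, dtype=np.int64).reshape(-1)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    def residuals(self, points: np.ndarray) -> np.ndarray:
        return np.abs(np.linalg.norm(points - self.center, axis=1) - self.radius)


# ---------------------------------------------------------------------------
# PLY I/O (element vertex; x,y,z double; red,green,blue uchar; label int)
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_header(fh) -> tuple[str, list[tuple[str, int, list[tuple[str, str]]]]]:
    magic = fh.readline().strip()
    if magic != b"ply":
        raise PlyHeaderError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    while True:
        raw = fh.readline()
        if not raw:
            raise PlyHeaderError("unterminated header (no end_header)")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        if line == "end_header":
            break
        parts = line.split()
        if parts[0] == "format":
            if parts[1] not in ("ascii", "binary_little_endian"):
                raise PlyHeaderError(f"unsupported PLY format '{parts[1]}'")
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise PlyHeaderError("property before any element")
            if parts[1] == "list":
                elements[-1][2].append((parts[-1], "list:" + parts[2] + ":" + parts[3]))
            else:
                if parts[1] not in _PLY_TYPES:
                    raise PlyHeaderError(f"unknown property type '{parts[1]}'")
                elements[-1][2].append((parts[-1], _PLY_TYPES[parts[1]]))
        else:
            raise PlyHeaderError(f"unrecognized header line: '{line}'")
    if fmt is None:
        raise PlyHeaderError("header missing 'format' line")
    return fmt, elements


def read_ply(path) -> PointCloud:
    """Read a colored point cloud from an ASCII or binary-little-endian PLY.

    Missing color properties default to (255, 255, 255); a missing ``label``
    property yields ``labels=None``.  Point order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PLY file not found: {path}")
    with open(path, "rb") as fh:
        fmt, elements = _parse_header(fh)
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise PlyPropertyError("PLY has no 'vertex' element")
        _, count, props = vertex
        names = [p[0] for p in props]
        for coord in ("x", "y", "z"):
            if coord not in names:
                raise PlyPropertyError(f"vertex element missing '{coord}' property")
        if any(t.startswith("list:") for _, t in props):
            raise PlyHeaderError("list properties on vertex element are unsupported")
        if elements[0][0] != "vertex" and fmt == "binary_little_endian":
            raise PlyHeaderError("binary PLY with non-leading vertex element unsupported")

        if fmt == "ascii":
            rows = []
            n_read = 0
            # vertex data starts at this element's position in file order;
            # ASCII elements are line-per-item so skip preceding elements
            for name, n, _eprops in elements:
                if name == "vertex":
                    break
                for _ in range(n):
                    fh.readline()
            while n_read < count:
                raw = fh.readline()
                if not raw:
                    raise PlyError(f"expected {count} vertices, file ended at {n_read}")
                line = raw.strip()
                if not line:
                    continue
                rows.append(line.split())
                n_read += 1
            if count == 0:
                data = {n: np.empty(0) for n in names}
            else:
                arr = np.array(rows, dtype=np.float64)
                if arr.shape[1] < len(names):
                    raise PlyError("vertex row has fewer fields than declared properties")
                data = {n: arr[:, i] for i, n in enumerate(names)}
        else:
            dtype = np.dtype([(n, "<" + t) for n, t in props])
            buf = fh.read(dtype.itemsize * count)
            if len(buf) < dtype.itemsize * count:
                raise PlyError("binary vertex data truncated")
            rec = np.frombuffer(buf, dtype=dtype, count=count)
            data = {n: rec[n] for n in names}

    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [data["red"], data["green"], data["blue"]]
        ).astype(np.int64)
    else:
        colors = np.full((count, 3), 255, dtype=np.int64)
    labels = data["label"].astype(np.int64) if "label" in names else None
    return PointCloud(points, colors, labels)


def write_ply(cloud: PointCloud, path, binary: bool = False) -> None:
    """Write a PointCloud as PLY (ASCII by default, for diffability).

    Coordinates are stored as doubles so read/write round-trips are
    lossless; colors as uchar; labels (if present) as int32.
    """
    path = Path(path)
    n = len(cloud)
    has_labels = cloud.labels is not None
    header = io.StringIO()
    header.write("ply\n")
    header.write(
        "format binary_little_endian 1.0\n" if binary else "format ascii 1.0\n"
    )
    header.write(f"element vertex {n}\n")
    header.write("property double x\nproperty double y\nproperty double z\n")
    header.write(
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
    )
    if has_labels:
        header.write("property int label\n")
    header.write("end_header\n")

    with open(path, "wb") as fh:
        fh.write(header.getvalue().encode("ascii"))
        if binary:
            fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                      ("red", "u1"), ("green", "u1"), ("blue", "u1")]
            if has_labels:
                fields.append(("label", "<i4"))
            rec = np.empty(n, dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = cloud.points.T
            rec["red"], rec["green"], rec["blue"] = cloud.colors.T
            if has_labels:
                rec["label"] = cloud.labels
            fh.write(rec.tobytes())
        else:
            lines = []
            for i in range(n):
                x, y, z = cloud.points[i]
                r, g, b = cloud.colors[i]
                row = f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b}"
                if has_labels:
                    row += f" {cloud.labels[i]}"
                lines.append(row)
            fh.write(("\n".join(lines) + ("\n" if lines else "")).encode("ascii"))
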