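"""Voxel-grid and mesh I/O plus the multi-view dataset loader.

Formats handled:

* ``binvox`` v1 — a header (``#binvox 1`` / ``dim`` / ``translate`` / ``scale`` /
  ``data``) followed by run-length-encoded ``(value, count)`` byte pairs.  The
  voxel order is the format's canonical x-major, y-fastest order: flat index
  ``x * N^2 + z * N + y``.  Reading and writing are bit-exact round trips for
  canonical maximal-run encodings.
* Wavefront OBJ — ``v``/``f`` records only.  Faces with more than three
  vertices are fan-triangulated; indices are 1-based on disk and 0-based in
  memory.
* Dataset directories laid out as ``<root>/<object_id>/views/*.png`` with an
  optional ``model.obj``, ``model.binvox`` and ``views.csv`` per object (the
  layout of multi-view reconstruction corpora such as ShapeNet renders and the
  32-tooth / 18-view dental collections this package targets).

Voxel cell convention: voxel ``(i, j, k)`` covers the cube whose center is
``translate + scale * ((i, j, k) + 0.5) / N``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "VoxelGrid",
    "ViewRecord",
    "MultiViewSample",
    "BinvoxFormatError",
    "read_binvox",
    "write_binvox",
    "read_obj",
    "write_obj",
    "voxelize_mesh",
    "load_multiview_dataset",
    "voxel_centers",
]


class BinvoxFormatError(ValueError):
    """Raised for malformed or corrupt binvox files."""


@dataclass
class TriangleMesh:
    """Triangle mesh with 0-based face indices."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise IndexError("face references a missing vertex")
        if len(self.faces):
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face with repeated vertex indices")

    @property
    def bounds(self) -> np.ndarray:
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass
class VoxelGrid:
    """Cubic occupancy grid with binvox placement metadata."""

    occupancy: np.ndarray  # (N, N, N), values in [0, 1]
    translate: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0
    is_binary: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=np.float64)
        self.translate = np.asarray(self.translate, dtype=np.float64).reshape(3)
        if self.occupancy.ndim != 3 or len(set(self.occupancy.shape)) != 1:
            raise ValueError("occupancy grid must be cubic (N, N, N)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.occupancy.min() < 0 or self.occupancy.max() > 1:
            raise ValueError("occupancy values must lie in [0, 1]")
        if self.is_binary and not np.all(np.isin(self.occupancy, (0.0, 1.0))):
            raise ValueError("is_binary grid contains non-{0,1} values")

    @property
    def resolution(self) -> int:
        return self.occupancy.shape[0]

    def binarize(self, threshold: float = 0.5) -> "VoxelGrid":
        """Strict threshold: occupied iff occupancy > threshold."""
        return VoxelGrid(
            (self.occupancy > threshold).astype(np.float64),
            translate=self.translate.copy(),
            scale=self.scale,
            is_binary=True,
            meta=dict(self.meta),
        )


@dataclass
class ViewRecord:
    """A view image name and its pose relative to the first view.

    ``relative_position`` is ``(rx, ry, rz, tx, ty, tz)``: intrinsic Z-Y-X
    Euler angles in radians followed by a translation, mapping first-view
    camera coordinates to this view's camera coordinates.
    """

    image_name: str
    relative_position: np.ndarray

    def __post_init__(self):
        self.relative_position = np.asarray(
            self.relative_position, dtype=np.float64
        ).reshape(6)


@dataclass
class MultiViewSample:
    object_id: str
    views: list[np.ndarray]  # each (H, W, 3) in [0, 1]
    view_records: list[ViewRecord] | None = None
    ground_truth: VoxelGrid | None = None
    mesh: TriangleMesh | None = None

    def __post_init__(self):
        if len(self.views) < 1:
            raise ValueError("a sample needs at least one view")
        shapes = {v.shape for v in self.views}
        if len(shapes) != 1:
            raise ValueError(f"views of {self.object_id} have mismatched sizes: {shapes}")
        if self.view_records is not None and len(self.view_records) != len(self.views):
            raise ValueError("view_records length must match number of views")


# ---------------------------------------------------------------------------
# binvox
# ---------------------------------------------------------------------------


def read_binvox(path) -> VoxelGrid:
    """Read a binvox v1 file into a binary :class:`VoxelGrid`."""
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if not line.startswith(b"#binvox"):
            raise BinvoxFormatError(f"{path}: missing #binvox magic")
        dims = translate = None
        scale = 1.0
        while True:
            line = fh.readline()
            if not line:
                raise BinvoxFormatError(f"{path}: header ended before 'data'")
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0]
            if key == b"data":
                break
            if key == b"dim":
                dims = [int(t) for t in tokens[1:]]
            elif key == b"translate":
                translate = [float(t) for t in tokens[1:]]
            elif key == b"scale":
                scale = float(tokens[1])
            # unknown header keys are ignored, as binvox tools do
        if dims is None or len(dims) != 3:
            raise BinvoxFormatError(f"{path}: missing or malformed dim line")
        if len(set(dims)) != 1:
            raise BinvoxFormatError(f"{path}: non-cubic grids are unsupported: {dims}")
        n = dims[0]
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size % 2 != 0:
        raise BinvoxFormatError(f"{path}: odd RLE byte count")
    values, counts = raw[::2], raw[1::2].astype(np.int64)
    if counts.sum() != n**3:
        raise BinvoxFormatError(
            f"{path}: RLE counts sum to {counts.sum()}, expected {n ** 3}"
        )
    flat = np.repeat(values, counts).astype(np.float64)
    # x-major, y-fastest: flat index = x*n^2 + z*n + y  ->  axes (x, z, y)
    occupancy = flat.reshape(n, n, n).transpose(0, 2, 1)
    return VoxelGrid(
        occupancy,
        translate=np.zeros(3) if translate is None else np.asarray(translate),
        scale=scale,
    )


def _rle_encode(flat: np.ndarray) -> bytes:
    """Maximal-run RLE with runs capped at 255, as binvox requires."""
    out = bytearray()
    boundaries = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [flat.size]])
    for s, e in zip(starts, ends):
        value = int(flat[s])
        run = int(e - s)
        while run > 255:
            out += bytes((value, 255))
            run -= 255
        out += bytes((value, run))
    return bytes(out)


def write_binvox(grid: VoxelGrid, path) -> None:
    """Write a binary grid as binvox v1 (canonical maximal-run encoding)."""
    if not grid.is_binary:
        raise ValueError("write_binvox requires a binary grid")
    n = grid.resolution
    flat = grid.occupancy.transpose(0, 2, 1).reshape(-1).astype(np.uint8)
    header = (
        b"#binvox 1\n"
        + f"dim {n} {n} {n}\n".encode()
        + ("translate " + " ".join(repr(float(t)) for t in grid.translate) + "\n").encode()
        + f"scale {float(grid.scale)!r}\n".encode()
        + b"data\n"
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(_rle_encode(flat))


# ---------------------------------------------------------------------------
# OBJ
# ---------------------------------------------------------------------------


def read_obj(path) -> TriangleMesh:
    """Read v/f records from a Wavefront OBJ file.

    Polygonal faces are fan-triangulated around their first vertex; on-disk
    1-based indices (including negative relative indices) become 0-based.
    """
    vertices: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path, "r") as fh:
        for line in fh:
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if tokens[0] == "v":
                vertices.append([float(t) for t in tokens[1:4]])
            elif tokens[0] == "f":
                idx = []
                for tok in tokens[1:]:
                    raw = int(tok.split("/")[0])
                    idx.append(raw - 1 if raw > 0 else len(vertices) + raw)
                for a, b in zip(idx[1:-1], idx[2:]):
                    faces.append((idx[0], a, b))
    return TriangleMesh(np.array(vertices, dtype=np.float64).reshape(-1, 3),
                        np.array(faces, dtype=np.int64).reshape(-1, 3))


def write_obj(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def voxel_centers(n: int, translate: np.ndarray, scale: float) -> np.ndarray:
    """Model-space centers of all n^3 cells, shaped (n, n, n, 3)."""
    axis = (np.arange(n) + 0.5) / n
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1)
    return np.asarray(translate) + scale * centers


def mesh_is_watertight(mesh: TriangleMesh) -> bool:
    """True iff every undirected edge is shared by exactly two faces."""
    if len(mesh.faces) == 0:
        return False
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def _parity_occupancy(mesh: TriangleMesh, n_v: int, translate: np.ndarray,
                      side: float, seed: int) -> np.ndarray:
    """Crossing-count occupancy: voxel center inside iff a +x ray from it
    crosses the surface an odd number of times.  Ray origins are jittered by
    a seeded epsilon in (y, z) to dodge edge/vertex-coincident hits."""
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    det = e1[:, 1] * e2[:, 2] - e2[:, 1] * e1[:, 2]  # yz-projected area
    ok = np.abs(det) > 1e-15
    v0, e1, e2, det = v0[ok], e1[ok], e2[ok], det[ok]

    axis = translate[:, None] + side * (np.arange(n_v) + 0.5)[None, :] / n_v
    xs, ys, zs = axis
    rng = np.random.default_rng(seed)
    eps = 1e-7 * side
    occ = np.zeros((n_v, n_v, n_v), dtype=bool)
    if len(v0) == 0:
        return occ
    for j in range(n_v):
        y = ys[j] + eps * (rng.random(n_v) - 0.5)
        z = zs + eps * (rng.random(n_v) - 0.5)
        # solve v0 + a e1 + b e2 = (x, y, z) in the yz components, per ray
        dy = y[:, None] - v0[None, :, 1]  # (n_v rays, F)
        dz = z[:, None] - v0[None, :, 2]
        a = (dy * e2[None, :, 2] - dz * e2[None, :, 1]) / det[None, :]
        b = (e1[None, :, 1] * dz - e1[None, :, 2] * dy) / det[None, :]
        inside = (a >= 0.0) & (b >= 0.0) & (a + b <= 1.0)
        x_hit = v0[None, :, 0] + a * e1[None, :, 0] + b * e2[None, :, 0]
        for k in range(n_v):
            xi = np.sort(x_hit[k, inside[k]])
            # crossings strictly beyond each voxel-center x, odd => inside
            n_beyond = xi.size - np.searchsorted(xi, xs, side="right")
            occ[:, j, k] = (n_beyond % 2) == 1
    return occ


def voxelize_mesh(mesh: TriangleMesh, n_v: int, seed: int = 0) -> VoxelGrid:
    """Occupancy grid: a cell is occupied iff its center is inside the mesh.

    Inside/outside is decided by a +x ray-parity (crossing-count) test with
    seeded epsilon-jittered ray origins to avoid edge-coincident hits.  Grid
    bounds are the mesh AABB expanded by 2% and cubified to the largest
    extent, recorded as binvox ``translate``/``scale``.  Open (non-watertight)
    meshes fall back to marking surface-crossed cells only, with
    ``meta['surface_only']`` set.
    """
    if n_v < 2:
        raise ValueError("n_v must be at least 2")
    lo, hi = mesh.bounds
    extent = float((hi - lo).max())
    if extent <= 0:
        raise ValueError("mesh has zero extent")
    side = 1.02 * extent
    center = (lo + hi) / 2.0
    translate = center - side / 2.0

    meta: dict = {}
    if mesh_is_watertight(mesh):
        occ = _parity_occupancy(mesh, n_v, translate, side, seed)
    else:
        warnings.warn(
            "mesh is not watertight; falling back to surface-only voxelization",
            RuntimeWarning,
            stacklevel=2,
        )
        meta["surface_only"] = True
        occ = np.zeros((n_v, n_v, n_v), dtype=bool)
        if len(mesh.faces):
            rng = np.random.default_rng(seed)
            tri = mesh.vertices[mesh.faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            # sample each triangle densely enough to hit every crossed cell
            n_samples = np.maximum(8, np.ceil(areas / (side / n_v) ** 2 * 8).astype(int))
            pts = []
            for t, ns in zip(tri, n_samples):
                r1 = np.sqrt(rng.random(ns))
                r2 = rng.random(ns)
                pts.append(
                    (1 - r1)[:, None] * t[0]
                    + (r1 * (1 - r2))[:, None] * t[1]
                    + (r1 * r2)[:, None] * t[2]
                )
            ijk = np.floor((np.concatenate(pts) - translate) / side * n_v).astype(int)
            ijk = np.clip(ijk, 0, n_v - 1)
            occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    return VoxelGrid(
        occ.astype(np.float64),
        translate=translate,
        scale=side,
        is_binary=True,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Dataset loading
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def _load_image(path: Path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    return np.clip(img, 0.0, 1.0)


def read_views_csv(path) -> list[ViewRecord]:
    """Read the pose CSV: header ``image_name,rx,ry,rz,tx,ty,tz``."""
    df = pd.read_csv(path)
    expected = ["image_name", "rx", "ry", "rz", "tx", "ty", "tz"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return [
        ViewRecord(str(row.image_name),
                   np.array([row.rx, row.ry, row.rz, row.tx, row.ty, row.tz]))
        for row in df.itertuples(index=False)
    ]


def write_views_csv(records: Sequence[ViewRecord], path) -> None:
    rows = [
        {"image_name": r.image_name,
         **dict(zip(["rx", "ry", "rz", "tx", "ty", "tz"], r.relative_position))}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_multiview_dataset(root) -> Iterator[MultiViewSample]:
    """Yield :class:`MultiViewSample` objects in lexicographic folder order.

    View order follows ``views.csv`` when present, else sorted filenames.
    Folders with no view images are skipped with a logged warning.  Ground
    truth (``model.binvox``/``model.obj``) is optional so inference-only
    directories load too.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(str(root))
    for obj_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        views_dir = obj_dir / "views"
        search_dir = views_dir if views_dir.is_dir() else obj_dir
        image_paths = sorted(
            p for p in search_dir.iterdir()
            if p.suffix.lower() in _IMAGE_SUFFIXES
        ) if search_dir.is_dir() else []
        if not image_paths:
            logger.warning("skipping %s: no view images found", obj_dir)
            continue

        records = None
        csv_path = obj_dir / "views.csv"
        if csv_path.exists():
            records = read_views_csv(csv_path)
            by_name = {p.name: p for p in image_paths}
            try:
                image_paths = [by_name[r.image_name] for r in records]
            except KeyError as exc:
                raise FileNotFoundError(
                    f"{csv_path} names missing image {exc}"
                ) from exc

        views = [_load_image(p) for p in image_paths]
        ground_truth = None
        binvox_path = obj_dir / "model.binvox"
        if binvox_path.exists():
            ground_truth = read_binvox(binvox_path)
        mesh = None
        obj_path = obj_dir / "model.obj"
        if obj_path.exists():
            mesh = read_obj(obj_path)
        yield MultiViewSample(
            object_id=obj_dir.name,
            views=views,
            view_records=records,
            ground_truth=ground_truth,
            mesh=mesh,
        )
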