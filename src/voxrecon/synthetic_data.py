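"""Synthetic multi-view dataset generation.

This module emulates the structure of multi-view reconstruction corpora: a
directory of objects, each with a ring of rendered RGB views, a ground-truth
mesh (OBJ) and voxel grid (binvox), and a CSV of per-view poses relative to
the first view.  The ``teethnet`` preset reproduces the layout of the
32-object / 18-view dental collection (folders named by ISO tooth numbers
11-48) that this package's reconstruction pipeline targets.

Shapes are parametric implicit solids (sphere, box, superellipsoid, and a
tooth-like union of a superellipsoid crown with downward root lobes) surfaced
by marching cubes, so every ground-truth mesh is closed and deterministic for
a given spec.  Rendering is a z-buffered triangle rasterizer with flat
Lambertian shading: pixel = albedo * (ambient + (1 - ambient) * max(0, n.l))
on a constant background.  All randomness is funnelled through per-object
seeds derived from (dataset seed, object index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .pose import euler_to_rotation, rotation_to_euler
from .voxel_io import (
    TriangleMesh,
    ViewRecord,
    voxelize_mesh,
    write_binvox,
    write_obj,
    write_views_csv,
)

__all__ = [
    "ShapeSpec",
    "Camera",
    "LightModel",
    "generate_shape",
    "make_camera_ring",
    "relative_view_records",
    "render_view",
    "build_dataset",
    "default_intrinsics",
    "TEETH_ISO_NAMES",
]

SHAPE_KINDS = ("sphere", "box", "superellipsoid", "tooth")

# FDI two-digit tooth notation: 4 quadrants x 8 teeth
TEETH_ISO_NAMES = tuple(f"{q}{i}" for q in (1, 2, 3, 4) for i in range(1, 9))

BACKGROUND = 0.05


@dataclass
class ShapeSpec:
    """Parametric solid: kind plus size parameters and a seed.

    ``size`` are semi-axes (a, b, c); ``exponent`` is the superellipsoid
    shape exponent (2 = ellipsoid, large = box-like); tooth shapes add
    ``root_lobes`` in {1, 2, 3} and ``root_length``.
    """

    kind: str = "sphere"
    size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    exponent: float = 2.0
    root_lobes: int = 2
    root_length: float = 1.0
    seed: int = 0
    grid_res: int = 40

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; choose from {SHAPE_KINDS}")
        if min(self.size) <= 0 or self.exponent <= 0 or self.root_length <= 0:
            raise ValueError("all size parameters must be positive")
        if self.kind == "tooth" and self.root_lobes not in (1, 2, 3):
            raise ValueError("tooth root_lobes must be 1, 2 or 3")


@dataclass
class Camera:
    """Pinhole camera: x_cam = R @ x_world + t, looking along +z."""

    K: np.ndarray  # (3, 3)
    R: np.ndarray  # (3, 3)
    t: np.ndarray  # (3,)
    width: int
    height: int

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=np.float64).reshape(3, 3)
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if np.abs(self.R @ self.R.T - np.eye(3)).max() > 1e-9 or np.linalg.det(self.R) < 0:
            raise ValueError("R must be orthonormal with det +1")
        if self.K[0, 0] <= 0 or self.K[1, 1] <= 0:
            raise ValueError("focal lengths must be positive")

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        return points @ self.R.T + self.t

    def project(self, points: np.ndarray):
        """Return (pixels (N,2), depth (N,)) for world points."""
        pc = self.world_to_camera(np.asarray(points, dtype=np.float64).reshape(-1, 3))
        z = pc[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.K[0, 0] * pc[:, 0] / z + self.K[0, 2]
            v = self.K[1, 1] * pc[:, 1] / z + self.K[1, 2]
        return np.stack([u, v], axis=1), z


@dataclass
class LightModel:
    """Directional light: ``direction`` points from the scene toward the light."""

    direction: np.ndarray = field(default_factory=lambda: np.array([0.5, -0.5, 0.8]))
    ambient: float = 0.25

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=np.float64).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("light direction must be non-zero")
        self.direction = d / n
        if not 0.0 <= self.ambient <= 1.0:
            raise ValueError("ambient must lie in [0, 1]")


def default_intrinsics(width: int = 128, height: int = 128) -> np.ndarray:
    """fx = fy = 1.2 * W, principal point at the image center."""
    f = 1.2 * width
    return np.array([
        [f, 0.0, (width - 1) / 2.0],
        [0.0, f, (height - 1) / 2.0],
        [0.0, 0.0, 1.0],
    ])


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------


def _implicit_field(spec: ShapeSpec, pts: np.ndarray) -> np.ndarray:
    """Positive inside the solid, negative outside."""
    a, b, c = spec.size
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]

    def superell(x, y, z, a, b, c, m):
        return 1.0 - (
            np.abs(x / a) ** m + np.abs(y / b) ** m + np.abs(z / c) ** m
        )

    if spec.kind == "sphere":
        return 1.0 - ((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    if spec.kind in ("superellipsoid", "box"):
        m = spec.exponent if spec.kind == "superellipsoid" else 10.0
        return superell(x, y, z, a, b, c, m)
    # tooth: superellipsoid crown above z=0, union of root lobes below
    rng = np.random.default_rng(spec.seed)
    crown = superell(x, y, z - 0.25 * c, a, b, 0.75 * c, 3.0)
    f = crown
    azimuths = rng.uniform(0, 2 * np.pi) + np.arange(spec.root_lobes) * (
        2 * np.pi / spec.root_lobes
    )
    lobe_r = 0.35 * min(a, b) * rng.uniform(0.85, 1.15, size=spec.root_lobes)
    offset = 0.4 * min(a, b)
    for az, lr in zip(azimuths, lobe_r):
        cx = offset * np.cos(az) if spec.root_lobes > 1 else 0.0
        cy = offset * np.sin(az) if spec.root_lobes > 1 else 0.0
        lobe = 1.0 - (
            ((x - cx) / lr) ** 2
            + ((y - cy) / lr) ** 2
            + ((z + 0.55 * spec.root_length) / (0.8 * spec.root_length)) ** 2
        )
        f = np.maximum(f, lobe)
    return f


def _shape_bounds(spec: ShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    a, b, c = spec.size
    if spec.kind == "tooth":
        lo = np.array([-1.2 * a, -1.2 * b, -1.2 * (0.55 + 0.8) * spec.root_length])
        hi = np.array([1.2 * a, 1.2 * b, 1.2 * c])
    else:
        lo = -1.1 * np.array([a, b, c])
        hi = 1.1 * np.array([a, b, c])
    return lo, hi


def generate_shape(spec: ShapeSpec) -> TriangleMesh:
    """Surface the implicit solid with marching cubes.

    The result is a closed, consistently outward-oriented triangle mesh,
    identical for identical specs.
    """
    from skimage import measure

    lo, hi = _shape_bounds(spec)
    n = spec.grid_res
    axes = [np.linspace(lo[d], hi[d], n) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    field_vals = _implicit_field(spec, np.stack([gx, gy, gz], axis=-1))
    spacing = tuple((hi[d] - lo[d]) / (n - 1) for d in range(3))
    verts, faces, _, _ = measure.marching_cubes(field_vals, level=0.0, spacing=spacing)
    verts = verts + lo
    mesh = TriangleMesh(verts, faces)
    # enforce outward orientation (field is positive inside)
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centroids = tri.mean(axis=1)
    outward = np.einsum("ij,ij->i", normals, centroids - mesh.vertices.mean(axis=0))
    if np.sum(outward < 0) > len(outward) / 2:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def checkerboard_box(subdiv: int = 10, size: float = 1.0, seed: int = 0):
    """A box with each face subdivided into a checker of albedo patches.

    Returns ``(mesh, face_albedo)``.  The high-contrast patch corners give
    feature detectors plenty of repeatable keypoints, and the three visible
    faces of a box corner are non-coplanar, which two-view geometry needs.
    Patch albedos are seeded-random greys on a checker parity, so textures
    are deterministic.
    """
    rng = np.random.default_rng(seed)
    h = size / 2.0
    vertices: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    albedo: list[np.ndarray] = []
    # each box face: origin corner, two edge vectors (outward orientation)
    face_frames = [
        (np.array([-h, -h, h]), np.array([size, 0, 0]), np.array([0, size, 0])),   # +z
        (np.array([-h, h, -h]), np.array([size, 0, 0]), np.array([0, -size, 0])),  # -z
        (np.array([h, -h, -h]), np.array([0, size, 0]), np.array([0, 0, size])),   # +x
        (np.array([-h, h, -h]), np.array([0, -size, 0]), np.array([0, 0, size])),  # -x
        (np.array([h, h, -h]), np.array([-size, 0, 0]), np.array([0, 0, size])),   # +y
        (np.array([-h, -h, -h]), np.array([size, 0, 0]), np.array([0, 0, size])),  # -y
    ]
    for origin, eu, ev in face_frames:
        base = len(vertices)
        for i in range(subdiv + 1):
            for j in range(subdiv + 1):
                vertices.append(origin + eu * (i / subdiv) + ev * (j / subdiv))
        for i in range(subdiv):
            for j in range(subdiv):
                a = base + i * (subdiv + 1) + j
                b = a + subdiv + 1
                faces.append((a, b, a + 1))
                faces.append((a + 1, b, b + 1))
                shade = rng.uniform(0.75, 1.0) if (i + j) % 2 == 0 else rng.uniform(0.0, 0.25)
                albedo.extend([np.full(3, shade)] * 2)
    mesh = TriangleMesh(np.array(vertices), np.array(faces))
    return mesh, np.array(albedo)


# ---------------------------------------------------------------------------
# Cameras
# ---------------------------------------------------------------------------


def _look_at(position: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation for a camera at ``position`` looking at ``target``.

    World +z is up; the camera looks along its +z axis, image y points down.
    """
    forward = target - position
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    if abs(forward @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    R = np.stack([right, down, forward])
    t = -R @ position
    return R, t


def make_camera_ring(
    n_views: int,
    radius: float = 3.0,
    elevation_deg: float = 20.0,
    K: np.ndarray | None = None,
    width: int = 128,
    height: int = 128,
) -> list[Camera]:
    """Cameras equally spaced in azimuth at fixed elevation, looking at origin."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if K is None:
        K = default_intrinsics(width, height)
    elev = np.deg2rad(elevation_deg)
    cams = []
    for j in range(n_views):
        az = 2.0 * np.pi * j / n_views
        pos = radius * np.array(
            [np.cos(az) * np.cos(elev), np.sin(az) * np.cos(elev), np.sin(elev)]
        )
        R, t = _look_at(pos, np.zeros(3))
        cams.append(Camera(K=np.array(K), R=R, t=t, width=width, height=height))
    return cams


def relative_view_records(cameras: list[Camera], image_names: list[str]) -> list[ViewRecord]:
    """Per-view pose relative to view 0: x_j = R_rel x_0 + t_rel.

    Rotation is stored as intrinsic Z-Y-X Euler angles (radians).  View 0's
    record is exactly zero.
    """
    R0, t0 = cameras[0].R, cameras[0].t
    records = []
    for cam, name in zip(cameras, image_names):
        if cam is cameras[0]:
            records.append(ViewRecord(name, np.zeros(6)))
            continue
        R_rel = cam.R @ R0.T
        t_rel = cam.t - R_rel @ t0
        ang = rotation_to_euler(R_rel).as_array()
        records.append(ViewRecord(name, np.concatenate([ang, t_rel])))
    return records


def compose_relative(record: ViewRecord, cam0: Camera) -> tuple[np.ndarray, np.ndarray]:
    """Apply a relative-pose record to the first camera: returns (R_j, t_j)."""
    rx, ry, rz, tx, ty, tz = record.relative_position
    R_rel = euler_to_rotation(rx, ry, rz)
    t_rel = np.array([tx, ty, tz])
    return R_rel @ cam0.R, R_rel @ cam0.t + t_rel


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_view(
    mesh: TriangleMesh,
    camera: Camera,
    light: LightModel | None = None,
    face_albedo: np.ndarray | None = None,
    background: float = BACKGROUND,
    return_depth: bool = False,
):
    """Z-buffered flat-shaded rasterization of ``mesh`` from ``camera``.

    ``face_albedo`` optionally gives per-face RGB in [0, 1] (default white).
    Faces with any vertex at or behind the camera plane are skipped; a mesh
    entirely behind the camera yields an all-background image with a warning.
    """
    import warnings

    if light is None:
        light = LightModel()
    H, W = camera.height, camera.width
    img = np.full((H, W, 3), background, dtype=np.float64)
    depth = np.full((H, W), np.inf)
    if len(mesh.faces) == 0:
        if return_depth:
            return img, depth
        return img

    pix, z = camera.project(mesh.vertices)
    tri_world = mesh.vertices[mesh.faces]
    normals = np.cross(
        tri_world[:, 1] - tri_world[:, 0], tri_world[:, 2] - tri_world[:, 0]
    )
    norm_len = np.linalg.norm(normals, axis=1)
    valid_n = norm_len > 1e-15
    normals[valid_n] /= norm_len[valid_n, None]
    lambert = np.maximum(0.0, normals @ light.direction)
    shade = light.ambient + (1.0 - light.ambient) * lambert

    if face_albedo is None:
        face_albedo = np.ones((len(mesh.faces), 3))
    else:
        face_albedo = np.asarray(face_albedo, dtype=np.float64).reshape(len(mesh.faces), 3)

    # backface culling in camera space (meshes are closed)
    cam_centroids = camera.world_to_camera(tri_world.mean(axis=1))
    n_cam = normals @ camera.R.T
    front = np.einsum("ij,ij->i", n_cam, cam_centroids) < 0

    z_tri = z[mesh.faces]
    visible = front & valid_n & np.all(z_tri > 1e-9, axis=1)
    if not visible.any():
        if np.all(z_tri <= 1e-9):
            warnings.warn("mesh is entirely behind the camera", RuntimeWarning, stacklevel=2)
        if return_depth:
            return img, depth
        return img

    uv_tri = pix[mesh.faces]
    for fi in np.flatnonzero(visible):
        (x0, y0), (x1, y1), (x2, y2) = uv_tri[fi]
        xmin = max(int(np.ceil(min(x0, x1, x2))), 0)
        xmax = min(int(np.floor(max(x0, x1, x2))), W - 1)
        ymin = max(int(np.ceil(min(y0, y1, y2))), 0)
        ymax = min(int(np.floor(max(y0, y1, y2))), H - 1)
        if xmin > xmax or ymin > ymax:
            continue
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(area) < 1e-15:
            continue
        xs = np.arange(xmin, xmax + 1)
        ys = np.arange(ymin, ymax + 1)
        gx, gy = np.meshgrid(xs, ys)
        w0 = ((x1 - gx) * (y2 - gy) - (x2 - gx) * (y1 - gy)) / area
        w1 = ((x2 - gx) * (y0 - gy) - (x0 - gx) * (y2 - gy)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        zf = w0 * z_tri[fi, 0] + w1 * z_tri[fi, 1] + w2 * z_tri[fi, 2]
        closer = inside & (zf < depth[ymin : ymax + 1, xmin : xmax + 1])
        if not closer.any():
            continue
        sub_depth = depth[ymin : ymax + 1, xmin : xmax + 1]
        sub_img = img[ymin : ymax + 1, xmin : xmax + 1]
        sub_depth[closer] = zf[closer]
        sub_img[closer] = shade[fi] * face_albedo[fi]
    if return_depth:
        return img, depth
    return img


# ---------------------------------------------------------------------------
# Dataset builder
# ---------------------------------------------------------------------------


def _object_spec(kind: str, seed: int) -> ShapeSpec:
    rng = np.random.default_rng(seed)
    if kind == "tooth":
        return ShapeSpec(
            kind="tooth",
            size=tuple(rng.uniform(0.7, 1.0, size=3)),
            root_lobes=int(rng.integers(1, 4)),
            root_length=float(rng.uniform(0.8, 1.2)),
            seed=seed,
            grid_res=32,
        )
    if kind == "sphere":
        r = float(rng.uniform(0.7, 1.0))
        return ShapeSpec(kind="sphere", size=(r, r, r), seed=seed, grid_res=32)
    if kind == "box":
        return ShapeSpec(kind="box", size=tuple(rng.uniform(0.5, 1.0, size=3)),
                         seed=seed, grid_res=32)
    return ShapeSpec(
        kind="superellipsoid",
        size=tuple(rng.uniform(0.6, 1.0, size=3)),
        exponent=float(rng.uniform(1.5, 5.0)),
        seed=seed,
        grid_res=32,
    )


def build_dataset(
    n_objects: int,
    n_views: int,
    n_v: int,
    out_dir,
    seed: int = 0,
    preset: str | None = None,
    width: int = 128,
    height: int = 128,
    radius: float = 3.0,
    elevation_deg: float = 20.0,
) -> Path:
    """Write a complete multi-view dataset and return its root path.

    ``preset='teethnet'`` fixes 32 tooth objects (folders named by ISO tooth
    numbers 11-48) with 18 views each, matching the published dental
    collection's structure; ``preset='small'`` is a 4-object / 5-view
    mixed-shape smoke-test configuration.  Without a preset, objects cycle
    through the four shape kinds.
    """
    if preset == "teethnet":
        n_objects, n_views = 32, 18
        object_ids = list(TEETH_ISO_NAMES)
        kinds = ["tooth"] * n_objects
    elif preset == "small":
        n_objects, n_views = 4, 5
        object_ids = [f"obj_{i:03d}" for i in range(n_objects)]
        kinds = ["sphere", "box", "superellipsoid", "tooth"]
    else:
        if n_objects < 1 or n_views < 1:
            raise ValueError("n_objects and n_views must be >= 1")
        object_ids = [f"obj_{i:03d}" for i in range(n_objects)]
        kinds = [SHAPE_KINDS[i % len(SHAPE_KINDS)] for i in range(n_objects)]

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cameras = make_camera_ring(
        n_views, radius=radius, elevation_deg=elevation_deg, width=width, height=height
    )
    image_names = [f"view_{j:03d}.png" for j in range(n_views)]
    records = relative_view_records(cameras, image_names)
    ss = np.random.SeedSequence(seed)
    object_seeds = [int(s) for s in ss.generate_state(n_objects)]

    for oid, kind, oseed in zip(object_ids, kinds, object_seeds):
        obj_dir = root / oid
        (obj_dir / "views").mkdir(parents=True, exist_ok=True)
        spec = _object_spec(kind, oseed % (2**31 - 1))
        mesh = generate_shape(spec)
        write_obj(mesh, obj_dir / "model.obj")
        write_binvox(voxelize_mesh(mesh, n_v, seed=oseed % (2**31 - 1)),
                     obj_dir / "model.binvox")
        light = LightModel()
        for cam, name in zip(cameras, image_names):
            img = render_view(mesh, cam, light)
            iio.imwrite(
                obj_dir / "views" / name,
                np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8),
            )
        write_views_csv(records, obj_dir / "views.csv")
    return root
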