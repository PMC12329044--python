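"""Two-view relative-pose recovery and Euler-angle extraction.

The chain mirrors the classical epipolar pipeline used to recover camera
motion between a pair of views of the same rigid scene:

    keypoints -> descriptor matching -> fundamental matrix F (normalized
    8-point inside seeded RANSAC) -> essential matrix E = K^T F K -> (R, t)
    by cheirality over the four decompositions -> intrinsic Z-Y-X Euler
    angles -> DLT triangulation of the matched points.

Pixel coordinates have their origin at the top-left pixel center, x right and
y down.  Translation is recovered only up to scale from two views, so ``t``
is always unit length.

Descriptor backends run behind a single interface.  SIFT (float, L2 metric),
ORB and corner+BRIEF (binary, Hamming metric) are provided via scikit-image;
``brisk`` and ``akaze`` are recognised names but no backend for them ships
with this package, so requesting them raises :class:`BackendUnavailableError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "MatchSet",
    "PoseEstimate",
    "EulerAngles",
    "FundamentalResult",
    "BackendUnavailableError",
    "DegenerateGeometryError",
    "euler_to_rotation",
    "rotation_to_euler",
    "detect_and_describe",
    "match_descriptors",
    "estimate_fundamental",
    "essential_from_fundamental",
    "recover_pose",
    "triangulate",
    "pose_error_metrics",
    "wrap_angle",
    "DESCRIPTOR_KINDS",
    "AVAILABLE_KINDS",
]

DESCRIPTOR_KINDS = ("brisk", "sift", "orb", "akaze", "brief")
AVAILABLE_KINDS = ("sift", "orb", "brief")
_BINARY_KINDS = {"brisk", "orb", "akaze", "brief"}


class BackendUnavailableError(RuntimeError):
    """A recognised descriptor backend that this package does not provide."""


class DegenerateGeometryError(RuntimeError):
    """Two-view geometry too degenerate to yield a unique pose."""


@dataclass
class MatchSet:
    keypoints_a: np.ndarray  # (Na, 2) pixel (x, y)
    keypoints_b: np.ndarray  # (Nb, 2)
    kind: str
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def points_a(self) -> np.ndarray:
        return self.keypoints_a[[p[0] for p in self.pairs]].reshape(-1, 2)

    @property
    def points_b(self) -> np.ndarray:
        return self.keypoints_b[[p[1] for p in self.pairs]].reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_correspondences(cls, pts_a, pts_b, kind: str = "synthetic") -> "MatchSet":
        """Build a MatchSet directly from known point correspondences."""
        pts_a = np.asarray(pts_a, dtype=np.float64).reshape(-1, 2)
        pts_b = np.asarray(pts_b, dtype=np.float64).reshape(-1, 2)
        if len(pts_a) != len(pts_b):
            raise ValueError("correspondence lists must have equal length")
        pairs = [(i, i, 0.0) for i in range(len(pts_a))]
        return cls(pts_a, pts_b, kind, pairs)


@dataclass
class PoseEstimate:
    R: np.ndarray  # (3, 3), det +1
    t: np.ndarray  # (3,), unit norm
    inliers: np.ndarray  # boolean mask over the matches used

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)


@dataclass
class EulerAngles:
    """Intrinsic Z-Y-X (yaw, pitch, roll) angles in radians."""

    alpha: float  # yaw, about z
    beta: float  # pitch, about y; in [-pi/2, pi/2]
    gamma: float  # roll, about x
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


@dataclass
class FundamentalResult:
    F: np.ndarray  # (3, 3), rank 2, unit Frobenius norm
    inliers: np.ndarray  # boolean mask over matches
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Euler angles
# ---------------------------------------------------------------------------


def euler_to_rotation(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """R = Rz(alpha) @ Ry(beta) @ Rx(gamma) (intrinsic Z-Y-X)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rx = np.array([[1, 0, 0], [0, cg, -sg], [0, sg, cg]])
    return rz @ ry @ rx


def rotation_to_euler(R: np.ndarray, atol: float = 1e-6) -> EulerAngles:
    """Extract intrinsic Z-Y-X angles; pitch is confined to [-pi/2, pi/2].

    At gimbal lock (|pitch| = pi/2) the yaw/roll split is not unique: roll is
    set to 0, yaw absorbs the free angle, and the result is flagged.
    """
    R = np.asarray(R, dtype=np.float64).reshape(3, 3)
    if (np.abs(R @ R.T - np.eye(3)).max() > atol) or abs(np.linalg.det(R) - 1.0) > atol:
        raise ValueError("input is not a proper rotation matrix")
    sb = -R[2, 0]
    if abs(sb) >= 1.0 - 1e-12:
        beta = np.pi / 2 if sb > 0 else -np.pi / 2
        # R reduces to a single yaw-like rotation; absorb it into alpha
        alpha = np.arctan2(np.sign(sb) * R[1, 2], R[1, 1])
        return EulerAngles(float(alpha), float(beta), 0.0, gimbal_lock=True)
    beta = np.arcsin(sb)
    alpha = np.arctan2(R[1, 0], R[0, 0])
    gamma = np.arctan2(R[2, 1], R[2, 2])
    return EulerAngles(float(alpha), float(beta), float(gamma))


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=np.float64)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


# ---------------------------------------------------------------------------
# Keypoints and matching
# ---------------------------------------------------------------------------


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image @ np.array([0.2125, 0.7154, 0.0721])
    return image


def detect_and_describe(image: np.ndarray, kind: str = "sift"):
    """Detect keypoints and compute descriptors with the requested backend.

    Returns ``(keypoints, descriptors, metric)`` where keypoints are (N, 2)
    pixel ``(x, y)`` coordinates and metric is ``"hamming"`` for binary
    descriptors or ``"euclidean"`` for float ones.  A texture-free image
    yields empty arrays rather than an error.
    """
    from skimage import feature

    kind = kind.lower()
    if kind not in DESCRIPTOR_KINDS:
        raise ValueError(f"unknown descriptor kind {kind!r}; choose from {DESCRIPTOR_KINDS}")
    if kind not in AVAILABLE_KINDS:
        raise BackendUnavailableError(
            f"descriptor backend {kind!r} is not provided by this package; "
            f"available backends: {AVAILABLE_KINDS}"
        )
    gray = _to_gray(image)
    metric = "hamming" if kind in _BINARY_KINDS else "euclidean"
    empty = (np.zeros((0, 2)), np.zeros((0, 0)), metric)

    try:
        if kind == "sift":
            det = feature.SIFT()
            det.detect_and_extract(gray)
            kp = det.keypoints  # (row, col)
            desc = det.descriptors.astype(np.float64)
        elif kind == "orb":
            det = feature.ORB(n_keypoints=1000)
            det.detect_and_extract(gray)
            kp = det.keypoints
            desc = det.descriptors.astype(np.uint8)
        else:  # brief: corner detector + BRIEF description
            corners = feature.corner_peaks(
                feature.corner_harris(gray), min_distance=4, threshold_rel=0.01
            )
            extractor = feature.BRIEF(descriptor_size=256, rng=1)
            extractor.extract(gray, corners)
            kp = corners[extractor.mask]
            desc = extractor.descriptors.astype(np.uint8)
    except RuntimeError:
        # scikit-image raises when no features survive extraction
        return empty
    if len(kp) == 0:
        return empty
    keypoints = np.stack([kp[:, 1], kp[:, 0]], axis=1).astype(np.float64)  # (x, y)
    return keypoints, desc, metric


def match_descriptors(
    keypoints_a, desc_a, keypoints_b, desc_b, metric: str, kind: str = "sift"
) -> MatchSet:
    """Exhaustive nearest-neighbour matching with symmetric cross-check.

    Hamming distance for binary descriptors, L2 for float; matches are sorted
    by ascending distance.
    """
    ms = MatchSet(
        np.asarray(keypoints_a, dtype=np.float64).reshape(-1, 2),
        np.asarray(keypoints_b, dtype=np.float64).reshape(-1, 2),
        kind,
    )
    if len(desc_a) == 0 or len(desc_b) == 0:
        return ms
    a = np.asarray(desc_a)
    b = np.asarray(desc_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("descriptor kinds/sizes do not match")
    if metric == "hamming":
        dist = cdist(a.astype(bool), b.astype(bool), metric="hamming") * a.shape[1]
    else:
        dist = cdist(a.astype(np.float64), b.astype(np.float64), metric="euclidean")
    fwd = dist.argmin(axis=1)
    bwd = dist.argmin(axis=0)
    idx_a = np.flatnonzero(bwd[fwd] == np.arange(len(a)))
    pairs = [(int(i), int(fwd[i]), float(dist[i, fwd[i]])) for i in idx_a]
    pairs.sort(key=lambda p: (p[2], p[0]))
    ms.pairs = pairs
    return ms


# ---------------------------------------------------------------------------
# Fundamental / essential matrices
# ---------------------------------------------------------------------------


def _hartley_normalize(pts: np.ndarray):
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])
    ph = np.column_stack([pts, np.ones(len(pts))]) @ T.T
    return ph, T


def _eight_point(pts_a: np.ndarray, pts_b: np.ndarray) -> np.ndarray:
    """Hartley-normalized 8-point estimate; rank-2, unit-Frobenius F."""
    pa, Ta = _hartley_normalize(pts_a)
    pb, Tb = _hartley_normalize(pts_b)
    A = np.column_stack([
        pb[:, 0] * pa[:, 0], pb[:, 0] * pa[:, 1], pb[:, 0],
        pb[:, 1] * pa[:, 0], pb[:, 1] * pa[:, 1], pb[:, 1],
        pa[:, 0], pa[:, 1], np.ones(len(pa)),
    ])
    _, _, vt = np.linalg.svd(A)
    F = vt[-1].reshape(3, 3)
    u, s, vt2 = np.linalg.svd(F)
    F = u @ np.diag([s[0], s[1], 0.0]) @ vt2
    F = Tb.T @ F @ Ta
    return F / np.linalg.norm(F)


def _sampson_distance(F: np.ndarray, pts_a: np.ndarray, pts_b: np.ndarray) -> np.ndarray:
    pa = np.column_stack([pts_a, np.ones(len(pts_a))])
    pb = np.column_stack([pts_b, np.ones(len(pts_b))])
    Fa = pa @ F.T  # epipolar lines in image b
    Ftb = pb @ F  # epipolar lines in image a
    num = np.einsum("ij,ij->i", pb, Fa) ** 2
    den = Fa[:, 0] ** 2 + Fa[:, 1] ** 2 + Ftb[:, 0] ** 2 + Ftb[:, 1] ** 2
    return num / np.maximum(den, 1e-300)


def estimate_fundamental(
    matches: MatchSet,
    threshold: float = 1.0,
    confidence: float = 0.999,
    max_iters: int = 10_000,
    seed: int = 0,
) -> FundamentalResult:
    """Seeded RANSAC around the normalized 8-point algorithm.

    The Sampson (first-order geometric) distance decides inliers; hypotheses
    are ranked by MSAC-style truncated cost.  The top hypotheses are then
    locally optimized (refit on their consensus set to a fixed point) and the
    basin with the lowest truncated cost wins, which makes the estimate
    effectively independent of the sampling seed on well-textured data.
    ``degenerate`` is flagged when the inliers are essentially collinear or
    the consensus is tiny.
    """
    pts_a, pts_b = matches.points_a, matches.points_b
    n = len(pts_a)
    if n < 8:
        raise ValueError(f"need at least 8 matched pairs, got {n}")
    rng = np.random.default_rng(seed)
    sq_thr = threshold**2
    # adaptive stopping from the inlier ratio, but never below a floor of
    # samples: local optimization below needs a pool of distinct hypotheses
    # or the answer inherits the quirks of the first lucky minimal sample
    min_iters = 500
    top_k = 8
    candidates: list[tuple[float, int, np.ndarray]] = []  # (cost, count, inliers)
    iters_needed = max_iters
    it = 0
    while it < min(max_iters, max(min_iters, iters_needed)):
        sample = rng.choice(n, size=8, replace=False)
        try:
            F = _eight_point(pts_a[sample], pts_b[sample])
        except np.linalg.LinAlgError:
            it += 1
            continue
        d = _sampson_distance(F, pts_a, pts_b)
        inliers = d < sq_thr
        count = int(inliers.sum())
        cost = float(np.minimum(d, sq_thr).sum())  # MSAC-style truncated cost
        if len(candidates) < top_k or cost < candidates[-1][0]:
            candidates.append((cost, count, inliers))
            candidates.sort(key=lambda c: c[0])
            del candidates[top_k:]
            ratio = max(candidates[0][1] / n, 1e-12)
            with np.errstate(divide="ignore"):
                denom = np.log(max(1.0 - ratio**8, 1e-300))
                iters_needed = int(np.ceil(np.log(1.0 - confidence) / denom)) if denom < 0 else max_iters
        it += 1
    if not candidates or candidates[0][1] < 8:
        empty = candidates[0][2] if candidates else np.zeros(n, dtype=bool)
        return FundamentalResult(np.eye(3) / np.sqrt(3), empty, degenerate=True)
    # local optimization: refit each hypothesis on its consensus set to a
    # fixed point, then keep the basin with the lowest truncated cost, so the
    # result depends on the data rather than on one lucky minimal sample
    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    for _, count, inliers in candidates:
        if count < 8:
            continue
        F = _eight_point(pts_a[inliers], pts_b[inliers])
        for _ in range(20):
            new_inliers = _sampson_distance(F, pts_a, pts_b) < sq_thr
            if new_inliers.sum() < 8:
                break
            F = _eight_point(pts_a[new_inliers], pts_b[new_inliers])
            if np.array_equal(new_inliers, inliers):
                break
            inliers = new_inliers
        d = _sampson_distance(F, pts_a, pts_b)
        cost = float(np.minimum(d, sq_thr).sum())
        if best is None or cost < best[0]:
            best = (cost, int(inliers.sum()), inliers, F)
    F, inliers = best[3], best[2]
    degenerate = _is_degenerate_set(pts_a[inliers]) or _is_degenerate_set(pts_b[inliers])
    return FundamentalResult(F, inliers, degenerate=degenerate)


def _is_degenerate_set(pts: np.ndarray) -> bool:
    """Collinear (or near-collinear) point sets cannot constrain F."""
    if len(pts) < 8:
        return True
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] < 1e-8 * max(s[0], 1.0))


def essential_from_fundamental(F: np.ndarray, K: np.ndarray) -> np.ndarray:
    """E = K^T F K, projected onto the essential manifold (sigma, sigma, 0)."""
    K = np.asarray(K, dtype=np.float64).reshape(3, 3)
    if abs(np.linalg.det(K)) < 1e-12:
        raise ValueError("intrinsic matrix K is singular")
    E = K.T @ np.asarray(F, dtype=np.float64) @ K
    u, s, vt = np.linalg.svd(E)
    sigma = (s[0] + s[1]) / 2.0
    return u @ np.diag([sigma, sigma, 0.0]) @ vt


def _triangulate_linear(P1, P2, pts_a, pts_b) -> np.ndarray:
    """Per-pair DLT triangulation; returns (N, 3) world points."""
    out = np.empty((len(pts_a), 3))
    for i, (xa, xb) in enumerate(zip(pts_a, pts_b)):
        A = np.stack([
            xa[0] * P1[2] - P1[0],
            xa[1] * P1[2] - P1[1],
            xb[0] * P2[2] - P2[0],
            xb[1] * P2[2] - P2[1],
        ])
        _, _, vt = np.linalg.svd(A)
        X = vt[-1]
        out[i] = X[:3] / X[3]
    return out


def recover_pose(E: np.ndarray, matches: MatchSet, K: np.ndarray,
                 inliers: np.ndarray | None = None) -> PoseEstimate:
    """Choose among the four (R, t) decompositions of E by cheirality.

    The winner must place a strict majority of triangulated inliers at
    positive depth in both views.  A pure-rotation scene has no usable
    baseline: triangulated rays are nearly parallel, so recovered depths
    blow up relative to the unit translation; that case (and a failed
    cheirality vote) raises :class:`DegenerateGeometryError`.
    """
    pts_a, pts_b = matches.points_a, matches.points_b
    if inliers is not None:
        pts_a, pts_b = pts_a[inliers], pts_b[inliers]
    if len(pts_a) < 1:
        raise ValueError("recover_pose needs at least one inlier pair")
    u, _, vt = np.linalg.svd(E)
    if np.linalg.det(u) < 0:
        u = -u
    if np.linalg.det(vt) < 0:
        vt = -vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    candidates = []
    for R in (u @ W @ vt, u @ W.T @ vt):
        for t in (u[:, 2], -u[:, 2]):
            candidates.append((R, t / np.linalg.norm(t)))
    K = np.asarray(K, dtype=np.float64).reshape(3, 3)
    P1 = K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    best = None
    best_good = -1
    best_depth = np.inf
    for R, t in candidates:
        P2 = K @ np.hstack([R, t[:, None]])
        X = _triangulate_linear(P1, P2, pts_a, pts_b)
        z1 = X[:, 2]
        z2 = (X @ R.T + t)[:, 2]
        good = int(np.sum((z1 > 0) & (z2 > 0)))
        if good > best_good:
            best_good = good
            best = (R, t)
            best_depth = float(np.median(np.abs(z1)))
    if best is None or best_good <= len(pts_a) / 2:
        raise DegenerateGeometryError(
            f"no pose candidate passes cheirality ({best_good}/{len(pts_a)} in front)"
        )
    if best_depth > 1e6:  # scene depth vs unit baseline: parallax-free geometry
        raise DegenerateGeometryError(
            f"near-zero baseline: median triangulated depth {best_depth:.2e} "
            "times the translation scale"
        )
    mask = inliers if inliers is not None else np.ones(len(matches), dtype=bool)
    return PoseEstimate(best[0], best[1], np.asarray(mask, dtype=bool))


def triangulate(matches: MatchSet, K: np.ndarray, pose: PoseEstimate) -> np.ndarray:
    """DLT triangulation from K[I|0] and K[R|t]; drops points behind a camera.

    Returns an (M, 3) point cloud in the first camera's frame (scale follows
    the unit-norm translation).  Raises if every point is dropped.
    """
    pts_a = matches.points_a[pose.inliers]
    pts_b = matches.points_b[pose.inliers]
    K = np.asarray(K, dtype=np.float64).reshape(3, 3)
    P1 = K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    P2 = K @ np.hstack([pose.R, pose.t[:, None]])
    X = _triangulate_linear(P1, P2, pts_a, pts_b)
    z1 = X[:, 2]
    z2 = (X @ pose.R.T + pose.t)[:, 2]
    keep = (z1 > 0) & (z2 > 0)
    if not keep.any():
        raise DegenerateGeometryError("all triangulated points fall behind a camera")
    return X[keep]


def pose_error_metrics(estimated, truth) -> tuple[float, float, float]:
    """(MAE, MSE, RMSE) over flattened Euler-angle lists.

    Angle differences are wrapped to (-pi, pi] before the error is taken, so
    a 179 deg vs -179 deg pair counts as a 2 deg error.
    """
    from .metrics import mae as _mae, mse as _mse, rmse as _rmse

    est = np.concatenate([
        e.as_array() if isinstance(e, EulerAngles) else np.asarray(e, dtype=np.float64).reshape(-1)
        for e in estimated
    ])
    tru = np.concatenate([
        t.as_array() if isinstance(t, EulerAngles) else np.asarray(t, dtype=np.float64).reshape(-1)
        for t in truth
    ])
    if est.shape != tru.shape:
        raise ValueError("estimated and truth angle lists differ in length")
    diff = wrap_angle(est - tru)
    zeros = np.zeros_like(diff)
    return _mae(zeros, diff), _mse(zeros, diff), _rmse(zeros, diff)
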