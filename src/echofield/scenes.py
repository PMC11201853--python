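"""Scenes, poses and coordinate transforms.

A scene is an ordered collection of point scatterers (Huygens approximation:
extended surfaces are represented by dense point samplings of their surface).
A pose is the 6-DOF state of the echolocating sensor: position in meters and
intrinsic yaw(Z)-pitch(Y)-roll(X) Euler angles in radians.  The body frame is
right-handed with forward = +X, left = +Y, up = +Z.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

__all__ = [
    "Pose",
    "Scatterer",
    "Scene",
    "pose_sphere",
    "body_to_world",
    "world_to_body",
    "build_three_spheres",
    "build_ua_scene",
    "build_leaf_scene",
    "load_scene",
    "save_scene",
    "scene_from_stl",
    "load_poses_csv",
    "save_poses_csv",
    "fibonacci_sphere",
]

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def _wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    a = float(a) % (2.0 * math.pi)
    if a > math.pi:
        a -= 2.0 * math.pi
    return a


@dataclass(frozen=True)
class Pose:
    """Sensor pose: position (m) and yaw/pitch/roll Euler angles (rad).

    The rotation matrix is ``Rz(alpha) @ Ry(beta) @ Rx(gamma)`` (intrinsic
    yaw-pitch-roll); it maps body-frame vectors into the world frame.
    """

    position: np.ndarray
    orientation: np.ndarray  # (alpha, beta, gamma) = yaw, pitch, roll

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        ori = np.asarray(self.orientation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(ori))):
            raise ValueError("pose position/orientation must be finite")
        ori = np.array([_wrap_angle(a) for a in ori])
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori)

    @property
    def rotation(self) -> np.ndarray:
        """3x3 body->world rotation matrix (orthonormal)."""
        a, b, g = self.orientation
        ca, sa = math.cos(a), math.sin(a)
        cb, sb = math.cos(b), math.sin(b)
        cg, sg = math.cos(g), math.sin(g)
        rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rx = np.array([[1, 0, 0], [0, cg, -sg], [0, sg, cg]])
        return rz @ ry @ rx

    @property
    def forward(self) -> np.ndarray:
        """World-frame unit vector of the body +X (forward) axis."""
        return self.rotation[:, 0]

    def as_row(self) -> np.ndarray:
        return np.concatenate([self.position, self.orientation])

    @staticmethod
    def from_row(row) -> "Pose":
        row = np.asarray(row, dtype=float).reshape(6)
        return Pose(row[:3], row[3:])

    @staticmethod
    def looking_at(position, target) -> "Pose":
        """Pose at ``position`` with the forward axis pointing at ``target``."""
        position = np.asarray(position, dtype=float).reshape(3)
        d = np.asarray(target, dtype=float).reshape(3) - position
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("pose position coincides with look-at target")
        d = d / n
        alpha = math.atan2(d[1], d[0])
        beta = -math.asin(np.clip(d[2], -1.0, 1.0))
        return Pose(position, np.array([alpha, beta, 0.0]))


@dataclass(frozen=True)
class Scatterer:
    """Point reflector: position p (m), scalar gain, optional spectral /
    directional reflectivity.

    ``spectrum`` is an optional complex per-band-bin reflection table; when
    absent the reflector is spectrally flat with amplitude ``gain``.  An
    optional cosine-power lobe (``lobe_axis``, ``lobe_exponent``) makes the
    reflectivity depend on the incidence direction eta (unit vector from the
    sensor toward the scatterer): the directional factor is
    ``max(0, -eta . axis)**exponent`` so a lobe facing the sensor reflects
    strongest.
    """

    position: np.ndarray
    gain: float = 1.0
    spectrum: np.ndarray | None = None
    lobe_axis: np.ndarray | None = None
    lobe_exponent: float = 1.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        object.__setattr__(self, "position", pos)
        if self.gain < 0:
            raise ValueError("scatterer gain must be >= 0")
        if self.spectrum is not None:
            spec = np.asarray(self.spectrum, dtype=complex).ravel()
            object.__setattr__(self, "spectrum", spec)
        if self.lobe_axis is not None:
            ax = np.asarray(self.lobe_axis, dtype=float).reshape(3)
            n = np.linalg.norm(ax)
            if n == 0:
                raise ValueError("lobe_axis must be nonzero")
            object.__setattr__(self, "lobe_axis", ax / n)

    def reflectivity(self, eta: np.ndarray, band_freqs: np.ndarray) -> np.ndarray:
        """Complex reflection spectrum H_p(eta, w) on the band bins."""
        if self.spectrum is not None:
            if self.spectrum.size != band_freqs.size:
                raise ValueError(
                    f"spectrum length {self.spectrum.size} != band bins {band_freqs.size}"
                )
            h = self.gain * self.spectrum.astype(complex)
        else:
            h = self.gain * np.ones(band_freqs.size, dtype=complex)
        if self.lobe_axis is not None:
            c = max(0.0, -float(np.dot(eta, self.lobe_axis)))
            h = h * (c ** self.lobe_exponent)
        return h


@dataclass
class Scene:
    """Named, bounded collection of point scatterers."""

    scatterers: list
    name: str = "scene"
    bounds: np.ndarray | None = None  # [[xmin,ymin,zmin],[xmax,ymax,zmax]]

    def __post_init__(self):
        if len(self.scatterers) < 1:
            raise ValueError("scene must contain at least one scatterer")
        pos = self.positions
        if self.bounds is None:
            lo = pos.min(axis=0) - 1e-6
            hi = pos.max(axis=0) + 1e-6
            self.bounds = np.stack([lo, hi])
        else:
            self.bounds = np.asarray(self.bounds, dtype=float).reshape(2, 3)
            if np.any(pos < self.bounds[0] - 1e-12) or np.any(pos > self.bounds[1] + 1e-12):
                raise ValueError("scene bounds do not contain every scatterer")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.scatterers], dtype=float)

    @property
    def center(self) -> np.ndarray:
        return self.bounds.mean(axis=0)

    @property
    def extent(self) -> float:
        """Radius of the bounding sphere about the bounds center."""
        return float(np.linalg.norm(self.positions - self.center, axis=1).max())

    def __len__(self) -> int:
        return len(self.scatterers)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def body_to_world(pose: Pose, points) -> np.ndarray:
    """Map body-frame points to world coordinates (rotate then translate)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts @ pose.rotation.T + pose.position


def world_to_body(pose: Pose, points) -> np.ndarray:
    """Inverse of :func:`body_to_world`."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - pose.position) @ pose.rotation


# ---------------------------------------------------------------------------
# quasi-uniform sphere sampling
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int, phase: float = 0.0) -> np.ndarray:
    """n quasi-uniform unit vectors on the full sphere (Fibonacci lattice).

    ``phase`` rotates the spiral about Z; it is the only stochastic degree of
    freedom (derived from a seed by callers), so sampling stays deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    th = GOLDEN_ANGLE * i + phase
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def pose_sphere(n: int, radius: float, center=(0.0, 0.0, 0.0), seed: int = 0) -> list:
    """n poses on a sphere about ``center``, each facing the center.

    Positions form a Fibonacci spiral lattice (quasi-uniform, deterministic);
    the seed only sets the spiral's azimuthal phase.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center, dtype=float).reshape(3)
    phase = float(np.random.default_rng(seed).uniform(0.0, 2.0 * math.pi))
    dirs = fibonacci_sphere(n, phase=phase)
    return [Pose.looking_at(center + radius * d, center) for d in dirs]


# ---------------------------------------------------------------------------
# builtin scenes
# ---------------------------------------------------------------------------

def _sphere_surface(center, radius: float, n_points: int, phase: float = 0.0) -> np.ndarray:
    return np.asarray(center, dtype=float) + radius * fibonacci_sphere(n_points, phase)


def build_three_spheres(
    diameter: float = 0.03,
    spacing: float = 0.06,
    points_per_sphere: int = 150,
    seed: int = 0,
    gain: float = 1.0,
) -> Scene:
    """Three spheres in an L-shaped configuration, surfaces sampled as points.

    Default diameter 3 cm; centers at the corner, +X arm and +Z arm of an L.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if points_per_sphere < 4:
        raise ValueError("points_per_sphere must be >= 4")
    phase = float(np.random.default_rng(seed).uniform(0.0, 2.0 * math.pi))
    centers = np.array(
        [[0.0, 0.0, 0.0], [spacing, 0.0, 0.0], [0.0, 0.0, spacing]]
    )
    centers -= centers.mean(axis=0)
    scatterers = []
    for c in centers:
        for p in _sphere_surface(c, diameter / 2.0, points_per_sphere, phase):
            scatterers.append(Scatterer(p, gain=gain))
    lo = centers.min(axis=0) - diameter
    hi = centers.max(axis=0) + diameter
    return Scene(scatterers, name="three-spheres-L", bounds=np.stack([lo, hi]))


def _ua_letter_centers(scale: float) -> np.ndarray:
    """19 sphere centers on the strokes of the letters 'UA' (X-Z plane)."""
    # U: two verticals of 3 + bottom of 3 (shared corners) = 9 centers
    u = [
        (0.0, 2.0), (0.0, 1.0), (0.0, 0.0),
        (1.0, 0.0),
        (2.0, 0.0), (2.0, 1.0), (2.0, 2.0),
        (0.5, 0.0), (1.5, 0.0),
    ]
    # A: two slanted legs + crossbar = 10 centers
    a = [
        (3.0, 0.0), (3.25, 1.0), (3.5, 2.0),
        (3.75, 1.0), (4.0, 0.0),
        (3.125, 0.5), (3.875, 0.5),
        (3.375, 1.5), (3.625, 1.5),
        (3.5, 0.98),
    ]
    pts = np.array(u + a, dtype=float)
    pts -= pts.mean(axis=0)
    xz = pts * scale
    return np.column_stack([xz[:, 0], np.zeros(len(xz)), xz[:, 1]])


def build_ua_scene(
    diameter: float = 0.02,
    scale: float = 0.04,
    points_per_sphere: int = 60,
    seed: int = 0,
    gain: float = 1.0,
) -> Scene:
    """19 spheres arranged to form the letters 'UA' in the X-Z plane."""
    phase = float(np.random.default_rng(seed).uniform(0.0, 2.0 * math.pi))
    centers = _ua_letter_centers(scale)
    scatterers = []
    for c in centers:
        for p in _sphere_surface(c, diameter / 2.0, points_per_sphere, phase):
            scatterers.append(Scatterer(p, gain=gain))
    lo = centers.min(axis=0) - diameter
    hi = centers.max(axis=0) + diameter
    sc = Scene(scatterers, name="ua-letters", bounds=np.stack([lo, hi]))
    sc.cluster_centers = centers
    return sc


def build_leaf_scene(
    with_insect: bool = False,
    leaf_radius: float = 0.04,
    n_leaf_points: int = 400,
    insect_location=(0.012, 0.008, 0.004),
    insect_radius: float = 0.006,
    n_insect_points: int = 60,
    insect_gain: float = 3.0,
    seed: int = 0,
) -> Scene:
    """Disc-shaped leaf analog in the X-Y plane, optionally with a compact
    high-gain scatterer cluster (insect analog) perched on it.

    The leaf is a planar sunflower-lattice point sampling of a disc; the
    insect is a small dense sphere-surface cluster with higher gain, centred
    at ``insect_location`` (on-leaf by default, slightly above the plane).
    """
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    i = np.arange(n_leaf_points, dtype=float)
    r = leaf_radius * np.sqrt((i + 0.5) / n_leaf_points)
    th = GOLDEN_ANGLE * i + phase
    leaf = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n_leaf_points)])
    scatterers = [Scatterer(p, gain=1.0) for p in leaf]
    lo = np.array([-leaf_radius, -leaf_radius, -0.01])
    hi = np.array([leaf_radius, leaf_radius, 0.02])
    insect_location = np.asarray(insect_location, dtype=float)
    if with_insect:
        for p in _sphere_surface(insect_location, insect_radius, n_insect_points, phase):
            scatterers.append(Scatterer(p, gain=insect_gain))
        hi = np.maximum(hi, insect_location + 2 * insect_radius)
        lo = np.minimum(lo, insect_location - 2 * insect_radius)
    name = "leaf-with-insect" if with_insect else "leaf"
    sc = Scene(scatterers, name=name, bounds=np.stack([lo, hi]))
    sc.insect_center = insect_location if with_insect else None
    return sc


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_scene(scene: Scene, path) -> None:
    """Write a scene to JSON (positions in meters)."""
    rec = {"name": scene.name, "bounds": scene.bounds.tolist(), "scatterers": []}
    for s in scene.scatterers:
        d = {"xyz": s.position.tolist(), "gain": float(s.gain)}
        if s.spectrum is not None:
            d["spectrum_real"] = np.real(s.spectrum).tolist()
            d["spectrum_imag"] = np.imag(s.spectrum).tolist()
        if s.lobe_axis is not None:
            d["lobe_axis"] = s.lobe_axis.tolist()
            d["lobe_exponent"] = float(s.lobe_exponent)
        rec["scatterers"].append(d)
    Path(path).write_text(json.dumps(rec))


def load_scene(path) -> Scene:
    """Load a scene from JSON, validating the schema field by field."""
    try:
        rec = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed scene file {path}: {e}") from e
    if "scatterers" not in rec:
        raise ValueError(f"malformed scene file {path}: missing field 'scatterers'")
    scatterers = []
    for i, d in enumerate(rec["scatterers"]):
        if "xyz" not in d:
            raise ValueError(f"malformed scene file {path}: scatterer {i} missing field 'xyz'")
        spec = None
        if "spectrum_real" in d:
            spec = np.asarray(d["spectrum_real"], dtype=float) + 1j * np.asarray(
                d.get("spectrum_imag", np.zeros(len(d["spectrum_real"]))), dtype=float
            )
        scatterers.append(
            Scatterer(
                np.asarray(d["xyz"], dtype=float),
                gain=float(d.get("gain", 1.0)),
                spectrum=spec,
                lobe_axis=d.get("lobe_axis"),
                lobe_exponent=float(d.get("lobe_exponent", 1.0)),
            )
        )
    bounds = np.asarray(rec["bounds"], dtype=float) if "bounds" in rec else None
    return Scene(scatterers, name=rec.get("name", "scene"), bounds=bounds)


def scene_from_stl(path, n_samples: int = 1000, seed: int = 0, gain: float = 1.0,
                   name: str | None = None) -> Scene:
    """Convert an STL mesh to point scatterers by area-weighted surface
    sampling (seeded)."""
    import trimesh

    mesh = trimesh.load_mesh(str(path))
    pts, _ = trimesh.sample.sample_surface(mesh, n_samples, seed=seed)
    scatterers = [Scatterer(np.asarray(p, dtype=float), gain=gain) for p in pts]
    return Scene(scatterers, name=name or Path(path).stem)


def save_poses_csv(poses, path) -> None:
    rows = np.array([p.as_row() for p in poses])
    header = "x,y,z,alpha,beta,gamma"
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


def load_poses_csv(path) -> list:
    with open(path) as f:
        header = f.readline().strip().lower().replace(" ", "")
    if header != "x,y,z,alpha,beta,gamma":
        raise ValueError(f"poses CSV {path}: expected header x,y,z,alpha,beta,gamma")
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return [Pose.from_row(r) for r in rows]
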