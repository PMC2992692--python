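"""Parametric model of an average-sized human stomach.

The stomach is built the way anatomical tube organs are classically
reconstructed from a planar silhouette: the midplane outline (the plane that
bisects the organ through its lesser and greater curvatures) is traced as two
spline branches, each branch is resampled to the same number of points at
prescribed normalized arclengths, corresponding point pairs are joined by
segments, and each segment's midpoint and half-length define an auxiliary
circle.  The ordered stack of circles is lofted into a closed,
mirror-symmetric triangulated surface (with a spherical dome closing the
fundus) whose characteristic dimensions — greater-curvature length, widest
width, pyloric ring diameter, enclosed volume — can then be measured.

The default pairing schedule is non-uniform: the chords tilt progressively
from the pyloric ring toward the cardia, exactly as the auxiliary circles of
image-derived stomach models fan in the corpus and fundus.  The tilt is what
makes a horizontally translating contraction wave indent the greater
curvature faster than the lesser one; with uniform (equal-arclength)
pairing, the ratio of wave speeds along the two curvatures degenerates to
the ratio of branch lengths regardless of the outline shape.

Conventions
-----------
* Units are centimeters throughout this module.
* The symmetry plane is ``z = 0``; the outline lives in the x-y plane.
* The x axis is horizontal with the pylorus at the largest x; antral
  contraction waves (see :mod:`gastroflow.motility`) propagate toward +x.
* Section index 0 is the pyloric ring; the last section carries the fundus
  dome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from scipy.interpolate import CubicSpline, PchipInterpolator


class GeometryError(ValueError):
    """Raised when an outline or loft cannot be constructed."""


_DOME_ARC_POINTS = 16  # midplane discretization of the fundus dome trace


# --------------------------------------------------------------------------
# Default shape
#
# The published silhouette this family of models descends from was never
# released as coordinates, so the default outline is generated from a compact
# analytic description in the centerline frame: the tangent angle theta, the
# circle radius rho and the chord tilt lambda (rotation of the pairing chord
# from the local normal toward the proximal tangent), each a monotone-cubic
# interpolant over normalized centerline arclength.  The frozen knots below
# were calibrated once, by least squares on the quantities computed through
# the actual construction pipeline, so that the greater curvature measures
# 34 cm, the widest section 10 cm, the pyloric ring 1.2 cm and the capacity
# 0.9 L, and so that a wave translating horizontally at 2.3 mm/s from the
# point 15 cm proximal of the pylorus (along the centerline) dies at the
# pylorus after its 58-s life with mean speeds of 4.6 mm/s along the greater
# and 2.1 mm/s along the lesser curvature (maximum 8.0 mm/s).
# --------------------------------------------------------------------------

_DEFAULT_PROFILE = {
    # knot positions are in normalized centerline arclength (pylorus -> fundus)
    "theta_knots": ((0.0, 0.08, 0.18, 0.30, 0.45, 0.60, 0.78, 1.0),
                    (231.77, 207.312, 191.217, 168.118, 149.782, 127.871, 112.017, 96.99)),
    "radius_knots": ((0.0, 0.10, 0.22, 0.38, 0.55, 0.775, 0.87, 1.0),
                     (0.6, 2.5974, 1.4, 4.5993, 3.7043, 5.0, 4.6412, 4.3501)),
    "tilt_knots": ((0.0, 0.10, 0.20, 0.32, 0.45, 0.58, 0.72, 0.87, 1.0),
                   (7.541, 10.901, 34.983, 23.293, 33.87, 43.691, 52.678, 52.353, 57.227)),
    "centerline_length": 22.2696,
}


def _profile_curves(profile=None, n_dense: int = 4001):
    """Dense greater/lesser branch curves and their arclength tables."""
    prof = dict(_DEFAULT_PROFILE)
    if profile:
        prof.update(profile)
    L_c = prof["centerline_length"]
    sig = np.linspace(0.0, 1.0, n_dense)
    s = sig * L_c
    theta = np.radians(PchipInterpolator(*prof["theta_knots"])(sig))
    rho = PchipInterpolator(*prof["radius_knots"])(sig)
    tilt = np.radians(PchipInterpolator(*prof["tilt_knots"])(sig))
    x = np.concatenate(([0.0], np.cumsum((np.cos(theta)[1:] + np.cos(theta)[:-1]) / 2 * np.diff(s))))
    y = np.concatenate(([0.0], np.cumsum((np.sin(theta)[1:] + np.sin(theta)[:-1]) / 2 * np.diff(s))))
    c = np.column_stack([x, y])
    ang_e = theta + np.pi / 2 - tilt  # chord direction: left normal tilted proximally
    e = np.column_stack([np.cos(ang_e), np.sin(ang_e)])
    g = c + rho[:, None] * e
    l = c - rho[:, None] * e
    S_g = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(g, axis=0), axis=1))))
    S_l = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(l, axis=0), axis=1))))
    return dict(s=s, c=c, g=g, l=l, S_g=S_g, S_l=S_l)


def make_default_control_points(profile=None, n_ctrl: int = 81, n_sections: int = 60):
    """Default control polylines and the calibrated pairing schedule.

    Returns ``(lesser_ctrl, greater_ctrl, pairing)`` where ``pairing`` is an
    ``(n_sections, 2)`` array of normalized-arclength fractions
    ``(greater, lesser)`` at which the branches are resampled before
    index-pairing.  Sections are stationed at equal centerline arclength.
    """
    d = _profile_curves(profile)
    idx = np.linspace(0, len(d["s"]) - 1, n_ctrl).round().astype(int)
    s_i = np.linspace(0.0, d["s"][-1], n_sections)
    u = np.interp(s_i, d["s"], d["S_g"]) / d["S_g"][-1]
    v = np.interp(s_i, d["s"], d["S_l"]) / d["S_l"][-1]
    pairing = np.column_stack([u, v])
    return d["l"][idx], d["g"][idx], pairing


@dataclass
class GeometryParams:
    """Inputs of the outline/loft construction.

    ``lesser_curve_ctrl`` and ``greater_curve_ctrl`` are planar control
    polylines (cm), ordered from the pylorus toward the fundus; a cubic
    spline is passed through them.  ``pairing`` optionally prescribes the
    normalized-arclength fractions ``(greater, lesser)`` at which the two
    branches are resampled before index-pairing; ``None`` means uniform
    (equal normalized arclength on both branches).  ``pyloric_diameter``
    documents the ring diameter implied by the first control-point pair and
    is validated against it.  ``esophageal_cap`` selects the closure rule at
    the proximal end: ``"dome"`` (a spherical cap over the last auxiliary
    circle, the default) or ``"flat"`` (a planar fan).
    """

    lesser_curve_ctrl: np.ndarray
    greater_curve_ctrl: np.ndarray
    n_sections: int = 60
    pyloric_diameter: float = 1.2
    esophageal_cap: str = "dome"
    pairing: np.ndarray | None = None
    circle_resolution: int = 64

    def __post_init__(self):
        self.lesser_curve_ctrl = np.asarray(self.lesser_curve_ctrl, float)
        self.greater_curve_ctrl = np.asarray(self.greater_curve_ctrl, float)
        if self.n_sections < 10:
            raise GeometryError("n_sections must be at least 10")
        if self.pyloric_diameter <= 0:
            raise GeometryError("pyloric_diameter must be positive")
        if self.esophageal_cap not in ("dome", "flat"):
            raise GeometryError(f"unknown esophageal cap rule {self.esophageal_cap!r}")
        for name in ("lesser_curve_ctrl", "greater_curve_ctrl"):
            pts = getattr(self, name)
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
                raise GeometryError(f"{name} must be an (n>=3, 2) array")
            if not shapely.LineString(pts).is_simple:
                raise GeometryError(f"{name} is self-intersecting")
        if self.pairing is not None:
            self.pairing = np.asarray(self.pairing, float)
            if self.pairing.shape != (self.n_sections, 2):
                raise GeometryError("pairing must have shape (n_sections, 2)")
            if np.any(np.diff(self.pairing, axis=0) <= 0) or self.pairing[0].any() \
                    or not np.allclose(self.pairing[-1], 1.0):
                raise GeometryError("pairing fractions must increase strictly from 0 to 1")


def default_params(**overrides) -> GeometryParams:
    """The calibrated average-stomach parameters (see module docstring)."""
    n_sections = overrides.pop("n_sections", 60)
    lesser, greater, pairing = make_default_control_points(n_sections=n_sections)
    return GeometryParams(lesser_curve_ctrl=lesser, greater_curve_ctrl=greater,
                          n_sections=n_sections, pairing=pairing, **overrides)


def tube_params(length=10.0, radius=1.0, n_sections=20, **overrides) -> GeometryParams:
    """A straight horizontal tube: two parallel branches of equal length.

    Degenerate geometry used as an analytic fixture: all sections have the
    given radius and collinear centers, and both curvature branches project
    onto the x axis, so a horizontally translating wave moves at identical
    speed along either branch.
    """
    overrides.setdefault("esophageal_cap", "flat")
    x = np.linspace(length, 0.0, max(n_sections, 4))  # pylorus at larger x
    greater = np.column_stack([x, np.full_like(x, -radius)])
    lesser = np.column_stack([x, np.full_like(x, radius)])
    return GeometryParams(
        lesser_curve_ctrl=lesser,
        greater_curve_ctrl=greater,
        n_sections=n_sections,
        pyloric_diameter=2 * radius,
        **overrides,
    )


# --------------------------------------------------------------------------
# Outline
# --------------------------------------------------------------------------


@dataclass
class MidplaneOutline:
    """Closed J-shaped midplane outline with tagged branches.

    Both branches hold ``n`` resampled points, index 0 at the pylorus.  The
    closed polyline is ``greater + cap arc + reversed(lesser)`` plus the
    pyloric ring edge; ``cap_arc`` is empty for a flat esophageal closure.
    """

    greater: np.ndarray
    lesser: np.ndarray
    cap_arc: np.ndarray

    @property
    def n(self) -> int:
        return len(self.greater)

    @property
    def closed_polyline(self) -> np.ndarray:
        return np.vstack([self.greater, self.cap_arc, self.lesser[::-1], self.greater[:1]])

    def branch_length(self, branch: str) -> float:
        return float(polyline_length(getattr(self, branch)))


def polyline_length(points: np.ndarray) -> float:
    """Total length of an open polyline."""
    points = np.asarray(points, float)
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _resample_at_fractions(ctrl: np.ndarray, fractions: np.ndarray, dense: int = 4000) -> np.ndarray:
    """Cubic spline through ``ctrl``, sampled at normalized arclengths."""
    ctrl = np.asarray(ctrl, float)
    chord = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))))
    if np.any(np.diff(chord) <= 0):
        raise GeometryError("coincident consecutive control points")
    spline = CubicSpline(chord, ctrl, axis=0)
    t = np.linspace(0, chord[-1], dense)
    pts = spline(t)
    s = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))))
    target = np.asarray(fractions, float) * s[-1]
    return np.column_stack([np.interp(target, s, pts[:, 0]), np.interp(target, s, pts[:, 1])])


def _cap_arc(g_end: np.ndarray, l_end: np.ndarray, rule: str,
             proximal_dir: np.ndarray) -> np.ndarray:
    """Midplane trace of the esophageal closure between the branch ends.

    ``proximal_dir`` orients the dome away from the stomach body (it is the
    local direction of centerline travel at the last section).
    """
    if rule == "flat":
        return np.empty((0, 2))
    center = (g_end + l_end) / 2
    radius = float(np.linalg.norm(g_end - l_end)) / 2
    u = (g_end - center) / radius
    n2d = np.array([-u[1], u[0]])
    if np.dot(n2d, proximal_dir) < 0:
        n2d = -n2d
    alpha = np.linspace(0, np.pi, _DOME_ARC_POINTS + 2)[1:-1]
    return center + radius * (np.cos(alpha)[:, None] * u + np.sin(alpha)[:, None] * n2d)


def build_outline(params: GeometryParams) -> MidplaneOutline:
    """Construct the resampled midplane outline from the control polylines."""
    n = params.n_sections
    if params.pairing is None:
        frac_g = frac_l = np.linspace(0.0, 1.0, n)
    else:
        frac_g, frac_l = params.pairing[:, 0], params.pairing[:, 1]
    greater = _resample_at_fractions(params.greater_curve_ctrl, frac_g)
    lesser = _resample_at_fractions(params.lesser_curve_ctrl, frac_l)
    centers = (greater + lesser) / 2
    arc = _cap_arc(greater[-1], lesser[-1], params.esophageal_cap,
                   proximal_dir=centers[-1] - centers[-3])
    outline = MidplaneOutline(greater=greater, lesser=lesser, cap_arc=arc)
    ring = shapely.LinearRing(outline.closed_polyline[:-1])
    if not ring.is_simple:
        raise GeometryError("outline is self-intersecting")
    ring_diam = float(np.linalg.norm(greater[0] - lesser[0]))
    if abs(ring_diam - params.pyloric_diameter) > 0.25 * params.pyloric_diameter:
        raise GeometryError(
            f"control points imply a pyloric ring of {ring_diam:.3g} cm, "
            f"inconsistent with pyloric_diameter={params.pyloric_diameter:g} cm"
        )
    return outline


# --------------------------------------------------------------------------
# Cross sections and loft
# --------------------------------------------------------------------------


@dataclass
class CrossSection:
    """One auxiliary circle of the lofting frame."""

    index: int
    center: np.ndarray  # (3,), in the z=0 plane
    radius: float
    normal: np.ndarray  # (3,) unit vector, in-plane, pointing proximally
    arclength_s: float  # centerline distance from the pylorus
    in_plane_dir: np.ndarray = field(default=None, repr=False)  # center->greater unit


def build_cross_sections(outline: MidplaneOutline, n_sections: int | None = None) -> list[CrossSection]:
    """Pair branch points by index and turn each chord into a circle.

    Section ``i`` joins greater point ``i`` to lesser point ``i``; its circle
    is centered at the chord midpoint with radius half the chord length, in
    the plane spanned by the chord and the out-of-plane axis (i.e. the circle
    normal is perpendicular to the chord within the construction plane).
    """
    if n_sections is not None and n_sections != outline.n:
        raise GeometryError("outline was resampled to a different section count")
    g, l = outline.greater, outline.lesser
    chords = g - l
    radii = np.linalg.norm(chords, axis=1) / 2
    if np.any(radii <= 1e-12):
        raise GeometryError("zero-length pairing segment (degenerate section)")
    centers2d = (g + l) / 2
    u = chords / (2 * radii[:, None])  # center -> greater edge

    sections = []
    s = 0.0
    for i in range(outline.n):
        if i > 0:
            s += float(np.linalg.norm(centers2d[i] - centers2d[i - 1]))
        # in-plane normal to the chord, oriented toward the next center
        n2d = np.array([-u[i, 1], u[i, 0]])
        ref = centers2d[min(i + 1, outline.n - 1)] - centers2d[max(i - 1, 0)]
        if np.dot(n2d, ref) < 0:
            n2d = -n2d
        sections.append(
            CrossSection(
                index=i,
                center=np.array([centers2d[i, 0], centers2d[i, 1], 0.0]),
                radius=float(radii[i]),
                normal=np.array([n2d[0], n2d[1], 0.0]),
                arclength_s=s,
                in_plane_dir=np.array([u[i, 0], u[i, 1], 0.0]),
            )
        )
    return sections


def ring_vertices(sections, radii=None, resolution: int = 64, cap: str = "dome"):
    """Vertex rings of the loft and the end-cap apex points.

    Returns ``(rings, apex0, apex1)``: rings have shape
    ``(n_rings, resolution, 3)``; ``apex1`` is the fundus apex (the dome tip
    for the spherical cap, the last ring center for a flat cap).  Each circle
    is sampled at angles ``2*pi*k/resolution`` with angle 0 on the
    greater-curvature edge and angle pi on the lesser one, so the sampling is
    symmetric under ``z -> -z`` (mirror symmetry maps vertices to vertices).

    With ``cap="dome"``, spherical-cap rings generated from the last section
    are appended: the dome scales with the last section's radius, so any
    deformation of that section carries the dome with it.
    """
    if radii is None:
        radii = np.array([sec.radius for sec in sections])
    centers = np.array([sec.center for sec in sections])
    u = np.array([sec.in_plane_dir for sec in sections])
    if cap == "dome":
        n_arc = _DOME_ARC_POINTS // 2
        chi = np.pi / 2 * np.arange(1, n_arc) / n_arc
        r_last = radii[-1]
        nrm = sections[-1].normal
        centers = np.vstack([centers, centers[-1] + r_last * np.sin(chi)[:, None] * nrm])
        radii = np.concatenate([radii, r_last * np.cos(chi)])
        u = np.vstack([u, np.repeat(u[-1:], len(chi), axis=0)])
        apex1 = sections[-1].center + r_last * nrm
    elif cap == "flat":
        apex1 = centers[-1]
    else:
        raise GeometryError(f"unknown cap rule {cap!r}")
    phi = 2 * np.pi * np.arange(resolution) / resolution
    zhat = np.array([0.0, 0.0, 1.0])
    rings = (
        centers[:, None, :]
        + radii[:, None, None] * np.cos(phi)[None, :, None] * u[:, None, :]
        + radii[:, None, None] * np.sin(phi)[None, :, None] * zhat[None, None, :]
    )
    return rings, centers[0], apex1


def _loft_arrays(rings: np.ndarray, apex0: np.ndarray, apex1: np.ndarray):
    """Vertices and triangle indices of the capped loft (vectorized)."""
    n, m, _ = rings.shape
    verts = rings.reshape(n * m, 3)
    k = np.arange(m)
    kn = (k + 1) % m
    tris = []
    for i in range(n - 1):
        a = i * m + k
        b = i * m + kn
        c = (i + 1) * m + k
        d = (i + 1) * m + kn
        tris.append(np.column_stack([a, b, d]))
        tris.append(np.column_stack([a, d, c]))
    c0 = n * m
    c1 = n * m + 1
    verts = np.vstack([verts, apex0, apex1])
    tris.append(np.column_stack([np.full(m, c0), kn, k]))
    base = (n - 1) * m
    tris.append(np.column_stack([np.full(m, c1), base + k, base + kn]))
    return verts, np.vstack(tris)


def loft_volume(rings: np.ndarray, apex0: np.ndarray, apex1: np.ndarray) -> float:
    """Enclosed volume (cm^3) of the capped loft, by the divergence theorem.

    Fast path used by the motility volume-conservation solver; agrees with
    ``trimesh``'s volume on the same triangulation.
    """
    verts, tris = _loft_arrays(rings, apex0, apex1)
    p0, p1, p2 = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    vol = np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0
    return abs(float(vol))


def loft_surface(sections, resolution: int = 64, cap: str = "dome") -> trimesh.Trimesh:
    """Loft the auxiliary circles into a watertight triangulated surface."""
    if len(sections) < 2:
        raise GeometryError("need at least two sections to loft")
    rings, apex0, apex1 = ring_vertices(sections, resolution=resolution, cap=cap)
    # fold-over guards: centers must advance monotonically and adjacent
    # chords (the circles' midplane traces) must not cross
    centers = np.array([s.center for s in sections])
    axes = np.diff(centers, axis=0)
    if np.any(np.einsum("ik,ik->i", axes[:-1], axes[1:]) <= 0):
        raise GeometryError("section centers reverse; loft would fold over")
    for a, b in zip(sections[:-1], sections[1:]):
        ca, ra, ua = a.center[:2], a.radius, a.in_plane_dir[:2]
        cb, rb, ub = b.center[:2], b.radius, b.in_plane_dir[:2]
        seg_a = shapely.LineString([ca - ra * ua, ca + ra * ua])
        seg_b = shapely.LineString([cb - rb * ub, cb + rb * ub])
        if seg_a.intersects(seg_b):
            raise GeometryError("adjacent circles intersect; loft would fold over")
    verts, tris = _loft_arrays(rings, apex0, apex1)
    mesh = trimesh.Trimesh(vertices=verts, faces=tris, process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GeometryError("lofted surface is not watertight")
    return mesh


@dataclass
class StomachGeometry:
    """The constructed stomach: outline, circle frame, surface, centerline."""

    params: GeometryParams
    midplane_outline: MidplaneOutline
    sections: list[CrossSection]
    surface: trimesh.Trimesh

    @property
    def centerline(self) -> np.ndarray:
        """(n, 3) section centers, ordered from the pylorus."""
        return np.array([s.center for s in self.sections])

    @property
    def arclengths(self) -> np.ndarray:
        return np.array([s.arclength_s for s in self.sections])

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.sections])

    @property
    def branch_fractions(self) -> np.ndarray:
        """(n, 2) normalized arclength of each section on (greater, lesser)."""
        if self.params.pairing is not None:
            return self.params.pairing
        f = np.linspace(0.0, 1.0, len(self.sections))
        return np.column_stack([f, f])


def build_geometry(params: GeometryParams | None = None) -> StomachGeometry:
    params = params or default_params()
    outline = build_outline(params)
    sections = build_cross_sections(outline)
    surface = loft_surface(sections, resolution=params.circle_resolution,
                           cap=params.esophageal_cap)
    return StomachGeometry(params=params, midplane_outline=outline, sections=sections, surface=surface)


# --------------------------------------------------------------------------
# Measurement
# --------------------------------------------------------------------------


def compute_volume(geometry: StomachGeometry | trimesh.Trimesh) -> float:
    """Enclosed volume in liters, by the divergence theorem over the surface."""
    mesh = geometry.surface if isinstance(geometry, StomachGeometry) else geometry
    if not mesh.is_watertight:
        raise GeometryError("volume requires a watertight surface")
    return abs(float(mesh.volume)) / 1000.0  # cm^3 -> L


def measure(geometry: StomachGeometry) -> dict:
    """Characteristic dimensions: lengths in cm, volume in L."""
    return {
        "greater_curvature_length": geometry.midplane_outline.branch_length("greater"),
        "widest_width": float(2 * geometry.radii.max()),
        "pyloric_diameter": float(2 * geometry.sections[0].radius),
        "volume": compute_volume(geometry),
    }


def midplane_domain(geometry: StomachGeometry, radii: np.ndarray | None = None) -> np.ndarray:
    """Closed CCW polygon of the surface's intersection with the ``z=0`` plane.

    With ``radii`` given, the polygon of the correspondingly deformed
    geometry is returned (used by the moving-boundary flow solver).
    """
    if radii is None:
        radii = geometry.radii
    centers = geometry.centerline[:, :2]
    u = np.array([s.in_plane_dir[:2] for s in geometry.sections])
    g = centers + radii[:, None] * u
    l = centers - radii[:, None] * u
    if geometry.params.esophageal_cap == "dome":
        r_last = radii[-1]
        nrm = geometry.sections[-1].normal[:2]
        alpha = np.linspace(0, np.pi, _DOME_ARC_POINTS + 2)[1:-1]
        arc = centers[-1] + r_last * (np.cos(alpha)[:, None] * u[-1] + np.sin(alpha)[:, None] * nrm)
        poly = np.vstack([g, arc, l[::-1]])
    else:
        poly = np.vstack([g, l[::-1]])
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    if area2 < 0:
        poly = poly[::-1]
    return poly


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------


def export_surface(geometry: StomachGeometry, path) -> None:
    """Write the surface as STL (ascii) or OBJ, by file extension."""
    path = str(path)
    if path.lower().endswith(".stl"):
        geometry.surface.export(path, file_type="stl_ascii")
    elif path.lower().endswith(".obj"):
        geometry.surface.export(path, file_type="obj")
    else:
        raise GeometryError(f"unsupported surface format: {path}")


def export_midplane_csv(geometry: StomachGeometry, path) -> None:
    poly = midplane_domain(geometry)
    np.savetxt(path, poly, delimiter=",", header="x_cm,y_cm", comments="")
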