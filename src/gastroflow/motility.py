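"""Prescribed gastric wall motility: antral contraction waves + tonic tone.

The wall motion has two ingredients:

* **Antral contraction waves (ACWs)** — circumferential indentations born
  every 20 s at the mid-corpus (15 cm proximal of the pylorus along the
  centerline), translating at a constant 2.3 mm/s along the horizontal axis
  of the symmetry plane, with a 58-s life span.  Each wave scales the radii
  of the auxiliary circles it covers by ``1 - occ(age) * B((s - s_w)/w)``,
  where ``B`` is a compactly supported cosine-squared bump of total
  centerline width 2.0 cm and ``occ`` is the piecewise-linear relative
  occlusion profile (0 -> 40% over 17.5 s, a 16-s plateau, then a terminal
  ramp to 80% at death).  Because the horizontal translation is constant
  while the J-shaped centerline curves, the wave's intersection with the
  greater curvature travels faster than with the lesser one, and both
  accelerate toward the pylorus — no explicit asymmetry is imposed.

* **Tonic contraction** — the stomach is a closed, liquid-filled chamber,
  so the capacity lost to the travelling indentations must be returned by
  the proximal wall.  Section radii above the mid-corpus apex are scaled by
  ``1 + f(t) * (s - s_apex)/(s_top - s_apex)``; the signed fraction ``f`` is
  solved at every instant so the lofted volume equals the rest volume to a
  relative tolerance of 1e-6, and stays within +-8%.

Units: centimeters and seconds; speeds are reported in mm/s where noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import StomachGeometry, loft_volume, midplane_domain, ring_vertices


class MotilityError(ValueError):
    pass


class OverOcclusionError(MotilityError):
    """A deformation drove a section radius to zero or below."""


class VolumeInfeasibleError(MotilityError):
    """No tonic fraction within +-8% can restore the rest volume."""


DEFAULT_OCCLUSION_KNOTS = ((0.0, 0.0), (17.5, 0.40), (33.5, 0.40), (58.0, 0.80))


@dataclass
class ACWParams:
    """Kinematic parameters of the antral contraction waves.

    ``horizontal_speed`` is in cm/s (2.3 mm/s); all lengths in cm, times
    in s.  ``occlusion_knots`` maps wave age to relative occlusion (the
    fractional narrowing of the midplane lumen width at the wave peak).
    """

    birth_interval: float = 20.0
    birth_arclength: float = 15.0
    life_span: float = 58.0
    horizontal_speed: float = 0.23
    width: float = 2.0
    occlusion_knots: tuple = DEFAULT_OCCLUSION_KNOTS
    max_occlusion: float = 0.80

    def __post_init__(self):
        if self.life_span <= self.birth_interval:
            raise MotilityError("life_span must exceed birth_interval")
        if self.width <= 0:
            raise MotilityError("width must be positive")
        occ = np.array([k[1] for k in self.occlusion_knots])
        if occ.min() < 0 or occ.max() > self.max_occlusion + 1e-12:
            raise MotilityError("occlusion knots must lie in [0, max_occlusion]")


def occlusion(age: float, params: ACWParams | None = None) -> float:
    """Relative occlusion of a wave at the given age (piecewise linear)."""
    params = params or ACWParams()
    if not 0.0 <= age <= params.life_span:
        raise MotilityError(f"age {age} outside the wave life span [0, {params.life_span}]")
    knots = np.asarray(params.occlusion_knots)
    return float(np.interp(age, knots[:, 0], knots[:, 1]))


@dataclass
class ACWInstance:
    """One live wave: its birth time and horizontal trajectory."""

    birth_time: float
    params: ACWParams
    x_birth: float

    def age(self, t: float) -> float:
        return t - self.birth_time

    def center_x(self, t: float) -> float:
        """Horizontal wave-peak coordinate: constant-speed translation."""
        return self.x_birth + self.params.horizontal_speed * self.age(t)

    def occlusion(self, t: float) -> float:
        return occlusion(self.age(t), self.params)

    def alive(self, t: float) -> bool:
        return 0.0 <= self.age(t) < self.params.life_span


def periodic_onset(params: ACWParams | None = None) -> float:
    """Earliest time after which the wall pattern repeats every birth interval.

    Waves are born every ``birth_interval`` with identical kinematics, so the
    set of live wave ages — hence the entire wall state — becomes periodic
    as soon as the first wave dies relative to the birth cycle:
    ``life_span - birth_interval`` (38 s for the defaults).
    """
    params = params or ACWParams()
    return params.life_span - params.birth_interval


@dataclass
class TonicContraction:
    """Linear-in-arclength proximal scaling, zero at the mid-corpus apex."""

    apex_arclength: float
    top_arclength: float
    max_fraction: float = 0.08

    def profile(self, s: np.ndarray) -> np.ndarray:
        """Weight in [0, 1]: 0 at the apex, 1 at the fundus top."""
        return np.clip((s - self.apex_arclength) / (self.top_arclength - self.apex_arclength), 0.0, 1.0)


@dataclass
class WallState:
    """Deformed wall at one instant."""

    time: float
    radii: np.ndarray  # per-section deformed radius (cm)
    fundus_fraction: float  # signed tonic fraction f(t)
    vertices: np.ndarray  # (n_sections, resolution, 3) surface rings (cm)
    volume: float  # enclosed volume (L)


class MotilityModel:
    """Binds a stomach geometry to the wave/tonic motility law."""

    def __init__(self, geometry: StomachGeometry, params: ACWParams | None = None,
                 volume_rtol: float = 1e-6):
        self.geometry = geometry
        self.params = params or ACWParams()
        self.volume_rtol = volume_rtol
        self.s = geometry.arclengths
        self.rest_radii = geometry.radii
        self.resolution = geometry.params.circle_resolution
        self.cap = geometry.params.esophageal_cap
        x = geometry.centerline[:, 0]
        self._x = x
        # maximal prefix (from the pylorus) over which x decreases with s:
        # the invertible region for the horizontal wave coordinate
        dec = np.diff(x) < 0
        k = int(np.argmin(dec)) + 1 if not dec.all() else len(x)
        if self.s[k - 1] < self.params.birth_arclength:
            raise MotilityError("centerline x not monotone out to the wave birth site")
        self._mono_s = self.s[:k]
        self._mono_x = x[:k]
        self.x_birth = float(np.interp(self.params.birth_arclength, self.s, x))
        self.x_pylorus = float(x[0])
        self.tonic = TonicContraction(
            apex_arclength=self.params.birth_arclength, top_arclength=float(self.s[-1])
        )
        self.rest_volume = self._volume(self.rest_radii)
        self._scale_cache: dict = {}

    # -- wave bookkeeping ---------------------------------------------------

    def active_waves(self, t: float) -> list[ACWInstance]:
        """Waves born at 0, 20, 40, ... that are still alive at ``t``."""
        if t < 0:
            raise MotilityError("t must be non-negative")
        p = self.params
        first = max(0, int(np.ceil((t - p.life_span) / p.birth_interval + 1e-12)))
        last = int(np.floor(t / p.birth_interval + 1e-12))
        waves = [
            ACWInstance(birth_time=k * p.birth_interval, params=p, x_birth=self.x_birth)
            for k in range(first, last + 1)
        ]
        return [w for w in waves if w.alive(t)]

    def wave_arclength(self, wave: ACWInstance, t: float) -> float:
        """Centerline arclength position of the wave peak.

        Once the peak passes the pyloric x coordinate the arclength is
        extrapolated to negative values: the terminal contraction slides off
        the sphincter, so its indentation vanishes smoothly (rather than
        jumping open at the end of the wave's life).
        """
        x = wave.center_x(t)
        if x > self.x_pylorus:
            dxds = (self._mono_x[1] - self._mono_x[0]) / (self._mono_s[1] - self._mono_s[0])
            return float((x - self.x_pylorus) / dxds)  # dxds < 0 -> negative s
        return float(np.interp(x, self._mono_x[::-1], self._mono_s[::-1]))

    # -- deformation --------------------------------------------------------

    @staticmethod
    def _bump(xi: np.ndarray) -> np.ndarray:
        """cos^2 bump with compact support on |xi| < 1/2, peak 1 at xi = 0."""
        out = np.zeros_like(xi)
        core = np.abs(xi) < 0.5
        out[core] = np.cos(np.pi * xi[core]) ** 2
        return out

    def wave_deformed_radii(self, t: float) -> np.ndarray:
        """Section radii after applying every active wave (no tonic term)."""
        r = self.rest_radii.copy()
        for wave in self.active_waves(t):
            s_w = self.wave_arclength(wave, t)
            b = self._bump((self.s - s_w) / self.params.width)
            r = r * (1.0 - wave.occlusion(t) * b)
        if np.any(r <= 0):
            raise OverOcclusionError(f"non-positive section radius at t={t}")
        return r

    def _volume(self, radii: np.ndarray) -> float:
        return loft_volume(*ring_vertices(self.geometry.sections, radii=radii,
                                          resolution=self.resolution, cap=self.cap))

    def fundus_scale(self, t: float) -> float:
        """Signed tonic fraction restoring the rest capacity at time ``t``."""
        key = round(t, 9)
        if key in self._scale_cache:
            return self._scale_cache[key]
        r_wave = self.wave_deformed_radii(t)
        w = self.tonic.profile(self.s)

        def residual(f):
            return self._volume(r_wave * (1.0 + f * w)) - self.rest_volume

        r0 = residual(0.0)
        if abs(r0) <= self.volume_rtol * self.rest_volume:
            f = 0.0
        else:
            lo, hi = -self.tonic.max_fraction, self.tonic.max_fraction
            if residual(lo) * residual(hi) > 0:
                raise VolumeInfeasibleError(
                    f"volume cannot be restored within +-{self.tonic.max_fraction:.0%} at t={t}"
                )
            f = brentq(residual, lo, hi, xtol=1e-12,
                       rtol=8.881784197001252e-16, maxiter=200)
        self._scale_cache[key] = float(f)
        return float(f)

    def radii(self, t: float) -> np.ndarray:
        """Fully deformed section radii (waves + volume-conserving tonic term)."""
        r_wave = self.wave_deformed_radii(t)
        f = self.fundus_scale(t)
        return r_wave * (1.0 + f * self.tonic.profile(self.s))

    def deform(self, t: float) -> WallState:
        """Wall state (positions only) at time ``t``."""
        r = self.radii(t)
        rings, a0, a1 = ring_vertices(self.geometry.sections, radii=r,
                                      resolution=self.resolution, cap=self.cap)
        return WallState(
            time=t,
            radii=r,
            fundus_fraction=self.fundus_scale(t),
            vertices=rings,
            volume=loft_volume(rings, a0, a1) / 1000.0,
        )

    def wall_velocity(self, t: float, dt: float = 1e-3) -> np.ndarray:
        """Surface vertex velocities (cm/s) by central finite difference."""
        if t < dt:
            raise MotilityError("wall velocity needs t > dt for a central difference")
        va = ring_vertices(self.geometry.sections, radii=self.radii(t + dt),
                           resolution=self.resolution, cap=self.cap)[0]
        vb = ring_vertices(self.geometry.sections, radii=self.radii(t - dt),
                           resolution=self.resolution, cap=self.cap)[0]
        return (va - vb) / (2 * dt)

    def midplane_wall(self, t: float, dt: float = 1e-3):
        """Midplane polygon (cm) and its vertex velocities (cm/s) at ``t``."""
        poly = midplane_domain(self.geometry, radii=self.radii(t))
        ra = self.radii(t + dt)
        rb = self.radii(max(t - dt, 0.0))
        pa = midplane_domain(self.geometry, radii=ra)
        pb = midplane_domain(self.geometry, radii=rb)
        vel = (pa - pb) / (t + dt - max(t - dt, 0.0))
        return poly, vel

    # -- kinematic measurements ---------------------------------------------

    def curve_speed(self, branch: str, sample_dt: float = 0.1) -> dict:
        """Propagation speed of a wave peak along a curvature branch (mm/s).

        Tracks the intersection of the wave-peak locus with the chosen
        branch over one wave life; by the equal-normalized-arclength pairing,
        the branch position is the branch length times the normalized section
        parameter at the wave's centerline position.
        """
        if branch not in ("greater", "lesser"):
            raise MotilityError("branch must be 'greater' or 'lesser'")
        L = self.geometry.midplane_outline.branch_length(branch)
        frac = self.geometry.branch_fractions[:, 0 if branch == "greater" else 1]
        wave = ACWInstance(birth_time=0.0, params=self.params, x_birth=self.x_birth)
        ages = np.arange(0.0, self.params.life_span + 1e-9, sample_dt)
        s_w = np.array([self.wave_arclength(wave, a) for a in ages])
        pos = L * np.interp(s_w, self.s, frac)  # branch arclength from the pylorus end
        speed = np.abs(np.diff(pos)) / np.diff(ages) * 10.0  # cm/s -> mm/s
        return {
            "mean": float(np.abs(pos[-1] - pos[0]) / (ages[-1] - ages[0]) * 10.0),
            "min": float(speed.min()),
            "max": float(speed.max()),
        }

    def periodic_onset(self) -> float:
        return periodic_onset(self.params)
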