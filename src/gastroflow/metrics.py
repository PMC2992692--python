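"""Flow descriptors of the gastric simulation.

Quantifies the two flow structures that dominate antral mixing and their
pressure signature:

* the **retropulsive jet** — backward flow (away from the closed pylorus)
  through the lumen narrowed by a contraction wave: peak velocity, origin,
  and the distance along the jet axis over which the speed decays by 40%;
* **eddy strength** — the average absolute vorticity over the antropyloric
  region (the distal third of the centerline by default);
* **pressure drops** across a wave, which are anchoring-invariant.

Lengths and velocities are reported in cm and cm/s (the scales of the
physiology literature); inputs are the SI :class:`~gastroflow.flow2d.FlowState`
fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .flow2d import FlowState


class MetricsError(ValueError):
    pass


@dataclass
class JetReport:
    """Retropulsive jet characterization at one instant."""

    initial_velocity: float  # cm/s at the jet origin
    length: float  # cm along the axis to 40% velocity decay
    origin: np.ndarray  # (2,) cm
    axis: np.ndarray  # (2,) unit vector, pointing away from the pylorus
    time: float  # s
    censored: bool = False  # decay point not reached before leaving the fluid


@dataclass
class VorticityTrace:
    times: np.ndarray  # s
    mean_abs_vorticity: np.ndarray  # 1/s

    def __post_init__(self):
        if np.any(np.asarray(self.mean_abs_vorticity) < 0):
            raise MetricsError("vorticity trace must be non-negative")


class StomachFrame:
    """Per-cell centerline directions for a stomach simulation grid.

    Associates every grid cell with its nearest centerline station; supplies
    the local "away from the pylorus" unit direction and the antropyloric
    region mask (distal third of the centerline arclength by default).
    """

    def __init__(self, geometry, antral_fraction: float = 1 / 3):
        self.centerline_m = geometry.centerline[:, :2] * 0.01
        self.s_m = geometry.arclengths * 0.01
        tang = np.gradient(self.centerline_m, self.s_m, axis=0)
        self.away = tang / np.linalg.norm(tang, axis=1, keepdims=True)
        self.chord_dirs = np.array([sec.in_plane_dir[:2] for sec in geometry.sections])
        self.antral_fraction = antral_fraction
        self._tree = cKDTree(self.centerline_m)
        self._cache: dict = {}

    def _cells(self, state: FlowState):
        g = state.grid
        key = (g.x0, g.y0, g.h, g.nx, g.ny)
        if key not in self._cache:
            X, Y = g.cell_centers()
            _, idx = self._tree.query(np.column_stack([X.ravel(), Y.ravel()]))
            self._cache[key] = idx.reshape(X.shape)
        return self._cache[key]

    def away_dirs(self, state: FlowState) -> np.ndarray:
        """(nx, ny, 2) unit direction pointing away from the pylorus."""
        return self.away[self._cells(state)]

    def arclength(self, state: FlowState) -> np.ndarray:
        """(nx, ny) centerline arclength (m) of the nearest station."""
        return self.s_m[self._cells(state)]

    def antropyloric_mask(self, state: FlowState) -> np.ndarray:
        return self.arclength(state) <= self.antral_fraction * self.s_m[-1]


def vorticity_field(state: FlowState) -> np.ndarray:
    """Cell-centered out-of-plane vorticity dv/dx - du/dy (1/s)."""
    uc, vc = state.cell_velocity()
    h = state.grid.h
    return np.gradient(vc, h, axis=0) - np.gradient(uc, h, axis=1)


def average_vorticity(state: FlowState, region: np.ndarray) -> float:
    """Mean absolute vorticity (1/s) over fluid cells in the region mask."""
    sel = region & state.fluid
    if not sel.any():
        raise MetricsError("empty region for vorticity average")
    return float(np.abs(vorticity_field(state))[sel].mean())


def retropulsive_velocity(state: FlowState, away_dirs: np.ndarray,
                          region: np.ndarray | None = None):
    """Maximum velocity component away from the pylorus, and its location.

    ``away_dirs`` is either a constant (2,) direction or a per-cell
    (nx, ny, 2) field.  Returns ``(speed_cm_s, location_m)``; the speed is
    clipped at zero when the flow is nowhere retropulsive.
    """
    sel = state.fluid if region is None else (region & state.fluid)
    if not sel.any():
        raise MetricsError("empty region for retropulsive velocity")
    uc, vc = state.cell_velocity()
    d = np.asarray(away_dirs, float)
    if d.ndim == 1:
        comp = uc * d[0] + vc * d[1]
    else:
        comp = uc * d[..., 0] + vc * d[..., 1]
    comp = np.where(sel, comp, -np.inf)
    i, j = np.unravel_index(int(np.argmax(comp)), comp.shape)
    speed = max(float(comp[i, j]), 0.0)
    loc = np.array([state.grid.cell_x[i], state.grid.cell_y[j]])
    return speed * 100.0, loc


def jet_report(state: FlowState, origin_m: np.ndarray, axis: np.ndarray,
               sample_step: float | None = None, max_length: float = 0.3) -> JetReport:
    """Characterize the jet from its origin along its axis.

    The jet speed is the velocity component along ``axis``; the length is
    the distance to the first sample at or below 60% of the initial speed
    (a 40% decay).  If the ray exits the fluid first, the length is
    censored at the exit point.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    step = sample_step or state.grid.h / 2
    n = max(int(max_length / step), 2)
    pts = np.asarray(origin_m, float)[None, :] + step * np.arange(n)[:, None] * axis[None, :]
    speed = state.interp_velocity(pts) @ axis
    g = state.grid
    ii = np.clip(((pts[:, 0] - g.x0) / g.h).astype(int), 0, g.nx - 1)
    jj = np.clip(((pts[:, 1] - g.y0) / g.h).astype(int), 0, g.ny - 1)
    inside = state.fluid[ii, jj]
    v0 = float(speed[0])
    if v0 <= 0:
        return JetReport(initial_velocity=0.0, length=0.0,
                         origin=np.asarray(origin_m, float) * 100,
                         axis=axis, time=state.t, censored=False)
    exit_k = int(np.argmin(inside)) if not inside.all() else n
    decayed = np.where(speed[:exit_k] <= 0.6 * v0)[0]
    if decayed.size:
        length = float(decayed[0]) * step
        censored = False
    else:
        length = float(max(exit_k - 1, 0)) * step
        censored = True
    return JetReport(initial_velocity=v0 * 100.0, length=length * 100.0,
                     origin=np.asarray(origin_m, float) * 100, axis=axis,
                     time=state.t, censored=censored)


def throat_profile(state: FlowState, frame: StomachFrame, model,
                   half_span: float = 0.025, n: int = 101):
    """Retropulsive velocity profile across the deepest wave's throat.

    Samples the velocity component along the local away-from-pylorus
    direction on the throat chord (the auxiliary-circle plane of the
    most-occluded wave).  Returns ``(peak_cm_s, origin_m, axis, occlusion)``
    or ``None`` when no wave is on the centerline.
    """
    waves = model.active_waves(state.t)
    if not waves:
        return None
    wave = max(waves, key=lambda w: w.occlusion(state.t))
    s_w = model.wave_arclength(wave, state.t) * 0.01
    if s_w < 0.005:
        return None
    k = int(np.argmin(np.abs(frame.s_m - s_w)))
    center = frame.centerline_m[k]
    chord = frame.chord_dirs[k]
    away = frame.away[k]
    offs = np.linspace(-half_span, half_span, n)
    pts = center[None, :] + offs[:, None] * chord[None, :]
    g = state.grid
    ii = np.clip(((pts[:, 0] - g.x0) / g.h).astype(int), 0, g.nx - 1)
    jj = np.clip(((pts[:, 1] - g.y0) / g.h).astype(int), 0, g.ny - 1)
    inside = state.fluid[ii, jj]
    if not inside.any():
        return None
    comp = state.interp_velocity(pts) @ away
    kmax = int(np.where(inside, comp, -np.inf).argmax())
    return float(comp[kmax]) * 100.0, pts[kmax], away, wave.occlusion(state.t)


def stomach_jet_report(state: FlowState, frame: StomachFrame, model) -> JetReport | None:
    """Jet report at the throat of the deepest active wave, or ``None``.

    The jet origin is the point of maximum retropulsive velocity on the
    throat chord; the axis is the local away-from-pylorus centerline
    direction.
    """
    prof = throat_profile(state, frame, model)
    if prof is None:
        return None
    _, origin, away, _ = prof
    return jet_report(state, origin, away)


def jet_onset(occlusions: np.ndarray, throat_speeds: np.ndarray,
              wave_speed: float, k: float = 2.0):
    """Smallest occlusion at which the throat retropulsive speed exceeds
    ``k`` times the wave propagation speed (speeds in cm/s).

    Returns ``None`` when the jet criterion is never met.
    """
    occlusions = np.asarray(occlusions, float)
    throat_speeds = np.asarray(throat_speeds, float)
    hits = throat_speeds > k * wave_speed
    if not hits.any():
        return None
    return float(occlusions[hits].min())


def pressure_drop(state: FlowState, probe_a, probe_b) -> float:
    """p(A) - p(B) in Pa; invariant under re-anchoring."""
    g = state.grid
    for name, pt in (("A", probe_a), ("B", probe_b)):
        i = int(np.clip((pt[0] - g.x0) / g.h, 0, g.nx - 1))
        j = int(np.clip((pt[1] - g.y0) / g.h, 0, g.ny - 1))
        if not state.fluid[i, j]:
            raise MetricsError(f"pressure probe {name} lies in solid")
    pa = float(state.interp_pressure(np.asarray(probe_a, float)[None, :])[0])
    pb = float(state.interp_pressure(np.asarray(probe_b, float)[None, :])[0])
    return pa - pb
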