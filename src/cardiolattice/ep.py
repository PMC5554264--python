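"""Monodomain electrophysiology on the labelled tissue lattice.

The transmembrane potential obeys

    dV/dt = div(D grad V) - (I_ion + I_stim) / C_m

with a heterogeneous, face-resolved coupling coefficient D taken from a
:class:`~cardiolattice.gj.ConductanceMap`.  Time stepping uses the
alternating-direction implicit (ADI) scheme: a hidden n+1/2 step, each
half-step implicit along one axis (independent tridiagonal systems, solved
exactly) and explicit along the other, with the reaction rate evaluated at
step n.  This is unconditionally stable for the diffusion part, which is
what makes h = 2.5 um workable with millisecond time steps.

The ionic model is pluggable.  The built-in default is a two-variable
excitable surrogate of the Aliev-Panfilov type (dimensionless V in [0, ~1],
one recovery variable), adequate for wavefront geometry, activation maps
and velocity ratios; a detailed ionic model can be dropped in through the
same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, Tuple

import numpy as np
from scipy import ndimage

from . import _kernels
from .gj import ConductanceMap
from .params import SPACING_UM

__all__ = [
    "MembraneState", "IonicModel", "AlievPanfilovModel", "StimulusProtocol",
    "adi_step", "simulate", "SimulationResult", "optical_smoothing",
    "conduction_velocity", "anisotropy_ratio", "NoPropagationError",
]

#: lattice spacing in cm (2.5 um)
H_CM = SPACING_UM * 1e-4
#: conversion: D [cm^2/s] -> [cm^2/ms]
CM2_PER_S_TO_MS = 1e-3


class NoPropagationError(RuntimeError):
    """Raised when a velocity is requested from an unactivated region."""


class InstabilityError(RuntimeError):
    """Raised when the solver produces non-finite potentials."""


class IonicModel(Protocol):
    """Contract for pluggable ionic models.

    ``resting_state()`` returns (V_rest, gates_rest) where gates_rest is a
    (n_gates,) vector; ``rates(V, gates)`` returns (dV/dt, dgates/dt) in
    1/ms, already including the -I_ion/C_m sign convention; ``threshold``
    is the activation-detection level for V.
    """

    threshold: float

    def resting_state(self) -> Tuple[float, np.ndarray]: ...

    def rates(self, V: np.ndarray,
              gates: np.ndarray) -> Tuple[np.ndarray, np.ndarray]: ...


@dataclass
class AlievPanfilovModel:
    """Two-variable excitable surrogate (activator V, recovery w).

    dV/dt' = k V (V - a)(1 - V) - V w
    dw/dt' = (eps0 + mu1 w / (mu2 + V)) (-w - k V (V - a - 1))

    with t' = t / time_scale_ms.  V is dimensionless (resting 0, peak ~1);
    the activation threshold is the 50% amplitude crossing.
    """

    k: float = 8.0
    a: float = 0.10
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    #: sets the upstroke speed; the default is stiff enough that the
    #: depolarisation length sqrt(D_eff * tau_up) stays well below the
    #: sub-millimetre tissue domains used here and that excitation
    #: crosses gap-junction faces with a comfortable safety factor
    time_scale_ms: float = 2.5
    threshold: float = 0.5

    def resting_state(self) -> Tuple[float, np.ndarray]:
        return 0.0, np.zeros(1)

    def rates(self, V, gates):
        # evaluate the kinetics on a clipped copy: the implicit diffusion
        # steps are non-monotone at extreme diffusion numbers and brief
        # under/overshoots must not reach the 1/(mu2 + V) pole
        V = np.clip(V, -0.2, 1.6)
        w = np.maximum(gates[0], 0.0)
        k, a = self.k, self.a
        dV = k * V * (V - a) * (1.0 - V) - V * w
        dw = (self.eps0 + self.mu1 * w / (self.mu2 + V)) \
            * (-w - k * V * (V - a - 1.0))
        return dV / self.time_scale_ms, dw[None] / self.time_scale_ms


@dataclass
class StimulusProtocol:
    """Stimulus current applied to a pixel region.

    ``region`` is a boolean grid; ``amplitude`` adds to dV/dt (1/ms) while
    active; pacing repeats every ``period_ms`` if set.
    """

    region: np.ndarray
    amplitude: float = 3.0
    onset_ms: float = 0.0
    duration_ms: float = 1.0
    period_ms: Optional[float] = None

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")

    def active(self, t_ms: float) -> bool:
        if t_ms < self.onset_ms:
            return False
        dt = t_ms - self.onset_ms
        if self.period_ms is not None:
            dt = dt % self.period_ms
        return dt < self.duration_ms

    @classmethod
    def point(cls, dims: Tuple[int, int], site: Tuple[int, int],
              radius: int = 3, **kw) -> "StimulusProtocol":
        yy, xx = np.indices(dims)
        region = (yy - site[0]) ** 2 + (xx - site[1]) ** 2 <= radius ** 2
        return cls(region=region, **kw)


@dataclass
class MembraneState:
    """Potential grid + gate grids + clock for one simulation."""

    V: np.ndarray
    gates: np.ndarray            # (n_gates, rows, cols)
    t: float = 0.0               # ms
    dt: float = 0.1              # ms
    h_cm: float = H_CM
    c_m: float = 1.0

    @classmethod
    def resting(cls, model: IonicModel, dims: Tuple[int, int],
                dt: float = 0.1) -> "MembraneState":
        v0, g0 = model.resting_state()
        V = np.full(dims, v0, dtype=np.float64)
        gates = np.empty((len(g0),) + tuple(dims), dtype=np.float64)
        for i, g in enumerate(g0):
            gates[i].fill(g)
        return cls(V=V, gates=gates, dt=dt)


def adi_step(ms: MembraneState, dmap: ConductanceMap, model: IonicModel,
             stim: Optional[StimulusProtocol] = None,
             excitable: Optional[np.ndarray] = None) -> MembraneState:
    """Advance one full ADI step (two half-steps) in place.

    Reaction rates are evaluated once from the step-n state and applied in
    both half-steps; gates advance once per full step (forward Euler).
    ``excitable`` restricts the reaction to a pixel subset (cardiomyocyte
    subcells); elsewhere V only diffuses (and D = 0 faces keep it frozen).
    """
    dV, dg = model.rates(ms.V, ms.gates)
    if stim is not None and stim.active(ms.t):
        dV = dV + stim.amplitude * stim.region
    if excitable is not None:
        dV = dV * excitable
        dg = dg * excitable
    beta = ms.dt * CM2_PER_S_TO_MS / (2.0 * ms.h_cm * ms.h_cm)
    half_dt = 0.5 * ms.dt
    Vh = np.empty_like(ms.V)
    Vn = np.empty_like(ms.V)
    _kernels._adi_half_x(ms.V, dV, dmap.horizontal, dmap.vertical,
                         beta, half_dt, Vh)
    _kernels._adi_half_y(Vh, dV, dmap.horizontal, dmap.vertical,
                         beta, half_dt, Vn)
    if not np.all(np.isfinite(Vn)):
        raise InstabilityError(
            f"non-finite potential after ADI step at t={ms.t} ms "
            f"(dt={ms.dt} ms, max D={dmap.max_d} cm^2/s)")
    ms.V = Vn
    ms.gates = ms.gates + ms.dt * dg
    ms.t += ms.dt
    return ms


@dataclass
class ActivationMap:
    """First-activation time per pixel, ms; NaN where never activated."""

    times: np.ndarray

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.times)


@dataclass
class SimulationResult:
    frames: np.ndarray           # (n_frames, rows, cols)
    frame_times: np.ndarray      # ms
    activation: ActivationMap
    state: MembraneState


def simulate(dmap: ConductanceMap, model: IonicModel,
             protocol: StimulusProtocol, duration_ms: float,
             dt: float = 0.1,
             excitable: Optional[np.ndarray] = None,
             frame_every_ms: Optional[float] = 1.0,
             state: Optional[MembraneState] = None) -> SimulationResult:
    """Integrate the monodomain equation and record the activation map.

    Activation time per pixel is the first upward crossing of the model's
    threshold, linearly interpolated between steps.
    """
    dims = (dmap.vertical.shape[0] + 1, dmap.horizontal.shape[1] + 1)
    if state is None:
        state = MembraneState.resting(model, dims, dt=dt)
    act = np.full(dims, np.nan)
    frames = []
    frame_times = []
    n_steps = int(round(duration_ms / dt))
    stride = max(1, int(round((frame_every_ms or duration_ms) / dt)))
    thr = model.threshold
    prev_V = state.V.copy()
    for step in range(n_steps):
        if frame_every_ms is not None and step % stride == 0:
            frames.append(state.V.copy())
            frame_times.append(state.t)
        adi_step(state, dmap, model, stim=protocol, excitable=excitable)
        crossed = np.isnan(act) & (prev_V < thr) & (state.V >= thr)
        if crossed.any():
            frac = (thr - prev_V[crossed]) / (state.V[crossed]
                                              - prev_V[crossed])
            act[crossed] = state.t - dt + frac * dt
        prev_V = state.V.copy()
    frames.append(state.V.copy())
    frame_times.append(state.t)
    return SimulationResult(frames=np.array(frames),
                            frame_times=np.array(frame_times),
                            activation=ActivationMap(times=act),
                            state=state)


def optical_smoothing(frames: np.ndarray, kernel_um: float = 250.0,
                      spacing_um: float = SPACING_UM) -> np.ndarray:
    """Optical-mapping-style Gaussian smoothing, per frame.

    ``kernel_um`` is the physical Gaussian kernel size (250 um for
    isotropic, 300 um for anisotropic samples), converted to pixels via
    the lattice spacing.
    """
    if kernel_um < spacing_um:
        raise ValueError("kernel must be at least one pixel")
    sigma_px = kernel_um / spacing_um
    out = np.empty_like(np.asarray(frames, dtype=np.float64))
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        return ndimage.gaussian_filter(frames, sigma_px)
    for i, f in enumerate(frames):
        out[i] = ndimage.gaussian_filter(f, sigma_px)
    return out


def smooth_activation_map(amap: ActivationMap, kernel_um: float,
                          spacing_um: float = SPACING_UM,
                          min_weight: float = 0.3) -> ActivationMap:
    """Gaussian smoothing of the activation map, ignoring unactivated
    pixels (normalised convolution).

    Mirrors the optical-mapping processing chain: activation times read
    from Gaussian-blurred fluorescence movies are effectively locally
    averaged arrival times.  Pixels whose neighbourhood carries less
    than ``min_weight`` activated mass stay unactivated.
    """
    t = amap.times
    w = np.isfinite(t).astype(np.float64)
    tw = np.where(np.isfinite(t), t, 0.0)
    sigma_px = kernel_um / spacing_um
    num = ndimage.gaussian_filter(tw, sigma_px)
    den = ndimage.gaussian_filter(w, sigma_px)
    out = np.full_like(t, np.nan)
    ok = den > min_weight
    out[ok] = num[ok] / den[ok]
    return ActivationMap(times=out)


def conduction_velocity(amap: ActivationMap,
                        line: Tuple[Tuple[int, int], Tuple[int, int]],
                        spacing_um: float = 1.0,
                        trim: float = 0.0,
                        band: int = 0) -> float:
    """Wavefront speed along a sampling segment, oriented away from the
    stimulus.

    Least-squares slope of activation time versus distance along the line;
    the speed is the inverse slope, in (``spacing_um`` units)/ms -- with
    the default spacing of 1 the unit is px/ms.  ``trim`` drops that
    fraction of samples at each end (junction/boundary effects) before
    fitting.  ``band`` widens the segment to ``2*band + 1`` parallel
    sample rows: on a cellular mesh single pixels may be inexcitable
    (fibroblasts, medium), so the fit pools every activated pixel in the
    band with its distance measured along the line direction.

    Raises :class:`NoPropagationError` if fewer than two samples
    activated, or if the activation times do not increase along the line
    (a stationary, effectively infinite-speed front).
    """
    (r0, c0), (r1, c1) = line
    n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
    rr = np.rint(np.linspace(r0, r1, n)).astype(int)
    cc = np.rint(np.linspace(c0, c1, n)).astype(int)
    if trim > 0:
        k = int(n * trim)
        if k > 0:
            rr = rr[k:n - k]
            cc = cc[k:n - k]
    # unit vector along the line and its normal (for the band offsets)
    length = np.hypot(r1 - r0, c1 - c0)
    if length == 0:
        raise ValueError("line has zero length")
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    pr, pc = -uc, ur
    ts, ds = [], []
    H, W = amap.times.shape
    for off in range(-band, band + 1):
        br = np.rint(rr + off * pr).astype(int)
        bc = np.rint(cc + off * pc).astype(int)
        ok = (br >= 0) & (br < H) & (bc >= 0) & (bc < W)
        t = amap.times[br[ok], bc[ok]]
        d = ((br[ok] - r0) * ur + (bc[ok] - c0) * uc) * spacing_um
        fin = np.isfinite(t)
        ts.append(t[fin])
        ds.append(d[fin])
    t = np.concatenate(ts)
    dist = np.concatenate(ds)
    if t.size < 2:
        raise NoPropagationError("fewer than two activated samples on line")
    slope = np.polyfit(dist, t, 1)[0]
    if slope <= 0 or not np.isfinite(slope) or np.ptp(t) == 0:
        raise NoPropagationError(
            "activation times do not increase along the line "
            "(stationary or retrograde front)")
    return float(1.0 / slope)


def directional_velocity(amap: ActivationMap, origin: Tuple[int, int],
                         angle: float, half_angle: float = np.pi / 8,
                         r_min: float = 15.0,
                         r_max: Optional[float] = None) -> float:
    """Front speed in one direction from a point stimulus, px/ms.

    Pools every activated pixel in the angular wedge
    ``[angle - half_angle, angle + half_angle]`` (angle 0 = +x/columns,
    measured counter-clockwise with rows pointing down) at radii
    ``[r_min, r_max]`` from the origin and fits activation time against
    radius.  Wedge pooling averages over the tortuous, discontinuous
    conduction paths of a cellular mesh, which single-line sampling does
    not.
    """
    times = amap.times
    H, W = times.shape
    yy, xx = np.indices(times.shape)
    dy = yy - origin[0]
    dx = xx - origin[1]
    r = np.hypot(dy, dx)
    if r_max is None:
        r_max = min(H, W) / 2.0 - 5.0
    th = np.arctan2(-dy, dx)  # counter-clockwise, +x = 0
    dth = np.angle(np.exp(1j * (th - angle)))
    sel = (np.abs(dth) <= half_angle) & (r >= r_min) & (r <= r_max) \
        & np.isfinite(times)
    if sel.sum() < 10:
        raise NoPropagationError("too few activated pixels in the wedge")
    slope = np.polyfit(r[sel], times[sel], 1)[0]
    if slope <= 0 or not np.isfinite(slope):
        raise NoPropagationError("front not moving outward in the wedge")
    return float(1.0 / slope)


def axis_velocity(amap: ActivationMap, origin: Tuple[int, int],
                  axis: float, half_angle: float = np.pi / 8,
                  r_min: float = 25.0,
                  r_max: Optional[float] = None) -> float:
    """Front speed along one axis from a point stimulus, px/ms.

    Pools the two opposite wedges of the axis in a single fit of
    activation time against radius; the two-sided pooling makes the
    estimate robust to one-sided conduction detours on cellular meshes.
    """
    times = amap.times
    H, W = times.shape
    if r_max is None:
        r_max = min(H, W) / 2.0 - 10.0
    yy, xx = np.indices(times.shape)
    dy = yy - origin[0]
    dx = xx - origin[1]
    r = np.hypot(dy, dx)
    th = np.arctan2(-dy, dx)
    sel = np.zeros_like(times, dtype=bool)
    for ang in (axis, axis + np.pi):
        dth = np.angle(np.exp(1j * (th - ang)))
        sel |= np.abs(dth) <= half_angle
    sel &= (r >= r_min) & (r <= r_max) & np.isfinite(times)
    if sel.sum() < 20:
        raise NoPropagationError("too few activated pixels on the axis")
    slope = np.polyfit(r[sel], times[sel], 1)[0]
    if slope <= 0 or not np.isfinite(slope):
        raise NoPropagationError("front not moving outward along the axis")
    return float(1.0 / slope)


def orthogonal_velocity_ratio(amap: ActivationMap,
                              origin: Tuple[int, int],
                              r_min: float = 25.0,
                              r_max: Optional[float] = None) -> float:
    """v_x / v_y from a point stimulus (the isotropy measurement)."""
    vx = axis_velocity(amap, origin, 0.0, r_min=r_min, r_max=r_max)
    vy = axis_velocity(amap, origin, np.pi / 2, r_min=r_min, r_max=r_max)
    return float(vx / vy)


def arm_front_velocity(amap: ActivationMap, origin: Tuple[int, int],
                       direction: Tuple[int, int], length: int,
                       width: int, d_min: int = 30,
                       min_coverage: float = 0.6) -> float:
    """Wavefront speed along one arm of an L-shaped sample, px/ms.

    For each distance ``d`` from the junction along ``direction``
    (a unit axis vector), the front arrival time is the earliest
    activation across the arm's cross-section (``width`` pixels centred
    on the arm middle line); the speed is the inverse slope of arrival
    time against distance over ``d in [d_min, length]``.  Using the
    cross-section minimum tracks the leading (possibly zig-zagging)
    front and is robust to partially activated tissue.
    """
    times = amap.times
    dr, dc = direction
    r0, c0 = origin
    ds, ts = [], []
    for d in range(d_min, length):
        r = r0 + dr * d
        c = c0 + dc * d
        if dr == 0:
            band = times[max(0, r - width // 2):r + width // 2, c]
        else:
            band = times[r, max(0, c - width // 2):c + width // 2]
        if np.isfinite(band).any():
            ds.append(d)
            ts.append(np.nanmin(band))
    if len(ds) < (length - d_min) * min_coverage or len(ds) < 10:
        raise NoPropagationError(
            f"front reached only {len(ds)}/{length - d_min} stations "
            "along the arm")
    slope = np.polyfit(ds, ts, 1)[0]
    if slope <= 0 or not np.isfinite(slope):
        raise NoPropagationError("arrival times do not increase along "
                                 "the arm")
    return float(1.0 / slope)


def anisotropy_ratio(amap: ActivationMap,
                     longitudinal_line: Tuple[Tuple[int, int],
                                              Tuple[int, int]],
                     transversal_line: Tuple[Tuple[int, int],
                                             Tuple[int, int]],
                     trim: float = 0.1) -> float:
    """Longitudinal over transversal conduction velocity.

    For the L-shaped protocol the two lines run along the arm middle
    lines, away from the stimulated junction, the longitudinal one along
    the fibre axis.
    """
    v_l = conduction_velocity(amap, longitudinal_line, trim=trim, band=3)
    v_t = conduction_velocity(amap, transversal_line, trim=trim, band=3)
    return v_l / v_t
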