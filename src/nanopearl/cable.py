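"""Action-potential conduction on pearled axon geometries.

Solves the generalized cable equation with Hodgkin-Huxley currents on a
radius-varying unmyelinated axon,

    c_m dV/dt = [1 / (2 pi a sqrt(1 + a'^2))] d/dx( pi a^2 / R_i dV/dx )
                - i_HH(V, m, h, n) + i_stim,

where a(x) is the local radius and the sqrt(1 + a'^2) factor accounts
for the true membrane area of the sloped pearl surface (both in the
capacitive and ionic terms; it can be disabled for comparison).  Gating
follows standard first-order kinetics dX/dt = alpha_X(V)(1-X) - beta_X(V) X.

The model axon spans -90 um (tip of the axon initial segment, AIS) to
+300 um; the trunk is either a cylinder or a periodic chain of
raised-cosine pearls (nonsynaptic varicosities, NSVs) joined by thin
connectors, built from the same analytic backbone as the synthetic EM
profiles.  Voltage-gated sodium channels are laid out either uniformly
or clustered every 190 nm (the spacing of the actin-spectrin membrane
periodic skeleton), with the axon-integrated sodium conductance matched
between layouts.  Conduction velocity is read out from the difference in
voltage time-to-peak between probes at 0 um and 277 um.

Numerics: finite volumes on a uniform grid (default dx = 20 nm),
Crank-Nicolson for the axial operator with the ionic conductances
semi-implicit, gating updated by a staggered exponential step (default
dt = 2 us).  Units follow the Hodgkin-Huxley convention: mV, ms, cm,
uF/cm^2, mS/cm^2, ohm cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from .profiles import PearlDims, pearl_radius_periodic

__all__ = [
    "AISSpec",
    "AxonGeometry",
    "EphysParams",
    "ChannelLayout",
    "Stimulus",
    "VoltageTraces",
    "VelocityEstimate",
    "build_geometry",
    "place_channels",
    "simulate_ap",
    "conduction_velocity",
    "predict_from_measurements",
    "sweep_dimension",
    "sweep_ratio",
    "REFERENCE_GEOMETRIES",
]

NM_TO_CM = 1e-7
UM_TO_CM = 1e-4

#: Measured mean geometries used for the velocity predictions
#: (nsv_length, nsv_width, connector_length, connector_width) in nm.
REFERENCE_GEOMETRIES = {
    "control": (638.0, 309.0, 486.0, 136.0),
    "mbcd": (573.0, 310.0, 567.0, 121.0),
    "blebbistatin": (590.0, 295.0, 431.0, 215.0),
    "hfs_no_stim": (449.0, 232.0, 462.0, 118.0),
    "hfs_5min": (541.0, 262.0, 512.0, 135.0),
    "hfs_30min": (526.0, 287.0, 510.0, 118.0),
}


@dataclass(frozen=True)
class AISSpec:
    """Axon initial segment: a cylinder with elevated NaV density.

    The AIS occupies [-length_um, 0] um; its last ``taper_um`` taper
    smoothly (half-cosine) onto the trunk radius so the geometry is
    continuous.
    """

    length_um: float = 90.0
    diameter_nm: float = 500.0
    taper_um: float = 5.0
    nav_multiplier: float = 5.0


@dataclass
class AxonGeometry:
    """Discretized radius profile of the model axon.

    ``x`` in cm (uniform spacing, from -AIS length to trunk length),
    ``a`` local radius in cm.  ``trunk_start`` is the index of x = 0.
    """

    x: np.ndarray
    a: np.ndarray
    dx: float
    trunk_start: int
    ais: AISSpec
    dims: Optional[PearlDims] = None
    cylinder_diameter_nm: Optional[float] = None
    include_slope_factor: bool = True

    @property
    def n(self) -> int:
        return self.x.size

    def membrane_width(self) -> np.ndarray:
        """Membrane area per unit length, w = 2 pi a sqrt(1 + a'^2), cm."""
        ap = np.gradient(self.a, self.dx)
        slope = np.sqrt(1.0 + ap**2) if self.include_slope_factor else 1.0
        return 2.0 * np.pi * self.a * slope

    def axial_conductance(self, r_i: float) -> np.ndarray:
        """pi a^2 / R_i per node, S cm."""
        return np.pi * self.a**2 / r_i


@dataclass(frozen=True)
class EphysParams:
    """Membrane and cytoplasm electrical parameters.

    Classic Hodgkin-Huxley kinetics and reversal potentials; the single
    ``conductance_scale`` multiplies the Na and K maximal conductances
    and is the model's one calibrated constant, chosen once so that the
    six reference pearled geometries (periodic NaV layout) reproduce
    their predicted conduction velocities with the smallest possible
    maximum relative error.  ``rate_scale`` is the kinetics temperature
    factor (1 = 6.3 C rates).
    """

    c_m: float = 1.0  # uF/cm^2
    r_i: float = 100.0  # ohm cm
    g_na: float = 120.0  # mS/cm^2 (before conductance_scale)
    g_k: float = 36.0
    g_leak: float = 0.3
    e_na: float = 50.0  # mV
    e_k: float = -77.0
    e_leak: float = -54.387
    rate_scale: float = 1.0
    #: reference calibration: chosen once (least-maximum relative error)
    #: so the six reference pearled geometries reproduce their predicted
    #: conduction velocities; see docs/methods.md
    conductance_scale: float = 2.26

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.r_i <= 0:
            raise ValueError("c_m and r_i must be > 0")
        if min(self.g_na, self.g_k, self.g_leak) < 0:
            raise ValueError("conductances must be >= 0")


@dataclass
class ChannelLayout:
    """Per-node relative NaV density (multiplies g_na)."""

    mode: str  # "uniform" | "periodic"
    density: np.ndarray
    period_nm: float = 190.0
    cluster_width_nm: float = 50.0
    n_clusters: int = 0


@dataclass(frozen=True)
class Stimulus:
    """Current injection over the proximal half of the AIS."""

    amplitude: float = 40.0  # uA/cm^2
    onset_ms: float = 0.05
    duration_ms: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1000.0:
            raise ValueError("stimulus amplitude out of range")


@dataclass
class VoltageTraces:
    """Probe voltages and AP bookkeeping."""

    t: np.ndarray
    v_probes: dict  # probe position um -> V(t) mV
    propagated: bool
    rest_mv: float
    meta: dict = field(default_factory=dict)


@dataclass
class VelocityEstimate:
    velocity_m_per_s: float
    t_peak_0: float
    t_peak_277: float
    distance_um: float = 277.0


# ---------------------------------------------------------------------------
# Hodgkin-Huxley kinetics (classic squid parametrization, mV / ms)

def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (exp(x/y) - 1), stable near x = 0."""
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1.0 - x[small] / y / 2.0)
    xs = x[~small]
    out[~small] = xs / (np.exp(xs / y) - 1.0)
    return out


def hh_rates(v: np.ndarray, rate_scale: float = 1.0):
    """alpha/beta for m, h, n at membrane potential v (mV)."""
    am = 0.1 * _vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    s = rate_scale
    return (am * s, bm * s), (ah * s, bh * s), (an * s, bn * s)


def _steady_gates(v: np.ndarray, rate_scale: float = 1.0):
    (am, bm), (ah, bh), (an, bn) = hh_rates(v, rate_scale)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def resting_potential(params: EphysParams, nav_density: float = 1.0) -> float:
    """Resting V where the steady-state HH current vanishes (0D Newton)."""
    g_na = params.g_na * params.conductance_scale * nav_density
    g_k = params.g_k * params.conductance_scale

    def current(v: float) -> float:
        vv = np.array([v])
        m, h, n = _steady_gates(vv, params.rate_scale)
        i = (
            g_na * m**3 * h * (vv - params.e_na)
            + g_k * n**4 * (vv - params.e_k)
            + params.g_leak * (vv - params.e_leak)
        )
        return float(i[0])

    v = -65.0
    for _ in range(60):
        f = current(v)
        df = (current(v + 1e-4) - f) / 1e-4
        if df == 0:
            break
        step = f / df
        v -= np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-10:
            break
    return float(v)


# ---------------------------------------------------------------------------
# Geometry construction

def build_geometry(
    nsv_length: Optional[float] = None,
    nsv_width: Optional[float] = None,
    connector_length: Optional[float] = None,
    connector_width: Optional[float] = None,
    cylinder_diameter: Optional[float] = None,
    ais: AISSpec = AISSpec(),
    trunk_length_um: float = 300.0,
    dx_nm: float = 20.0,
    include_slope_factor: bool = True,
) -> AxonGeometry:
    """Build the model axon: AIS plus pearled or cylindrical trunk.

    Pearl mode takes the four dimensions in nm; cylinder mode a single
    diameter.  The trunk starts at a connector midpoint; the AIS tapers
    onto the trunk radius over its last few um.  The grid must resolve
    the connector with >= 8 samples.
    """
    dims = None
    if cylinder_diameter is not None:
        trunk_radius_nm = lambda x_nm: np.full_like(x_nm, cylinder_diameter / 2.0)
        r_at_zero = cylinder_diameter / 2.0
    else:
        if None in (nsv_length, nsv_width, connector_length, connector_width):
            raise ValueError("give all four pearl dimensions or a cylinder diameter")
        dims = PearlDims(nsv_length, nsv_width, connector_length, connector_width).validate()
        if dims.connector_length < 8 * dx_nm:
            raise ValueError(
                f"dx = {dx_nm} nm too coarse: fewer than 8 samples per "
                f"{dims.connector_length} nm connector"
            )
        trunk_radius_nm = lambda x_nm: pearl_radius_periodic(x_nm, dims)
        r_at_zero = dims.connector_width / 2.0

    dx = dx_nm * NM_TO_CM
    n_ais = int(round(ais.length_um * UM_TO_CM / dx))
    n_trunk = int(round(trunk_length_um * UM_TO_CM / dx)) + 1
    x = (np.arange(n_ais + n_trunk) - n_ais) * dx

    a = np.empty(x.size)
    a[:n_ais] = ais.diameter_nm / 2.0 * NM_TO_CM
    trunk_x_nm = (x[n_ais:] / NM_TO_CM)
    a[n_ais:] = trunk_radius_nm(trunk_x_nm) * NM_TO_CM

    # half-cosine taper from the AIS radius to the trunk entry radius
    n_taper = int(round(ais.taper_um * UM_TO_CM / dx))
    if n_taper > 0 and n_ais > n_taper:
        s = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_taper) / n_taper))  # 0 -> 1
        r0_cm = ais.diameter_nm / 2.0 * NM_TO_CM
        r1_cm = r_at_zero * NM_TO_CM
        a[n_ais - n_taper : n_ais] = r0_cm + (r1_cm - r0_cm) * s
    return AxonGeometry(
        x=x, a=a, dx=dx, trunk_start=n_ais, ais=ais, dims=dims,
        cylinder_diameter_nm=cylinder_diameter,
        include_slope_factor=include_slope_factor,
    )


def place_channels(
    geometry: AxonGeometry,
    mode: str = "uniform",
    period_nm: float = 190.0,
    cluster_width_nm: float = 50.0,
) -> ChannelLayout:
    """NaV density profile: uniform, or 190-nm periodic clusters.

    In periodic mode the trunk sodium conductance is concentrated into
    clusters of ``cluster_width_nm`` every ``period_nm``, rescaled so
    the membrane-area-integrated Na conductance over the trunk equals
    the uniform layout's (well within 0.1%); the AIS keeps its uniform
    elevated density, and K/leak conductances are always uniform.
    """
    if mode not in ("uniform", "periodic"):
        raise ValueError("mode must be 'uniform' or 'periodic'")
    n = geometry.n
    i0 = geometry.trunk_start
    density = np.ones(n)
    density[:i0] = geometry.ais.nav_multiplier
    if mode == "uniform":
        return ChannelLayout(mode, density, period_nm, cluster_width_nm)

    if cluster_width_nm < geometry.dx / NM_TO_CM:
        raise ValueError("cluster width below the grid spacing")
    x_nm = geometry.x[i0:] / NM_TO_CM
    phase = np.mod(x_nm, period_nm)
    in_cluster = (phase <= cluster_width_nm / 2.0) | (
        phase >= period_nm - cluster_width_nm / 2.0
    )
    cluster_id = np.round(x_nm / period_nm).astype(int)
    w = geometry.membrane_width()[i0:]
    total_uniform = float(np.sum(w))
    if not np.any(in_cluster):
        raise ValueError("no cluster nodes on the trunk grid")
    # Each cluster is one spectrin-actin ring and carries the same
    # channel complement regardless of the local axon caliber, so the
    # per-area density inside a cluster scales inversely with the local
    # membrane area; the grand total matches the uniform layout exactly.
    n_clusters = int(np.floor(x_nm[-1] / period_nm)) + 1
    per_cluster = total_uniform / n_clusters
    trunk_density = np.zeros(x_nm.size)
    for cid in range(n_clusters):
        sel = in_cluster & (cluster_id == cid)
        area = float(np.sum(w[sel]))
        if area > 0:
            trunk_density[sel] = per_cluster / area
    density[i0:] = trunk_density
    return ChannelLayout(mode, density, period_nm, cluster_width_nm, n_clusters)


# ---------------------------------------------------------------------------
# Simulation

PROBE_POSITIONS_UM = (-90.0, 0.0, 277.0)


def simulate_ap(
    geometry: AxonGeometry,
    params: EphysParams = EphysParams(),
    layout: Optional[ChannelLayout] = None,
    stimulus: Stimulus = Stimulus(),
    dt_ms: float = 0.002,
    t_max_ms: float = 8.0,
    probes_um=PROBE_POSITIONS_UM,
    stop_after_peak: bool = True,
    track_diagnostics: bool = False,
) -> VoltageTraces:
    """Integrate the generalized cable + HH system; return probe traces.

    Sealed (zero axial current) ends; the initial condition is the
    uniform resting state with gating at steady state.  Crank-Nicolson
    treats the axial operator and the instantaneous ionic conductances
    implicitly; gating is advanced by an exact exponential step at the
    frozen voltage (staggered).  Raises on numerical blow-up
    (|V| > 500 mV); non-propagation is reported in the traces, not an
    error.  The run stops early once the distal probe's peak has safely
    passed (disable with ``stop_after_peak=False``).
    """
    if layout is None:
        layout = place_channels(geometry, "uniform")
    n = geometry.n
    dx = geometry.dx
    w = geometry.membrane_width()  # cm
    g_ax = geometry.axial_conductance(params.r_i) * 1e3  # mS cm

    # half-node axial conductances -> tridiagonal operator, sealed ends
    g_half = 0.5 * (g_ax[:-1] + g_ax[1:]) / dx**2  # mS/cm
    diag_a = np.zeros(n)
    diag_a[:-1] -= g_half
    diag_a[1:] -= g_half

    def apply_axial(vv: np.ndarray) -> np.ndarray:
        out = diag_a * vv
        out[1:] += g_half * vv[:-1]
        out[:-1] += g_half * vv[1:]
        return out

    gna_scaled = params.g_na * params.conductance_scale * layout.density  # mS/cm^2
    # The AIS co-elevates K and leak alongside its Na multiplier (real
    # initial segments are dense in Kv channels too).  Scaling all three
    # by the same factor leaves the resting potential exactly uniform
    # along the axon while making the AIS more excitable per area.
    # Trunk K and leak are always uniform.
    ais_density = np.ones(n)
    ais_density[: geometry.trunk_start] = geometry.ais.nav_multiplier
    gk = params.g_k * params.conductance_scale * ais_density
    gleak = params.g_leak * ais_density
    v_rest = resting_potential(params)
    v = np.full(n, v_rest)
    m, h, gate_n = _steady_gates(v, params.rate_scale)

    # stimulated nodes: proximal half of the AIS
    x_um = geometry.x / UM_TO_CM
    ais_len = geometry.ais.length_um
    stim_mask = (x_um >= -ais_len) & (x_um <= -ais_len / 2.0)

    probe_idx = {p: int(np.argmin(np.abs(x_um - p))) for p in probes_um}
    n_steps = int(round(t_max_ms / dt_ms))
    t = np.arange(n_steps + 1) * dt_ms
    traces = {p: np.empty(n_steps + 1) for p in probes_um}
    for p, idx in probe_idx.items():
        traces[p][0] = v[idx]

    # uF/cm^2 * mV/ms = uA/cm^2, matching mS/cm^2 * mV = uA/cm^2
    cw_dt = params.c_m * w / dt_ms
    distal = max(probes_um)
    distal_idx = probe_idx[distal]
    distal_peak_t = None
    distal_max = -np.inf
    n_done = n_steps

    gate_min, gate_max = 1.0, 0.0
    charge0 = float(np.sum(params.c_m * w * (v - v_rest)) * dx)  # uC/cm relative to rest
    injected = 0.0

    ab = np.zeros((3, n))
    for step in range(1, n_steps + 1):
        t_now = (step - 0.5) * dt_ms
        # (1) gating: exact exponential update at frozen voltage
        (am, bm), (ah, bh), (an, bn) = hh_rates(v, params.rate_scale)
        for gate, alpha, beta in ((0, am, bm), (1, ah, bh), (2, an, bn)):
            tau = 1.0 / (alpha + beta)
            inf = alpha * tau
            decay = np.exp(-dt_ms / tau)
            if gate == 0:
                m = inf + (m - inf) * decay
            elif gate == 1:
                h = inf + (h - inf) * decay
            else:
                gate_n = inf + (gate_n - inf) * decay

        # (2) semi-implicit CN solve for V
        g_ion = gna_scaled * m**3 * h + gk * gate_n**4 + gleak  # mS/cm^2
        s_ion = (
            gna_scaled * m**3 * h * params.e_na
            + gk * gate_n**4 * params.e_k
            + gleak * params.e_leak
        )
        stim_on = stimulus.onset_ms <= t_now < stimulus.onset_ms + stimulus.duration_ms
        i_stim = np.where(stim_mask, stimulus.amplitude, 0.0) if stim_on else 0.0
        # units: mS, mV, ms, cm (currents uA/cm^2)
        diag_lhs = cw_dt + 0.5 * w * g_ion - 0.5 * diag_a
        rhs = (cw_dt - 0.5 * w * g_ion) * v + 0.5 * apply_axial(v) + w * (s_ion + i_stim)
        ab[0, 1:] = -0.5 * g_half
        ab[1] = diag_lhs
        ab[2, :-1] = -0.5 * g_half
        v = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > 500.0:
            raise FloatingPointError(f"voltage blow-up at step {step} (t = {step * dt_ms} ms)")

        if track_diagnostics:
            gate_min = min(gate_min, float(m.min()), float(h.min()), float(gate_n.min()))
            gate_max = max(gate_max, float(m.max()), float(h.max()), float(gate_n.max()))
            if np.ndim(i_stim):
                injected += float(np.sum(w * i_stim)) * dx * dt_ms  # uC/cm... per cm? (nC)

        for p, idx in probe_idx.items():
            traces[p][step] = v[idx]
        if v[distal_idx] > distal_max:
            distal_max = v[distal_idx]
            distal_peak_t = step * dt_ms
        if (
            stop_after_peak
            and distal_max > 0.0
            and step * dt_ms - distal_peak_t > 0.5
        ):
            n_done = step
            break

    t = t[: n_done + 1]
    traces = {p: tr[: n_done + 1] for p, tr in traces.items()}
    propagated = bool(traces[distal].max() > 0.0)
    return VoltageTraces(
        t=t,
        v_probes=traces,
        propagated=propagated,
        rest_mv=v_rest,
        meta={
            "dt_ms": dt_ms,
            "dx_nm": geometry.dx / NM_TO_CM,
            "layout": layout.mode,
            "stimulus_uA_cm2": stimulus.amplitude,
            **(
                {
                    "gate_min": gate_min,
                    "gate_max": gate_max,
                    "charge_final": float(np.sum(params.c_m * w * (v - v_rest)) * dx) - charge0,
                    "charge_injected": injected,
                }
                if track_diagnostics
                else {}
            ),
        },
    )


def _interp_peak(t: np.ndarray, y: np.ndarray) -> float:
    """Quadratic-interpolated time of the maximum of y(t)."""
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(t[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(t[i] + np.clip(delta, -1, 1) * (t[1] - t[0]))


def conduction_velocity(traces: VoltageTraces, x0_um: float = 0.0, x1_um: float = 277.0) -> VelocityEstimate:
    """Velocity from the voltage time-to-peak at the two probes, m/s."""
    if not traces.propagated:
        raise ValueError("no propagated AP: velocity undefined")
    t0 = _interp_peak(traces.t, traces.v_probes[x0_um])
    t1 = _interp_peak(traces.t, traces.v_probes[x1_um])
    if t1 <= t0:
        raise ValueError("distal peak does not lag proximal peak")
    dist_m = (x1_um - x0_um) * 1e-6
    dt_s = (t1 - t0) * 1e-3
    return VelocityEstimate(dist_m / dt_s, t0, t1, x1_um - x0_um)


def upstroke_velocity(traces: VoltageTraces, x0_um: float = 0.0, x1_um: float = 277.0) -> float:
    """Alternative readout: velocity from half-maximum upstroke crossings."""
    out = []
    for p in (x0_um, x1_um):
        y = traces.v_probes[p]
        base = y[0]
        half = base + 0.5 * (y.max() - base)
        i = int(np.argmax(y >= half))
        if i == 0:
            raise ValueError("no upstroke at probe")
        frac = (half - y[i - 1]) / (y[i] - y[i - 1])
        out.append(traces.t[i - 1] + frac * (traces.t[i] - traces.t[i - 1]))
    dt_s = (out[1] - out[0]) * 1e-3
    return (x1_um - x0_um) * 1e-6 / dt_s


# ---------------------------------------------------------------------------
# Predictions and sweeps

def predict_from_measurements(
    row,
    params: EphysParams = EphysParams(),
    layout_mode: str = "periodic",
    dx_nm: float = 20.0,
    dt_ms: float = 0.002,
) -> float:
    """Velocity (m/s) predicted from one measured geometry.

    ``row`` is a (nsv_length, nsv_width, connector_length,
    connector_width) tuple in nm, or a mapping with those keys.
    """
    if hasattr(row, "keys"):
        vals = tuple(
            float(row[k])
            for k in ("nsv_length", "nsv_width", "connector_length", "connector_width")
        )
    else:
        vals = tuple(float(v) for v in row)
    geom = build_geometry(*vals, dx_nm=dx_nm)
    layout = place_channels(geom, layout_mode)
    traces = simulate_ap(geom, params, layout, dt_ms=dt_ms)
    return conduction_velocity(traces).velocity_m_per_s


def _gaussian(x, amp, mu, sd, base):
    return base + amp * np.exp(-((x - mu) ** 2) / (2 * sd**2))


def sweep_dimension(
    which: str,
    values: np.ndarray,
    base: dict | None = None,
    params: EphysParams = EphysParams(),
    layout_mode: str = "periodic",
    dx_nm: float = 20.0,
    dt_ms: float = 0.002,
):
    """Velocity versus one geometric dimension, with the trend fit.

    ``which`` is one of nsv_length / nsv_width / connector_length /
    connector_width / cylinder_diameter; the other pearl dimensions stay
    at the control values (or ``base``).  Linear fit for connector and
    cylinder dimensions; concave Gaussian fit (with interior argmax
    report) for NSV width.  Non-propagating points are flagged and
    excluded from the fit.

    Returns (pandas DataFrame, fit dict).
    """
    import pandas as pd
    from scipy.optimize import curve_fit
    from scipy.stats import linregress

    base_dims = dict(
        zip(
            ("nsv_length", "nsv_width", "connector_length", "connector_width"),
            REFERENCE_GEOMETRIES["control"],
        )
    )
    if base:
        base_dims.update(base)
    rows = []
    for val in np.asarray(values, dtype=float):
        if which == "cylinder_diameter":
            geom = build_geometry(cylinder_diameter=val, dx_nm=dx_nm)
        else:
            d = dict(base_dims)
            d[which] = float(val)
            geom = build_geometry(**d, dx_nm=dx_nm)
        layout = place_channels(geom, layout_mode)
        try:
            traces = simulate_ap(geom, params, layout, dt_ms=dt_ms)
            vel = conduction_velocity(traces).velocity_m_per_s if traces.propagated else np.nan
        except FloatingPointError:
            vel = np.nan
        rows.append({which: float(val), "velocity_m_per_s": vel, "propagated": np.isfinite(vel)})
    df = pd.DataFrame(rows)
    ok = df[df.propagated]
    fit: dict = {"kind": None}
    if len(ok) >= 3:
        xs = ok[which].values
        ys = ok["velocity_m_per_s"].values
        if which == "nsv_width":
            p0 = (ys.max() - ys.min(), xs[np.argmax(ys)], (xs.max() - xs.min()) / 3, ys.min())
            try:
                popt, _ = curve_fit(_gaussian, xs, ys, p0=p0, maxfev=20000)
                fit = {
                    "kind": "gaussian",
                    "argmax": float(popt[1]),
                    "amplitude": float(popt[0]),
                    "sd": float(abs(popt[2])),
                    "baseline": float(popt[3]),
                }
            except RuntimeError:
                fit = {"kind": "gaussian", "argmax": float(xs[np.argmax(ys)])}
        else:
            res = linregress(xs, ys)
            fit = {
                "kind": "linear",
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r_value": float(res.rvalue),
            }
    return df, fit


def sweep_ratio(
    nsv_lengths: np.ndarray,
    nsv_widths: np.ndarray,
    params: EphysParams = EphysParams(),
    layout_mode: str = "periodic",
    dx_nm: float = 20.0,
    dt_ms: float = 0.002,
):
    """Joint NSV length x width sweep; returns the velocity grid table.

    Connector dimensions stay at control values.  The NSV length:width
    ratio at the velocity maximum is the headline readout.
    """
    import pandas as pd

    _, _, cl, cw = REFERENCE_GEOMETRIES["control"]
    rows = []
    for ln in np.asarray(nsv_lengths, dtype=float):
        for wd in np.asarray(nsv_widths, dtype=float):
            if wd <= cw:
                continue
            geom = build_geometry(ln, wd, cl, cw, dx_nm=dx_nm)
            layout = place_channels(geom, layout_mode)
            try:
                traces = simulate_ap(geom, params, layout, dt_ms=dt_ms)
                vel = conduction_velocity(traces).velocity_m_per_s if traces.propagated else np.nan
            except FloatingPointError:
                vel = np.nan
            rows.append(
                {
                    "nsv_length": ln,
                    "nsv_width": wd,
                    "ratio": ln / wd,
                    "velocity_m_per_s": vel,
                }
            )
    df = pd.DataFrame(rows)
    ok = df.dropna()
    best = ok.loc[ok["velocity_m_per_s"].idxmax()] if len(ok) else None
    return df, (float(best["ratio"]) if best is not None else np.nan)
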