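"""Axisymmetric membrane mechanics of axon pearling.

The axon membrane is modeled as a thin elastic surface with the Helfrich
bending energy plus tension and osmotic pressure-volume work,

    E = integral (kappa/2) (2H - C0)^2 dA  +  sigma * A  +  E_osm(V),

evaluated on axisymmetric shapes r(z) over a periodic axial domain (the
tube is open-ended and connected to implicit membrane reservoirs, so
area is free to exchange at fixed tension sigma).  The enclosed solute
amount n is fixed and the osmotic term is the ideal (van 't Hoff)
potential E_osm(V) = kBT [c_ext V - n ln(V/V_ref)], whose negative
volume-derivative is the pressure difference

    dP = kBT (n/V - c_ext),

so shrinkage under raised external osmolarity is emergent rather than
imposed.  Units: lengths nm, energies kBT, tension kBT/nm^2, pressure
kBT/nm^3; osmolarity input in mOsm is converted to particles/nm^3.

A cylinder under sufficient tension (sigma r0^2 / kappa >> 1) is
linearly unstable to peristaltic modulation (pearling); the relaxed
shapes are unduloid-like, with constant mean curvature in the
tension/pressure-dominated regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .profiles import RadiusProfile

__all__ = [
    "MOSM_TO_PER_NM3",
    "MembraneParams",
    "ShapeState",
    "EnergyBreakdown",
    "helfrich_energy",
    "osmotic_pressure",
    "relax_shape",
    "relax_cylinder",
    "cmc_deviation",
    "pearling_stability",
    "sweep_parameters",
]

#: 1 mOsm = 1 mol/m^3 = N_A / 1e27 particles per nm^3
MOSM_TO_PER_NM3 = 6.02214076e-4


@dataclass(frozen=True)
class MembraneParams:
    """Material and osmotic parameters of the membrane model.

    kappa : bending rigidity, kBT (physiological sweep range 20-100)
    sigma : surface tension, kBT/nm^2
    c0 : spontaneous curvature, 1/nm
    c_ext_mosm : external osmolarity, mOsm
    n_solute : enclosed solute amount, particle count (fixed)
    temperature : K, bookkeeping only (energies are already in kBT)
    """

    kappa: float = 50.0
    sigma: float = 0.05
    c0: float = 0.0
    c_ext_mosm: float = 300.0
    n_solute: float = 0.0
    temperature: float = 310.0
    osmotic_coupling: float = 0.003

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.c_ext_mosm < 0 or self.n_solute < 0:
            raise ValueError("c_ext_mosm and n_solute must be >= 0")
        if self.osmotic_coupling <= 0:
            raise ValueError("osmotic_coupling must be > 0")

    @property
    def c_ext(self) -> float:
        """Effective external osmolarity in particles/nm^3.

        ``osmotic_coupling`` scales the raw van 't Hoff stiffness down to
        an effective osmotic modulus: on membrane-shape relaxation
        timescales a neuron is far from an ideal osmometer (channels and
        transporters exchange solute), and the raw physiological value
        would pin the volume four orders of magnitude more stiffly than
        any membrane stress.  The default puts the osmotic stiffness at
        the scale of the Laplace pressure of a ~100-nm tube, where
        tension, pressure and rigidity all visibly shape the pearls;
        osmolarity values are therefore milliosmolar *equivalents*.
        """
        return self.osmotic_coupling * self.c_ext_mosm * MOSM_TO_PER_NM3

    def with_isotonic_solute(self, volume: float) -> "MembraneParams":
        """Copy with n_solute set so dP = 0 at the given volume."""
        from dataclasses import replace

        return replace(self, n_solute=self.c_ext * volume)


@dataclass
class ShapeState:
    """Axisymmetric shape r(z) on a uniform axial grid.

    ``periodic`` selects wrap-around derivatives/quadrature (the pearl
    lattice) versus one-sided ends (e.g. a sphere cap parametrization).
    """

    z: np.ndarray
    r: np.ndarray
    periodic: bool = True

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.r.shape or self.z.size < 8:
            raise ValueError("z and r must be equal-length 1D arrays (>= 8 points)")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")

    @property
    def h(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def domain_length(self) -> float:
        """Axial extent; for periodic states the period is n*h."""
        n = self.z.size
        return float(n * self.h) if self.periodic else float(self.z[-1] - self.z[0])

    def geometry(self):
        """(area, volume, mean curvature field) by solid-of-revolution quadrature."""
        a, v, hfield, _ = _geometry_batch(self.r[None, :], self.h, self.periodic)
        return float(a[0]), float(v[0]), hfield[0]

    def to_profile(self, tile: int = 1) -> RadiusProfile:
        """Export as a RadiusProfile, optionally tiling a periodic shape."""
        if self.periodic and tile > 1:
            n = self.z.size
            r = np.tile(self.r, tile)
            z = np.arange(r.size) * self.h
            return RadiusProfile(z, r)
        return RadiusProfile(self.z - self.z[0], self.r)


@dataclass
class EnergyBreakdown:
    """Helfrich energy terms in kBT."""

    bending: float
    tension: float
    osmotic: float
    area: float
    volume: float

    @property
    def total(self) -> float:
        return self.bending + self.tension + self.osmotic


def _geometry_batch(r: np.ndarray, h: float, periodic: bool):
    """Vectorized area/volume/curvature for shapes r of shape (B, N).

    Mean curvature of a surface of revolution:
        H = 1/(2 r sqrt(1 + r'^2)) - r'' / (2 (1 + r'^2)^(3/2))
    """
    if periodic:
        rp = (np.roll(r, -1, axis=1) - np.roll(r, 1, axis=1)) / (2 * h)
        rpp = (np.roll(r, -1, axis=1) - 2 * r + np.roll(r, 1, axis=1)) / h**2
        w = np.full(r.shape[1], h)
    else:
        rp = np.gradient(r, h, axis=1)
        rpp = np.gradient(rp, h, axis=1)
        w = np.full(r.shape[1], h)
        w[0] = w[-1] = h / 2  # trapezoid ends
    g = 1.0 + rp**2
    sqrt_g = np.sqrt(g)
    area = (2 * np.pi * r * sqrt_g) @ w
    volume = (np.pi * r**2) @ w
    hfield = 1.0 / (2 * r * sqrt_g) - rpp / (2 * g**1.5)
    darea = 2 * np.pi * r * sqrt_g * w  # per-node area element
    return area, volume, hfield, darea


def _osmotic_potential(volume: np.ndarray, params: MembraneParams):
    """E_osm(V) = c_ext V - n ln(V/V_ref), kBT (kBT == 1 internally)."""
    v_ref = params.n_solute / params.c_ext if params.c_ext > 0 and params.n_solute > 0 else 1.0
    out = params.c_ext * volume
    if params.n_solute > 0:
        out = out - params.n_solute * np.log(volume / v_ref)
    return out


def _energy_batch(r: np.ndarray, h: float, periodic: bool, params: MembraneParams):
    area, volume, hfield, darea = _geometry_batch(r, h, periodic)
    bend = params.kappa / 2.0 * np.sum((2 * hfield - params.c0) ** 2 * darea, axis=1)
    return bend + params.sigma * area + _osmotic_potential(volume, params)


def helfrich_energy(state: ShapeState, params: MembraneParams) -> EnergyBreakdown:
    """Energy terms of a shape by quadrature over the surface of revolution.

    Refinement-convergent: for smooth shapes, halving the grid changes
    the total by well under 0.1%.  Raises if the radius is non-positive
    anywhere.
    """
    if np.any(state.r <= 0):
        raise ValueError("radius must be positive everywhere")
    area, volume, hfield, darea = _geometry_batch(state.r[None, :], state.h, state.periodic)
    bend = float(params.kappa / 2.0 * np.sum((2 * hfield[0] - params.c0) ** 2 * darea[0]))
    return EnergyBreakdown(
        bending=bend,
        tension=float(params.sigma * area[0]),
        osmotic=float(_osmotic_potential(volume, params)[0]),
        area=float(area[0]),
        volume=float(volume[0]),
    )


def osmotic_pressure(volume: float, params: MembraneParams) -> float:
    """Pressure difference dP = kBT (n/V - c_ext), in kBT/nm^3.

    Decreasing in V; zero at the isotonic volume V = n/c_ext; tends to
    -kBT c_ext as V -> infinity.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return params.n_solute / volume - params.c_ext


def cmc_deviation(
    state: ShapeState, params: MembraneParams, boundary_layer_mult: float = 2.5
) -> float:
    """Area-weighted relative spread of mean curvature, neck layers excluded.

    At mechanical equilibrium the tension/pressure balance 2 sigma H = dP
    makes H constant (the unduloid property) wherever bending is
    subdominant; bending necessarily becomes order-one within a boundary
    layer of width ~ sqrt(kappa/sigma) around the necks, because that is
    what saturates the pearling instability.  The constancy check is
    therefore restricted to the surface with r > mult * sqrt(kappa/sigma).

    Returns sd(H)/|mean(H)| over that region (area-weighted).
    """
    _, _, hfield, darea = _geometry_batch(state.r[None, :], state.h, state.periodic)
    h_field, da = hfield[0], darea[0]
    bl = np.sqrt(params.kappa / max(params.sigma, 1e-12))
    mask = state.r > boundary_layer_mult * bl
    if mask.sum() < 8:
        mask = state.r > np.median(state.r)  # very thick layer: use bulges
    w = da[mask] / da[mask].sum()
    hm = float(np.sum(h_field[mask] * w))
    hsd = float(np.sqrt(np.sum(w * (h_field[mask] - hm) ** 2)))
    return hsd / abs(hm)


@dataclass
class ConvergenceReport:
    converged: bool
    iterations: int
    final_energy: float
    gradient_norm: float
    pinched_off: bool = False
    message: str = ""
    energy_trace: Optional[np.ndarray] = None


def relax_shape(
    initial: ShapeState,
    params: MembraneParams,
    step: float = 5.0,
    tol: float = 1e-7,
    max_iter: int = 20000,
    r_min: float = 2.0,
    record_energy: bool = False,
) -> tuple[ShapeState, ConvergenceReport]:
    """Gradient-flow descent of the total energy to mechanical equilibrium.

    The osmotic term is orders of magnitude stiffer than the elastic
    terms (it effectively pins the volume), and its stiffness lives
    almost entirely in the uniform-inflation direction: peristaltic
    modes change volume only at second order.  Each iteration therefore
    (1) relaxes the uniform component exactly by a scalar line
    minimization over r -> r + s, then (2) takes a backtracking gradient
    step on the zero-mean shape component.  Both sub-steps decrease the
    energy, so the accepted-energy sequence is non-increasing.

    The shape gradient is the finite-difference gradient of the
    discretized energy (batched central differences), which makes the
    descent an exact gradient flow of the discrete functional.

    Returns the relaxed state and a convergence report; detection of
    pinch-off (min radius below ``r_min``) terminates with a flag and
    the partial state.
    """
    r = initial.r.copy()
    h = initial.h
    periodic = initial.periodic
    n = r.size
    eye = np.eye(n)
    fd = 1e-4  # nm, gradient probe
    energies = []

    def energy(rr: np.ndarray) -> float:
        return float(_energy_batch(rr[None, :], h, periodic, params)[0])

    def grad(rr: np.ndarray) -> np.ndarray:
        plus = _energy_batch(rr[None, :] + fd * eye, h, periodic, params)
        minus = _energy_batch(rr[None, :] - fd * eye, h, periodic, params)
        return (plus - minus) / (2 * fd)

    # Fourier-diagonal preconditioner: the bending term contributes an
    # ~ 2 pi kappa r h k^4 diagonal to the Hessian at high wavenumber,
    # which throttles an explicit flow; dividing the gradient by
    # (1 + alpha c k^4) treats that stiffness semi-implicitly while the
    # Armijo backtracking below still guarantees monotone energy descent.
    kvec = 2 * np.pi * np.fft.rfftfreq(n, h) if periodic else None

    def descent_direction(g0: np.ndarray, alpha: float, r_mean: float) -> np.ndarray:
        if kvec is None:
            return g0
        c_pre = 2 * np.pi * params.kappa * max(r_mean, 1.0) * h
        return np.fft.irfft(np.fft.rfft(g0) / (1.0 + alpha * c_pre * kvec**4), n=n)

    e = energy(r)
    alpha = step
    gnorm = np.inf
    pinched = False
    it = 0
    def relax_uniform(r: np.ndarray, e: float) -> tuple[np.ndarray, float]:
        """Newton steps on the uniform shift r -> r + s (volume-stiff mode)."""
        ds = 1e-3
        for _ in range(3):
            probes = r[None, :] + np.array([[-ds], [0.0], [ds]])
            em, e0, ep = _energy_batch(probes, h, periodic, params)
            d1, d2 = (ep - em) / (2 * ds), (ep - 2 * e0 + em) / ds**2
            if d2 <= 0 or not np.isfinite(d2):
                break
            s = float(np.clip(-d1 / d2, -0.2 * r.min(), 0.5 * r.mean()))
            if abs(s) < 1e-9:
                break
            e_new = energy(r + s)
            if e_new >= e:
                break
            r, e = r + s, e_new
        return r, e

    for it in range(1, max_iter + 1):
        # (1) relaxation of the uniform (volume-stiff) mode
        r, e = relax_uniform(r, e)

        # (2) backtracking step along the zero-mean shape gradient
        g = grad(r)
        g0 = g - g.mean()
        gnorm = float(np.max(np.abs(g0)))
        if record_energy:
            energies.append(e)
        if gnorm < tol:
            report = ConvergenceReport(True, it, e, gnorm, False, "gradient tolerance reached")
            break
        accepted = False
        while alpha > 1e-12:
            d = descent_direction(g0, alpha, float(r.mean()))
            slope = float(np.sum(g0 * d))  # > 0: preconditioner is SPD
            trial = r - alpha * d
            if trial.min() <= 0 or slope <= 0:
                alpha *= 0.5
                continue
            e_trial = energy(trial)
            if e_trial <= e - 1e-4 * alpha * slope:
                r = trial
                e = e_trial
                accepted = True
                alpha = min(alpha * 1.5, 1e6)
                break
            alpha *= 0.5
        if not accepted:
            report = ConvergenceReport(True, it, e, gnorm, False, "line search exhausted (stationary)")
            break
        if r.min() < r_min:
            pinched = True
            report = ConvergenceReport(False, it, e, gnorm, True, "pinch-off detected")
            break
    else:
        report = ConvergenceReport(False, max_iter, e, gnorm, False, "max iterations reached")

    if record_energy:
        report.energy_trace = np.asarray(energies)
    return ShapeState(initial.z.copy(), r, periodic), report


def pearling_stability(
    r0: float,
    params: MembraneParams,
    wavelengths: Optional[np.ndarray] = None,
    eps: float = 0.5,
    grid_n: int = 64,
):
    """Discrete linear stability of a cylinder to peristaltic modulation.

    For each candidate wavelength, the energy curvature along the
    cos(2 pi z / wavelength) mode is estimated by a symmetric second
    difference on a one-period domain (solute fixed at the isotonic
    amount for the unperturbed cylinder).  Negative curvature means the
    mode grows; the most negative one sets the expected pearl period.

    Returns (wavelengths, curvatures, fastest_wavelength); the fastest
    wavelength is NaN when the cylinder is linearly stable.
    """
    from scipy.optimize import minimize_scalar

    if wavelengths is None:
        wavelengths = r0 * np.linspace(3.0, 30.0, 55)
    curv = np.empty(wavelengths.size)
    for i, lam in enumerate(wavelengths):
        h = lam / grid_n
        z = np.arange(grid_n) * h
        p = params.with_isotonic_solute(np.pi * r0**2 * lam)

        # Equilibrate the uniform mode first: tension deflates the tube
        # until the osmotic pressure difference carries the Laplace load.
        # Only around that base state does the modulation instability of
        # a tense tube show up in the energy curvature.
        def e_uniform(rr: float) -> float:
            return float(_energy_batch(np.full((1, grid_n), rr), h, True, p)[0])

        res = minimize_scalar(
            e_uniform, bounds=(0.2 * r0, 2.0 * r0), method="bounded",
            options={"xatol": 1e-8},
        )
        r_eq = float(res.x)
        mode = np.cos(2 * np.pi * z / lam)
        e0 = float(res.fun)
        ep = _energy_batch(r_eq + eps * mode[None, :], h, True, p)[0]
        em = _energy_batch(r_eq - eps * mode[None, :], h, True, p)[0]
        # curvature per unit length, so different wavelengths are comparable
        curv[i] = (ep + em - 2 * e0) / eps**2 / lam

    if not np.any(curv < 0):
        return wavelengths, curv, float("nan")
    # Marginal wavelength: sign change from stable (short) to unstable
    # (long).  The energy analysis alone has no growth rate; the classic
    # fastest-growing peristaltic mode lies at k_marginal / sqrt(2),
    # i.e. at sqrt(2) times the marginal wavelength.
    unstable = np.where(curv < 0)[0]
    j = unstable[0]
    if j == 0:
        lam_c = float(wavelengths[0])
    else:
        w0, w1 = wavelengths[j - 1], wavelengths[j]
        c0, c1 = curv[j - 1], curv[j]
        lam_c = float(w0 + (w1 - w0) * c0 / (c0 - c1))
    return wavelengths, curv, float(np.sqrt(2.0) * lam_c)


def relax_cylinder(
    r0: float,
    params: MembraneParams,
    domain: Optional[float] = None,
    grid_n: int = 96,
    perturbation: float = 0.02,
    seed: int = 0,
    **relax_kwargs,
) -> tuple[ShapeState, ConvergenceReport]:
    """Relax a perturbed cylinder of radius r0 on a one-period domain.

    The domain defaults to the fastest-growing wavelength of the linear
    stability analysis (falling back to 4 pi r0 when the cylinder is
    stable); the enclosed solute is fixed at the isotonic amount for the
    initial cylinder, and a small seeded cosine perturbation breaks the
    translational symmetry.
    """
    if domain is None:
        _, _, fastest = pearling_stability(r0, params)
        domain = fastest if np.isfinite(fastest) else 4 * np.pi * r0
    z = np.arange(grid_n) * (domain / grid_n)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    r = r0 * (1.0 + perturbation * np.cos(2 * np.pi * z / domain + phase))
    p = params.with_isotonic_solute(np.pi * r0**2 * domain)
    state = ShapeState(z, r, periodic=True)
    return relax_shape(state, p, **relax_kwargs)


def sweep_parameters(
    c_ext_mosm: Optional[np.ndarray] = None,
    sigma: Optional[np.ndarray] = None,
    kappa: Optional[np.ndarray] = None,
    r0: float = 100.0,
    base: Optional[MembraneParams] = None,
    grid_n: int = 96,
    seed: int = 0,
    n_solute_ref: Optional[float] = None,
    **relax_kwargs,
):
    """Relax shapes over parameter grids and measure the pearl dimensions.

    One parameter list at a time is swept against the ``base`` template
    (the others fixed); all runs share the seed and resolution.  For the
    osmolarity sweep the enclosed solute is fixed at the isotonic amount
    of the *reference* (base) condition, so raising external osmolarity
    deflates the equilibrium volume.  Each relaxed one-period shape is
    tiled and segmented with the standard morphometry pipeline to read
    off NSV width and length.

    Returns a pandas DataFrame with one row per grid point.
    """
    import pandas as pd
    from dataclasses import replace

    from .morphometry import segment_profile

    base = base or MembraneParams()
    grids = []
    if c_ext_mosm is not None:
        grids += [("c_ext_mosm", float(v)) for v in c_ext_mosm]
    if sigma is not None:
        grids += [("sigma", float(v)) for v in sigma]
    if kappa is not None:
        grids += [("kappa", float(v)) for v in kappa]
    if not grids:
        raise ValueError("no sweep values given")

    # reference solute amount: isotonic cylinder at the base osmolarity,
    # on the base condition's expected period
    _, _, lam_ref = pearling_stability(r0, base)
    if not np.isfinite(lam_ref):
        lam_ref = 4 * np.pi * r0
    if n_solute_ref is None:
        n_solute_ref = base.c_ext * np.pi * r0**2 * lam_ref

    rows = []
    for name, val in grids:
        # identical configuration for every run -- same seed, resolution,
        # domain period (the base condition's fastest-growing wavelength)
        # and enclosed solute -- except the one swept parameter
        lam = lam_ref
        z = np.arange(grid_n) * (lam / grid_n)
        rng = np.random.default_rng(seed)
        r = r0 * (1.0 + 0.02 * np.cos(2 * np.pi * z / lam + rng.uniform(0, 2 * np.pi)))
        p_run = replace(base, **{name: val}, n_solute=n_solute_ref)
        state, report = relax_shape(ShapeState(z, r, periodic=True), p_run, **relax_kwargs)
        nsv_w = nsv_l = np.nan
        if not report.pinched_off:
            prof = state.to_profile(tile=max(4, int(np.ceil(3000.0 / lam))))
            segs = segment_profile(prof, smoothing_window=max(15.0, 2.5 * prof.spacing))
            widths = [s.width for s in segs if s.kind == "nsv"]
            lengths = [s.length for s in segs if s.kind == "nsv"]
            if widths:
                nsv_w = float(np.median(widths))
                nsv_l = float(np.median(lengths))
        rows.append(
            {
                "parameter": name,
                "value": val,
                "kappa": p_run.kappa,
                "sigma": p_run.sigma,
                "c_ext_mosm": p_run.c_ext_mosm,
                "period_nm": lam,
                "nsv_width_nm": nsv_w,
                "nsv_length_nm": nsv_l,
                "converged": bool(report.converged),
                "pinched_off": bool(report.pinched_off),
                "iterations": report.iterations,
            }
        )
    return pd.DataFrame(rows)
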