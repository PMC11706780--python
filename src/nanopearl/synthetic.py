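"""Synthetic pearled-axon data with known ground truth.

Generates the inputs that the measurement and simulation stages consume:
EM-like 1D radius profiles of pearled axons, STED-like intensity profiles,
serial-section stacks and annotated axon populations.  Default dimensions
follow the EM cohort summaries of dissociated hippocampal cultures
(NSV 600 x 311 nm, connector 552 x 127 nm); cohort generators draw
per-axon dimensions from zero-truncated normals because only mean +/-
s.e.m. summaries are reported for the real cohorts, with the per-axon
s.d. back-computed as s.e.m. * sqrt(n) and user-overridable.

All generators take explicit integer seeds and are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .profiles import PearlDims, RadiusProfile, chain_radius

__all__ = [
    "PearlChainSpec",
    "GroundTruth",
    "IntensityProfile",
    "SectionStack",
    "DEFAULT_SAMPLE_SPACING_NM",
    "gen_pearl_profile",
    "gen_population",
    "gen_sted_profile",
    "gen_serial_sections",
]

#: Default axial sample spacing (nm); >= 10x finer than the thinnest
#: reported connector (52 nm), so no feature is under-resolved.
DEFAULT_SAMPLE_SPACING_NM = 5.0

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class PearlChainSpec:
    """Specification of one synthetic pearled axon.

    Dimensions in nm; ``jitter_cv`` is the per-period coefficient of
    variation applied independently to each of the four dimensions;
    ``noise_sd`` is additive Gaussian radius noise in nm.
    """

    nsv_length: float = 600.0
    nsv_width: float = 311.0
    connector_length: float = 552.0
    connector_width: float = 127.0
    n_periods: int = 10
    jitter_cv: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    spacing: float = DEFAULT_SAMPLE_SPACING_NM

    def validate(self) -> "PearlChainSpec":
        PearlDims(
            self.nsv_length, self.nsv_width, self.connector_length, self.connector_width
        ).validate()
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.jitter_cv < 0 or self.noise_sd < 0:
            raise ValueError("jitter_cv and noise_sd must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        return self

    @property
    def dims(self) -> PearlDims:
        return PearlDims(
            self.nsv_length, self.nsv_width, self.connector_length, self.connector_width
        )


@dataclass
class GroundTruth:
    """Exact pre-noise geometry of a generated chain.

    ``boundaries`` are the analytic inflection-point positions (nm),
    strictly increasing; segments between them alternate
    connector/NSV/connector/...  ``nsv_dims`` and ``connector_dims``
    are per-segment (length, width) pairs in axial order.
    """

    boundaries: np.ndarray
    nsv_dims: list[tuple[float, float]]
    connector_dims: list[tuple[float, float]]
    is_synaptic: np.ndarray
    axon_max_diameter: float

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("ground-truth boundaries must be strictly increasing")
        self.boundaries = b
        self.is_synaptic = np.asarray(self.is_synaptic, dtype=bool)


@dataclass
class IntensityProfile:
    """1D fluorescence-like intensity versus axial position (nm)."""

    x: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.shape != self.intensity.shape:
            raise ValueError("x and intensity must have equal shapes")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass
class SectionStack:
    """Serial ultrathin sections: per-section in-plane displacements.

    ``displacements`` is an (n_sections, 2) array of nm offsets of the
    axon centerline between consecutive sections (first row zero);
    ``section_thickness`` the cutting thickness in nm (40 by default).
    """

    displacements: np.ndarray
    section_thickness: float = 40.0
    true_3d_length: Optional[float] = None

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be > 0")
        if self.displacements.ndim != 2 or self.displacements.shape[0] < 2:
            raise ValueError("need at least 2 sections of 2D displacements")

    @property
    def n_sections(self) -> int:
        return int(self.displacements.shape[0])

    @property
    def inplane_length(self) -> float:
        return float(np.linalg.norm(self.displacements[1:], axis=1).sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "section_thickness_nm": self.section_thickness,
                "displacements_nm": self.displacements.tolist(),
                "true_3d_length_nm": self.true_3d_length,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SectionStack":
        obj = json.loads(text)
        return cls(
            np.asarray(obj["displacements_nm"], dtype=float),
            obj["section_thickness_nm"],
            obj.get("true_3d_length_nm"),
        )


def _truncated_normal(rng: np.random.Generator, mean, sd, size=None) -> np.ndarray:
    """Normal draw truncated (by redraw) at zero; degenerate when sd == 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), np.shape(mean) if size is None else size)
    out = rng.normal(mean, sd)
    out = np.atleast_1d(np.asarray(out, dtype=float))
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], sd)
    else:  # pragma: no cover - pathological mean/sd
        raise ValueError("could not draw positive dimensions; mean/sd too extreme")
    return out


def gen_pearl_profile(spec: PearlChainSpec) -> tuple[RadiusProfile, GroundTruth]:
    """Generate one pearled radius profile with exact ground truth.

    The noiseless backbone has, per period, a smooth C^2 bump of maximal
    diameter ``nsv_width`` whose inflection points are ``nsv_length``
    apart, joined by connectors of diameter ``connector_width`` and
    length ``connector_length`` (chains start and end with a connector).
    Per-period dimensional jitter and additive radius noise are applied
    on top; ``GroundTruth`` records the pre-noise geometry exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    means = np.array(
        [spec.nsv_length, spec.nsv_width, spec.connector_length, spec.connector_width]
    )
    if spec.jitter_cv > 0:
        draws = np.column_stack(
            [
                _truncated_normal(rng, np.full(spec.n_periods, m), spec.jitter_cv * m)
                for m in means
            ]
        )
        # keep each period pearled: NSV must stay wider than its connector
        bad = draws[:, 1] <= draws[:, 3]
        draws[bad, 1] = draws[bad, 3] * 1.05
    else:
        draws = np.tile(means, (spec.n_periods, 1))

    dims = [PearlDims(*row) for row in draws]
    total = sum(d.period for d in dims) + dims[-1].connector_length
    x = np.arange(0.0, total + spec.spacing / 2.0, spec.spacing)
    r, boundaries = chain_radius(x, dims)
    if spec.noise_sd > 0:
        r = r + rng.normal(0.0, spec.noise_sd, size=r.shape)
        r = np.maximum(r, 1e-3)

    nsv_dims = [(d.nsv_length, d.nsv_width) for d in dims]
    conn_dims = [(d.connector_length, d.connector_width) for d in dims]
    conn_dims.append((dims[-1].connector_length, dims[-1].connector_width))
    truth = GroundTruth(
        boundaries=boundaries,
        nsv_dims=nsv_dims,
        connector_dims=conn_dims,
        is_synaptic=np.zeros(spec.n_periods, dtype=bool),
        axon_max_diameter=float(max(d.nsv_width for d in dims)),
    )
    profile = RadiusProfile(
        x,
        r,
        is_synaptic=truth.is_synaptic.copy(),
        axon_max_diameter=truth.axon_max_diameter,
        meta={"seed": spec.seed, "spacing_nm": spec.spacing},
    )
    return profile, truth


def gen_population(
    dim_means: Sequence[float],
    dim_sds: Sequence[float],
    n_axons: int,
    synaptic_fraction: float = 0.0,
    seed: int = 0,
    n_periods: int = 8,
    noise_sd: float = 0.0,
):
    """Generate a cohort of pearled axons with per-axon dimension draws.

    ``dim_means``/``dim_sds`` order: (nsv_length, nsv_width,
    connector_length, connector_width), nm.  Per-axon dimensions are
    drawn from zero-truncated normals; a ``synaptic_fraction`` of
    varicosities is flagged synaptic (for exclusion-rule testing).

    Returns (profiles, truths, table) where ``table`` is a pandas
    DataFrame of the true per-axon dimensions.
    """
    import pandas as pd

    if n_axons < 1:
        raise ValueError("n_axons must be >= 1")
    means = np.asarray(dim_means, dtype=float)
    sds = np.asarray(dim_sds, dtype=float)
    if means.shape != (4,) or sds.shape != (4,):
        raise ValueError("dim_means and dim_sds must each have 4 entries")
    if np.any(sds < 0):
        raise ValueError("dim_sds must be >= 0")
    if not 0.0 <= synaptic_fraction <= 1.0:
        raise ValueError("synaptic_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    profiles, truths, rows = [], [], []
    for i in range(n_axons):
        d = np.array([_truncated_normal(rng, m, s)[0] for m, s in zip(means, sds)])
        if d[1] <= d[3]:
            d[1] = d[3] * 1.05
        spec = PearlChainSpec(
            *d,
            n_periods=n_periods,
            jitter_cv=0.0,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        profile, truth = gen_pearl_profile(spec)
        flags = rng.random(n_periods) < synaptic_fraction
        truth.is_synaptic = flags
        profile.is_synaptic = flags.copy()
        profiles.append(profile)
        truths.append(truth)
        rows.append(
            {
                "axon": i,
                "nsv_length_nm": d[0],
                "nsv_width_nm": d[1],
                "connector_length_nm": d[2],
                "connector_width_nm": d[3],
                "n_synaptic": int(flags.sum()),
                "n_varicosities": n_periods,
            }
        )
    return profiles, truths, pd.DataFrame(rows)


def gen_sted_profile(
    profile: RadiusProfile,
    psf_fwhm: float,
    pixel: float,
    noise: float = 0.0,
    seed: int = 0,
) -> IntensityProfile:
    """STED-like axial intensity profile of a pearled axon.

    The fluorophore is cytosolic, so the axial signal is proportional to
    the local cross-section area pi r(x)^2, blurred by a Gaussian PSF of
    the stated FWHM and sampled at ``pixel`` nm.  ``noise`` sets the
    expected photon count at the brightest pixel; 0 disables noise.
    """
    if psf_fwhm <= 0 or pixel <= 0:
        raise ValueError("psf_fwhm and pixel must be > 0")
    if pixel > profile.length:
        raise ValueError("pixel spacing exceeds profile length")
    from scipy.ndimage import gaussian_filter1d

    area = np.pi * profile.r**2
    sigma_samples = psf_fwhm * _FWHM_TO_SD / profile.spacing
    blurred = gaussian_filter1d(area, sigma_samples, mode="nearest")
    x_px = np.arange(profile.x[0], profile.x[-1] + pixel / 2.0, pixel)
    intensity = np.interp(x_px, profile.x, blurred)
    if noise > 0:
        rng = np.random.default_rng(seed)
        scale = noise / intensity.max()
        intensity = rng.poisson(intensity * scale).astype(float) / scale
    return IntensityProfile(
        x_px, intensity, meta={"psf_fwhm_nm": psf_fwhm, "pixel_nm": pixel, "seed": seed}
    )


def gen_serial_sections(
    total_inplane_length: float,
    n_sections: int,
    thickness: float = 40.0,
    seed: int = 0,
) -> SectionStack:
    """Random serial-section stack with a known true 3D length.

    In-plane step directions are random but their lengths are scaled so
    the summed in-plane displacement equals ``total_inplane_length``;
    the true 3D length follows from the Pythagorean theorem with the
    section span (n_sections - 1) * thickness.
    """
    if n_sections < 2:
        raise ValueError("need at least 2 sections")
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    if total_inplane_length < 0:
        raise ValueError("total_inplane_length must be >= 0")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_sections, 2))
    if total_inplane_length > 0:
        theta = rng.uniform(0, 2 * np.pi, n_sections - 1)
        mags = rng.uniform(0.5, 1.5, n_sections - 1)
        mags *= total_inplane_length / mags.sum()
        steps[1:, 0] = mags * np.cos(theta)
        steps[1:, 1] = mags * np.sin(theta)
    depth = (n_sections - 1) * thickness
    true_len = float(np.hypot(total_inplane_length, depth))
    return SectionStack(steps, thickness, true_3d_length=true_len)
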