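"""Radius profiles of pearled axons and the analytic pearl backbone.

The common currency of the package is a 1D axisymmetric radius profile
r(x): axial position (nm) -> local radius (nm).  Electron-microscopy
tracings, relaxed membrane shapes and simulated cable geometries are all
reduced to this representation.

The parametric pearl backbone used throughout is a C^2 piecewise-cosine
chain: each nonsynaptic varicosity (NSV) is a smooth bump whose inflection
points are exactly ``nsv_length`` apart and whose maximal diameter is
``nsv_width``; neighbouring NSVs are joined by connectors of diameter
``connector_width`` whose central half is exactly flat.  Inflection points
therefore exist in closed form, which gives every downstream measurement an
analytic ground truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RadiusProfile",
    "PearlDims",
    "pearl_radius_periodic",
    "chain_radius",
]


@dataclass
class RadiusProfile:
    """Discretized axon radius versus axial position.

    Parameters
    ----------
    x : ndarray
        Axial positions in nm, strictly increasing, uniformly spaced.
    r : ndarray
        Local radii in nm (> 0). Widths reported elsewhere are diameters.
    is_synaptic : ndarray of bool, optional
        Per-varicosity annotation (one entry per candidate varicosity,
        in axial order): whether the varicosity contains ~40-nm synaptic
        vesicles and must be excluded from NSV statistics.
    axon_max_diameter : float, optional
        Maximal diameter of the traced structure in nm, used by the
        axon-inclusion rule (structures >= 1 um in diameter without a
        presynaptic terminal are not axons).
    has_presynaptic_terminal : bool
        Whether the traced structure contains a presynaptic terminal.
    """

    x: np.ndarray
    r: np.ndarray
    is_synaptic: Optional[np.ndarray] = None
    axon_max_diameter: Optional[float] = None
    has_presynaptic_terminal: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.r.shape:
            raise ValueError("x and r must be 1D arrays of equal length")
        if self.x.size >= 2:
            dx = np.diff(self.x)
            if np.any(dx <= 0):
                raise ValueError("axial positions must be strictly increasing")
            if not np.allclose(dx, dx[0], rtol=1e-9, atol=0.0):
                raise ValueError("axial positions must be uniformly spaced")

    @property
    def spacing(self) -> float:
        """Sample spacing in nm."""
        return float(self.x[1] - self.x[0])

    @property
    def length(self) -> float:
        """Axial extent in nm."""
        return float(self.x[-1] - self.x[0])

    @property
    def diameter(self) -> np.ndarray:
        return 2.0 * self.r

    def to_text(self) -> str:
        """Serialize as 2-column delimited text with a commented header."""
        buf = io.StringIO()
        buf.write("# nanopearl radius profile\n")
        buf.write("# columns: axial_position_nm\tradius_nm\n")
        for key, val in sorted(self.meta.items()):
            buf.write(f"# {key}: {val}\n")
        if self.axon_max_diameter is not None:
            buf.write(f"# axon_max_diameter_nm: {self.axon_max_diameter!r}\n")
        np.savetxt(buf, np.column_stack([self.x, self.r]), fmt="%.6f", delimiter="\t")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "RadiusProfile":
        meta: dict = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            rows.append([float(v) for v in line.replace(",", "\t").split()])
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("profile text must have two columns")
        amd = meta.pop("axon_max_diameter_nm", None)
        return cls(
            arr[:, 0],
            arr[:, 1],
            axon_max_diameter=float(amd) if amd is not None else None,
            meta=meta,
        )

    @classmethod
    def read(cls, path) -> "RadiusProfile":
        with open(path) as fh:
            return cls.from_text(fh.read())


@dataclass(frozen=True)
class PearlDims:
    """The four morphometric dimensions of a pearl chain, in nm.

    ``nsv_length`` is the inflection-to-inflection axial extent of one
    varicosity; ``nsv_width`` its maximal diameter; ``connector_length``
    the boundary-to-boundary extent of the intervening thin segment;
    ``connector_width`` its (minimal, central) diameter.
    """

    nsv_length: float
    nsv_width: float
    connector_length: float
    connector_width: float

    def validate(self) -> "PearlDims":
        vals = (
            self.nsv_length,
            self.nsv_width,
            self.connector_length,
            self.connector_width,
        )
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError(f"all pearl dimensions must be positive, got {vals}")
        if self.nsv_width <= self.connector_width:
            raise ValueError(
                "nsv_width must exceed connector_width for a pearled "
                f"(non-inverted) chain, got {self.nsv_width} <= {self.connector_width}"
            )
        return self

    @property
    def period(self) -> float:
        return self.nsv_length + self.connector_length


def _bump_coefficients(nsv_length: float, r_nsv: float, r_conn: float, tail: float):
    """Coefficients of one NSV half-bump meeting a connector of radius r_conn.

    Inner quarter-cosine over the half NSV plus a quarter-sine tail of
    length ``tail`` reaching the flat connector; the join is C^2 and the
    curvature sign change (inflection) sits exactly at the end of the
    inner part, i.e. at the NSV boundary.
    """
    a = (r_nsv - r_conn) * nsv_length / (nsv_length + 2.0 * tail)
    b = (r_nsv - r_conn) * 2.0 * tail / (nsv_length + 2.0 * tail)
    m = r_conn + b  # radius at the inflection point
    return a, b, m


def _half_bump(d: np.ndarray, nsv_length: float, r_nsv: float, r_conn: float, tail: float) -> np.ndarray:
    """Radius at distance d >= 0 from an NSV peak (one side)."""
    a, b, m = _bump_coefficients(nsv_length, r_nsv, r_conn, tail)
    half = nsv_length / 2.0
    r = np.full_like(d, r_conn, dtype=float)
    inner = d <= half
    r[inner] = m + a * np.cos(np.pi * d[inner] / nsv_length)
    in_tail = (~inner) & (d <= half + tail)
    u = d[in_tail] - half
    r[in_tail] = m - b * np.sin(np.pi * u / (2.0 * tail))
    return r


def pearl_radius_periodic(x: np.ndarray, dims: PearlDims, tail_fraction: float = 0.25) -> np.ndarray:
    """Radius of an infinite periodic pearl chain at axial positions ``x`` (nm).

    The canonical period starts at a connector midpoint, so r(0) equals
    the connector radius and the NSV peak sits at half a period.

    ``tail_fraction`` is the fraction of the connector length taken by
    each tapering tail of the flanking NSV bumps; the default 1/4 leaves
    the central half of every connector exactly flat.
    """
    dims.validate()
    if not 0.0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    p = dims.period
    tail = tail_fraction * dims.connector_length
    s = np.mod(np.asarray(x, dtype=float), p)
    d = np.abs(s - p / 2.0)  # distance from the NSV peak
    return _half_bump(d, dims.nsv_length, dims.nsv_width / 2.0, dims.connector_width / 2.0, tail)


def chain_radius(
    x: np.ndarray,
    nsv_dims: Sequence[PearlDims],
    tail_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius of a finite chain of possibly heterogeneous pearls.

    The chain is laid out as: full connector, NSV 1, connector, NSV 2,
    ..., NSV n, full connector.  The i-th entry of ``nsv_dims`` carries
    the dimensions of NSV i together with the connector *preceding* it;
    the trailing connector reuses the last entry's connector dimensions.

    Returns
    -------
    r : ndarray
        Radii at ``x`` (nm).
    boundaries : ndarray
        Inflection-point positions (nm), strictly increasing; segments
        between consecutive boundaries alternate connector/NSV starting
        and ending with a connector.
    """
    if len(nsv_dims) == 0:
        raise ValueError("need at least one NSV")
    for d in nsv_dims:
        d.validate()
    x = np.asarray(x, dtype=float)

    # Axial layout: cumulative boundaries.
    bounds = [0.0]
    for d in nsv_dims:
        bounds.append(bounds[-1] + d.connector_length)
        bounds.append(bounds[-1] + d.nsv_length)
    bounds.append(bounds[-1] + nsv_dims[-1].connector_length)
    boundaries = np.asarray(bounds)

    r = np.empty_like(x)
    r.fill(np.nan)
    n = len(nsv_dims)
    for i, d in enumerate(nsv_dims):
        start = boundaries[1 + 2 * i]
        end = boundaries[2 + 2 * i]
        peak = 0.5 * (start + end)
        r_nsv = d.nsv_width / 2.0
        # left flank: connector i (preceding)
        lc = d.connector_length
        rc_left = d.connector_width / 2.0
        tail_l = tail_fraction * lc
        # right flank: connector i+1 (following); last NSV reuses its own.
        d_next = nsv_dims[i + 1] if i + 1 < n else d
        rc_right = d_next.connector_width / 2.0
        tail_r = tail_fraction * d_next.connector_length

        # Each NSV owns the region between the midpoints of its flanking
        # connectors; tails (<= L_conn/4) never reach a midpoint, so the
        # territories tile the chain without clobbering a neighbour's tail.
        left_lo = 0.0 if i == 0 else 0.5 * (boundaries[2 * i] + boundaries[1 + 2 * i])
        right_hi = (
            boundaries[3 + 2 * i]
            if i == n - 1
            else 0.5 * (boundaries[2 + 2 * i] + boundaries[3 + 2 * i])
        )
        left = (x >= left_lo) & (x < peak)
        right = (x >= peak) & (x <= right_hi)
        r[left] = _half_bump(peak - x[left], d.nsv_length, r_nsv, rc_left, tail_l)
        r[right] = _half_bump(x[right] - peak, d.nsv_length, r_nsv, rc_right, tail_r)
    # positions outside the chain (shouldn't occur) -> end connector radius
    r[np.isnan(r)] = nsv_dims[-1].connector_width / 2.0
    return r, boundaries
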