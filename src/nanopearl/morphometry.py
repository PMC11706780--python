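"""Morphometry of pearled axon profiles.

Implements the EM measurement procedure on 1D radius profiles: the axon
outline alternates nonsynaptic varicosities (NSVs) and thin connectors,
with the boundary between the two features defined by the inflection
points of the (smoothed) diameter function.  NSV length is the
inflection-to-inflection distance, NSV width the maximal diameter within
the segment; connector length is the distance between the boundaries of
the two flanking NSVs, connector width the median diameter over the
connector's central half (robust to the taper at its ends).

Also provides the STED-style FWHM length readout, the center-to-center
spacing/periodicity check against the 190-nm membrane skeleton period,
the serial-section Pythagorean 3D correction, the axon/varicosity
inclusion rules, and cohort summaries (mean +/- s.e.m. per dimension).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .profiles import RadiusProfile
from .synthetic import IntensityProfile, SectionStack

__all__ = [
    "Segment",
    "MorphometryRecord",
    "DEFAULT_SMOOTHING_NM",
    "segment_profile",
    "measure_segments",
    "measure_profile",
    "apply_exclusions",
    "fwhm_length",
    "spacing_periodicity",
    "reconstruct_3d",
    "summarize",
]

#: Default Gaussian smoothing s.d. (nm) applied before differentiation:
#: well below the thinnest reported connector width (52 nm) yet large
#: enough to suppress sampling-scale noise on 5-nm grids.
DEFAULT_SMOOTHING_NM = 15.0


@dataclass(frozen=True)
class Segment:
    """One NSV or connector, bounded by inflection points.

    ``start``/``end`` are axial positions in nm; ``width`` is a diameter.
    """

    kind: str  # "nsv" | "connector"
    start: float
    end: float
    length: float
    width: float
    is_synaptic: bool = False

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class MorphometryRecord:
    """Per-axon measured dimensions, one row per segment."""

    nsv: list[tuple[float, float]] = field(default_factory=list)  # (length, width) nm
    connector: list[tuple[float, float]] = field(default_factory=list)
    nsv_centers: list[float] = field(default_factory=list)
    nsv_synaptic: list[bool] = field(default_factory=list)
    axon_max_diameter: Optional[float] = None
    has_presynaptic_terminal: bool = False
    group: str = ""

    def summary(self) -> dict:
        """Mean and s.e.m. (s.d./sqrt(n)) of each dimension."""
        out = {}
        for name, pairs in (("nsv", self.nsv), ("connector", self.connector)):
            arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
            for j, dim in enumerate(("length", "width")):
                vals = arr[:, j]
                key = f"{name}_{dim}"
                n = vals.size
                out[key + "_mean_nm"] = float(vals.mean()) if n else np.nan
                out[key + "_sem_nm"] = (
                    float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else np.nan)
                )
                out[key + "_n"] = n
        return out


def _smoothed_diameter(profile: RadiusProfile, smoothing_nm: float):
    d = profile.diameter
    sigma = smoothing_nm / profile.spacing
    return gaussian_filter1d(d, sigma, mode="nearest")


def _zero_crossing(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Linear-interpolated zero of y between samples i and i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(0.5 * (x[i] + x[i + 1]))
    t = -y0 / (y1 - y0)
    return float(x[i] + t * (x[i + 1] - x[i]))


def segment_profile(
    profile: RadiusProfile,
    smoothing_window: float = DEFAULT_SMOOTHING_NM,
    min_prominence_frac: float = 0.05,
) -> list[Segment]:
    """Split a radius profile into alternating NSV/connector segments.

    The diameter function is Gaussian-smoothed (s.d. ``smoothing_window``
    nm) and segment boundaries are placed at zero crossings of its second
    derivative: for each local diameter maximum (NSV candidate) the two
    flanking concave-to-convex inflections bound the NSV; everything
    between consecutive NSVs is a connector.  Partial segments at the
    profile ends are dropped.  A constant (or feature-free) profile
    yields an empty list.

    ``min_prominence_frac`` filters peaks whose prominence is below this
    fraction of the overall diameter range, guarding against noise bumps.
    """
    if smoothing_window < 2 * profile.spacing:
        raise ValueError("smoothing_window must be >= 2x the sample spacing")
    x = profile.x
    d = _smoothed_diameter(profile, smoothing_window)
    drange = float(d.max() - d.min())
    if drange <= 1e-9 * max(1.0, float(d.max())):
        return []  # constant cylinder

    prominence = min_prominence_frac * drange
    peaks, _ = signal.find_peaks(d, prominence=prominence)
    if peaks.size == 0:
        return []

    # Slope fields at two scales.  The mean is removed first: the
    # discrete derivative kernels' weights do not sum exactly to zero,
    # and the tiny constant leak would otherwise shift extrema by
    # several nm on these gently-sloped profiles.
    diam0 = profile.diameter - profile.diameter.mean()
    sig = smoothing_window / profile.spacing
    d1 = gaussian_filter1d(diam0, sig, order=1, mode="nearest")
    d1c = gaussian_filter1d(diam0, 2.0 * sig, order=1, mode="nearest")

    def slope_extremum(arr: np.ndarray, lo: int, hi: int, downslope: bool):
        """Quadratic-interpolated extremum of the slope field in [lo, hi]."""
        if hi - lo < 2:
            return None
        flank = -arr[lo : hi + 1] if downslope else arr[lo : hi + 1]
        m = int(np.argmax(flank))
        if m == 0 or m == flank.size - 1:
            return None  # extremum at interval edge: flank truncated
        y0, y1, y2 = flank[m - 1], flank[m], flank[m + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        return float(x[lo + m] + np.clip(delta, -1, 1) * profile.spacing)

    def locate(lo: int, hi: int, downslope: bool):
        """Boundary inside [lo, hi]: the inflection point is the steepest
        point of the flank, i.e. the extremum of the smoothed first
        derivative.  Its position drifts ~ linearly with the smoothing
        scale where the profile's curvature has a kink, so positions at
        scales s and 2s are extrapolated linearly to s -> 0."""
        x_sig = slope_extremum(d1, lo, hi, downslope)
        if x_sig is None:
            return None
        x_2sig = slope_extremum(d1c, lo, hi, downslope)
        if x_2sig is None or abs(x_2sig - x_sig) > 2.0 * smoothing_window:
            return x_sig
        return 2.0 * x_sig - x_2sig

    boundaries: list[tuple[float, float]] = []  # (left, right) per retained peak
    kept_peaks: list[int] = []
    for k, p in enumerate(peaks):
        prev_p = peaks[k - 1] if k > 0 else 0
        next_p = peaks[k + 1] if k + 1 < peaks.size else x.size - 1
        left = locate(prev_p, p, downslope=False)
        right = locate(p, next_p, downslope=True)
        if left is None or right is None:
            continue  # partial segment at a profile end: drop
        if right <= left:
            continue
        boundaries.append((left, right))
        kept_peaks.append(int(p))

    # merge peaks that share (near-)coincident boundaries (one sample apart)
    merged: list[tuple[float, float, int]] = []
    tol = profile.spacing
    for (l, r), p in zip(boundaries, kept_peaks):
        if merged and l <= merged[-1][1] + tol:
            pl, pr, pp = merged[-1]
            best = pp if d[pp] >= d[p] else p
            merged[-1] = (pl, max(pr, r), best)
        else:
            merged.append((l, r, p))

    flags = profile.is_synaptic
    segments: list[Segment] = []
    for k, (l, r, p) in enumerate(merged):
        mask = (x >= l) & (x <= r)
        width = float(d[mask].max()) if mask.any() else float(d[p])
        syn = bool(flags[k]) if flags is not None and k < len(flags) else False
        segments.append(Segment("nsv", l, r, r - l, width, is_synaptic=syn))
        if k + 1 < len(merged):
            nl = merged[k + 1][0]
            segments.append(Segment("connector", r, nl, nl - r, _connector_width(x, d, r, nl)))

    # interleave back into axial order: nsv, connector, nsv, ...
    segments.sort(key=lambda s: s.start)
    return segments


def _connector_width(x: np.ndarray, d: np.ndarray, start: float, end: float) -> float:
    """Median diameter over the central 50% of the connector."""
    lo = start + 0.25 * (end - start)
    hi = end - 0.25 * (end - start)
    mask = (x >= lo) & (x <= hi)
    if not mask.any():
        mask = (x >= start) & (x <= end)
    return float(np.median(d[mask]))


def measure_segments(segments: Sequence[Segment], group: str = "") -> MorphometryRecord:
    """Collect per-segment dimensions into a record; empty in -> empty out."""
    rec = MorphometryRecord(group=group)
    for seg in segments:
        if seg.kind == "nsv":
            rec.nsv.append((seg.length, seg.width))
            rec.nsv_centers.append(seg.center)
            rec.nsv_synaptic.append(seg.is_synaptic)
        else:
            rec.connector.append((seg.length, seg.width))
    return rec


def measure_profile(
    profile: RadiusProfile,
    smoothing_window: float = DEFAULT_SMOOTHING_NM,
    group: str = "",
) -> MorphometryRecord:
    """Segment and measure in one step."""
    rec = measure_segments(segment_profile(profile, smoothing_window), group=group)
    rec.axon_max_diameter = profile.axon_max_diameter
    if rec.axon_max_diameter is None and profile.r.size:
        rec.axon_max_diameter = float(profile.diameter.max())
    rec.has_presynaptic_terminal = profile.has_presynaptic_terminal
    return rec


def apply_exclusions(records: Iterable[MorphometryRecord]):
    """Apply the inclusion/exclusion rules to measured records.

    Varicosities flagged as synaptic (containing ~40-nm vesicles) are
    removed from the NSV statistics; traced structures with maximal
    diameter >= 1 um that lack a presynaptic terminal are not counted as
    axons and are dropped entirely.

    Returns (filtered_records, counts) with counts of removed axons and
    varicosities.
    """
    kept: list[MorphometryRecord] = []
    n_axons_removed = 0
    n_varicosities_removed = 0
    for rec in records:
        if (
            rec.axon_max_diameter is not None
            and rec.axon_max_diameter >= 1000.0
            and not rec.has_presynaptic_terminal
        ):
            n_axons_removed += 1
            continue
        flags = list(rec.nsv_synaptic) + [False] * (len(rec.nsv) - len(rec.nsv_synaptic))
        keep_idx = [i for i, f in enumerate(flags[: len(rec.nsv)]) if not f]
        n_varicosities_removed += len(rec.nsv) - len(keep_idx)
        kept.append(
            replace(
                rec,
                nsv=[rec.nsv[i] for i in keep_idx],
                nsv_centers=[rec.nsv_centers[i] for i in keep_idx if i < len(rec.nsv_centers)],
                nsv_synaptic=[False] * len(keep_idx),
            )
        )
    counts = {
        "axons_removed": n_axons_removed,
        "varicosities_removed": n_varicosities_removed,
    }
    return kept, counts


def fwhm_length(
    intensity: IntensityProfile,
    min_prominence_frac: float = 0.1,
) -> np.ndarray:
    """Full-width-at-half-maximum length of each intensity peak, in nm.

    Peaks are detected above their local background (prominence bases);
    each width is measured at half the prominence with linear
    interpolation between samples.  Returns an empty array when no peak
    rises above background.
    """
    y = intensity.intensity
    rng = float(y.max() - y.min())
    if rng <= 0:
        return np.array([])
    peaks, props = signal.find_peaks(y, prominence=min_prominence_frac * rng)
    if peaks.size == 0:
        return np.array([])
    widths, _, _, _ = signal.peak_widths(
        y, peaks, rel_height=0.5, prominence_data=(
            props["prominences"], props["left_bases"], props["right_bases"]
        )
    )
    return widths * intensity.spacing


def spacing_periodicity(
    nsv_centers: Sequence[float],
    target: float = 190.0,
    tolerance_frac: float = 0.10,
    bin_width: float = 20.0,
):
    """Center-to-center NSV spacings versus a candidate periodicity.

    Returns (spacings, histogram, fraction) where ``fraction`` is the
    share of spacings within +/- ``tolerance_frac`` of ``target`` nm
    (default: within 10% of the 190-nm membrane-skeleton period).
    ``histogram`` is a (counts, bin_edges) pair at ``bin_width`` nm.
    """
    centers = np.sort(np.asarray(nsv_centers, dtype=float))
    if centers.size < 2:
        raise ValueError("need at least 2 NSV centers")
    spacings = np.diff(centers)
    lo, hi = target * (1 - tolerance_frac), target * (1 + tolerance_frac)
    fraction = float(np.mean((spacings >= lo) & (spacings <= hi)))
    edges = np.arange(0.0, spacings.max() + bin_width, bin_width)
    hist = np.histogram(spacings, bins=edges)
    return spacings, hist, fraction


def reconstruct_3d(stack: SectionStack, inplane_length: Optional[float] = None) -> float:
    """3D length of a feature spanning a serial-section stack.

    Pythagorean combination of the in-plane length with the sectioning
    depth, assuming aligned images and equal section thickness:
    sqrt(L_inplane^2 + ((n_sections - 1) * thickness)^2).
    """
    if inplane_length is None:
        inplane_length = stack.inplane_length
    if inplane_length < 0:
        raise ValueError("inplane_length must be >= 0")
    depth = (stack.n_sections - 1) * stack.section_thickness
    return float(np.hypot(inplane_length, depth))


def estimate_noise_sd(profile: RadiusProfile) -> float:
    """Robust estimate of additive radius noise (nm).

    Median-absolute-deviation of the high-pass residual after a 2-sample
    Gaussian smooth; the 0.862 factor undoes the high-pass attenuation
    of white noise at that kernel width.
    """
    resid = profile.r - gaussian_filter1d(profile.r, 2.0, mode="nearest")
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))) / 0.862)


def cohort_dimension_means(
    profiles: Sequence[RadiusProfile],
    smoothing_window: float = DEFAULT_SMOOTHING_NM,
    bias_correction: bool = True,
    n_rep: int = 12,
    seed: int = 0,
) -> dict:
    """Cohort-mean pearl dimensions with parametric-bootstrap debiasing.

    Measurement noise biases inflection-point boundaries inward (the
    slope extremum of a flank whose varicosity side is much flatter than
    its connector side wanders preferentially toward the flat side under
    noise), shortening NSVs by up to ~8% at realistic EM tracing noise.
    When ``bias_correction`` is on and noise is detected, a noise-matched
    pearl-chain template is rebuilt at the raw cohort means, re-measured
    through the identical pipeline ``n_rep`` times, and the measured
    template bias is subtracted from the raw means.

    Returns a dict with raw and corrected means for the four dimensions
    plus the estimated noise level.
    """
    from .synthetic import PearlChainSpec, gen_pearl_profile

    def pooled_means(profs) -> np.ndarray:
        agg: list[list[float]] = [[], [], [], []]
        for p in profs:
            for s in segment_profile(p, smoothing_window):
                if s.kind == "nsv":
                    agg[0].append(s.length)
                    agg[1].append(s.width)
                else:
                    agg[2].append(s.length)
                    agg[3].append(s.width)
        return np.array([np.mean(a) if a else np.nan for a in agg])

    names = ("nsv_length", "nsv_width", "connector_length", "connector_width")
    raw = pooled_means(profiles)
    noise = float(np.median([estimate_noise_sd(p) for p in profiles]))
    out = {f"raw_{k}_nm": float(v) for k, v in zip(names, raw)}
    out["noise_sd_nm"] = noise
    corrected = raw.copy()
    if bias_correction and noise >= 0.5 and np.all(np.isfinite(raw)) and raw[1] > raw[3]:
        # fixed-point iteration: the template bias depends on the (unknown)
        # true dimensions, so re-estimate it at the corrected means once
        for it in range(2):
            reps = []
            for i in range(n_rep):
                template, _ = gen_pearl_profile(
                    PearlChainSpec(
                        *corrected,
                        n_periods=10,
                        noise_sd=noise,
                        seed=(seed * 1009 + it * 131 + i) % 2**31,
                    )
                )
                reps.append(pooled_means([template]))
            bias = np.nanmean(reps, axis=0) - corrected
            corrected = raw - bias
            if corrected[1] <= corrected[3] or np.any(corrected <= 0):
                corrected = raw
                break
    for k, v in zip(names, corrected):
        out[f"{k}_nm"] = float(v)
    return out


def summarize(records: Sequence[MorphometryRecord], groups: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Cohort summary table: mean +/- s.e.m. per dimension and group.

    Pools all segments within each group; s.e.m. = s.d./sqrt(n) over the
    pooled segments.  Empty groups are omitted with a warning.
    """
    import warnings

    if groups is None:
        groups = [rec.group or "all" for rec in records]
    rows = []
    for grp in dict.fromkeys(groups):  # preserve order, unique
        members = [r for r, g in zip(records, groups) if g == grp]
        pooled = {
            "nsv_length": [], "nsv_width": [],
            "connector_length": [], "connector_width": [],
        }
        for rec in members:
            for ln, w in rec.nsv:
                pooled["nsv_length"].append(ln)
                pooled["nsv_width"].append(w)
            for ln, w in rec.connector:
                pooled["connector_length"].append(ln)
                pooled["connector_width"].append(w)
        if not any(pooled.values()):
            warnings.warn(f"group {grp!r} has no measured segments; omitted")
            continue
        for dim, vals in pooled.items():
            arr = np.asarray(vals, dtype=float)
            n = arr.size
            rows.append(
                {
                    "group": grp,
                    "dimension": dim,
                    "mean_nm": arr.mean() if n else np.nan,
                    "sem_nm": arr.std(ddof=1) / np.sqrt(n) if n > 1 else (0.0 if n == 1 else np.nan),
                    "n": n,
                    "n_axons": len(members),
                }
            )
    return pd.DataFrame(rows)
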