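"""Sub-diffraction hotspot localisation and the glutamate–Ca2+ distance test.

Averaging evoked response maps over repeated trials beats the
diffraction limit: the intensity-weighted centroid of the brightest
part of a trial-averaged hotspot localises the underlying release site
far more precisely than the PSF width. The module builds peri-peak
response heat maps from trial stacks, localises glutamate hotspots
(top-brightness centroid after ~100 nm spatial filtering, with a
bimodality rule), fits the exponential spatial decay of the signal on
geodesic-corrected maps, detects Ca2+ entry hotspots against the noisy
background, and tests observed glutamate–Ca2+ hotspot distances
against a random-scatter null (uniform point pairs in a disc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.stats import ttest_ind

from .geometry import GeodesicMap
from .maps import HeatMap

__all__ = [
    "HotspotResult",
    "DistanceTest",
    "SpatialDecayResult",
    "build_response_heatmap",
    "localize_hotspot",
    "fit_spatial_decay",
    "detect_ca_hotspot",
    "random_pair_null",
    "compare_distances",
]


@dataclass
class HotspotResult:
    """Localised hotspot centroid(s), in-plane µm."""

    centroids: list
    modality: str  # "unimodal" | "bimodal"
    top_fraction: float
    channel: str = ""

    @property
    def primary(self) -> tuple[float, float]:
        return self.centroids[0]


@dataclass
class DistanceTest:
    """Two-sample comparison of hotspot distances against a scatter null."""

    observed: np.ndarray
    null: np.ndarray
    null_disc_radius: float
    t_statistic: float
    p_value: float

    @property
    def n_observed(self) -> int:
        return self.observed.size

    @property
    def n_null(self) -> int:
        return self.null.size

    @property
    def mean_observed(self) -> float:
        return float(self.observed.mean())

    @property
    def mean_null(self) -> float:
        return float(self.null.mean())

    @property
    def sem_observed(self) -> float:
        return float(self.observed.std(ddof=1) / math.sqrt(self.observed.size))

    @property
    def sem_null(self) -> float:
        return float(self.null.std(ddof=1) / math.sqrt(self.null.size))

    def summary(self) -> str:
        return (
            "Hotspot distance test (Welch t-test)\n"
            "------------------------------------\n"
            f"  observed : {self.mean_observed:.3f} +/- {self.sem_observed:.3f} um (n={self.n_observed})\n"
            f"  null     : {self.mean_null:.3f} +/- {self.sem_null:.3f} um (n={self.n_null})\n"
            f"  t = {self.t_statistic:.3f}, p = {self.p_value:.4g}"
        )


def _detect_peaks(avg_trace: np.ndarray, ap_idx: np.ndarray, dt: float, search_ms: float = 25.0) -> np.ndarray:
    """Per-AP peak sample indices of the pooled average trace."""
    n = avg_trace.size
    peaks = []
    for i_ap in ap_idx:
        i1 = min(n, i_ap + int(round(search_ms / dt)) + 1)
        if i_ap >= n or i1 <= i_ap:
            raise ValueError("AP window outside the recording")
        peaks.append(i_ap + int(np.argmax(avg_trace[i_ap:i1])))
    return np.asarray(peaks)


def build_response_heatmap(
    trials,
    ap_times_ms=None,
    pre_ms: float = 2.0,
    post_ms: float = 10.0,
    baseline_ms: float = 300.0,
    channel: str = "glu",
    mode: str = "dff",
    curve=None,
    min_photons: float = 10_000,
    mask_threshold: float = 0.1,
) -> HeatMap:
    """Average peri-peak response heat map over APs and trials.

    For each AP the per-pixel signal is averaged between ``pre_ms``
    before and ``post_ms`` after the AP-evoked peak of the pooled
    average trace (excluding inter-AP troughs), then averaged across
    APs and trials. With ``mode="dff"`` the map holds ΔF/F against the
    per-pixel prepulse baseline; ``mode="flim"`` pools the photon decay
    tensor instead and returns the FLIM [Ca2+] increment (evoked minus
    resting, nM) using the supplied calibration ``curve``.

    The mask keeps pixels whose baseline exceeds ``mask_threshold``
    times the maximum baseline (the visible bouton profile).
    """
    if not isinstance(trials, (list, tuple)):
        trials = [trials]
    if len(trials) == 0:
        raise ValueError("no trials")
    t0 = trials[0]
    dt = t0.sample_interval_ms
    ap_times = np.asarray(ap_times_ms if ap_times_ms is not None else t0.ap_times_ms, dtype=float)
    if ap_times.size == 0:
        raise ValueError("no AP times")
    ap_idx = np.round(ap_times / dt).astype(int)

    if mode == "flim":
        from .flim import flim_readout

        if curve is None:
            raise ValueError("flim mode needs a calibration curve")
        t_first, t_last = ap_times[0], ap_times[-1]
        evoked = flim_readout(
            list(trials), curve, (t_first, t_last + post_ms + 15.0),
            per_pixel=True, min_photons=min_photons,
        )
        resting = flim_readout(
            list(trials), curve, (max(0.0, t_first - baseline_ms), t_first),
            per_pixel=True, min_photons=min_photons,
        )
        values = evoked.values - resting.values
        return HeatMap(
            values,
            pixel_um=evoked.pixel_um,
            channel=channel,
            n_trials=len(trials),
            mask=np.isfinite(values),
            meta={"mode": "flim_increment_nM"},
        )

    stack = np.stack([np.asarray(tr.intensity[channel], dtype=float) for tr in trials])
    mean_movie = stack.mean(axis=0)  # (ny, nx, T)
    avg_trace = mean_movie.sum(axis=(0, 1))
    i_base1 = ap_idx[0]
    i_base0 = max(0, i_base1 - int(round(baseline_ms / dt)))
    base_trace = avg_trace[i_base0:i_base1]
    peaks = _detect_peaks(avg_trace, ap_idx, dt)
    if avg_trace[peaks].max() <= base_trace.mean() + 3 * base_trace.std(ddof=1):
        raise ValueError("no detectable AP-evoked peaks in the average trace")

    pre_n = int(round(pre_ms / dt))
    post_n = int(round(post_ms / dt))
    sel = np.zeros(avg_trace.size, dtype=bool)
    for pk in peaks:
        sel[max(0, pk - pre_n) : min(avg_trace.size, pk + post_n + 1)] = True

    f0 = mean_movie[:, :, i_base0:i_base1].mean(axis=2)
    resp = mean_movie[:, :, sel].mean(axis=2)
    mask = f0 > mask_threshold * f0.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(mask, (resp - f0) / f0, np.nan)
    return HeatMap(
        values,
        pixel_um=t0.pixel_um or 1.0,
        channel=channel,
        n_trials=len(trials),
        mask=mask,
        origin_um=getattr(trials[0], "meta", {}).get("origin_um", (0.0, 0.0)),
    )


def _weighted_centroid(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    w = values[rows, cols]
    w = np.clip(w, 0, None)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return float(np.average(rows, weights=w)), float(np.average(cols, weights=w))


def localize_hotspot(
    heatmap,
    smooth_um: float = 0.1,
    top_fraction: float = 0.05,
    psf_fwhm_um: float = 0.3,
    channel: str | None = None,
) -> HotspotResult:
    """Localise the signal hotspot(s) of a masked heat map.

    The map is mean-filtered over a ~``smooth_um`` footprint and the
    intensity-weighted centroid of the top-``top_fraction`` brightness
    pixel set is returned (equivalent to Gaussian PSF localisation for
    symmetric hotspots). When that set splits into two connected
    components separated by more than one PSF FWHM, both centroids are
    returned and the profile is classed bimodal.

    Works on :class:`~synmux.maps.HeatMap` and
    :class:`~synmux.geometry.GeodesicMap`; centroids are in µm. For
    plain heat maps they are absolute in-plane positions; for geodesic
    maps they are geodesic offsets from the profile centre.
    """
    if isinstance(heatmap, GeodesicMap):
        values, mask, pixel = heatmap.values, heatmap.mask, heatmap.pixel_um
        u, v = heatmap.axis_coords()
        to_xy = lambda r, c: (float(np.interp(c, np.arange(u.size), u)), float(np.interp(r, np.arange(v.size), v)))
    else:
        values, mask, pixel = heatmap.values, heatmap.mask, heatmap.pixel_um
        to_xy = lambda r, c: tuple(map(float, heatmap.to_um(r, c)))
    if not np.any(mask):
        raise ValueError("empty mask")
    size = max(1, int(round(smooth_um / pixel)) | 1)
    filled = np.where(mask, np.nan_to_num(values, nan=0.0), 0.0)
    norm = ndimage.uniform_filter(mask.astype(float), size=size)
    smooth = ndimage.uniform_filter(filled, size=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        smooth = np.where(norm > 0, smooth / norm, np.nan)
    vals = smooth[mask]
    thr = np.nanquantile(vals, 1.0 - top_fraction)
    top = mask & (smooth >= thr)
    labels, n_comp = ndimage.label(top, structure=np.ones((3, 3), dtype=int))
    centroids_px = []
    masses = []
    for lab in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == lab)
        centroids_px.append(_weighted_centroid(smooth, rows, cols))
        masses.append(smooth[rows, cols].sum())
    order = np.argsort(masses)[::-1]
    modality = "unimodal"
    keep = [centroids_px[order[0]]]
    if n_comp >= 2:
        c0, c1 = centroids_px[order[0]], centroids_px[order[1]]
        sep = math.hypot(c0[0] - c1[0], c0[1] - c1[1]) * pixel
        if sep > psf_fwhm_um and masses[order[1]] > 0.2 * masses[order[0]]:
            modality = "bimodal"
            keep.append(c1)
    if modality == "unimodal":
        rows, cols = np.nonzero(top)
        keep = [_weighted_centroid(smooth, rows, cols)]
    centroids = [to_xy(r, c) for r, c in keep]
    return HotspotResult(
        centroids=centroids,
        modality=modality,
        top_fraction=top_fraction,
        channel=channel or getattr(heatmap, "channel", "") or "",
    )


@dataclass
class SpatialDecayResult:
    """Exponential spatial-decay constants fitted per bouton and pooled."""

    constants_um: np.ndarray
    mean_um: float
    sem_um: float
    r_min_um: float
    r_max_um: float
    profiles: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.constants_um.size

    def summary(self) -> str:
        return (
            "Spatial decay of the geodesic-corrected signal\n"
            "----------------------------------------------\n"
            f"  boutons : {self.n}\n"
            f"  decay constant : {self.mean_um:.3f} +/- {self.sem_um:.3f} um (mean +/- s.e.m.)\n"
            f"  fit range : {self.r_min_um:.2f} – {self.r_max_um:.2f} um"
        )


def _radial_profile(dist: np.ndarray, values: np.ndarray, mask: np.ndarray, n_bins: int, r_max: float):
    ok = mask & np.isfinite(values) & (dist <= r_max)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    idx = np.digitize(dist[ok], edges) - 1
    prof = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sel = idx == i
        if np.count_nonzero(sel) >= 2:
            prof[i] = values[ok][sel].mean()
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, prof


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def _ellipse_arc_vectorised(theta: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Arc length from the apex of an ellipse (semi-axes a, b), vectorised.

    Fixed-order Gauss–Legendre quadrature of
    ``integral_0^theta sqrt(a^2 cos^2 t + b^2 sin^2 t) dt`` with
    per-element semi-axis ``a``; matches the adaptive scalar version to
    ~1e-10 for the smooth integrand involved.
    """
    half = theta / 2.0
    t = half[..., None] * (_GL_NODES + 1.0)
    integrand = np.sqrt((a[..., None] * np.cos(t)) ** 2 + (b * np.sin(t)) ** 2)
    return half * (integrand * _GL_WEIGHTS).sum(axis=-1)


def _fit_profile_exponential(centres, prof, m2, fit_sel, blur_correct: bool):
    """Single-exponential fit with optional analytic blur compensation.

    ``m2`` holds the per-bin mean squared effective radial blur width
    after the geodesic stretch. The known first-order effect of a
    Gaussian blur on an exponential tail is the factor
    ``exp(sigma_eff^2 / (2 lambda^2))``, which is divided out and the
    fit iterated (it depends on the estimate itself).
    """

    def model(r, amp, lam):
        return amp * np.exp(-r / lam)

    prof0 = prof / np.nanmax(prof)
    lam = curve_fit(model, centres[fit_sel], prof0[fit_sel], p0=[1.0, 0.5],
                    bounds=([1e-6, 1e-3], [10.0, 20.0]), maxfev=10000)[0][1]
    if blur_correct and m2 is not None:
        for _ in range(2):
            corr = prof / np.exp(m2 / (2 * lam**2))
            corr = corr / np.nanmax(corr)
            lam = curve_fit(model, centres[fit_sel], corr[fit_sel], p0=[1.0, lam],
                            bounds=([1e-6, 1e-3], [10.0, 20.0]), maxfev=10000)[0][1]
    return float(lam)


def fit_spatial_decay(
    maps,
    r_min_um: float = 0.3,
    r_max_um: float = 1.3,
    n_bins: int = 26,
    smooth_um: float = 0.1,
    rho_max: float = 0.85,
    psf_fwhm_um: float | None = 0.3,
) -> SpatialDecayResult:
    """Exponential spatial-decay constant of corrected hotspot profiles.

    For each geodesic-corrected map the radial profile about the
    located peak is computed, normalised to its maximum, and fitted
    with a single exponential ``A * exp(-r / sigma)`` over
    ``[r_min_um, r_max_um]``.

    Three numerical safeguards keep the estimator unbiased:

    * per-pixel distances are obtained by the directional arcsin
      correction applied to the projected displacement from the peak
      (exact for a central hotspot on a spherical bouton, and within
      the same few-percent family as the per-axis rule for ellipsoids);
    * pixels whose projected radius exceeds ``rho_max`` of the local
      silhouette radius are excluded — near the rim the geodesic
      stretch amplifies the PSF blur without bound;
    * the known first-order flattening of an exponential tail by
      Gaussian blur (of stretched width ``psf / cos(theta)``) is
      divided out iteratively when ``psf_fwhm_um`` is given.

    The fit starts beyond the diffraction-dominated core (default
    ``r_min_um`` of one PSF FWHM). Returns per-bouton constants and
    their mean ± s.e.m.
    """
    if isinstance(maps, GeodesicMap):
        maps = [maps]
    constants = []
    profiles = []
    for gmap in maps:
        if isinstance(gmap, HeatMap):
            # uncorrected projected map: fit against raw planar distances
            peak = localize_hotspot(gmap, smooth_um=smooth_um).primary
            xx, yy = gmap.pixel_coords()
            dist = np.hypot(xx - peak[0], yy - peak[1])
            values, mask = gmap.values, gmap.mask
            sig_eff2 = None
            if psf_fwhm_um is not None:
                sig_eff2 = np.full_like(dist, (psf_fwhm_um / 2.3548) ** 2)
        elif gmap.source is not None:
            src = gmap.source
            geom = gmap.geometry
            peak = localize_hotspot(src, smooth_um=smooth_um).primary
            xx, yy = src.pixel_coords()
            dx, dy = xx - peak[0], yy - peak[1]
            r = np.hypot(dx, dy)
            phi = np.arctan2(dy, dx)
            cphi = np.cos(phi - geom.orientation)
            sphi = np.sin(phi - geom.orientation)
            s_dir = 1.0 / np.sqrt(cphi**2 / geom.a**2 + sphi**2 / geom.b**2)
            ratio = np.clip(r / s_dir, 0.0, 1.0)
            theta = np.arcsin(ratio)
            # exact planar-section arc from the apex: ellipse with
            # semi-axes (silhouette radius along phi, depth b)
            dist = _ellipse_arc_vectorised(theta, s_dir, geom.b)
            values, mask = src.values, src.mask & (ratio <= rho_max)
            if psf_fwhm_um is not None:
                sig = psf_fwhm_um / 2.3548
                th = np.arcsin(np.clip(ratio, 0.0, 0.95))
                stretch = np.sqrt((s_dir * np.cos(th)) ** 2 + (geom.b * np.sin(th)) ** 2) / (
                    s_dir * np.cos(th)
                )
                sig_eff2 = (sig * stretch) ** 2
            else:
                sig_eff2 = None
        else:  # stretched-plane fallback for maps without a source
            peak = localize_hotspot(gmap, smooth_um=smooth_um).primary
            dist = gmap.distance_from(peak)
            values, mask, sig_eff2 = gmap.values, gmap.mask, None
        centres, prof = _radial_profile(dist, values, mask, n_bins, r_max_um)
        m2 = None
        if sig_eff2 is not None:
            _, m2 = _radial_profile(dist, sig_eff2, mask, n_bins, r_max_um)
        ok = np.isfinite(prof)
        fit_sel = ok & (centres >= r_min_um)
        if np.count_nonzero(fit_sel) < 3:
            raise ValueError("radial profile shorter than 3 bins in the fit range")
        lam = _fit_profile_exponential(centres, prof, m2, fit_sel, sig_eff2 is not None)
        constants.append(lam)
        profiles.append((centres, prof / np.nanmax(prof)))
    constants = np.asarray(constants)
    mean = float(constants.mean())
    sem = float(constants.std(ddof=1) / math.sqrt(constants.size)) if constants.size > 1 else float("nan")
    return SpatialDecayResult(
        constants_um=constants,
        mean_um=mean,
        sem_um=sem,
        r_min_um=r_min_um,
        r_max_um=r_max_um,
        profiles=profiles,
    )


def detect_ca_hotspot(
    ca_map: HeatMap,
    z_threshold: float = 2.0,
    smooth_um: float = 0.1,
    min_area_um2: float | None = None,
    psf_fwhm_um: float = 0.3,
) -> HotspotResult | None:
    """Detect a Ca2+ entry hotspot against the noisy background, if any.

    The map is mean-filtered (~100 nm), the background median and SD
    are estimated from masked pixels excluding the brightest decile,
    and a contiguous region exceeding background + ``z_threshold`` SD
    of at least one PSF-footprint area yields its intensity-weighted
    centroid. Absence of such a region is a valid result (None). The
    input should be the (uncorrected) Ca2+ increment map, since Ca2+
    entry may occur within the bouton volume rather than on the
    surface.
    """
    values, mask, pixel = ca_map.values, ca_map.mask, ca_map.pixel_um
    if not np.any(mask):
        raise ValueError("empty mask")
    size = max(1, int(round(smooth_um / pixel)) | 1)
    filled = np.where(mask, np.nan_to_num(values, nan=0.0), 0.0)
    norm = ndimage.uniform_filter(mask.astype(float), size=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        smooth = np.where(norm > 0, ndimage.uniform_filter(filled, size=size) / norm, np.nan)
    vals = smooth[mask & np.isfinite(smooth)]
    bg = vals[vals <= np.quantile(vals, 0.9)]
    med, sd = np.median(bg), bg.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return None
    thr = med + z_threshold * sd
    above = mask & np.isfinite(smooth) & (smooth > thr)
    if min_area_um2 is None:
        # a genuine diffraction-limited hotspot smoothed over ~100 nm
        # covers comfortably more than one PSF half-max footprint; the
        # 1.5x factor keeps chance clusters of correlated noise below
        # the nominal false-positive level
        min_area_um2 = 1.5 * math.pi * (psf_fwhm_um / 2) ** 2
    min_px = max(1, int(round(min_area_um2 / pixel**2)))
    labels, n_comp = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    best, best_mass = None, -np.inf
    for lab in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_px:
            continue
        mass = (smooth[rows, cols] - med).sum()
        if mass > best_mass:
            best_mass = mass
            best = _weighted_centroid(smooth - med, rows, cols)
    if best is None:
        return None
    x, y = ca_map.to_um(best[0], best[1])
    return HotspotResult(centroids=[(float(x), float(y))], modality="unimodal", top_fraction=np.nan, channel="ca")


def random_pair_null(disc_radius: float, n_pairs: int, seed=None) -> np.ndarray:
    """Distances between independent uniform point pairs in a disc.

    The analytic mean of this null is ``(128 / (45 pi)) * R``, about
    0.9054 R; all distances are below 2R.
    """
    if disc_radius <= 0:
        raise ValueError("disc_radius must be positive")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r = disc_radius * np.sqrt(rng.random((2, n_pairs)))
    th = 2 * np.pi * rng.random((2, n_pairs))
    x = r * np.cos(th)
    y = r * np.sin(th)
    return np.hypot(x[0] - x[1], y[0] - y[1])


def compare_distances(observed, null, null_disc_radius: float = float("nan"), equal_var: bool = False) -> DistanceTest:
    """Welch t-test of observed hotspot distances against the scatter null."""
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size < 2 or nul.size < 2:
        raise ValueError("both samples need at least 2 points")
    t, p = ttest_ind(obs, nul, equal_var=equal_var)
    return DistanceTest(
        observed=obs,
        null=nul,
        null_disc_radius=null_disc_radius,
        t_statistic=float(t),
        p_value=float(p),
    )
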