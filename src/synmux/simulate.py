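"""Synthetic-data generators with recorded ground truth.

Every input the analysis chain consumes can be generated here with the
true parameters preserved, enabling recovery tests of the full
pipeline:

* photon decay histograms of a Ca2+ indicator whose lifetime mixes a
  fast Ca-free and a slow Ca-bound component (bound fraction
  ``ca / (ca + Kd)``), with Gaussian instrument-response jitter,
  Poisson photon statistics and laser-period wrap-around;
* trains of 1–4 AP-evoked glutamate-sensor transients with quantal
  amplitude structure (binomial vesicle counts times the quantal size
  plus Gaussian noise) and a matched Ca2+ photon channel;
* tornado-scanned ellipsoidal boutons with a membrane glutamate
  hotspot spreading exponentially along the surface and a cytosolic
  Ca2+ entry site, blurred by the microscope PSF;
* interleaved multi-bouton point-scan streams.

All generators accept an integer seed (or numpy Generator) and are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import exponnorm

from .geometry import BoutonGeometry
from .io import TrialRecording

__all__ = [
    "DecayModel",
    "GroundTruth",
    "QuantalSimulation",
    "BoutonScanSimulation",
    "MultiBoutonStream",
    "simulate_decay_histogram",
    "simulate_quantal_trials",
    "simulate_bouton_scan",
    "simulate_multibouton_stream",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class DecayModel:
    """Phenomenological two-lifetime decay model of a Ca2+ indicator.

    The indicator emits with lifetime ``tau_free`` when Ca-free and
    ``tau_bound`` when Ca-bound; the fraction of photons from the bound
    state is ``ca / (ca + kd)``. Arrival times are jittered by a
    Gaussian instrument response of width ``irf_sigma`` and wrap within
    the laser period (12.5 ns at 80 MHz). The decay peak sits
    ``t_peak`` after pulse onset. Component lifetimes are free model
    parameters — the calibration step makes the readout self-consistent
    for any sensible choice.
    """

    tau_free: float = 0.4  # ns
    tau_bound: float = 2.0  # ns
    kd: float = 560.0  # nM
    irf_sigma: float = 0.15  # ns
    background_rate: float = 0.0  # counts per bin
    laser_period: float = 12.5  # ns
    t_peak: float = 1.3  # ns

    def __post_init__(self) -> None:
        if min(self.tau_free, self.tau_bound, self.kd, self.laser_period) <= 0:
            raise ValueError("tau_free, tau_bound, kd and laser_period must be positive")
        if self.irf_sigma < 0 or self.background_rate < 0:
            raise ValueError("irf_sigma and background_rate must be non-negative")
        if math.isclose(self.tau_free, self.tau_bound):
            raise ValueError("tau_free and tau_bound must differ (no Ca sensitivity otherwise)")

    def bound_fraction(self, ca) -> np.ndarray:
        ca = np.asarray(ca, dtype=float)
        out = ca / (ca + self.kd)
        return out if out.ndim else float(out)

    def _component_pdf(self, t: np.ndarray, tau: float) -> np.ndarray:
        """Wrapped exponentially-modified-Gaussian photon delay density."""
        pdf = np.zeros_like(t, dtype=float)
        for k in range(3):  # previous-pulse wrap-around terms
            if self.irf_sigma > 0:
                pdf += exponnorm.pdf(
                    t + k * self.laser_period,
                    K=tau / self.irf_sigma,
                    loc=self.t_peak,
                    scale=self.irf_sigma,
                )
            else:
                tt = t + k * self.laser_period - self.t_peak
                pdf += np.where(tt >= 0, np.exp(-tt / tau) / tau, 0.0)
        return pdf

    def bin_probabilities(self, ca: float, n_bins: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Per-bin arrival probabilities of the free and bound components.

        Returns ``(p_free, p_bound, bin_width)`` with each vector summing
        to 1 over the ``n_bins`` delay bins that tile the laser period.
        """
        bw = self.laser_period / n_bins
        centres = (np.arange(n_bins) + 0.5) * bw
        p_free = self._component_pdf(centres, self.tau_free)
        p_bound = self._component_pdf(centres, self.tau_bound)
        return p_free / p_free.sum(), p_bound / p_bound.sum(), bw


def simulate_decay_histogram(ca: float, n_photons: float, model: DecayModel | None = None, seed=None, n_bins: int = 256):
    """Simulate a TCSPC decay histogram at clamped [Ca2+].

    Each photon is assigned to the Ca-bound component with probability
    ``ca / (ca + kd)``, given an exponential delay of the component
    lifetime plus Gaussian IRF jitter, and wrapped into the laser
    period. The total photon number is Poisson around ``n_photons``.
    """
    from .flim import DecayHistogram

    if ca < 0:
        raise ValueError("ca must be non-negative")
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    model = model or DecayModel()
    rng = _rng(seed)
    n = rng.poisson(n_photons)
    f = model.bound_fraction(ca)
    bound = rng.random(n) < f
    tau = np.where(bound, model.tau_bound, model.tau_free)
    t = model.t_peak + rng.exponential(tau)
    if model.irf_sigma > 0:
        t = t + rng.normal(0.0, model.irf_sigma, size=n)
    t = np.mod(t, model.laser_period)
    bw = model.laser_period / n_bins
    counts, _ = np.histogram(t, bins=n_bins, range=(0.0, model.laser_period))
    counts = counts.astype(float)
    if model.background_rate > 0:
        counts += rng.poisson(model.background_rate, size=n_bins)
    return DecayHistogram(counts, bw)


@dataclass
class GroundTruth:
    """Simulator ground truth for a single bouton.

    Release follows a binomial model: each AP releases
    ``Binomial(n_sites, pv)`` vesicles, each contributing the quantal
    amplitude ``quantal_size_q`` (ΔF/F); measured amplitudes carry
    Gaussian noise ``noise_sigma``. Presynaptic Ca2+ rests at
    ``ca_rest`` and each AP adds ``ca_increment_per_ap`` (nM,
    volume-equilibrated). The glutamate hotspot spreads over the bouton
    surface with exponential geodesic decay constant
    ``glu_spatial_decay`` from ``release_site`` (3-D surface point;
    default the apex facing the objective); Ca2+ enters at
    ``ca_entry_site`` (in-plane µm from the bouton centre).
    """

    ca_rest: float = 50.0  # nM
    ca_increment_per_ap: float = 80.0  # nM
    quantal_size_q: float = 0.35  # ΔF/F
    noise_sigma: float = 0.06  # ΔF/F
    pv: float = 0.4
    n_sites: int = 3
    release_site: tuple[float, float, float] | None = None  # µm, on the surface
    ca_entry_site: tuple[float, float] = (0.15, 0.1)  # µm, in-plane
    glu_spatial_decay: float = 0.55  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pv <= 1.0:
            raise ValueError("pv must lie in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("ca_rest", "ca_increment_per_ap", "quantal_size_q", "noise_sigma", "glu_spatial_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def _ap_kernel(t_ms: np.ndarray, ap_times: np.ndarray, tau_ms: float) -> np.ndarray:
    """Sum of causal exponential transients, unit amplitude each, shape (n_aps, n_t)."""
    dt = t_ms[None, :] - np.asarray(ap_times)[:, None]
    return np.where(dt >= 0, np.exp(-np.clip(dt, 0, None) / tau_ms), 0.0)


@dataclass
class QuantalSimulation:
    """Output of :func:`simulate_quantal_trials` with full ground truth."""

    trials: list
    vesicle_counts: np.ndarray  # (n_trials, n_aps)
    amplitudes: np.ndarray  # (n_trials, n_aps), ΔF/F including noise
    ca_multipliers: np.ndarray  # per-trial evoked Ca scale factors
    ap_times_ms: np.ndarray
    truth: GroundTruth
    sample_interval_ms: float
    baseline_ms: float


def simulate_quantal_trials(
    truth: GroundTruth,
    n_trials: int = 20,
    n_aps: int = 4,
    inter_ap_interval: float = 50.0,
    seed=None,
    *,
    dt_ms: float = 2.0,
    baseline_ms: float = 300.0,
    tail_ms: float = 100.0,
    glu_tau_ms: float = 15.0,
    ca_tau_ms: float = 150.0,
    photon_rate_per_ms: float = 20.0,
    photon_ramp_fold: float = 1.0,
    trace_noise: float = 0.01,
    facilitation: Sequence[float] | None = None,
    ca_dependence: bool = False,
    ca_cv: float = 0.25,
    link_slope: float = 3.0,
    ca_drift_per_trial: float = 0.0,
    decay_bins: int = 256,
    decay_model: DecayModel | None = None,
) -> QuantalSimulation:
    """Simulate repeated single-bouton trials of an evoked AP train.

    Per AP, the glutamate amplitude is ``(vesicles released) * q`` plus
    Gaussian noise, with vesicle counts Binomial(n_sites, pv); optional
    per-AP ``facilitation`` factors scale pv along the train. The Ca2+
    channel is generated as a photon-decay tensor whose [Ca2+] time
    course follows the AP train, so FLIM readout can be exercised on
    the same trials. With ``ca_dependence`` on, trial-to-trial
    fluctuations of evoked Ca2+ entry drive pv through a logistic link,
    producing the Ca–release correlation the trial-wise statistics are
    designed to detect. ``photon_ramp_fold`` linearly scales the photon
    rate across trials (dye equilibration after break-in);
    ``ca_drift_per_trial`` injects a true resting-Ca drift in nM/trial
    for sensitivity controls.
    """
    if n_trials < 1 or n_aps < 1:
        raise ValueError("n_trials and n_aps must be >= 1")
    rng = _rng(seed if seed is not None else truth.seed)
    model = decay_model or DecayModel()
    fac = np.ones(n_aps) if facilitation is None else np.asarray(facilitation, dtype=float)
    if fac.size != n_aps:
        raise ValueError("facilitation must have one factor per AP")

    ap_times = baseline_ms + inter_ap_interval * np.arange(n_aps)
    t_total = baseline_ms + inter_ap_interval * (n_aps - 1) + tail_ms
    n_t = int(round(t_total / dt_ms))
    t_ms = np.arange(n_t) * dt_ms
    glu_kernel = _ap_kernel(t_ms, ap_times, glu_tau_ms)
    ca_kernel = _ap_kernel(t_ms, ap_times, ca_tau_ms)
    p_free, p_bound, bw = model.bin_probabilities(truth.ca_rest, decay_bins)

    base_pv = truth.pv
    logit = math.log(base_pv / (1 - base_pv)) if 0 < base_pv < 1 else None

    m = np.ones(n_trials)
    if ca_dependence and ca_cv > 0:
        m = np.clip(1.0 + ca_cv * rng.normal(size=n_trials), 0.2, None)
    pv_trial = np.full(n_trials, base_pv)
    if ca_dependence and logit is not None:
        pv_trial = 1.0 / (1.0 + np.exp(-(logit + link_slope * (m - 1.0))))

    vesicles = np.zeros((n_trials, n_aps), dtype=int)
    amplitudes = np.zeros((n_trials, n_aps))
    trials = []
    ramp = np.linspace(1.0, photon_ramp_fold, n_trials)
    for i in range(n_trials):
        pv_ap = np.clip(pv_trial[i] * fac, 0.0, 1.0)
        vesicles[i] = rng.binomial(truth.n_sites, pv_ap)
        amplitudes[i] = vesicles[i] * truth.quantal_size_q + rng.normal(0.0, truth.noise_sigma, n_aps)

        glu = 1.0 + amplitudes[i] @ glu_kernel
        if trace_noise > 0:
            glu = glu + rng.normal(0.0, trace_noise, n_t)

        ca_rest_i = truth.ca_rest + ca_drift_per_trial * i
        ca_t = ca_rest_i + truth.ca_increment_per_ap * m[i] * ca_kernel.sum(axis=0)
        f_t = ca_t / (ca_t + model.kd)
        f_rest = ca_rest_i / (ca_rest_i + model.kd)
        rate_t = photon_rate_per_ms * dt_ms * ramp[i] * (1.0 + 2.0 * (f_t - f_rest))
        expected = rate_t[None, :] * ((1.0 - f_t)[None, :] * p_free[:, None] + f_t[None, :] * p_bound[:, None])
        decay = rng.poisson(expected).astype(np.int32)
        ca_counts = decay.sum(axis=0)

        trials.append(
            TrialRecording(
                intensity={"glu": glu, "ca": ca_counts.astype(float)},
                decay=decay[:, None, None, None, :],
                decay_bin_ns=bw,
                sample_interval_ms=dt_ms,
                ap_times_ms=ap_times,
                scan={"kind": "point"},
                meta={"trial": i, "photon_ramp": float(ramp[i])},
            )
        )
    return QuantalSimulation(
        trials=trials,
        vesicle_counts=vesicles,
        amplitudes=amplitudes,
        ca_multipliers=m,
        ap_times_ms=ap_times,
        truth=truth,
        sample_interval_ms=dt_ms,
        baseline_ms=baseline_ms,
    )


# ---------------------------------------------------------------------------
# Ellipsoidal bouton surface machinery


def _ellipsoid_mesh(geom: BoutonGeometry, n_u: int = 180, n_v: int = 90):
    """Parametric mesh of a rotational ellipsoid (rotation axis = x).

    Returns vertex positions (n_v * n_u, 3), per-vertex surface areas,
    and the grid shape. v in (0, pi) is the polar angle from the +x
    apex, u the rotation angle about x measured from the +y direction.
    """
    a, b = geom.a, geom.b
    v = (np.arange(n_v) + 0.5) * math.pi / n_v
    u = np.arange(n_u) * 2 * math.pi / n_u
    vv, uu = np.meshgrid(v, u, indexing="ij")
    x = a * np.cos(vv)
    y = b * np.sin(vv) * np.cos(uu)
    z = b * np.sin(vv) * np.sin(uu)
    # area element |P_v x P_u| dv du for the rotational ellipsoid
    r_profile = b * np.sin(vv)
    ds_dv = np.hypot(a * np.sin(vv), b * np.cos(vv))
    dA = ds_dv * r_profile * (math.pi / n_v) * (2 * math.pi / n_u)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    return verts, dA.ravel(), (n_v, n_u)


def _mesh_geodesics(verts: np.ndarray, shape: tuple[int, int], source_idx: int) -> np.ndarray:
    """Approximate surface geodesic distances from one vertex by Dijkstra.

    The graph connects each (v, u) grid vertex to its 1- and 2-ring
    knight-move neighbours (wrapping in u), which keeps the metric
    error of the polyline approximation below ~0.5 %.
    """
    n_v, n_u = shape
    idx = np.arange(n_v * n_u).reshape(n_v, n_u)
    offsets = [(0, 1), (1, 0), (1, 1), (1, -1), (1, 2), (2, 1), (1, -2), (2, -1)]
    rows, cols = [], []
    for dv, du in offsets:
        v0 = np.arange(max(0, -dv), min(n_v, n_v - dv))
        src = idx[v0][:, np.arange(n_u)]
        dst = idx[v0 + dv][:, (np.arange(n_u) + du) % n_u]
        rows.append(src.ravel())
        cols.append(dst.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.linalg.norm(verts[rows] - verts[cols], axis=1)
    n = n_v * n_u
    graph = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    dist = dijkstra(graph, directed=False, indices=source_idx)
    return dist


def _nearest_vertex(verts: np.ndarray, point: np.ndarray) -> int:
    return int(np.argmin(np.sum((verts - point[None, :]) ** 2, axis=1)))


@dataclass
class BoutonScanSimulation:
    """Output of :func:`simulate_bouton_scan`."""

    trials: list
    geometry: BoutonGeometry
    truth: GroundTruth
    pixel_um: float
    origin_um: tuple[float, float]
    psf_fwhm_um: float
    release_site_xy: tuple[float, float]
    ca_entry_xy: tuple[float, float]
    ap_times_ms: np.ndarray
    expected_dff_map: np.ndarray  # noise-free relative ΔF/F map (ground truth)
    baseline_map: np.ndarray
    sample_interval_ms: float
    baseline_ms: float


def simulate_bouton_scan(
    geom: BoutonGeometry,
    truth: GroundTruth,
    psf_fwhm_xy: float = 0.3,
    pixel_um: float = 0.0625,
    n_trials: int = 20,
    seed=None,
    *,
    dt_ms: float = 2.0,
    baseline_ms: float = 300.0,
    n_aps: int = 4,
    inter_ap_interval: float = 50.0,
    tail_ms: float = 60.0,
    glu_tau_ms: float = 15.0,
    ca_tau_ms: float = 150.0,
    photons_per_sample: float = 4000.0,
    ca_photons_per_sample: float = 1500.0,
    peak_dff_per_quantum: float = 0.8,
    z_excitation_fwhm_um: float = 1.0,
    focus_z_um: float | None = None,
    ca_entry_gain: float = 1.5,
    ca_entry_sigma_um: float = 0.2,
    ca_diffuse_dff: float = 0.15,
    ca_hotspot_dff: float = 0.45,
    background_rate: float = 0.05,
    mesh: tuple[int, int] = (180, 90),
    no_noise: bool = False,
) -> BoutonScanSimulation:
    """Simulate tornado-scan trials of an ellipsoidal bouton.

    The membrane glutamate signal spreads from the release site with
    exponential geodesic decay constant ``truth.glu_spatial_decay``,
    is projected onto the focal plane (surface-area weighting
    reproduces the shell-projection edge brightening), attenuated by a
    Gaussian two-photon axial-sectioning profile (FWHM
    ``z_excitation_fwhm_um``) centred on the focal plane — by default
    the depth of the release site — convolved with the lateral PSF and
    Poisson sampled. The Ca2+ channel is a blurred cytosolic signal
    with an entry hotspot at ``truth.ca_entry_site``.

    The lateral PSF FWHM should lie in the realistic two-photon range
    of 0.2–0.4 µm.
    """
    if not (0.2 <= psf_fwhm_xy <= 0.4):
        raise ValueError("psf_fwhm_xy must lie in the two-photon range 0.2–0.4 µm")
    rng = _rng(seed if seed is not None else truth.seed)
    a, b = geom.a, geom.b

    verts, areas, shape = _ellipsoid_mesh(geom, *mesh)
    if truth.release_site is None:
        release = np.array([0.0, 0.0, b])  # apex facing the objective
    else:
        release = np.asarray(truth.release_site, dtype=float)
        src = _nearest_vertex(verts, release)
        if np.linalg.norm(verts[src] - release) > 0.1 * b:
            raise ValueError("release_site does not lie on the ellipsoid surface")
    src = _nearest_vertex(verts, release)
    gdist = _mesh_geodesics(verts, shape, src)
    g = np.exp(-gdist / truth.glu_spatial_decay)

    sigma_z = z_excitation_fwhm_um / 2.3548
    focus = verts[src, 2] if focus_z_um is None else focus_z_um
    w_z = np.exp(-((verts[:, 2] - focus) ** 2) / (2 * sigma_z**2))

    margin = 2.0 * psf_fwhm_xy
    x0, y0 = -a - margin, -b - margin
    nx = int(math.ceil(2 * (a + margin) / pixel_um))
    ny = int(math.ceil(2 * (b + margin) / pixel_um))
    ct, st = math.cos(geom.orientation), math.sin(geom.orientation)
    vx = geom.centre_um[0] + ct * verts[:, 0] - st * verts[:, 1]
    vy = geom.centre_um[1] + st * verts[:, 0] + ct * verts[:, 1]
    col = np.clip(((vx - x0) / pixel_um).astype(int), 0, nx - 1)
    row = np.clip(((vy - y0) / pixel_um).astype(int), 0, ny - 1)
    flat = row * nx + col

    base_img = np.bincount(flat, weights=areas * w_z, minlength=ny * nx).reshape(ny, nx)
    hot_img = np.bincount(flat, weights=areas * w_z * g, minlength=ny * nx).reshape(ny, nx)
    sigma_px = psf_fwhm_xy / 2.3548 / pixel_um
    base_img = gaussian_filter(base_img, sigma_px)
    hot_img = gaussian_filter(hot_img, sigma_px)

    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(base_img > 1e-6 * base_img.max(), hot_img / base_img, 0.0)
    dff_map = peak_dff_per_quantum * rel / rel.max()

    rate_px = photons_per_sample * base_img / base_img.sum() + background_rate

    ap_times = baseline_ms + inter_ap_interval * np.arange(n_aps)
    t_total = baseline_ms + inter_ap_interval * (n_aps - 1) + tail_ms
    n_t = int(round(t_total / dt_ms))
    t_ms = np.arange(n_t) * dt_ms
    glu_kernel = _ap_kernel(t_ms, ap_times, glu_tau_ms)
    ca_kernel = _ap_kernel(t_ms, ap_times, ca_tau_ms)

    # cytosolic Ca channel geometry (principal frame)
    xs = x0 + (np.arange(nx) + 0.5) * pixel_um
    ys = y0 + (np.arange(ny) + 0.5) * pixel_um
    xx, yy = np.meshgrid(xs, ys)
    dxp = ct * (xx - geom.centre_um[0]) + st * (yy - geom.centre_um[1])
    dyp = -st * (xx - geom.centre_um[0]) + ct * (yy - geom.centre_um[1])
    rho2 = (dxp / a) ** 2 + (dyp / b) ** 2
    depth = 2 * b * np.sqrt(np.clip(1 - rho2, 0.0, None))
    depth = gaussian_filter(depth, sigma_px)
    ca_rate_px = ca_photons_per_sample * depth / depth.sum() + background_rate
    ex, ey = truth.ca_entry_site
    entry = np.exp(-((dxp - ex) ** 2 + (dyp - ey) ** 2) / (2 * ca_entry_sigma_um**2))
    entry = gaussian_filter(entry, sigma_px)
    ca_dff_map = ca_diffuse_dff * (depth > 0) + ca_hotspot_dff * entry / max(entry.max(), 1e-12)

    p_success = 1.0 - (1.0 - truth.pv) ** truth.n_sites
    trials = []
    for i in range(n_trials):
        quanta = rng.binomial(truth.n_sites, truth.pv, size=n_aps) if not no_noise else np.ones(n_aps)
        s_t = quanta @ glu_kernel  # quanta-weighted transient time course
        rate = rate_px[:, :, None] * (1.0 + dff_map[:, :, None] * s_t[None, None, :])
        s_ca = ca_kernel.sum(axis=0)
        ca_rate = ca_rate_px[:, :, None] * (1.0 + ca_dff_map[:, :, None] * s_ca[None, None, :])
        if no_noise:
            glu_counts, ca_counts = rate, ca_rate
        else:
            glu_counts = rng.poisson(rate).astype(np.float32)
            ca_counts = rng.poisson(ca_rate).astype(np.float32)
        trials.append(
            TrialRecording(
                intensity={"glu": glu_counts, "ca": ca_counts},
                sample_interval_ms=dt_ms,
                ap_times_ms=ap_times,
                pixel_um=pixel_um,
                scan={"kind": "tornado", "radius_um": float(max(a, b))},
                meta={"trial": i, "quanta": quanta.tolist()},
            )
        )
    rel_xy = (
        geom.centre_um[0] + ct * release[0] - st * release[1],
        geom.centre_um[1] + st * release[0] + ct * release[1],
    )
    ca_xy = (
        geom.centre_um[0] + ct * ex - st * ey,
        geom.centre_um[1] + st * ex + ct * ey,
    )
    return BoutonScanSimulation(
        trials=trials,
        geometry=geom,
        truth=truth,
        pixel_um=pixel_um,
        origin_um=(x0 + 0.5 * pixel_um, y0 + 0.5 * pixel_um),
        psf_fwhm_um=psf_fwhm_xy,
        release_site_xy=rel_xy,
        ca_entry_xy=ca_xy,
        ap_times_ms=ap_times,
        expected_dff_map=dff_map,
        baseline_map=rate_px,
        sample_interval_ms=dt_ms,
        baseline_ms=baseline_ms,
    )


@dataclass
class MultiBoutonStream:
    """Interleaved point-scan stream over several boutons."""

    streams: np.ndarray  # (n_trials, n_samples) fluorescence samples
    cycle_map: list  # [(bouton_id, samples_per_dwell), ...]
    sample_interval_ms: float
    cycle_period_ms: float
    ap_times_ms: np.ndarray
    vesicle_counts: np.ndarray  # (n_boutons, n_trials, n_aps)
    amplitudes: np.ndarray  # (n_boutons, n_trials, n_aps)
    truths: list


def simulate_multibouton_stream(
    truths: Sequence[GroundTruth],
    dwell_ms: float = 1.5,
    ap_times: Sequence[float] = (300.0, 350.0),
    n_trials: int = 20,
    seed=None,
    *,
    samples_per_dwell: int = 1,
    sweep_ms: float = 500.0,
    glu_tau_ms: float = 25.0,
    trace_noise: float = 0.04,
) -> MultiBoutonStream:
    """Simulate a laser trajectory cycling over several bouton centres.

    The single sample stream visits each bouton for ``dwell_ms`` per
    cycle, so the cycle period is ``n_boutons * dwell_ms`` and each
    bouton is revisited at that resolution. Boutons release
    independently (no cross-talk): each carries its own binomial
    quantal process.
    """
    n_boutons = len(truths)
    if n_boutons == 0:
        raise ValueError("truth list is empty")
    if not 1 <= n_boutons <= 8:
        raise ValueError("n_boutons must lie in 1..8")
    if dwell_ms <= 0:
        raise ValueError("dwell_ms must be positive")
    rng = _rng(seed)
    ap_times = np.asarray(ap_times, dtype=float)
    n_aps = ap_times.size
    dt = dwell_ms / samples_per_dwell
    cycle_period = n_boutons * dwell_ms
    n_cycles = int(sweep_ms // cycle_period)
    n_samples = n_cycles * n_boutons * samples_per_dwell

    # absolute acquisition time of every sample in the stream
    t_stream = np.arange(n_samples) * dt
    bouton_of_sample = (np.arange(n_samples) // samples_per_dwell) % n_boutons

    vesicles = np.zeros((n_boutons, n_trials, n_aps), dtype=int)
    amplitudes = np.zeros((n_boutons, n_trials, n_aps))
    streams = np.zeros((n_trials, n_samples))
    for j, truth in enumerate(truths):
        sel = bouton_of_sample == j
        t_b = t_stream[sel]
        kernel = _ap_kernel(t_b, ap_times, glu_tau_ms)
        for i in range(n_trials):
            vesicles[j, i] = rng.binomial(truth.n_sites, truth.pv, size=n_aps)
            amplitudes[j, i] = vesicles[j, i] * truth.quantal_size_q + rng.normal(
                0.0, truth.noise_sigma, n_aps
            )
            streams[i, sel] = 1.0 + amplitudes[j, i] @ kernel
    if trace_noise > 0:
        streams += rng.normal(0.0, trace_noise, streams.shape)
    return MultiBoutonStream(
        streams=streams,
        cycle_map=[(j, samples_per_dwell) for j in range(n_boutons)],
        sample_interval_ms=dt,
        cycle_period_ms=cycle_period,
        ap_times_ms=ap_times,
        vesicle_counts=vesicles,
        amplitudes=amplitudes,
        truths=list(truths),
    )
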