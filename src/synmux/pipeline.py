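"""End-to-end synthetic study: simulate → calibrate → analyse → report.

Composes the full analysis chain on synthetic data with known ground
truth: FLIM calibration from clamped-[Ca2+] decays, multi-bouton
quantal simulations with trial-wise Ca2+ readout and release
statistics, the dye-equilibration stability control, and the
bouton-scan hotspot study (localisation, geodesic-corrected spatial
decay, Ca2+ entry detection, distance test against the random-scatter
null). Every stage seed derives deterministically from the single run
seed, and every output table carries the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, hotspots, quantal, stats
from .flim import NtcCalibration, compute_ntc, flim_readout
from .simulate import (
    DecayModel,
    GroundTruth,
    simulate_bouton_scan,
    simulate_decay_histogram,
    simulate_quantal_trials,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_end_to_end", "build_calibration", "stability_table"]


@dataclass
class CalibrationSettings:
    ca_grid_nM: tuple = (10.0, 25.0, 50.0, 100.0, 150.0, 250.0, 600.0, 5000.0)
    photons_per_point: float = 1e6
    window_ns: float = 3.0
    min_photons: float = 10_000.0


@dataclass
class QuantalSettings:
    n_boutons: int = 12
    n_trials: int = 20
    n_aps: int = 4
    inter_ap_ms: float = 50.0
    baseline_ms: float = 8.0
    response_ms: float = 14.0
    centre_margin: float = 0.15
    sigma_margin: float = 0.15
    max_components: int = 6
    pv_range: tuple = (0.15, 0.75)
    ca_dependence: bool = True


@dataclass
class GeometrySettings:
    quad_epsrel: float = 1e-8
    x_max_fraction: float = 0.5
    mean_a_um: float = 1.18
    mean_b_um: float = 0.89
    sd_b_um: float = 0.12
    aspect_mean: float = 1.35
    aspect_sd: float = 0.2


@dataclass
class HotspotSettings:
    n_boutons: int = 8
    smooth_um: float = 0.1
    top_fraction: float = 0.05
    z_threshold: float = 2.0
    null_radius_um: float = 0.52
    n_null_pairs: int = 80
    psf_fwhm_um: float = 0.3
    pixel_um: float = 0.0625
    ca_glu_offset_um: float = 0.25


@dataclass
class StatsSettings:
    alpha: float = 0.05
    welch: bool = True
    stability_trials: int = 20
    stability_ramp_fold: float = 2.5
    stability_photon_rate_per_ms: float = 40.0


@dataclass
class RunConfig:
    """Complete configuration of an end-to-end synthetic study."""

    seed: int = 0
    outdir: str = "synmux_run"
    save_recordings: bool = False
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    quantal: QuantalSettings = field(default_factory=QuantalSettings)
    geometry: GeometrySettings = field(default_factory=GeometrySettings)
    hotspots: HotspotSettings = field(default_factory=HotspotSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(text.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, default=list))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            payload = yaml.safe_load(path.read_text())
        else:
            payload = json.loads(path.read_text())
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        kwargs = dict(payload)
        for name, sub in (
            ("calibration", CalibrationSettings),
            ("quantal", QuantalSettings),
            ("geometry", GeometrySettings),
            ("hotspots", HotspotSettings),
            ("stats", StatsSettings),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                d = kwargs[name]
                fields = {f.name for f in dataclasses.fields(sub)}
                kwargs[name] = sub(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items() if k in fields})
        return cls(**kwargs)


def _stage_seeds(seed: int, n: int):
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def build_calibration(settings: CalibrationSettings, model: DecayModel, seed: int):
    """Simulate clamped-[Ca2+] decays and fit the NTC calibration."""
    seeds = _stage_seeds(seed, len(settings.ca_grid_nM))
    points = []
    for ca, s in zip(settings.ca_grid_nM, seeds):
        hist = simulate_decay_histogram(ca, settings.photons_per_point, model, seed=s)
        points.append((ca, compute_ntc(hist, window=settings.window_ns)))
    curve = NtcCalibration([p[0] for p in points], [p[1] for p in points]).fit()
    return curve, pd.DataFrame(points, columns=["ca_nM", "ntc_ns"])


def stability_table(sim, curve, min_photons: float = 5000.0) -> pd.DataFrame:
    """Per-trial photon totals and FLIM readouts for the stability check."""
    rows = []
    t_ap0 = float(sim.ap_times_ms[0])
    for i, tr in enumerate(sim.trials):
        rest = flim_readout(tr, curve, (0.0, t_ap0), min_photons=min_photons)
        evoked = flim_readout(tr, curve, (t_ap0, t_ap0 + 210.0), min_photons=min_photons)
        rows.append(
            {
                "trial": i,
                "total_photons": float(np.asarray(tr.intensity["ca"]).sum()),
                "ca_rest": rest,
                "ca_evoked": evoked - rest,
            }
        )
    return pd.DataFrame(rows)


def _quantal_stage(config: RunConfig, curve, rng: np.random.Generator) -> dict:
    qs = config.quantal
    bouton_rows = []
    trial_rows = []
    for bid in range(qs.n_boutons):
        pv = float(rng.uniform(*qs.pv_range))
        truth = GroundTruth(pv=pv, seed=int(rng.integers(2**31)))
        sim = simulate_quantal_trials(
            truth,
            n_trials=qs.n_trials,
            n_aps=qs.n_aps,
            inter_ap_interval=qs.inter_ap_ms,
            seed=truth.seed,
            ca_dependence=qs.ca_dependence,
        )
        amps = quantal.extract_amplitudes(
            sim.trials, baseline_ms=qs.baseline_ms, response_ms=qs.response_ms
        )
        ca_amps = quantal.extract_amplitudes(
            sim.trials, baseline_ms=qs.baseline_ms, response_ms=40.0, channel="ca"
        )
        try:
            sigma0 = quantal.fit_failure_noise(amps["amplitude"])
            fit = quantal.QuantalHistogramModel(
                amps["amplitude"],
                sigma0,
                max_components=qs.max_components,
                centre_margin=qs.centre_margin,
                sigma_margin=qs.sigma_margin,
            ).fit()
            q_est, content = fit.q, fit.quantal_content
            cutoff = fit.failure_cutoff
        except (quantal.NoFailuresError, quantal.QuantalFitError) as exc:
            logger.warning("bouton %d: quantal fit unavailable (%s)", bid, exc)
            sigma0, q_est, content, cutoff = float("nan"), float("nan"), None, float("nan")
        first = amps.loc[amps["ap"] == 1, "amplitude"]
        pr = quantal.release_probability(first, cutoff) if np.isfinite(cutoff) else float("nan")
        rest_ca = []
        for tr in sim.trials:
            try:
                rest_ca.append(flim_readout(tr, curve, (0.0, sim.ap_times_ms[0]), min_photons=5000))
            except Exception:
                rest_ca.append(float("nan"))
        table = amps.copy()
        table["bouton"] = bid
        table["quantal_content"] = content if content is not None else np.nan
        table["true_vesicles"] = sim.vesicle_counts.ravel()
        table["ca_amplitude"] = ca_amps["amplitude"].to_numpy()
        table["ca_rest_nM"] = np.repeat(rest_ca, qs.n_aps)
        table["total_photons"] = np.repeat(
            [float(np.asarray(t.intensity["ca"]).sum()) for t in sim.trials], qs.n_aps
        )
        trial_rows.append(table)
        mean_by_ap = amps.groupby("ap")["amplitude"].mean()
        ppr = stats.paired_pulse_ratio(amps, noise_cutoff=0.0)
        stp = stats.stp_slope(mean_by_ap.to_numpy()) if qs.n_aps == 4 else None
        bouton_rows.append(
            {
                "bouton": bid,
                "pv_true": pv,
                "pr_true": 1 - (1 - pv) ** truth.n_sites,
                "pr": pr,
                "sigma0": sigma0,
                "q": q_est,
                "q_true": truth.quantal_size_q,
                "ppr": ppr.ppr,
                "stp_slope": stp.slope if stp is not None else float("nan"),
            }
        )
    return {
        "boutons": pd.DataFrame(bouton_rows),
        "trials": pd.concat(trial_rows, ignore_index=True),
    }


def _hotspot_stage(config: RunConfig, rng: np.random.Generator) -> dict:
    hs, gs = config.hotspots, config.geometry
    gmaps, proj_maps = [], []
    distances = []
    loc_errors = []
    detected = 0
    for bid in range(hs.n_boutons):
        b = float(np.clip(rng.normal(gs.mean_b_um, gs.sd_b_um), 0.6, 1.2))
        a = float(max(b, b * np.clip(rng.normal(gs.aspect_mean, gs.aspect_sd), 1.0, 1.8)))
        geom = geometry.BoutonGeometry(a=a, b=b)
        angle = rng.uniform(0, 2 * np.pi)
        offset = hs.ca_glu_offset_um
        truth = GroundTruth(
            pv=float(rng.uniform(0.3, 0.7)),
            ca_entry_site=(offset * np.cos(angle), offset * np.sin(angle)),
            seed=int(rng.integers(2**31)),
        )
        sim = simulate_bouton_scan(
            geom,
            truth,
            psf_fwhm_xy=hs.psf_fwhm_um,
            pixel_um=hs.pixel_um,
            n_trials=int(rng.integers(20, 23)),
            seed=truth.seed,
        )
        glu_map = hotspots.build_response_heatmap(sim.trials, channel="glu")
        glu_map.origin_um = sim.origin_um
        ca_map = hotspots.build_response_heatmap(sim.trials, channel="ca")
        ca_map.origin_um = sim.origin_um
        loc = hotspots.localize_hotspot(
            glu_map, smooth_um=hs.smooth_um, top_fraction=hs.top_fraction, psf_fwhm_um=hs.psf_fwhm_um
        )
        loc_errors.append(
            float(np.hypot(loc.primary[0] - sim.release_site_xy[0], loc.primary[1] - sim.release_site_xy[1]))
        )
        gmaps.append(geometry.geodesic_correct_map(glu_map, geom))
        proj_maps.append(glu_map)
        det = hotspots.detect_ca_hotspot(ca_map, z_threshold=hs.z_threshold, smooth_um=hs.smooth_um)
        if det is not None:
            detected += 1
            distances.append(
                float(np.hypot(det.primary[0] - loc.primary[0], det.primary[1] - loc.primary[1]))
            )
    decay = hotspots.fit_spatial_decay(gmaps, psf_fwhm_um=hs.psf_fwhm_um)
    null = hotspots.random_pair_null(hs.null_radius_um, hs.n_null_pairs, seed=int(rng.integers(2**31)))
    test = (
        hotspots.compare_distances(np.asarray(distances), null, hs.null_radius_um)
        if len(distances) >= 2
        else None
    )
    return {
        "decay": decay,
        "loc_errors": np.asarray(loc_errors),
        "distances": np.asarray(distances),
        "null": null,
        "test": test,
        "n_detected": detected,
    }


def run_end_to_end(config: RunConfig, outdir=None) -> dict:
    """Run the full synthetic study; returns and writes the report bundle."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    seeds = _stage_seeds(config.seed, 4)
    report: dict = {"seed": config.seed, "config_hash": cfg_hash}

    logger.info("stage 1/4: FLIM calibration")
    model = DecayModel()
    try:
        curve, cal_points = build_calibration(config.calibration, model, seeds[0])
    except Exception as exc:
        raise RuntimeError(f"calibration stage failed on input {config.calibration}: {exc}") from exc
    cal_points["config_hash"] = cfg_hash
    cal_points.to_csv(outdir / "calibration_points.csv", index=False)
    curve.to_json(outdir / "calibration_curve.json")
    report["calibration"] = {"r2": curve.r2, "chi2": curve.chi2, "ec50_nM": curve.ec50, "hill": curve.hill}

    logger.info("stage 2/4: quantal analysis of %d boutons", config.quantal.n_boutons)
    try:
        rng_q = np.random.default_rng(seeds[1])
        qout = _quantal_stage(config, curve, rng_q)
    except Exception as exc:
        raise RuntimeError(f"quantal stage failed: {exc}") from exc
    for name, df in (("bouton_summary", qout["boutons"]), ("trial_table", qout["trials"])):
        df = df.copy()
        df["config_hash"] = cfg_hash
        df.to_csv(outdir / f"{name}.csv", index=False)
    bt = qout["boutons"]
    ok = bt.dropna(subset=["q", "pr"])
    trials_tbl = qout["trials"].dropna(subset=["quantal_content", "ca_amplitude"])
    if len(trials_tbl) >= 3:
        reg_ca = stats.trialwise_regression(trials_tbl, "ca_amplitude", "quantal_content")
        reg_summary = {"slope": reg_ca.slope, "r": reg_ca.pearson_r, "p": reg_ca.p_slope, "n": reg_ca.n}
    else:
        reg_summary = {"slope": float("nan"), "r": float("nan"), "p": float("nan"), "n": int(len(trials_tbl))}
    stp_signs = np.sign(bt["stp_slope"].dropna())
    report["quantal"] = {
        "n_boutons": int(len(bt)),
        "median_q_rel_error": float(np.median(np.abs(ok["q"] - ok["q_true"]) / ok["q_true"])),
        "pr_bias": float((ok["pr"] - ok["pr_true"]).mean()),
        "ca_release_regression": reg_summary,
        "facilitating_fraction": float((stp_signs > 0).mean()) if len(stp_signs) else float("nan"),
    }

    logger.info("stage 3/4: dye-equilibration stability check")
    try:
        ss = config.stats
        sim = simulate_quantal_trials(
            GroundTruth(seed=seeds[2]),
            n_trials=ss.stability_trials,
            seed=seeds[2],
            photon_rate_per_ms=ss.stability_photon_rate_per_ms,
            photon_ramp_fold=ss.stability_ramp_fold,
        )
        stab = stats.stability_check(stability_table(sim, curve))
        report["stability"] = {
            name: {"slope": r.slope, "p": r.p_slope, "r": r.pearson_r} for name, r in stab.items()
        }
    except Exception as exc:
        raise RuntimeError(f"stability stage failed: {exc}") from exc

    logger.info("stage 4/4: hotspot study (%d boutons)", config.hotspots.n_boutons)
    try:
        hout = _hotspot_stage(config, np.random.default_rng(seeds[3]))
    except Exception as exc:
        raise RuntimeError(f"hotspot stage failed: {exc}") from exc
    report["hotspots"] = {
        "spatial_decay_um": hout["decay"].mean_um,
        "spatial_decay_sem_um": hout["decay"].sem_um,
        "spatial_decay_truth_um": GroundTruth().glu_spatial_decay,
        "median_localisation_error_um": float(np.median(hout["loc_errors"])),
        "n_ca_hotspots_detected": hout["n_detected"],
        "mean_hotspot_distance_um": float(hout["distances"].mean()) if hout["distances"].size else float("nan"),
        "null_mean_um": float(hout["null"].mean()),
    }
    if hout["test"] is not None:
        report["hotspots"]["distance_test_p"] = hout["test"].p_value
        report["hotspots"]["distance_test_t"] = hout["test"].t_statistic

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    config.save(outdir / "config.json")
    logger.info("report written to %s", outdir / "report.json")
    return report
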