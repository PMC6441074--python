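"""Synthetic-data generators: statistical properties and ground truth."""

import numpy as np
import pytest

from synmux.geometry import BoutonGeometry
from synmux.simulate import (
    DecayModel,
    GroundTruth,
    simulate_bouton_scan,
    simulate_decay_histogram,
    simulate_multibouton_stream,
    simulate_quantal_trials,
)


def _fit_component_fractions(hist, model, ca_grid_bins=256):
    """Linear least-squares decomposition into the two known components."""
    p_free, p_bound, _ = model.bin_probabilities(0.0, hist.counts.size)
    design = np.column_stack([p_free, p_bound])
    coef, *_ = np.linalg.lstsq(design, hist.counts, rcond=None)
    coef = np.clip(coef, 0, None)
    return coef / coef.sum()


class TestDecayHistogram:
    def test_photon_total_is_poisson_consistent(self, decay_model):
        totals = [
            simulate_decay_histogram(100.0, 5000, decay_model, seed=s).total for s in range(60)
        ]
        ratio = np.var(totals) / np.mean(totals)
        assert 0.5 < ratio < 1.7  # variance/mean ~ 1 within Monte-Carlo error
        assert np.mean(totals) == pytest.approx(5000, rel=0.05)

    def test_zero_ca_decays_with_free_lifetime(self, decay_model):
        hist = simulate_decay_histogram(0.0, 2e6, decay_model, seed=1)
        # log-linear slope over an early post-peak window
        peak = hist.peak_index
        sel = slice(peak + 4, peak + 16)
        t = hist.times[sel]
        y = np.log(hist.counts[sel])
        tau = -1.0 / np.polyfit(t, y, 1)[0]
        assert tau == pytest.approx(decay_model.tau_free, rel=0.1)

    def test_saturating_ca_decays_with_bound_lifetime(self, decay_model):
        hist = simulate_decay_histogram(1e6, 2e6, decay_model, seed=2)
        peak = hist.peak_index
        sel = slice(peak + 8, peak + 40)
        t = hist.times[sel]
        y = np.log(np.clip(hist.counts[sel], 1, None))
        tau = -1.0 / np.polyfit(t, y, 1)[0]
        assert tau == pytest.approx(decay_model.tau_bound, rel=0.1)

    def test_half_occupancy_at_kd(self, decay_model):
        """At ca = Kd the bound component carries half the photons."""
        fracs = []
        for s in range(50):
            hist = simulate_decay_histogram(decay_model.kd, 2e5, decay_model, seed=s)
            fracs.append(_fit_component_fractions(hist, decay_model)[1])
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)

    def test_seed_reproducibility(self, decay_model):
        h1 = simulate_decay_histogram(50, 1e4, decay_model, seed=9)
        h2 = simulate_decay_histogram(50, 1e4, decay_model, seed=9)
        h3 = simulate_decay_histogram(50, 1e4, decay_model, seed=10)
        assert np.array_equal(h1.counts, h2.counts)
        assert not np.array_equal(h1.counts, h3.counts)

    def test_invalid_inputs_rejected(self, decay_model):
        with pytest.raises(ValueError):
            simulate_decay_histogram(-1.0, 1000, decay_model)
        with pytest.raises(ValueError):
            simulate_decay_histogram(10.0, 0, decay_model)
        with pytest.raises(ValueError):
            DecayModel(tau_free=1.0, tau_bound=1.0)
        with pytest.raises(ValueError):
            DecayModel(kd=-5.0)


class TestQuantalTrials:
    def test_pv_zero_gives_pure_noise_failures(self):
        truth = GroundTruth(pv=0.0)
        sim = simulate_quantal_trials(truth, n_trials=100, n_aps=2, seed=0)
        assert np.all(sim.vesicle_counts == 0)
        amps = sim.amplitudes.ravel()
        assert np.mean(amps) == pytest.approx(0.0, abs=3 * truth.noise_sigma / np.sqrt(amps.size))
        assert np.std(amps) == pytest.approx(truth.noise_sigma, rel=0.2)

    def test_deterministic_release_gives_exact_quanta(self):
        truth = GroundTruth(pv=1.0, n_sites=1, noise_sigma=0.0)
        sim = simulate_quantal_trials(truth, n_trials=10, seed=1)
        assert np.allclose(sim.amplitudes, truth.quantal_size_q)

    def test_success_rate_matches_binomial_complement(self):
        truth = GroundTruth(pv=0.4, n_sites=3)
        sim = simulate_quantal_trials(truth, n_trials=500, n_aps=1, seed=3)
        rate = np.mean(sim.vesicle_counts > 0)
        expected = 1 - (1 - 0.4) ** 3  # 0.784
        assert rate == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 500))

    def test_amplitude_peaks_at_quantal_multiples(self):
        """With noise << q, amplitudes cluster at integer multiples of q."""
        truth = GroundTruth(quantal_size_q=0.4, noise_sigma=0.02, pv=0.5, n_sites=3)
        sim = simulate_quantal_trials(truth, n_trials=200, n_aps=1, seed=5)
        quanta = np.round(sim.amplitudes.ravel() / 0.4).astype(int)
        assert np.array_equal(quanta, sim.vesicle_counts.ravel())
        from scipy.stats import binom, chisquare

        observed = np.bincount(quanta, minlength=4)[:4]
        expected = binom.pmf(np.arange(4), 3, 0.5) * quanta.size
        _, p = chisquare(observed, expected * observed.sum() / expected.sum())
        assert p > 0.001

    def test_invalid_pv_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(pv=1.5)

    def test_reproducible(self):
        t = GroundTruth()
        s1 = simulate_quantal_trials(t, n_trials=5, seed=2)
        s2 = simulate_quantal_trials(t, n_trials=5, seed=2)
        assert np.array_equal(s1.amplitudes, s2.amplitudes)
        assert np.array_equal(s1.trials[0].decay, s2.trials[0].decay)


class TestMultiBoutonStream:
    def test_cycle_period_matches_dwell_times(self):
        truths = [GroundTruth(seed=i) for i in range(4)]
        stream = simulate_multibouton_stream(truths, dwell_ms=1.5, seed=0)
        assert stream.cycle_period_ms == pytest.approx(6.0)

    def test_single_bouton_stream_is_plain_scan(self):
        truth = GroundTruth(pv=1.0, n_sites=1, noise_sigma=0.0)
        stream = simulate_multibouton_stream([truth], dwell_ms=1.0, seed=1, trace_noise=0.0)
        assert stream.streams.shape[1] == stream.streams[0].size
        # with deterministic release the trace is exactly baseline + quantal transient
        assert stream.streams[0].min() >= 1.0 - 1e-9

    def test_neighbouring_boutons_release_independently(self):
        truths = [GroundTruth(pv=0.4, seed=i) for i in range(2)]
        stream = simulate_multibouton_stream(truths, n_trials=100, seed=2)
        succ = stream.vesicle_counts[:, :, 0] > 0
        r = np.corrcoef(succ[0], succ[1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(100)

    def test_empty_truth_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_multibouton_stream([], seed=0)
        with pytest.raises(ValueError):
            simulate_multibouton_stream([GroundTruth()] * 9, seed=0)


class TestBoutonScan:
    def test_noise_free_heatmap_peaks_at_release_site(self):
        geom = BoutonGeometry(a=1.0, b=0.8)
        truth = GroundTruth(pv=1.0)
        sim = simulate_bouton_scan(geom, truth, n_trials=1, seed=0, no_noise=True)
        iy, ix = np.unravel_index(np.argmax(sim.expected_dff_map), sim.expected_dff_map.shape)
        x = sim.origin_um[0] + ix * sim.pixel_um
        y = sim.origin_um[1] + iy * sim.pixel_um
        assert abs(x - sim.release_site_xy[0]) <= 2 * sim.pixel_um
        assert abs(y - sim.release_site_xy[1]) <= 2 * sim.pixel_um

    def test_uniform_shell_projection_brightens_toward_edge(self):
        """The baseline (uniformly labelled membrane) projection rises off-centre."""
        geom = BoutonGeometry(a=0.9, b=0.9)
        sim = simulate_bouton_scan(geom, GroundTruth(), n_trials=1, seed=0, no_noise=True,
                                   z_excitation_fwhm_um=50.0)  # no axial sectioning
        base = sim.baseline_map
        ny, nx = base.shape
        xs = sim.origin_um[0] + np.arange(nx) * sim.pixel_um
        ys = sim.origin_um[1] + np.arange(ny) * sim.pixel_um
        xx, yy = np.meshgrid(xs, ys)
        rho = np.hypot(xx, yy) / 0.9
        centre = base[(rho < 0.25)].mean()
        annulus = base[(rho > 0.6) & (rho < 0.8)].mean()
        assert annulus > 1.1 * centre

    def test_psf_range_enforced(self):
        with pytest.raises(ValueError, match="0.2"):
            simulate_bouton_scan(BoutonGeometry(1.0, 0.8), GroundTruth(), psf_fwhm_xy=0.6, seed=0)

    def test_off_surface_release_site_rejected(self):
        truth = GroundTruth(release_site=(0.0, 0.0, 0.0))  # bouton centre, not surface
        with pytest.raises(ValueError, match="surface"):
            simulate_bouton_scan(BoutonGeometry(1.0, 0.8), truth, seed=0)
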