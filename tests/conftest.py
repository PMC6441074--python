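import numpy as np
import pytest

from synmux.flim import NtcCalibration, compute_ntc
from synmux.geometry import BoutonGeometry
from synmux.simulate import DecayModel, GroundTruth, simulate_bouton_scan, simulate_decay_histogram, simulate_quantal_trials

CA_GRID = (10.0, 25.0, 50.0, 100.0, 150.0, 250.0, 600.0, 5000.0)


@pytest.fixture(scope="session")
def decay_model():
    return DecayModel()


@pytest.fixture(scope="session")
def calibration_curve(decay_model):
    """Calibration fitted to simulated clamped-[Ca2+] decay histograms."""
    points = []
    for i, ca in enumerate(CA_GRID):
        hist = simulate_decay_histogram(ca, 1e6, decay_model, seed=1000 + i)
        points.append((ca, compute_ntc(hist)))
    return NtcCalibration([p[0] for p in points], [p[1] for p in points]).fit()


@pytest.fixture(scope="session")
def quantal_sim():
    """300-sample quantal simulation at the default study conditions."""
    truth = GroundTruth(quantal_size_q=0.35, noise_sigma=0.06, pv=0.4, n_sites=3)
    return simulate_quantal_trials(truth, n_trials=75, n_aps=4, seed=0)


@pytest.fixture(scope="session")
def bouton_scan():
    """Tornado-scan simulation of a population-mean ellipsoidal bouton."""
    geom = BoutonGeometry(a=1.18, b=0.89)
    truth = GroundTruth(glu_spatial_decay=0.547, ca_entry_site=(0.25, 0.1))
    return simulate_bouton_scan(geom, truth, seed=1)
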