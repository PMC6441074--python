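"""Trial-wise and cross-bouton presynaptic statistics.

Linear regressions relate glutamate release (ΔF/F amplitude or quantal
content) to presynaptic Ca2+ readouts trial by trial; the paired-pulse
ratio and the short-term-plasticity slope summarise use-dependent
changes along 4-AP trains; and the stability check verifies that a
rising indicator concentration (total photon count) leaves the
concentration-independent FLIM readouts flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "PairedPulseResult",
    "trialwise_regression",
    "paired_pulse_ratio",
    "stp_slope",
    "stability_check",
]


@dataclass
class RegressionResult:
    """Ordinary least-squares line with Pearson correlation.

    ``p_slope`` is the two-sided t-test p value of the slope, which for
    simple regression equals the correlation test p value.
    """

    slope: float
    intercept: float
    pearson_r: float
    p_slope: float
    n: int
    slope_stderr: float = float("nan")
    x_name: str = "x"
    y_name: str = "y"

    @property
    def significant(self) -> bool:
        return self.p_slope < 0.05

    def summary(self) -> str:
        return (
            f"OLS {self.y_name} ~ {self.x_name} (n={self.n}): "
            f"slope={self.slope:.4g} +/- {self.slope_stderr:.2g}, "
            f"r={self.pearson_r:.3f}, p={self.p_slope:.4g}"
        )


def _ols(x: np.ndarray, y: np.ndarray, x_name: str = "x", y_name: str = "y") -> RegressionResult:
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        pearson_r=r,
        p_slope=float(model.pvalues[1]),
        n=int(x.size),
        slope_stderr=float(model.bse[1]),
        x_name=x_name,
        y_name=y_name,
    )


def trialwise_regression(table: pd.DataFrame, x: str, y: str) -> RegressionResult:
    """OLS of column ``y`` on column ``x`` over complete rows."""
    sub = table[[x, y]].dropna()
    return _ols(sub[x].to_numpy(dtype=float), sub[y].to_numpy(dtype=float), x, y)


@dataclass
class PairedPulseResult:
    """Paired-pulse ratio with a validity flag.

    The PPR is the ratio of mean second to mean first ΔF/F amplitudes
    (means over trials, failures included). When the first-AP mean does
    not exceed the noise cut-off the ratio is undefined and flagged.
    """

    ppr: float
    defined: bool
    mean_first: float
    mean_second: float
    n_trials: int


def paired_pulse_ratio(amplitudes: pd.DataFrame, noise_cutoff: float = 0.0) -> PairedPulseResult:
    """PPR from a tidy amplitude table (columns ``trial, ap, amplitude``)."""
    firsts = amplitudes.loc[amplitudes["ap"] == 1, "amplitude"].to_numpy(dtype=float)
    seconds = amplitudes.loc[amplitudes["ap"] == 2, "amplitude"].to_numpy(dtype=float)
    if firsts.size == 0 or seconds.size == 0:
        raise ValueError("need trials with at least two AP amplitudes")
    m1, m2 = float(firsts.mean()), float(seconds.mean())
    if m1 <= noise_cutoff:
        return PairedPulseResult(ppr=float("nan"), defined=False, mean_first=m1, mean_second=m2, n_trials=firsts.size)
    return PairedPulseResult(ppr=m2 / m1, defined=True, mean_first=m1, mean_second=m2, n_trials=firsts.size)


def stp_slope(mean_amplitudes) -> RegressionResult:
    """Short-term plasticity slope over a 4-AP train.

    Mean amplitudes for APs 1..4 are normalised to the first AP and
    regressed against the AP number; a positive slope classifies
    facilitation, a negative one depression.
    """
    amps = np.asarray(mean_amplitudes, dtype=float)
    if amps.size != 4 or not np.isfinite(amps).all():
        raise ValueError("need finite mean amplitudes for APs 1..4")
    if amps[0] == 0:
        raise ValueError("first-AP amplitude is zero; cannot normalise")
    rel = amps / amps[0]
    ap = np.arange(1, 5, dtype=float)
    return _ols(ap, rel, "ap_number", "relative_amplitude")


def stability_check(table: pd.DataFrame, min_trials: int = 10) -> dict[str, RegressionResult]:
    """Dye-equilibration stability regressions against trial number.

    Expects per-trial columns ``trial, total_photons, ca_rest,
    ca_evoked``. In a conforming dataset (dye still equilibrating, true
    Ca2+ stable) the photon count rises significantly with trial number
    while both FLIM readouts show null slopes — the signature that the
    lifetime readout is concentration-independent.
    """
    n = table["trial"].nunique()
    if n < min_trials:
        warnings.warn(
            f"only {n} trials (<{min_trials}); stability regressions are low-powered",
            stacklevel=2,
        )
    out = {}
    for col, name in (
        ("total_photons", "photon_count"),
        ("ca_rest", "resting_ca"),
        ("ca_evoked", "evoked_ca"),
    ):
        out[name] = trialwise_regression(table, "trial", col)
    return out
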