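"""Recording containers and scan-stream utilities.

FLIM line-scan recordings are stored as 5-D photon-count tensors with
axes ``(t, x, y, z, T)`` where ``t`` is the lifetime-decay delay axis
and ``T`` the global experiment time, alongside per-sample intensity
traces for each spectral channel. On disk the container is an HDF5
hierarchy (one group per trial plus a ``/meta`` group); round trips are
lossless.

The module also provides the scan-geometry helpers: rearrangement of an
interleaved multi-bouton point-scan stream into per-bouton
"pseudo-linescans" (one displayed row per scan cycle), the Archimedean
spiral coordinate map of tornado scans, and ΔF/F computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "TrialRecording",
    "PseudoLinescan",
    "TornadoScan",
    "read_trials",
    "write_trials",
    "rearrange_pseudo_linescan",
    "tornado_to_xy",
    "dff",
]


class SchemaError(ValueError):
    """Raised when an on-disk container is missing required structure."""


@dataclass
class TrialRecording:
    """One recorded trial: intensity traces plus optional FLIM photon data.

    Attributes
    ----------
    intensity : dict of str -> ndarray
        Per-channel sample arrays with global time as the last axis.
        Point recordings are 1-D ``(T,)``; imaged recordings are
        ``(ny, nx, T)``.
    decay : ndarray or None
        5-D photon-count tensor ``(t, x, y, z, T)`` for the FLIM channel.
    decay_bin_ns : float
        Width of the lifetime-delay bins, ns.
    sample_interval_ms : float
        Global-time sampling interval, ms.
    ap_times_ms : ndarray
        Action-potential times within the sweep, ms.
    pixel_um : float or None
        Pixel pitch for imaged recordings, µm.
    scan : dict
        Scan-geometry descriptor (``kind``: "tornado" or "point-cycle",
        plus geometry parameters).
    meta : dict
        Free-form metadata (seed, bouton id, ground truth, ...).
    """

    intensity: Mapping[str, np.ndarray]
    decay: np.ndarray | None = None
    decay_bin_ns: float = 0.0
    sample_interval_ms: float = 1.0
    ap_times_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    pixel_um: float | None = None
    scan: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = {k: np.asarray(v) for k, v in self.intensity.items()}
        self.ap_times_ms = np.asarray(self.ap_times_ms, dtype=float)
        if self.decay is not None:
            self.decay = np.asarray(self.decay)
            if self.decay.ndim != 5:
                raise ValueError("decay tensor must have axes (t, x, y, z, T)")
            if np.any(self.decay < 0):
                raise ValueError("photon counts must be non-negative")
            if self.decay_bin_ns <= 0:
                raise ValueError("decay_bin_ns must be positive when a decay tensor is present")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be positive")
        n_t = self.n_samples
        if n_t and self.ap_times_ms.size:
            t_end = n_t * self.sample_interval_ms
            if np.any(self.ap_times_ms < 0) or np.any(self.ap_times_ms > t_end):
                raise ValueError("ap_times_ms must lie within the recording")

    @property
    def n_samples(self) -> int:
        for arr in self.intensity.values():
            return arr.shape[-1]
        return self.decay.shape[-1] if self.decay is not None else 0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_ms

    @property
    def channels(self) -> list[str]:
        return list(self.intensity.keys())


def write_trials(trials: Sequence[TrialRecording], path, ground_truth: dict | None = None) -> None:
    """Write a trial sequence to an HDF5 container.

    Layout: ``/trials/NNNNN/{decay, intensity/<channel>, ap_times_ms}``
    with scalar metadata as group attributes, plus ``/meta`` carrying
    the trial count and an optional ground-truth JSON sidecar string.
    """
    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        meta.attrs["n_trials"] = len(trials)
        meta.attrs["format"] = "synmux-trials-v1"
        if ground_truth is not None:
            meta.attrs["ground_truth"] = json.dumps(ground_truth)
        root = fh.create_group("trials")
        for i, trial in enumerate(trials):
            grp = root.create_group(f"{i:05d}")
            inten = grp.create_group("intensity")
            for name, arr in trial.intensity.items():
                inten.create_dataset(name, data=arr)
            if trial.decay is not None:
                grp.create_dataset("decay", data=trial.decay)
                grp.attrs["decay_bin_ns"] = trial.decay_bin_ns
            grp.create_dataset("ap_times_ms", data=trial.ap_times_ms)
            grp.attrs["sample_interval_ms"] = trial.sample_interval_ms
            if trial.pixel_um is not None:
                grp.attrs["pixel_um"] = trial.pixel_um
            grp.attrs["scan"] = json.dumps(trial.scan)
            grp.attrs["meta"] = json.dumps(trial.meta)


def read_trials(path) -> list[TrialRecording]:
    """Read a trial sequence written by :func:`write_trials`.

    Raises :class:`SchemaError` naming the missing element if the
    container does not conform. A 0-trial container yields an empty
    list.
    """
    trials: list[TrialRecording] = []
    with h5py.File(path, "r") as fh:
        if "meta" not in fh:
            raise SchemaError("container is missing /meta")
        if "trials" not in fh:
            raise SchemaError("container is missing /trials")
        for key in sorted(fh["trials"].keys()):
            grp = fh["trials"][key]
            if "intensity" not in grp:
                raise SchemaError(f"/trials/{key} is missing intensity")
            if "ap_times_ms" not in grp:
                raise SchemaError(f"/trials/{key} is missing ap_times_ms")
            if "sample_interval_ms" not in grp.attrs:
                raise SchemaError(f"/trials/{key} is missing sample_interval_ms")
            intensity = {name: ds[()] for name, ds in grp["intensity"].items()}
            decay = grp["decay"][()] if "decay" in grp else None
            trials.append(
                TrialRecording(
                    intensity=intensity,
                    decay=decay,
                    decay_bin_ns=float(grp.attrs.get("decay_bin_ns", 0.0)),
                    sample_interval_ms=float(grp.attrs["sample_interval_ms"]),
                    ap_times_ms=grp["ap_times_ms"][()],
                    pixel_um=float(grp.attrs["pixel_um"]) if "pixel_um" in grp.attrs else None,
                    scan=json.loads(grp.attrs.get("scan", "{}")),
                    meta=json.loads(grp.attrs.get("meta", "{}")),
                )
            )
    return trials


def read_ground_truth(path) -> dict | None:
    with h5py.File(path, "r") as fh:
        if "meta" in fh and "ground_truth" in fh["meta"].attrs:
            return json.loads(fh["meta"].attrs["ground_truth"])
    return None


@dataclass
class PseudoLinescan:
    """Per-bouton image assembled from successive multi-bouton scan cycles.

    Row ``i`` holds the within-dwell samples recorded at this bouton
    during cycle ``i``; rows are therefore strictly ordered in time with
    one row per cycle.
    """

    image: np.ndarray
    bouton_id: object
    cycle_period_ms: float
    dwell_offset: int = 0

    @property
    def n_cycles(self) -> int:
        return self.image.shape[0]


def rearrange_pseudo_linescan(
    stream: np.ndarray,
    cycle_map: Sequence[tuple[object, int]],
    sample_interval_ms: float = 1.0,
) -> dict:
    """Rearrange an interleaved point-scan stream into per-bouton images.

    ``cycle_map`` lists ``(bouton_id, n_dwell_samples)`` in acquisition
    order within one cycle. Sample ``(cycle i, bouton j, within-dwell
    k)`` lands at row ``i``, column ``k`` of bouton ``j``'s image; the
    rearrangement is a pure permutation, so concatenating the images
    column-wise in dwell order and flattening row-major reproduces the
    stream. A trailing partial cycle is dropped with a logged warning.
    """
    stream = np.asarray(stream)
    if stream.ndim != 1:
        raise ValueError("stream must be 1-D")
    if len(cycle_map) == 0:
        raise ValueError("cycle_map is empty")
    dwells = [int(n) for _, n in cycle_map]
    if any(n <= 0 for n in dwells):
        raise ValueError("dwell sample counts must be positive")
    per_cycle = sum(dwells)
    n_cycles = stream.size // per_cycle
    if n_cycles == 0:
        raise ValueError(
            f"stream of {stream.size} samples shorter than one cycle ({per_cycle} samples)"
        )
    dropped = stream.size - n_cycles * per_cycle
    if dropped:
        logger.warning("dropping trailing partial cycle of %d samples", dropped)
    table = stream[: n_cycles * per_cycle].reshape(n_cycles, per_cycle)
    out: dict = {}
    offset = 0
    for (bouton_id, _), n in zip(cycle_map, dwells):
        out[bouton_id] = PseudoLinescan(
            image=table[:, offset : offset + n].copy(),
            bouton_id=bouton_id,
            cycle_period_ms=per_cycle * sample_interval_ms,
            dwell_offset=offset,
        )
        offset += n
    return out


def flatten_pseudo_linescans(scans: Mapping[object, PseudoLinescan]) -> np.ndarray:
    """Inverse of :func:`rearrange_pseudo_linescan` (up to a dropped tail)."""
    ordered = sorted(scans.values(), key=lambda s: s.dwell_offset)
    table = np.concatenate([s.image for s in ordered], axis=1)
    return table.reshape(-1)


@dataclass
class TornadoScan:
    """Archimedean spiral scan descriptor.

    The spiral angle runs from 0 to ``2*pi*n_turns`` with the radius
    growing linearly in angle up to ``radius_um``; 2.5 and 5 turns are
    the two standard settings.
    """

    radius_um: float
    n_turns: float = 2.5
    n_samples: int = 256
    centre_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.n_turns <= 0 or self.n_samples < 2:
            raise ValueError("invalid tornado scan parameters")


def tornado_to_xy(scan: TornadoScan, sample_index) -> tuple[np.ndarray, np.ndarray]:
    """In-plane position (µm) of spiral-scan samples.

    Uniformly spaced angular samples of the linear-radius spiral; the
    first sample sits at the scan centre and the final sample at the
    full scan radius. Per-area sampling density falls off as 1/r.
    """
    idx = np.asarray(sample_index)
    if np.any(idx < 0) or np.any(idx > scan.n_samples - 1):
        raise ValueError("sample index outside the sweep")
    theta_max = 2.0 * np.pi * scan.n_turns
    theta = theta_max * idx / (scan.n_samples - 1)
    r = scan.radius_um * theta / theta_max
    x = scan.centre_um[0] + r * np.cos(theta)
    y = scan.centre_um[1] + r * np.sin(theta)
    return x, y


def dff(trace: np.ndarray, baseline_window_ms: tuple[float, float], sample_interval_ms: float) -> np.ndarray:
    """ΔF/F of a fluorescence trace.

    ``F0`` is the mean over the baseline window (which must precede the
    analysed part of the sweep and be strictly positive); the result is
    ``(F - F0) / F0`` sample-wise along the last axis.
    """
    trace = np.asarray(trace, dtype=float)
    lo, hi = baseline_window_ms
    if hi <= lo:
        raise ValueError("baseline window is empty")
    i0 = int(round(lo / sample_interval_ms))
    i1 = int(round(hi / sample_interval_ms))
    i1 = max(i1, i0 + 1)
    if i1 > trace.shape[-1]:
        raise ValueError("baseline window extends past the trace")
    f0 = trace[..., i0:i1].mean(axis=-1, keepdims=True)
    if np.any(f0 <= 0):
        raise ValueError("baseline mean must be positive")
    return (trace - f0) / f0
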