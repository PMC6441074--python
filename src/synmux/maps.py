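"""Spatial heat maps of bouton-resolved signals.

A :class:`HeatMap` is the common container for 2-D per-pixel readouts —
glutamate-sensor ΔF/F response maps, FLIM-derived [Ca2+] maps, or their
geodesic-corrected versions. Pixel coordinates are physical (µm), with
the map origin at the centre of pixel (0, 0) unless shifted; helper
methods convert between pixel indices and in-plane µm positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class HeatMap:
    """2-D spatial map of a per-pixel signal.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Per-pixel signal (ΔF/F, nM, or photon counts). May contain NaN
        for pixels with insufficient data.
    pixel_um : float
        Pixel pitch in µm (square pixels).
    channel : str
        Channel label, e.g. ``"glu"`` or ``"ca"``.
    n_trials : int
        Number of trials averaged into the map.
    mask : ndarray of bool, optional
        Valid-pixel mask (same shape as ``values``). Defaults to all
        finite pixels.
    corrected : bool
        Whether geodesic distance correction has been applied.
    origin_um : tuple of float
        In-plane (x, y) position of pixel (row 0, col 0) centre, µm.
    """

    values: np.ndarray
    pixel_um: float
    channel: str = ""
    n_trials: int = 1
    mask: np.ndarray | None = None
    corrected: bool = False
    origin_um: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("HeatMap values must be 2-D")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return per-pixel (x, y) positions in µm as two 2-D arrays.

        x varies along columns, y along rows.
        """
        ny, nx = self.values.shape
        x = self.origin_um[0] + np.arange(nx) * self.pixel_um
        y = self.origin_um[1] + np.arange(ny) * self.pixel_um
        return np.meshgrid(x, y)

    def to_um(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Convert fractional pixel indices to in-plane µm positions."""
        x = self.origin_um[0] + np.asarray(col) * self.pixel_um
        y = self.origin_um[1] + np.asarray(row) * self.pixel_um
        return x, y

    def masked(self) -> np.ndarray:
        """Values with invalid pixels replaced by NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def copy_with(self, **kwargs) -> "HeatMap":
        return replace(self, **kwargs)

    def save_tiff(self, path) -> None:
        """Export the map as a 32-bit TIFF with pixel-size metadata."""
        res = 1.0 / self.pixel_um  # pixels per µm
        tifffile.imwrite(
            str(path),
            self.masked().astype(np.float32),
            resolution=(res, res),
            metadata={"unit": "um", "channel": self.channel, "n_trials": self.n_trials},
        )

    @classmethod
    def load_tiff(cls, path, pixel_um: float, **kwargs) -> "HeatMap":
        values = tifffile.imread(str(path))
        return cls(values=np.asarray(values, dtype=float), pixel_um=pixel_um, **kwargs)
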