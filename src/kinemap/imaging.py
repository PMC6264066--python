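"""Encoding of decomposed acceleration windows into 28×28 binary images.

Each image summarises a 51-sample (5.1 s at 10 Hz) window of movement
acceleration.  Every sample in the window contributes one pixel: its row is
the binned horizontal-magnitude ratio ``|a_h|/|g'|`` and its column the binned
vertical ratio ``|a_v|/|g'|``, with bin

    index = floor(1 + 9 * min(3, ratio))

so one g of movement spans nine bins and everything at or above three g lands
in the saturation bin 28.  Pixels hit more than once stay 1 — the image is a
binary occupancy map of the window's intensity signature, not a histogram.
Consecutive windows advance by 25 samples (2.5 s).

Bin indices follow the 1-based convention of the encoding's pseudo-code in all
serialized artefacts; in-memory arrays are 0-based numpy as usual, with
``pixels[h-1, v-1]`` holding bin pair ``(h, v)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_core import AccelSeries, DecomposedSeries, ProcessingConfig, decompose_series

__all__ = [
    "AccelImage",
    "ImageStack",
    "InvalidWindowError",
    "bin_index",
    "make_image",
    "valid_window_centers",
    "session_to_images",
]


class InvalidWindowError(ValueError):
    """Raised when an image window touches samples without a valid decomposition."""


@dataclass
class AccelImage:
    """One binary acceleration image and its provenance."""

    pixels: np.ndarray          # (image_size, image_size) uint8 in {0, 1}
    center_index: int
    t_center: float
    participant_id: str
    sensor_site: str

    def set_bins(self) -> list[tuple[int, int]]:
        """1-based ``(index_h, index_v)`` pairs of the set pixels."""
        rows, cols = np.nonzero(self.pixels)
        return [(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)]


@dataclass
class ImageStack:
    """An ordered batch of acceleration images from one recording session."""

    pixels: np.ndarray          # (k, image_size, image_size) uint8
    center_index: np.ndarray    # (k,)
    t_center: np.ndarray        # (k,)
    participant_id: str
    sensor_site: str
    label: str | None = None    # group label inherited by every image
    counts: bool = False        # True when pixels hold per-bin sample counts

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def __getitem__(self, k: int) -> AccelImage:
        return AccelImage(
            pixels=self.pixels[k],
            center_index=int(self.center_index[k]),
            t_center=float(self.t_center[k]),
            participant_id=self.participant_id,
            sensor_site=self.sensor_site,
        )


def bin_index(ratio, config: ProcessingConfig | None = None):
    """Map a nonnegative movement/gravity ratio to a 1-based image bin.

    ``floor(1 + bins_per_g * min(saturation_ratio, ratio))`` — bins 1..27 tile
    ratios in [0, 3) at the defaults and bin 28 is reached exactly at
    saturation (ratio ≥ 3).  Accepts scalars or arrays.
    """
    config = config or ProcessingConfig()
    r = np.asarray(ratio, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("ratio must be nonnegative (magnitudes cannot be negative)")
    idx = np.floor(1.0 + config.bins_per_g * np.minimum(config.saturation_ratio, r))
    idx = idx.astype(np.int64)
    if np.ndim(ratio) == 0:
        return int(idx)
    return idx


def _window_ratios(dec: DecomposedSeries, window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = dec.g_mag[window]
    return dec.av_mag[window] / g, dec.ah_mag[window] / g


def make_image(
    dec: DecomposedSeries, center: int, config: ProcessingConfig | None = None
) -> AccelImage:
    """Encode the window centered at ``center`` into one acceleration image.

    Raises :class:`InvalidWindowError` if any window sample lacks a valid
    gravity estimate (callers emitting streams skip such windows instead).
    """
    config = config or ProcessingConfig()
    n_half = config.half_window
    if center - n_half < 0 or center + n_half >= len(dec):
        raise InvalidWindowError(f"window at {center} exceeds series bounds")
    window = np.arange(center - n_half, center + n_half + 1)
    if not np.all(dec.valid[window]):
        raise InvalidWindowError(f"window at {center} touches invalid samples")
    rv, rh = _window_ratios(dec, window)
    img = np.zeros((config.image_size, config.image_size), dtype=np.uint8)
    img[bin_index(rh, config) - 1, bin_index(rv, config) - 1] = 1
    return AccelImage(
        pixels=img,
        center_index=center,
        t_center=float(dec.t[center]),
        participant_id=dec.participant_id,
        sensor_site=dec.sensor_site,
    )


def valid_window_centers(
    valid: np.ndarray, config: ProcessingConfig, start: int = 0, stop: int | None = None
) -> np.ndarray:
    """Window centers with full sample support, advancing by ``hop_samples``.

    The first candidate center within ``[start, stop)`` is the earliest index
    whose whole window is in range; centers whose window touches an invalid
    sample are dropped (the hop grid is not re-anchored after a drop).
    """
    stop = len(valid) if stop is None else stop
    n_half = config.half_window
    first = start + n_half
    last = stop - 1 - n_half
    if last < first:
        return np.empty(0, dtype=np.int64)
    centers = np.arange(first, last + 1, config.hop_samples, dtype=np.int64)
    window = centers[:, None] + np.arange(-n_half, n_half + 1)
    ok = np.all(valid[window], axis=1)
    return centers[ok]


def session_to_images(
    series: AccelSeries,
    config: ProcessingConfig | None = None,
    interval: tuple[float, float] | None = None,
    *,
    label: str | None = None,
    counts: bool = False,
) -> ImageStack:
    """Encode a whole recording into its stack of acceleration images.

    Gap-separated segments are decomposed and windowed independently, so no
    window straddles a gap.  ``interval`` restricts output to windows whose
    center timestamp falls inside ``[t0, t1]`` (e.g. school hours in
    session-relative seconds).  With ``counts=True`` pixels accumulate the
    number of window samples per bin instead of the binary occupancy map.
    """
    config = config or ProcessingConfig()
    dec = decompose_series(series, config)
    n_half = config.half_window

    all_centers: list[np.ndarray] = []
    for seg in series.segments(config):
        centers = valid_window_centers(dec.valid, config, seg.start, seg.stop)
        if len(centers):
            all_centers.append(centers)
    centers = np.concatenate(all_centers) if all_centers else np.empty(0, np.int64)
    if interval is not None:
        t0, t1 = interval
        tc = series.t[centers]
        centers = centers[(tc >= t0) & (tc <= t1)]

    size = config.image_size
    if len(centers) == 0:
        warnings.warn(
            f"no valid image window in session {series.participant_id}/{series.sensor_site}",
            stacklevel=2,
        )
        return ImageStack(
            pixels=np.zeros((0, size, size), dtype=np.uint8),
            center_index=np.empty(0, np.int64),
            t_center=np.empty(0, np.float64),
            participant_id=series.participant_id,
            sensor_site=series.sensor_site,
            label=label,
            counts=counts,
        )

    offsets = np.arange(-n_half, n_half + 1)
    windows = centers[:, None] + offsets                    # (k, N+1)
    g = dec.g_mag[windows]
    bv = bin_index(dec.av_mag[windows] / g, config) - 1     # 0-based columns
    bh = bin_index(dec.ah_mag[windows] / g, config) - 1     # 0-based rows
    k = len(centers)
    flat = (np.repeat(np.arange(k), windows.shape[1]) * size * size
            + bh.ravel() * size + bv.ravel())
    if counts:
        pix = np.bincount(flat, minlength=k * size * size).astype(np.uint8)
    else:
        pix = np.zeros(k * size * size, dtype=np.uint8)
        pix[flat] = 1
    return ImageStack(
        pixels=pix.reshape(k, size, size),
        center_index=centers,
        t_center=series.t[centers].astype(np.float64),
        participant_id=series.participant_id,
        sensor_site=series.sensor_site,
        label=label,
        counts=counts,
    )
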