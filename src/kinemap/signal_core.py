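"""Gravity estimation and geo-referenced decomposition of tri-axial acceleration.

The raw signal from a body-worn tri-axial accelerometer mixes the quasi-static
gravity component (which encodes sensor orientation) with the acceleration
caused by limb movement.  This module separates the two and projects the
movement-related acceleration onto a geo-referenced frame:

1. gravity is estimated per sample with a centered moving-average low-pass
   filter over ``N + 1`` samples (5.1 s at 10 Hz with the default ``N = 50``);
2. movement acceleration is the raw signal minus the gravity estimate;
3. movement acceleration is split into a *vertical* component (the orthogonal
   projection onto the gravity estimate) and a *horizontal* residual.

Because the decomposition only uses the gravity direction recovered from the
data itself, the resulting vertical/horizontal magnitudes are invariant to how
the sensor was strapped on: rigidly rotating the raw series leaves them
unchanged.

All internal math is in units of g (standard gravity); readers convert m/s²
input at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STANDARD_GRAVITY",
    "AccelSeries",
    "ProcessingConfig",
    "DecomposedSeries",
    "estimate_gravity",
    "movement_acceleration",
    "decompose",
    "decompose_series",
]

#: Standard acceleration of free fall, m/s² per g.
STANDARD_GRAVITY = 9.80665

_SENSOR_SITES = ("wrist", "ankle")


@dataclass
class ProcessingConfig:
    """Parameters of the gravity filter and the acceleration-image encoder.

    Attributes
    ----------
    window_samples:
        ``N``, the moving-average span minus one; the filter averages
        ``N + 1`` centered samples.  Must be even and positive.
    sample_rate_hz:
        Nominal sampling rate of the input series.
    image_size:
        Side length of the square acceleration image.
    bins_per_g:
        Slope of the intensity-to-bin mapping: one bin covers ``1/bins_per_g``
        of a g of movement acceleration (relative to local gravity).
    saturation_ratio:
        Movement/gravity ratios above this value are clamped into the top
        (saturation) bin.
    hop_samples:
        Sliding-window advance between consecutive images (``N/2`` = 2.5 s at
        the defaults).
    min_gravity_g:
        Gravity-estimate magnitudes below this threshold (free fall or corrupt
        data) mark the sample invalid instead of risking division by ~0.
    gap_factor:
        A timestamp jump larger than ``gap_factor`` sample periods splits the
        series into independently processed segments (sensor removed).
    """

    window_samples: int = 50
    sample_rate_hz: float = 10.0
    image_size: int = 28
    bins_per_g: float = 9.0
    saturation_ratio: float = 3.0
    hop_samples: int = 25
    min_gravity_g: float = 0.1
    gap_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.window_samples <= 0 or self.window_samples % 2:
            raise ValueError(
                f"window_samples must be a positive even integer, got {self.window_samples}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.hop_samples < 1:
            raise ValueError("hop_samples must be >= 1")
        max_bin = int(np.floor(1 + self.bins_per_g * self.saturation_ratio))
        if self.image_size < max_bin:
            raise ValueError(
                f"image_size={self.image_size} cannot hold the saturation bin {max_bin}"
            )

    @property
    def half_window(self) -> int:
        """Half-width ``N/2`` of the gravity filter / image window."""
        return self.window_samples // 2


@dataclass
class AccelSeries:
    """A timestamped tri-axial acceleration recording from one sensor.

    ``t`` holds session-relative timestamps in seconds (strictly increasing)
    and ``a`` the (n, 3) array of samples in g units.
    """

    participant_id: str
    sensor_site: str
    sample_rate_hz: float
    t: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.sensor_site not in _SENSOR_SITES:
            raise ValueError(f"sensor_site must be one of {_SENSOR_SITES}")
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError(f"a must be (n, 3), got {self.a.shape}")
        if self.t.shape != (self.a.shape[0],):
            raise ValueError("t and a lengths differ")
        if len(self.t) < 1:
            raise ValueError("series must contain at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.a))):
            raise ValueError("non-finite values in series")

    def __len__(self) -> int:
        return len(self.t)

    def segments(self, config: ProcessingConfig) -> list[slice]:
        """Contiguous index ranges separated by timestamp gaps.

        A jump exceeding ``gap_factor`` sample periods indicates the sensor
        was removed or the recording paused; each side is processed on its own
        so the gravity filter never averages across the gap.
        """
        period = 1.0 / self.sample_rate_hz
        breaks = np.flatnonzero(np.diff(self.t) > config.gap_factor * period) + 1
        edges = [0, *breaks.tolist(), len(self.t)]
        return [slice(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]


@dataclass
class DecomposedSeries:
    """Per-sample gravity estimate and vertical/horizontal movement magnitudes.

    Samples outside ``valid`` (filter edges, free-fall-like gravity norms) are
    NaN-filled and must not be consumed downstream.
    """

    participant_id: str
    sensor_site: str
    sample_rate_hz: float
    t: np.ndarray
    g_est: np.ndarray          # (n, 3) gravity estimate, g units
    a_m: np.ndarray            # (n, 3) movement acceleration
    av_mag: np.ndarray         # (n,) |vertical component|
    ah_mag: np.ndarray         # (n,) |horizontal component|
    g_mag: np.ndarray          # (n,) |gravity estimate|
    valid: np.ndarray          # (n,) bool
    av_vec: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    ah_vec: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.t)


class InsufficientDataError(ValueError):
    """Raised when a segment is too short for the centered gravity filter."""


class DegenerateGravityError(ValueError):
    """Raised when the gravity estimate has (near-)zero norm."""


def estimate_gravity(
    a: np.ndarray, config: ProcessingConfig | None = None
) -> tuple[np.ndarray, tuple[int, int]]:
    """Centered moving-average gravity estimate of a contiguous segment.

    For each index ``i`` with full support, the estimate is the component-wise
    mean of samples ``i - N/2 .. i + N/2`` (``N + 1`` samples).  The first and
    last ``N/2`` indices have no full window and are NaN.

    Parameters
    ----------
    a:
        (n, 3) acceleration samples in g units, gap-free.
    config:
        Processing parameters; defaults used when omitted.

    Returns
    -------
    g_est:
        (n, 3) array, NaN outside the valid range.
    valid_range:
        Half-open index interval ``(start, stop)`` where the estimate exists.
    """
    config = config or ProcessingConfig()
    a = np.asarray(a, dtype=np.float64)
    n_half = config.half_window
    span = config.window_samples + 1
    if a.shape[0] < span:
        raise InsufficientDataError(
            f"need at least {span} samples for the centered filter, got {a.shape[0]}"
        )
    # Exact windowed mean via prefix sums; span is small so cancellation is negligible.
    csum = np.cumsum(a, axis=0, dtype=np.float64)
    csum = np.vstack([np.zeros((1, 3)), csum])
    means = (csum[span:] - csum[:-span]) / span
    g_est = np.full_like(a, np.nan)
    g_est[n_half : a.shape[0] - n_half] = means
    return g_est, (n_half, a.shape[0] - n_half)


def movement_acceleration(a: np.ndarray, g_est: np.ndarray) -> np.ndarray:
    """Movement-related acceleration: raw samples minus the gravity estimate."""
    a = np.asarray(a, dtype=np.float64)
    g_est = np.asarray(g_est, dtype=np.float64)
    if a.shape != g_est.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {g_est.shape}")
    return a - g_est


def decompose(
    a_m: np.ndarray, g_est: np.ndarray, *, return_vectors: bool = False
):
    """Split movement acceleration into vertical and horizontal components.

    The vertical component is the orthogonal projection of ``a_m`` onto the
    gravity estimate, ``a_v = (a_m · g / |g|²) g``; the horizontal component
    is the residual ``a_h = a_m − a_v``.  Works on single vectors or (n, 3)
    arrays.

    Returns ``(av_mag, ah_mag)`` or, with ``return_vectors``,
    ``(av_vec, ah_vec, av_mag, ah_mag)``.
    """
    a_m = np.atleast_2d(np.asarray(a_m, dtype=np.float64))
    g_est = np.atleast_2d(np.asarray(g_est, dtype=np.float64))
    g_sq = np.einsum("ij,ij->i", g_est, g_est)
    if np.any(g_sq <= 0):
        raise DegenerateGravityError("zero-norm gravity estimate (free fall or bad data)")
    coef = np.einsum("ij,ij->i", a_m, g_est) / g_sq
    av = coef[:, None] * g_est
    ah = a_m - av
    av_mag = np.linalg.norm(av, axis=1)
    ah_mag = np.linalg.norm(ah, axis=1)
    if return_vectors:
        return av, ah, av_mag, ah_mag
    return av_mag, ah_mag


def decompose_series(
    series: AccelSeries, config: ProcessingConfig | None = None
) -> DecomposedSeries:
    """Run the full gravity/vertical/horizontal decomposition on one recording.

    Gap-separated segments are processed independently.  A sample is valid
    when its gravity filter window lies inside one segment and the gravity
    norm is at least ``min_gravity_g``.
    """
    config = config or ProcessingConfig()
    n = len(series)
    g_est = np.full((n, 3), np.nan)
    a_m = np.full((n, 3), np.nan)
    av_vec = np.full((n, 3), np.nan)
    ah_vec = np.full((n, 3), np.nan)
    av_mag = np.full(n, np.nan)
    ah_mag = np.full(n, np.nan)
    g_mag = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    span = config.window_samples + 1
    for seg in series.segments(config):
        a_seg = series.a[seg]
        if a_seg.shape[0] < span:
            continue  # segment too short for the filter; all samples invalid
        g_seg, (lo, hi) = estimate_gravity(a_seg, config)
        sl = slice(seg.start + lo, seg.start + hi)
        g = g_seg[lo:hi]
        g_norm = np.linalg.norm(g, axis=1)
        ok = g_norm >= config.min_gravity_g
        m = movement_acceleration(a_seg[lo:hi], g)
        g_est[sl] = g
        a_m[sl] = m
        g_mag[sl] = g_norm
        if np.any(ok):
            av, ah, avm, ahm = decompose(m[ok], g[ok], return_vectors=True)
            idx = np.arange(sl.start, sl.stop)[ok]
            av_vec[idx] = av
            ah_vec[idx] = ah
            av_mag[idx] = avm
            ah_mag[idx] = ahm
        valid[sl] = ok

    return DecomposedSeries(
        participant_id=series.participant_id,
        sensor_site=series.sensor_site,
        sample_rate_hz=series.sample_rate_hz,
        t=series.t,
        g_est=g_est,
        a_m=a_m,
        av_mag=av_mag,
        ah_mag=ah_mag,
        g_mag=g_mag,
        valid=valid,
        av_vec=av_vec,
        ah_vec=ah_vec,
    )
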