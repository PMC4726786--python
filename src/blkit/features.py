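"""Multi-timescale high-gamma band-power features for ECoG/EEG groups.

Each signal is cut into non-overlapping windows from t=0 at several durations
(500 ms, 1 s, 1.5 s and 5 s by default; each duration forms its own window
set). Per window and channel, spectral power is estimated with a plain FFT —
rectangular window, no detrend, unnormalized coefficients — and the
magnitude-squared coefficients over the high-gamma band (bin centers in
[60, 100] Hz, edges inclusive) are summed. Band powers are then z-scored per
channel across all windows of one duration, so every window is described by
exactly n numbers where n is the channel count, regardless of sampling rate
or window length. That compression is the point: one second of 64-channel
data at 10 kHz becomes a single length-64 vector at the 1 s timescale.

The z-score uses the population standard deviation (ddof=0) by default. A
channel whose band power never varies across windows has no z-score; its
column is set to zero and flagged in ``FeatureMatrix.constant_channels`` so
downstream correlations stay defined.

Parseval note: with this normalization, summing magnitude-squared rfft
coefficients over all bins — counting the symmetric negative-frequency half
of each interior bin twice — equals ``N * sum(x**2)`` for an N-sample window.
The constant is irrelevant after z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .format import BrainLinerFile, DataGroup

__all__ = [
    "ChannelTimeSeries",
    "SpectralConfig",
    "WindowGrid",
    "FeatureMatrix",
    "segment",
    "band_power",
    "extract_features",
    "save_features",
    "load_features",
    "FEATURIZABLE_TYPES",
]

#: group ``type`` values the feature extractor accepts: intracranial grids and
#: scalp recordings; every other type is an annotation source, not a signal.
FEATURIZABLE_TYPES = ("ECoG", "EEG")

DEFAULT_DURATIONS = (0.5, 1.0, 1.5, 5.0)
DEFAULT_BAND = (60.0, 100.0)


@dataclass
class ChannelTimeSeries:
    """A ``samples x channels`` recording with its sampling rate."""

    values: np.ndarray
    sampling_rate: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a samples x channels matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one channel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @classmethod
    def from_group(cls, group: DataGroup) -> "ChannelTimeSeries":
        """Build a series from an ECoG/EEG data group of a format file."""
        if group.props.type not in FEATURIZABLE_TYPES:
            raise ValueError(
                f"group {group.name!r} has type {group.props.type!r}; only "
                f"{'/'.join(FEATURIZABLE_TYPES)} groups are featurized"
            )
        if group.data is None:
            raise ValueError(f"group {group.name!r} has no data matrix")
        if not group.props.sampling_rate:
            raise ValueError(f"group {group.name!r} has no samplingRate")
        return cls(
            values=group.data,
            sampling_rate=group.props.sampling_rate,
            channel_names=group.props.channel_names,
        )


@dataclass(frozen=True)
class SpectralConfig:
    """Feature-extraction parameters.

    ``band`` is the summed frequency range in Hz (high gamma, 60-100 Hz by
    default); ``durations`` the window lengths in seconds, ascending and
    unique; ``zscore`` the standard-deviation denominator convention.
    """

    band: tuple[float, float] = DEFAULT_BAND
    durations: tuple[float, ...] = DEFAULT_DURATIONS
    zscore: str = "population"  # or "sample"

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"need 0 < low < high, got band {self.band}")
        d = self.durations
        if not d or any(x <= 0 for x in d) or list(d) != sorted(set(d)):
            raise ValueError("durations must be positive, ascending and unique")
        if self.zscore not in ("population", "sample"):
            raise ValueError("zscore must be 'population' or 'sample'")

    @property
    def ddof(self) -> int:
        return 0 if self.zscore == "population" else 1


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping windows of one duration covering a recording from t=0."""

    duration: float
    starts: np.ndarray  # window start times, seconds
    samples_per_window: int

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def window_of(self, t: float) -> int:
        """Index of the half-open window [k*d, (k+1)*d) containing time *t*."""
        return int(np.floor(t / self.duration + 1e-9))


@dataclass
class FeatureMatrix:
    """z-scored band powers, one row per window, one column per channel."""

    duration: float
    features: np.ndarray  # windows x channels
    grid: WindowGrid
    constant_channels: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]


def segment(series: ChannelTimeSeries, duration: float) -> WindowGrid:
    """Lay a maximal grid of contiguous *duration*-second windows from t=0.

    The trailing partial window is discarded; a duration longer than the
    whole recording yields an empty grid with a warning, not an error.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    spw = int(round(duration * series.sampling_rate))
    n = series.n_samples // spw
    if n == 0:
        warnings.warn(
            f"window duration {duration} s exceeds recording length "
            f"{series.duration:.3f} s; empty grid"
        )
    starts = np.arange(n) * (spw / series.sampling_rate)
    return WindowGrid(duration=duration, starts=starts, samples_per_window=spw)


def band_power(
    window: np.ndarray, sampling_rate: float, low: float, high: float
) -> np.ndarray:
    """Summed magnitude-squared FFT coefficients over [low, high] Hz, per channel.

    *window* is ``samples x channels``. Bin centers are ``k * fs / N``; both
    band edges are inclusive. Raises if the band lies entirely above Nyquist.
    """
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    n = window.shape[0]
    if n < 2:
        raise ValueError("window must have at least 2 samples")
    if not low < high:
        raise ValueError("need low < high")
    if low > sampling_rate / 2:
        raise ValueError(
            f"band [{low}, {high}] Hz lies above Nyquist ({sampling_rate / 2} Hz)"
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    mask = (freqs >= low) & (freqs <= high)
    coeffs = np.fft.rfft(window, axis=0)
    return np.sum(np.abs(coeffs[mask]) ** 2, axis=0)


def extract_features(
    series: ChannelTimeSeries, config: SpectralConfig | None = None
) -> dict[float, FeatureMatrix]:
    """Band-power feature matrices for every configured window duration.

    For each duration: segment, band-power per window, then z-score each
    channel across that duration's windows. Durations yielding fewer than two
    windows (z-scoring undefined) are skipped with a warning; if none
    survive, the result is empty.
    """
    if config is None:
        config = SpectralConfig()
    low, high = config.band
    if high >= series.sampling_rate / 2:
        raise ValueError(
            f"band upper edge {high} Hz must lie below Nyquist "
            f"({series.sampling_rate / 2} Hz)"
        )
    out: dict[float, FeatureMatrix] = {}
    for duration in config.durations:
        grid = segment(series, duration)
        if grid.n_windows < 2:
            warnings.warn(
                f"duration {duration} s yields {grid.n_windows} window(s); "
                "skipping (need >= 2 for z-scoring)"
            )
            continue
        spw = grid.samples_per_window
        w = grid.n_windows
        stacked = series.values[: w * spw].reshape(w, spw, series.n_channels)
        freqs = np.fft.rfftfreq(spw, d=1.0 / series.sampling_rate)
        mask = (freqs >= low) & (freqs <= high)
        coeffs = np.fft.rfft(stacked, axis=1)
        powers = np.sum(np.abs(coeffs[:, mask, :]) ** 2, axis=1)  # w x channels

        mean = powers.mean(axis=0)
        sd = powers.std(axis=0, ddof=config.ddof)
        constant = sd == 0
        sd_safe = np.where(constant, 1.0, sd)
        z = (powers - mean) / sd_safe
        z[:, constant] = 0.0
        out[duration] = FeatureMatrix(
            duration=duration, features=z, grid=grid, constant_channels=constant
        )
    if not out:
        warnings.warn("no duration produced >= 2 windows; empty feature set")
    return out


def extract_features_from_file(
    file: BrainLinerFile, group_name: str, config: SpectralConfig | None = None
) -> dict[float, FeatureMatrix]:
    """Convenience: featurize the named ECoG/EEG group of a format file."""
    return extract_features(ChannelTimeSeries.from_group(file.group(group_name)), config)


# ---------------------------------------------------------------------------
# sidecar cache (HDF5): one subgroup per duration with the matrix and its grid


def save_features(features: dict[float, FeatureMatrix], path) -> None:
    with h5py.File(path, "w") as h5:
        for duration, fm in features.items():
            g = h5.create_group(f"duration={duration:g}")
            g.attrs["duration"] = duration
            g.attrs["samples_per_window"] = fm.grid.samples_per_window
            g.create_dataset("features", data=fm.features)
            g.create_dataset("window_starts", data=fm.grid.starts)
            g.create_dataset("constant_channels", data=fm.constant_channels)


def load_features(path) -> dict[float, FeatureMatrix]:
    out: dict[float, FeatureMatrix] = {}
    with h5py.File(path, "r") as h5:
        for name in h5:
            g = h5[name]
            duration = float(g.attrs["duration"])
            grid = WindowGrid(
                duration=duration,
                starts=g["window_starts"][()],
                samples_per_window=int(g.attrs["samples_per_window"]),
            )
            out[duration] = FeatureMatrix(
                duration=duration,
                features=g["features"][()],
                grid=grid,
                constant_channels=g["constant_channels"][()].astype(bool),
            )
    return out
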