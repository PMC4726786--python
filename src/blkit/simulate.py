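"""Synthetic block-design ECoG recordings with condition-dependent high gamma.

The generator emulates a block-design sensory stimulation session — e.g. a
rodent viewing a grating while a 32-channel ECoG array records — at desk
scale. The recording is a sequence of equal-length condition blocks. Every
channel carries 1/f-shaped Gaussian background noise (white noise whose
Fourier amplitudes are scaled by 1/sqrt(f), then rescaled to unit standard
deviation and multiplied by the configured noise amplitude). During a block
whose condition has a configured gamma amplitude, each channel of that
condition's channel subset additionally receives a sinusoid with a random
frequency drawn per block and channel from the configured gamma band (center
+/- width, 80 +/- 20 Hz by default, i.e. inside 60-100 Hz) and a random
phase — so the high-gamma feature pattern differs across channels, blocks and
conditions instead of being rank-1.

Condition channel subsets default to overlapping halves of the array (first
half vs. the middle half), which makes retrieval non-trivial: some channels
respond to both conditions.

The output is simultaneously a raw :class:`ChannelTimeSeries`, a
:class:`GroundTruth` (block intervals and per-window condition labels for
retrieval evaluation) and a valid :class:`BrainLinerFile` with one ECoG data
group and one stimulus group whose timespans/labels encode the blocks. The
same seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .features import ChannelTimeSeries, WindowGrid
from .format import BrainLinerFile, DataGroup, FileHeader, GroupProps

__all__ = ["SimConfig", "GroundTruth", "simulate"]

_DEFAULT_SEQUENCE = ("A", "rest", "B", "rest") * 10


def _default_subsets(channels: int) -> dict[str, tuple[int, ...]]:
    half = channels // 2
    quarter = channels // 4
    return {
        "A": tuple(range(0, half)),
        "B": tuple(range(quarter, quarter + half)),
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic session.

    Defaults give a 60 s, 32-channel, 1 kHz session of forty 1.5 s blocks
    cycling A / rest / B / rest, with gamma amplitudes 2.0 (A) and 2.5 (B)
    over unit-amplitude 1/f noise.
    """

    channels: int = 32
    sampling_rate: float = 1000.0
    block_duration: float = 1.5
    condition_sequence: tuple[str, ...] = _DEFAULT_SEQUENCE
    gamma_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"A": 2.0, "B": 2.5}
    )
    condition_channels: Mapping[str, Sequence[int]] | None = None
    gamma_center: float = 80.0
    gamma_width: float = 20.0
    noise_amplitude: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.channels < 3:
            raise ValueError("need at least 3 channels")
        if self.sampling_rate <= 2 * (self.gamma_center + self.gamma_width):
            raise ValueError("sampling_rate must exceed twice the gamma band top")
        if self.block_duration <= 0:
            raise ValueError("block_duration must be positive")
        if not self.condition_sequence:
            raise ValueError("condition_sequence must be non-empty")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        subsets = self.subsets()
        for label, chans in subsets.items():
            if any(c < 0 or c >= self.channels for c in chans):
                raise ValueError(f"condition {label!r} channel subset out of range")

    def subsets(self) -> dict[str, tuple[int, ...]]:
        if self.condition_channels is not None:
            return {k: tuple(v) for k, v in self.condition_channels.items()}
        return {k: _default_subsets(self.channels).get(k, ()) for k in self.gamma_amplitudes}

    @property
    def duration(self) -> float:
        return len(self.condition_sequence) * self.block_duration

    def noise_free(self) -> "SimConfig":
        """The deterministic-separation variant: no background noise, no rest
        blocks (all-zero rest windows would have undefined correlations)."""
        n = len(self.condition_sequence)
        return replace(
            self,
            noise_amplitude=0.0,
            condition_sequence=("A", "B") * max(n // 2, 1),
        )


@dataclass
class GroundTruth:
    """Block intervals with labels, and the label lookup for window grids."""

    blocks: list[tuple[float, float, str]]

    def window_labels(self, grid: WindowGrid) -> list[str]:
        """Condition label per window: the block containing the window midpoint."""
        labels = []
        for start in grid.starts:
            mid = start + grid.duration / 2
            for b0, b1, label in self.blocks:
                if b0 <= mid < b1:
                    labels.append(label)
                    break
            else:
                labels.append(self.blocks[-1][2])
        return labels

    def label_counts(self, grid: WindowGrid) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.window_labels(grid):
            out[lab] = out.get(lab, 0) + 1
        return out


def _pink_noise(rng: np.random.Generator, n_samples: int, channels: int) -> np.ndarray:
    """1/f-shaped unit-variance Gaussian noise, one column per channel."""
    white = rng.standard_normal((n_samples, channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale[:, None], n=n_samples, axis=0)
    sd = shaped.std(axis=0)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate(
    config: SimConfig | None = None,
) -> tuple[ChannelTimeSeries, GroundTruth, BrainLinerFile]:
    """Generate one synthetic session.

    Returns the raw multichannel series, the ground truth (blocks and window
    labels) and a format-valid file model with an ``ecog`` data group and a
    ``stimulus`` timespan group carrying the block labels.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    spb = int(round(config.block_duration * fs))
    n_blocks = len(config.condition_sequence)
    n_samples = n_blocks * spb

    if config.noise_amplitude > 0:
        signal = config.noise_amplitude * _pink_noise(rng, n_samples, config.channels)
    else:
        signal = np.zeros((n_samples, config.channels))
        # keep the random stream identical in structure across noise settings
        _ = rng.standard_normal((n_samples, config.channels))

    subsets = config.subsets()
    t_block = np.arange(spb) / fs
    blocks: list[tuple[float, float, str]] = []
    f_lo = config.gamma_center - config.gamma_width
    f_hi = config.gamma_center + config.gamma_width
    for b, label in enumerate(config.condition_sequence):
        t0 = b * spb / fs
        blocks.append((t0, t0 + spb / fs, label))
        amp = config.gamma_amplitudes.get(label, 0.0)
        chans = subsets.get(label, ())
        if amp == 0.0 or not chans:
            continue
        for ch in chans:
            freq = rng.uniform(f_lo, f_hi)
            phase = rng.uniform(0, 2 * np.pi)
            signal[b * spb : (b + 1) * spb, ch] += amp * np.sin(
                2 * np.pi * freq * (t0 + t_block) + phase
            )

    series = ChannelTimeSeries(
        values=signal,
        sampling_rate=fs,
        channel_names=[f"ch{c + 1:02d}" for c in range(config.channels)],
    )
    truth = GroundTruth(blocks=blocks)

    spans = np.array([[b0, b1] for b0, b1, _ in blocks], dtype=np.float64)
    labels = [label for _, _, label in blocks]
    model = BrainLinerFile(
        header=FileHeader(
            description=(
                "Synthetic block-design ECoG session: condition-dependent "
                "high-gamma modulation over 1/f background noise"
            ),
            attributes={"species": "synthetic", "subjectId": f"sim{config.seed}"},
        ),
        groups=[
            DataGroup(
                name="ecog",
                props=GroupProps(
                    title="Synthetic ECoG array",
                    type="ECoG",
                    sampling_rate=fs,
                    channel_names=series.channel_names,
                ),
                data=signal,
            ),
            DataGroup(
                name="stimulus",
                props=GroupProps(title="Stimulus blocks", type="stimulus"),
                timespans=spans,
                labels=labels,
            ),
        ],
    )
    return series, truth, model
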