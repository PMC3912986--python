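"""Synthetic visual input: counterphase gratings, On/Off rate coding, Poisson spikes.

This module is the data source for the whole package — there is no external
data.  A stimulus is a grayscale sinusoidal grating on an N x N pixel grid
with values in [-1, 1], whose contrast reverses sinusoidally in time
(a counterphase grating).  Signed pixel contrast is split into two
nonnegative rate channels (the On- and Off-center pathways of the LGN),
scaled by a maximum Poisson rate, and converted to spike trains by iterating
exponential interspike intervals  t_{i+1} = t_i - ln(x_i) / r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GratingConfig",
    "make_grating",
    "encode_on_off",
    "poisson_spike_times",
    "poisson_spike_trains",
    "noise_epoch",
    "training_angles",
    "test_angles",
]


@dataclass(frozen=True)
class GratingConfig:
    """Spatial/temporal layout of the grating family.

    spatial_frequency : cycles across the grid (default 2, ~two bars visible)
    spatial_phase     : radians (default 0; phase 0 keeps the theta ~ theta+pi
                        identity exact)
    counterphase_frequency : Hz of the contrast reversal (default 2)
    """

    spatial_frequency: float = 2.0
    spatial_phase: float = 0.0
    counterphase_frequency: float = 2.0


def make_grating(
    orientation: float,
    grid_size: int,
    t_ms: float = 0.0,
    config: GratingConfig = GratingConfig(),
) -> np.ndarray:
    """Pixel grid of a counterphase grating at the given orientation.

    The sinusoid varies along the axis perpendicular to the bar orientation
    and the whole pattern is multiplied by cos(2 pi f_cp t).  Values are
    clipped to [-1, 1].

    Parameters
    ----------
    orientation : bar orientation in radians, positive; the pattern has
        period pi in this argument (theta and theta + pi coincide), with the
        canonical domain (0, pi].
    grid_size : pixels per side (>= 2).
    t_ms : time in milliseconds, for the counterphase modulation.
    """
    if grid_size < 2:
        raise ValueError(f"grid_size must be >= 2, got {grid_size}")
    if not orientation > 0.0:
        raise ValueError(f"orientation must be positive, got {orientation}")
    coords = np.arange(grid_size) - (grid_size - 1) / 2.0
    x, y = np.meshgrid(coords, coords, indexing="xy")
    # Coordinate along the axis perpendicular to the bars; cos makes the
    # pattern even in this coordinate, so theta and theta + pi coincide.
    u = -x * np.sin(orientation) + y * np.cos(orientation)
    k = 2.0 * np.pi * config.spatial_frequency / grid_size
    temporal = np.cos(2.0 * np.pi * config.counterphase_frequency * t_ms / 1000.0)
    return np.clip(np.cos(k * u - config.spatial_phase) * temporal, -1.0, 1.0)


def encode_on_off(pixels: np.ndarray, max_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Split signed contrast into On/Off firing rates (Hz).

    on = max(p, 0) * max_rate and off = max(-p, 0) * max_rate, so exactly one
    of the two channels is nonzero for any nonzero pixel.
    """
    if max_rate <= 0:
        raise ValueError(f"max_rate must be positive, got {max_rate}")
    p = np.asarray(pixels, dtype=float)
    return np.maximum(p, 0.0) * max_rate, np.maximum(-p, 0.0) * max_rate


def _exclusive_uniform(rng: np.random.Generator, size) -> np.ndarray:
    """Uniform draws on the open interval (0, 1): never exactly 0 or 1."""
    x = rng.random(size)
    # rng.random() is in [0, 1); 1 - x is in (0, 1].  Map the single excluded
    # endpoint (x == 0 -> 1.0) to the smallest normal step below 1.
    x = 1.0 - x
    return np.where(x == 1.0, 1.0 - np.finfo(float).eps, x)


def poisson_spike_times(
    rate_hz: float, duration_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike times (ms) of a homogeneous Poisson process on [0, duration).

    Interspike intervals are generated iteratively as -ln(x)/r with x uniform
    on (0, 1), vectorized by drawing batches of intervals and accumulating.
    """
    if rate_hz < 0:
        raise ValueError(f"rate must be nonnegative, got {rate_hz}")
    if rate_hz == 0 or duration_ms <= 0:
        return np.empty(0, dtype=float)
    mean_count = rate_hz * duration_ms / 1000.0
    times: list[np.ndarray] = []
    t = 0.0
    while t < duration_ms:
        n = int(max(16, mean_count + 4.0 * np.sqrt(mean_count) + 16))
        isi_ms = -np.log(_exclusive_uniform(rng, n)) / rate_hz * 1000.0
        batch = t + np.cumsum(isi_ms)
        times.append(batch)
        t = batch[-1]
    all_times = np.concatenate(times)
    return all_times[all_times < duration_ms]


def poisson_spike_trains(
    rates_hz: np.ndarray, duration_ms: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Independent Poisson trains for a vector of rates, on [0, duration).

    Returns (times_ms, neuron_ids), sorted by time.  Uses the same
    exponential-ISI construction as :func:`poisson_spike_times`, drawing the
    interval matrix for all neurons at once.
    """
    rates = np.asarray(rates_hz, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    n = rates.size
    if n == 0 or duration_ms <= 0 or not np.any(rates > 0):
        return np.empty(0, dtype=float), np.empty(0, dtype=np.int64)
    active = np.flatnonzero(rates > 0)
    r = rates[active]
    max_mean = float(np.max(r)) * duration_ms / 1000.0
    k = int(max(8, max_mean + 4.0 * np.sqrt(max_mean) + 8))
    out_t: list[np.ndarray] = []
    out_i: list[np.ndarray] = []
    offset = np.zeros(active.size)
    pending = np.arange(active.size)
    while pending.size:
        isi = -np.log(_exclusive_uniform(rng, (pending.size, k)))
        isi /= r[pending][:, None] / 1000.0
        times = offset[pending][:, None] + np.cumsum(isi, axis=1)
        mask = times < duration_ms
        rows, cols = np.nonzero(mask)
        out_t.append(times[rows, cols])
        out_i.append(active[pending[rows]])
        offset[pending] = times[:, -1]
        pending = pending[mask[:, -1]]  # rows that never crossed the horizon
    times = np.concatenate(out_t)
    ids = np.concatenate(out_i)
    order = np.argsort(times, kind="stable")
    return times[order], ids[order]


def noise_epoch(
    n_neurons: int,
    rng: np.random.Generator,
    rate_hz: float = 1.0,
    duration_ms: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform background Poisson drive between pattern presentations.

    Every input neuron (both On and Off channels) fires at ``rate_hz``
    regardless of any stimulus, for ``duration_ms``.
    """
    if duration_ms <= 0:
        return np.empty(0, dtype=float), np.empty(0, dtype=np.int64)
    rates = np.full(n_neurons, float(rate_hz))
    return poisson_spike_trains(rates, duration_ms, rng)


def training_angles(n: int = 40) -> np.ndarray:
    """The n training orientations k*pi/n, k = 1..n (from pi/n to pi)."""
    return np.arange(1, n + 1) * np.pi / n


def test_angles(n: int = 40) -> np.ndarray:
    """The n test orientations k*pi/n, k = 1..n."""
    return np.arange(1, n + 1) * np.pi / n
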