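"""Training/testing protocol, tuning curves, receptive fields, decoding.

One *trial* of an individual is: decode its genome, build the network,
train with plasticity enabled on a shuffled sequence of counterphase
gratings (interleaved with low-rate Poisson noise epochs), then freeze
plasticity and measure a tuning curve by presenting each test orientation
and recording the output-group firing rates.  The fitness of the trial is
computed from that tuning curve.

The module also implements population-vector decoding of orientation from
many tuned neurons: each neuron contributes a vector of length rate/2 at
its preferred orientation (angles are doubled internally so the period-pi
orientation circle maps onto the full circle, and halved back after the
sum), the vectors are summed and normalized, and the decoded orientation is
compared to the true one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitness import (
    FitnessConfig,
    FitnessReport,
    TuningCurve,
    circular_orientation_distance,
    evaluate_tuning,
    worst_fitness_report,
)
from .network import Network, build_network, decode_genome
from .simulator import SimConfig, Simulator
from .stimulus import (
    GratingConfig,
    encode_on_off,
    make_grating,
    test_angles,
    training_angles,
)

__all__ = [
    "ProtocolConfig",
    "DecodingResult",
    "present_grating",
    "present_noise",
    "train_individual",
    "test_tuning",
    "run_trial",
    "evaluate_individual",
    "population_decode",
    "receptive_field_image",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Durations and sizes of the train/test protocol.

    Defaults are the full-scale conditions: 40 training orientations
    presented 2 s each with 500 ms of 1 Hz noise in between, repeated until
    ~100 simulated minutes (60 passes), then 40 test orientations of 1 s
    each.  ``frame_ms`` is the piecewise-constant-rate frame used to follow
    the counterphase contrast reversal.
    """

    n_train_patterns: int = 40
    pattern_duration_ms: int = 2000
    noise_duration_ms: int = 500
    noise_rate_hz: float = 1.0
    train_repeats: int = 60
    n_test_angles: int = 40
    test_duration_ms: int = 1000
    frame_ms: int = 25
    grating: GratingConfig = GratingConfig()

    @classmethod
    def desk(cls) -> "ProtocolConfig":
        """Reduced preset (~10 simulated minutes of training, 10 patterns)."""
        return cls(n_train_patterns=10, train_repeats=24, n_test_angles=8)

    @classmethod
    def micro(cls) -> "ProtocolConfig":
        """Minimal preset for fast smoke runs and the evolutionary tests:
        ~8 s of training, 8 test angles of 500 ms."""
        return cls(
            n_train_patterns=6,
            pattern_duration_ms=1000,
            noise_duration_ms=250,
            train_repeats=1,
            n_test_angles=8,
            test_duration_ms=500,
        )


def present_grating(
    sim: Simulator,
    orientation: float,
    duration_ms: int,
    rng: np.random.Generator,
    plastic: bool,
    frame_ms: int = 25,
    grating: GratingConfig = GratingConfig(),
    record_raster: bool = False,
) -> np.ndarray:
    """Present one counterphase grating; returns Exc spike counts.

    The time-varying contrast is followed by piecewise-constant Poisson
    rates over frames of ``frame_ms``, each frame encoded at its midpoint.
    """
    grid = sim.net.grid_size
    max_rate = sim.net.params["max_poisson_rate"]
    exc_counts = np.zeros(4)
    t = 0
    while t < duration_ms:
        frame = min(frame_ms, duration_ms - t)
        pixels = make_grating(orientation, grid, t_ms=t + frame / 2.0, config=grating)
        on, off = encode_on_off(pixels, max_rate)
        rates = np.concatenate([on.ravel(), off.ravel()])
        res = sim.run_segment(rates, frame, rng, plastic=plastic, record_raster=record_raster)
        exc_counts += res.exc_counts
        t += frame
    return exc_counts


def present_noise(
    sim: Simulator,
    duration_ms: int,
    rng: np.random.Generator,
    plastic: bool,
    rate_hz: float = 1.0,
) -> None:
    """Uniform low-rate Poisson drive between pattern presentations."""
    if duration_ms <= 0:
        return
    rates = np.full(sim.net.n_buffer, rate_hz)
    sim.run_segment(rates, duration_ms, rng, plastic=plastic)


def train_individual(
    sim: Simulator, protocol: ProtocolConfig, rng: np.random.Generator
) -> None:
    """Run the plastic training phase on the bound network, in place.

    Each pass presents all training orientations in a freshly shuffled
    order, with a noise epoch after every presentation.
    """
    angles = training_angles(protocol.n_train_patterns)
    for _ in range(protocol.train_repeats):
        for angle in angles[rng.permutation(angles.size)]:
            present_grating(
                sim,
                angle,
                protocol.pattern_duration_ms,
                rng,
                plastic=True,
                frame_ms=protocol.frame_ms,
                grating=protocol.grating,
            )
            present_noise(
                sim,
                protocol.noise_duration_ms,
                rng,
                plastic=True,
                rate_hz=protocol.noise_rate_hz,
            )


def test_tuning(
    sim: Simulator,
    angles: np.ndarray,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
) -> TuningCurve:
    """Measure the Exc tuning curve with plasticity frozen.

    Weights are bit-identical before and after: the testing phase runs the
    engine with all plasticity disabled.
    """
    angles = np.asarray(angles, dtype=float)
    rates = np.zeros((4, angles.size))
    for j, angle in enumerate(angles):
        counts = present_grating(
            sim,
            angle,
            protocol.test_duration_ms,
            rng,
            plastic=False,
            frame_ms=protocol.frame_ms,
            grating=protocol.grating,
        )
        rates[:, j] = counts / (protocol.test_duration_ms / 1000.0)
    return TuningCurve(rates=rates, angles=angles)


def run_trial(
    genome: np.ndarray,
    grid_size: int,
    protocol: ProtocolConfig,
    seed: int,
    sim_config: SimConfig = SimConfig(),
    plastic: bool = True,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> tuple[Network, TuningCurve]:
    """One full decode -> build -> train -> test cycle.

    Returns the trained network and the testing-phase tuning curve.  With
    ``plastic=False`` the training phase is skipped entirely and the curve
    reflects the random initial weights.
    """
    params = decode_genome(genome, ranges)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    net = build_network(grid_size, params, rng)
    sim = Simulator(net, sim_config)
    if plastic:
        train_individual(sim, protocol, rng)
    curve = test_tuning(sim, test_angles(protocol.n_test_angles), protocol, rng)
    return net, curve


def evaluate_individual(
    genome: np.ndarray,
    grid_size: int,
    protocol: ProtocolConfig,
    seed: int,
    sim_config: SimConfig = SimConfig(),
    fitness_config: FitnessConfig = FitnessConfig(),
    ranges: dict[str, tuple[float, float]] | None = None,
) -> FitnessReport:
    """Fitness of one genome: a pure function of (genome, seed).

    Any numerical failure during the trial (diverging membrane state or
    weight update) yields the worst constraint-violating fitness instead of
    propagating.
    """
    try:
        _, curve = run_trial(genome, grid_size, protocol, seed, sim_config, ranges=ranges)
        return evaluate_tuning(curve, fitness_config)
    except FloatingPointError:
        return worst_fitness_report(fitness_config)


@dataclass
class DecodingResult:
    """Population-vector decode of one presented orientation."""

    component_angles: np.ndarray  # preferred orientation per neuron (rad)
    component_lengths: np.ndarray  # mean rate / 2 per neuron
    population_vector: np.ndarray  # unit 2-vector in doubled-angle space
    decoded_angle: float  # rad, in (0, pi]
    true_angle: float  # rad
    error_deg: float  # circular orientation error, degrees


def population_decode(
    preferred_angles: np.ndarray,
    rates_hz: np.ndarray,
    true_angle: float,
) -> DecodingResult:
    """Decode a stimulus orientation from many neurons' responses.

    Each neuron contributes a component vector of length (rate / 2) at its
    preferred orientation.  Orientation has period pi, so angles are doubled
    before the vector sum and the resultant angle halved, keeping opposite
    directions from cancelling.  The summed vector is normalized to unit
    length; the decode error is the circular orientation distance to the
    true angle, in degrees.
    """
    theta = np.asarray(preferred_angles, dtype=float)
    rates = np.asarray(rates_hz, dtype=float)
    if theta.shape != rates.shape:
        raise ValueError("preferred angles and rates must have the same shape")
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    if not np.any(rates > 0):
        raise ValueError("undecodable: all rates are zero")
    lengths = rates / 2.0
    vx = float(np.sum(lengths * np.cos(2.0 * theta)))
    vy = float(np.sum(lengths * np.sin(2.0 * theta)))
    norm = float(np.hypot(vx, vy))
    if norm == 0.0:
        raise ValueError("undecodable: population vector cancelled exactly")
    decoded = 0.5 * float(np.arctan2(vy, vx))  # in (-pi/2, pi/2]
    if decoded <= 0.0:
        decoded += np.pi  # into (0, pi]
    error = float(
        np.degrees(circular_orientation_distance(decoded, float(true_angle)))
    )
    return DecodingResult(
        component_angles=theta,
        component_lengths=lengths,
        population_vector=np.array([vx, vy]) / norm,
        decoded_angle=decoded,
        true_angle=float(true_angle),
        error_deg=error,
    )


def receptive_field_image(net: Network) -> np.ndarray:
    """Per-output-neuron On/Off weight maps, shape (4, 2, grid, grid).

    Reshapes each Exc neuron's incoming Buffer weights into the pixel grid;
    index 0 of the second axis is the On map, index 1 the Off map.  Strong
    weights correspond to bright regions of the learned receptive field.
    """
    g = net.grid_size
    w = net.buff_exc.w  # (2 g^2, 4)
    maps = np.empty((4, 2, g, g))
    for i in range(4):
        maps[i, 0] = w[: g * g, i].reshape(g, g)
        maps[i, 1] = w[g * g :, i].reshape(g, g)
    return maps
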