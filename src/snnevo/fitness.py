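"""Multi-component fitness for evolved orientation-selective networks.

The objective, to be maximized, is the reciprocal of a sum of three
penalty-style components computed from the testing-phase tuning curves of
the four output (Exc) neurons:

    total = 1 / (decorr + gauss + K * max_rate  [+ 240 per violated limit])

* ``decorr``  — sum over neurons of |D_min - pi/4|, where D_min is the
  circular orientation distance (period pi) to the nearest other neuron's
  preferred orientation.  Minimal when the four preferred orientations are
  spread evenly over the half-circle.
* ``gauss``   — sum over neurons and test angles of |R - G| between the
  peak-normalized tuning curve and a peak-normalized circular Gaussian of
  width sigma = 15 degrees centered on the preferred orientation.
* ``max_rate``— sum over neurons of |r_max - 60 Hz|, scaled by K = 4.4.

Each component carries an upper limit (15 / 1300 / 160); a violated limit
adds a flat 240 to the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningCurve",
    "FitnessConfig",
    "FitnessReport",
    "circular_orientation_distance",
    "fitness_decorr",
    "fitness_gauss",
    "fitness_max_rate",
    "total_fitness",
    "evaluate_tuning",
    "worst_fitness_report",
]


def circular_orientation_distance(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Distance between orientations on the period-pi circle, in [0, pi/2]."""
    d = np.mod(np.abs(np.asarray(theta) - np.asarray(phi)), np.pi)
    return np.minimum(d, np.pi - d)


@dataclass
class TuningCurve:
    """Per-neuron firing rate vs. test orientation.

    rates : (n_neurons, n_angles) array of nonnegative rates in Hz.
    angles : the n_angles test orientations (rad, in (0, pi]).
    """

    rates: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        self.angles = np.asarray(self.angles, dtype=float)
        if self.rates.shape[1] != self.angles.size:
            raise ValueError("rates and angles have mismatched lengths")
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be nonnegative")

    @property
    def theta_max(self) -> np.ndarray:
        """Preferred orientation of each neuron (angle of maximum response)."""
        return self.angles[np.argmax(self.rates, axis=1)]

    @property
    def r_max(self) -> np.ndarray:
        """Peak firing rate of each neuron (Hz)."""
        return np.max(self.rates, axis=1)


@dataclass(frozen=True)
class FitnessConfig:
    """Constants of the objective (values as used in all reported runs)."""

    d_target: float = np.pi / 4
    sigma: float = 15.0 * np.pi / 180.0
    r_max_target: float = 60.0
    k_scaling: float = 4.4
    limit_decorr: float = 15.0
    limit_gauss: float = 1300.0
    limit_max_rate: float = 160.0
    penalty: float = 240.0
    epsilon: float = 1e-9


@dataclass
class FitnessReport:
    """The three components, their constraint flags, and the total."""

    decorr: float
    gauss: float
    max_rate: float
    violated: tuple[bool, bool, bool]
    total: float
    normalized: float | None = None

    @property
    def n_violations(self) -> int:
        return sum(self.violated)


def fitness_decorr(theta_max: np.ndarray, config: FitnessConfig = FitnessConfig()) -> float:
    """Sum over neurons of |D_min - D_target| on the orientation circle."""
    theta = np.asarray(theta_max, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("decorrelation needs at least two neurons")
    d = circular_orientation_distance(theta[:, None], theta[None, :])
    np.fill_diagonal(d, np.inf)
    d_min = d.min(axis=1)
    return float(np.sum(np.abs(d_min - config.d_target)))


def fitness_gauss(curve: TuningCurve, config: FitnessConfig = FitnessConfig()) -> float:
    """Sum of |normalized rate - normalized Gaussian| over neurons and angles.

    Both the tuning curve and the Gaussian template are normalized to peak 1,
    and the Gaussian is evaluated on the circular orientation difference so
    curves wrap at pi.  A neuron with zero peak rate has no defined
    normalized curve; it pushes the component above its limit (an
    unresponsive neuron is unfit).
    """
    r_max = curve.r_max
    theta_max = curve.theta_max
    responsive = r_max > 0
    value = 0.0
    if not np.all(responsive):
        value += config.limit_gauss + 1.0
    if np.any(responsive):
        rates = curve.rates[responsive]
        delta = circular_orientation_distance(
            curve.angles[None, :], theta_max[responsive, None]
        )
        template = np.exp(-0.5 * (delta / config.sigma) ** 2)
        normalized = rates / r_max[responsive, None]
        value += float(np.sum(np.abs(normalized - template)))
    return value


def fitness_max_rate(r_max: np.ndarray, config: FitnessConfig = FitnessConfig()) -> float:
    """Sum over neurons of |r_max - target| with target 60 Hz."""
    r = np.asarray(r_max, dtype=float)
    if np.any(r < 0):
        raise ValueError("peak rates must be nonnegative")
    return float(np.sum(np.abs(r - config.r_max_target)))


def total_fitness(
    decorr: float,
    gauss: float,
    max_rate: float,
    config: FitnessConfig = FitnessConfig(),
) -> FitnessReport:
    """Combine the components into the reciprocal objective with penalties.

    The denominator is decorr + gauss + K * max_rate plus one flat penalty
    of 240 per component exceeding its upper limit; an epsilon guards the
    all-zero case.
    """
    for name, v in (("decorr", decorr), ("gauss", gauss), ("max_rate", max_rate)):
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite fitness component {name}={v}")
    violated = (
        decorr > config.limit_decorr,
        gauss > config.limit_gauss,
        max_rate > config.limit_max_rate,
    )
    denom = decorr + gauss + config.k_scaling * max_rate + config.penalty * sum(violated)
    total = 1.0 / max(denom, config.epsilon)
    return FitnessReport(
        decorr=float(decorr),
        gauss=float(gauss),
        max_rate=float(max_rate),
        violated=violated,
        total=total,
    )


def evaluate_tuning(curve: TuningCurve, config: FitnessConfig = FitnessConfig()) -> FitnessReport:
    """Full fitness evaluation of a testing-phase tuning curve."""
    return total_fitness(
        fitness_decorr(curve.theta_max, config),
        fitness_gauss(curve, config),
        fitness_max_rate(curve.r_max, config),
        config,
    )


def worst_fitness_report(config: FitnessConfig = FitnessConfig()) -> FitnessReport:
    """The report assigned to an individual whose evaluation failed.

    All three limits count as violated and each component sits at its limit,
    giving the smallest total any constraint-violating individual can have.
    """
    denom = (
        config.limit_decorr
        + config.limit_gauss
        + config.k_scaling * config.limit_max_rate
        + 3 * config.penalty
    )
    return FitnessReport(
        decorr=config.limit_decorr,
        gauss=config.limit_gauss,
        max_rate=config.limit_max_rate,
        violated=(True, True, True),
        total=1.0 / denom,
    )
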