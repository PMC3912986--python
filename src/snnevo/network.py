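"""Network construction: genome decoding and the LGN -> V1 architecture.

The model network maps a square pixel grid through paired On/Off Poisson
input groups (one per pixel each), matching On/Off buffer groups of
regular-spiking neurons (one-to-one, fixed excitatory synapses), onto four
regular-spiking output neurons (Exc) with plastic all-to-all E->E synapses.
The Exc group excites four fast-spiking inhibitory neurons (Inh) through
plastic all-to-all E->I synapses, and Inh projects fixed all-to-all
inhibition back onto Exc.  Total neuron count is therefore
4 * grid_size^2 + 8.

Fourteen real-valued genes in [0, 1] decode affinely into the tunable
parameters: the maximum input Poisson rate, three projection weight scales,
the two homeostatic target rates, and the four amplitudes/time constants of
each of the two STDP curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neurons import FS, RS, IzhikevichParams
from .plasticity import (
    HomeostasisState,
    PlasticConnectionState,
    STDPPolarity,
    STDPRule,
)

__all__ = [
    "PARAM_RANGES",
    "GENE_NAMES",
    "N_GENES",
    "N_EXC",
    "N_INH",
    "decode_genome",
    "random_genome",
    "Network",
    "build_network",
    "count_neurons",
]

#: Allowable range of each evolved parameter, in decode order.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "max_poisson_rate": (10.0, 40.0),   # Hz
    "buff_exc_w": (4.0e-3, 1.6e-2),     # Buffer -> Exc weight scale
    "exc_inh_w": (0.1, 1.0),            # Exc -> Inh weight scale
    "inh_exc_w": (0.1, 0.5),            # Inh -> Exc weight scale
    "r_target_exc": (10.0, 30.0),       # Hz
    "r_target_inh": (40.0, 100.0),      # Hz
    "a_plus_exc": (9.6e-6, 4.8e-5),
    "a_minus_exc": (9.6e-6, 4.8e-5),
    "tau_plus_exc": (10.0, 60.0),       # ms
    "tau_minus_exc": (5.0, 100.0),      # ms
    "a_plus_inh": (9.6e-6, 4.8e-5),
    "a_minus_inh": (9.6e-6, 4.8e-5),
    "tau_plus_inh": (10.0, 60.0),       # ms
    "tau_minus_inh": (5.0, 100.0),      # ms
}

GENE_NAMES: tuple[str, ...] = tuple(PARAM_RANGES)
N_GENES = len(GENE_NAMES)

#: Output and inhibitory group sizes (fixed by the architecture).
N_EXC = 4
N_INH = 4

#: Fixed weight of the one-to-one Poisson -> buffer synapses.  Chosen so a
#: buffer neuron's firing rate approximately tracks its Poisson input rate
#: over the decodable 10-40 Hz range (see the rate-transfer test).
POISS_BUFFER_WEIGHT = 0.5


def decode_genome(
    genome: np.ndarray, ranges: dict[str, tuple[float, float]] | None = None
) -> dict[str, float]:
    """Map 14 genes in [0, 1] to parameter values, affinely per range.

    ``ranges`` may override the default bounds per parameter (same keys).
    """
    g = np.asarray(genome, dtype=float)
    if g.shape != (N_GENES,):
        raise ValueError(f"genome must have exactly {N_GENES} genes, got shape {g.shape}")
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("genes must lie in [0, 1]")
    bounds = PARAM_RANGES if ranges is None else {**PARAM_RANGES, **ranges}
    return {
        name: float(bounds[name][0] + gene * (bounds[name][1] - bounds[name][0]))
        for gene, name in zip(g, GENE_NAMES)
    }


def random_genome(rng: np.random.Generator) -> np.ndarray:
    """A uniform random genome in [0, 1]^14."""
    return rng.random(N_GENES)


def count_neurons(grid_size: int | None, n_exc: int = N_EXC, n_inh: int = N_INH) -> int:
    """Total neurons: two Poisson + two buffer groups of grid^2 each, plus Exc/Inh."""
    if grid_size is None or grid_size == 0:
        return 0
    return 4 * grid_size * grid_size + n_exc + n_inh


@dataclass
class Network:
    """A fully built network: group sizes, weights, plasticity attachments.

    Izhikevich groups are the buffers (2 * grid^2 RS neurons, On first),
    Exc (4 RS) and Inh (4 FS).  The Poisson groups are pure spike sources
    handled by the simulator and carry no membrane state.
    """

    grid_size: int
    params: dict[str, float]
    w_poiss_buffer: float
    buff_exc: PlasticConnectionState
    exc_inh: PlasticConnectionState
    w_inh_exc: np.ndarray
    homeo_exc: HomeostasisState
    homeo_inh: HomeostasisState

    @property
    def n_pixels(self) -> int:
        return self.grid_size * self.grid_size

    @property
    def n_buffer(self) -> int:
        return 2 * self.n_pixels

    @property
    def n_neurons(self) -> int:
        return count_neurons(self.grid_size)

    def group_params(self) -> tuple[IzhikevichParams, IzhikevichParams, IzhikevichParams]:
        """Izhikevich presets of (buffer, Exc, Inh)."""
        return RS, RS, FS

    def summary(self) -> str:
        """Plain-text description of groups, projections and parameters."""
        g = self.grid_size
        lines = [
            f"grid_size = {g} ({self.n_neurons} neurons total)",
            f"groups: OnPoiss/OffPoiss {g * g} each (Poisson), "
            f"OnBuffer/OffBuffer {g * g} each (RS), Exc {N_EXC} (RS), Inh {N_INH} (FS)",
            "projections:",
            f"  Poiss -> Buffer   one-to-one fixed excitatory, w = {self.w_poiss_buffer}",
            f"  Buffer -> Exc     all-to-all plastic E->E, w_max = {self.buff_exc.w_max:.6g}",
            f"  Exc -> Inh        all-to-all plastic E->I, w_max = {self.exc_inh.w_max:.6g}",
            f"  Inh -> Exc        all-to-all fixed inhibitory, scale = "
            f"{self.params['inh_exc_w']:.6g}",
            "parameters:",
        ]
        lines += [f"  {k} = {v:.8g}" for k, v in self.params.items()]
        return "\n".join(lines)


def build_network(
    grid_size: int,
    params: dict[str, float],
    rng: np.random.Generator,
    w_poiss_buffer: float = POISS_BUFFER_WEIGHT,
) -> Network:
    """Instantiate the architecture for a grid size and decoded parameters.

    Initial weights of every projection are drawn uniformly in
    [0, scale] where scale is that projection's evolved weight parameter;
    for the plastic projections the same scale also serves as the clipping
    bound w_max.
    """
    if grid_size < 2:
        raise ValueError(f"grid_size must be >= 2, got {grid_size}")
    n_buffer = 2 * grid_size * grid_size

    rule_ee = STDPRule(
        a_plus=params["a_plus_exc"],
        a_minus=params["a_minus_exc"],
        tau_plus=params["tau_plus_exc"],
        tau_minus=params["tau_minus_exc"],
        polarity=STDPPolarity.E_E,
    )
    rule_ei = STDPRule(
        a_plus=params["a_plus_inh"],
        a_minus=params["a_minus_inh"],
        tau_plus=params["tau_plus_inh"],
        tau_minus=params["tau_minus_inh"],
        polarity=STDPPolarity.E_I,
    )

    buff_exc = PlasticConnectionState(
        w=rng.uniform(0.0, params["buff_exc_w"], size=(n_buffer, N_EXC)),
        w_max=params["buff_exc_w"],
        rule=rule_ee,
    )
    exc_inh = PlasticConnectionState(
        w=rng.uniform(0.0, params["exc_inh_w"], size=(N_EXC, N_INH)),
        w_max=params["exc_inh_w"],
        rule=rule_ei,
    )
    w_inh_exc = rng.uniform(0.0, params["inh_exc_w"], size=(N_INH, N_EXC))

    return Network(
        grid_size=grid_size,
        params=dict(params),
        w_poiss_buffer=w_poiss_buffer,
        buff_exc=buff_exc,
        exc_inh=exc_inh,
        w_inh_exc=w_inh_exc,
        homeo_exc=HomeostasisState(r_target=params["r_target_exc"], r_bar=np.zeros(N_EXC)),
        homeo_inh=HomeostasisState(r_target=params["r_target_inh"], r_bar=np.zeros(N_INH)),
    )
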