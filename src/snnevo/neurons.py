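"""Izhikevich point neurons with four-channel conductance-based synapses.

The neuron model is the two-variable quadratic integrate-and-reset system

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)          with reset  v >= 30 mV  ->  v <- c, u <- u + d,

integrated by forward Euler at 0.5 ms, while synaptic conductances decay at
the 1 ms network tick.  Synaptic input is carried by four channels (NMDA,
AMPA, GABA_A, GABA_B) with per-channel reversal potentials and exponential
decay; the NMDA channel carries the usual sigmoidal magnesium-block voltage
dependence.

The functions in this module are scalar reference operations: they define
the semantics one neuron at a time and are the oracle the vectorized engine
in :mod:`snnevo.simulator` is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "IzhikevichParams",
    "RS",
    "FS",
    "NeuronState",
    "ConductanceState",
    "TAU_NMDA",
    "TAU_AMPA",
    "TAU_GABA_A",
    "TAU_GABA_B",
    "E_NMDA",
    "E_AMPA",
    "E_GABA_A",
    "E_GABA_B",
    "SPIKE_CUTOFF",
    "V_FLOOR",
    "synaptic_current",
    "synaptic_drive",
    "decay_conductances",
    "deliver_spike",
    "step_izhikevich",
]

# Conductance decay constants (ms) and reversal potentials (mV).
TAU_NMDA = 100.0
TAU_AMPA = 5.0
TAU_GABA_A = 6.0
TAU_GABA_B = 150.0

E_NMDA = 0.0
E_AMPA = 0.0
E_GABA_A = -70.0
E_GABA_B = -90.0

#: Membrane potential (mV) at which a spike is registered and the state reset.
SPIKE_CUTOFF = 30.0

#: Numerical floor on the membrane potential (mV).  Synaptic input cannot
#: physically drive v below the most negative reversal potential (GABA_B,
#: -90 mV); without the floor, forward Euler can catapult a strongly
#: inhibited neuron through the quadratic term into a divergent oscillation.
V_FLOOR = -90.0


@dataclass(frozen=True)
class IzhikevichParams:
    """The four phenomenological constants of an Izhikevich neuron.

    a : recovery time scale (1/ms), b : recovery sensitivity,
    c : post-spike reset potential (mV), d : post-spike recovery increment.
    """

    a: float
    b: float
    c: float
    d: float


#: Regular-spiking (excitatory) preset.
RS = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: Fast-spiking (inhibitory) preset.
FS = IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=2.0)


@dataclass
class NeuronState:
    """Membrane potential v (mV) and recovery variable u."""

    v: float
    u: float

    @classmethod
    def resting(cls, params: IzhikevichParams) -> "NeuronState":
        """State at the reset potential with u on the b*v nullcline."""
        return cls(v=params.c, u=params.b * params.c)


@dataclass
class ConductanceState:
    """The four synaptic conductances of one neuron (dimensionless weight units)."""

    g_nmda: float = 0.0
    g_ampa: float = 0.0
    g_gaba_a: float = 0.0
    g_gaba_b: float = 0.0


def synaptic_current(cond: ConductanceState, v: float) -> float:
    """Total synaptic current in the printed sign convention.

    Returns ``g_nmda * s(v) * (v - 0) + g_ampa * (v - 0) + g_gaba_a * (v + 70)
    + g_gaba_b * (v + 90)`` with ``s(v) = ((v+80)/60)^2 / (1 + ((v+80)/60)^2)``
    the NMDA voltage factor.  Note this raw sum is *negative* for excitatory
    conductances at subthreshold v; the depolarizing drive actually added to
    the membrane equation is :func:`synaptic_drive`, its negative.
    """
    s = ((v + 80.0) / 60.0) ** 2
    nmda_gate = s / (1.0 + s)
    return (
        cond.g_nmda * nmda_gate * (v - E_NMDA)
        + cond.g_ampa * (v - E_AMPA)
        + cond.g_gaba_a * (v - E_GABA_A)
        + cond.g_gaba_b * (v - E_GABA_B)
    )


def synaptic_drive(cond: ConductanceState, v: float) -> float:
    """Drive term I added to dv/dt: the negative of :func:`synaptic_current`.

    With this convention channels with reversal at 0 mV depolarize a
    subthreshold neuron and the GABA channels hyperpolarize it.
    """
    return -synaptic_current(cond, v)


def decay_conductances(cond: ConductanceState, dt: float) -> ConductanceState:
    """One forward-Euler step of the first-order decay dg/dt = -g/tau.

    The step factor is floored at zero so an oversized dt (dt > tau) empties
    the channel instead of producing an unphysical negative conductance.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return ConductanceState(
        g_nmda=cond.g_nmda * max(1.0 - dt / TAU_NMDA, 0.0),
        g_ampa=cond.g_ampa * max(1.0 - dt / TAU_AMPA, 0.0),
        g_gaba_a=cond.g_gaba_a * max(1.0 - dt / TAU_GABA_A, 0.0),
        g_gaba_b=cond.g_gaba_b * max(1.0 - dt / TAU_GABA_B, 0.0),
    )


def deliver_spike(
    cond: ConductanceState,
    weight: float,
    inhibitory: bool,
    *,
    nmda_split: float = 1.0,
    ampa_split: float = 1.0,
    gaba_a_split: float = 1.0,
    gaba_b_split: float = 1.0,
) -> ConductanceState:
    """Increment conductances for one presynaptic spike of the given weight.

    Excitatory spikes raise g_ampa and g_nmda by ``weight`` times the
    respective split factor (both 1 by default); inhibitory spikes likewise
    raise g_gaba_a and g_gaba_b.
    """
    if weight < 0:
        raise ValueError(f"synaptic weight must be nonnegative, got {weight}")
    if inhibitory:
        return replace(
            cond,
            g_gaba_a=cond.g_gaba_a + weight * gaba_a_split,
            g_gaba_b=cond.g_gaba_b + weight * gaba_b_split,
        )
    return replace(
        cond,
        g_nmda=cond.g_nmda + weight * nmda_split,
        g_ampa=cond.g_ampa + weight * ampa_split,
    )


def step_izhikevich(
    state: NeuronState,
    params: IzhikevichParams,
    drive: float,
    dt: float = 0.5,
) -> tuple[NeuronState, bool]:
    """One Euler substep of the membrane equations, with the reset rule.

    The reset is checked at substep entry: if v >= 30 mV the neuron spikes,
    v <- c and u <- u + d, and no integration happens this substep.
    Otherwise v is advanced first, then u (using the updated v), and the new
    v is confined to [V_FLOOR, 30]: the cap keeps the end-of-step potential
    at or below the cutoff, the floor keeps strongly inhibited neurons from
    being thrown below the lowest synaptic reversal by a single Euler step.
    """
    if not (math.isfinite(state.v) and math.isfinite(state.u)):
        raise FloatingPointError("non-finite neuron state: numerical blow-up")
    if state.v >= SPIKE_CUTOFF:
        return NeuronState(v=params.c, u=state.u + params.d), True
    v = state.v + dt * (0.04 * state.v**2 + 5.0 * state.v + 140.0 - state.u + drive)
    v = min(max(v, V_FLOOR), SPIKE_CUTOFF)
    u = state.u + dt * params.a * (params.b * v - state.u)
    return NeuronState(v=v, u=u), False
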