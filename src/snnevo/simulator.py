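"""Vectorized time-stepped engine for the grating-driven network.

The network advances in 1-ms ticks.  Per tick, in order: spikes emitted at
the previous tick (a uniform 1-ms synaptic delay) are delivered as
conductance increments, conductances decay one Euler step, the synaptic
drive is computed once from the fresh conductances and membrane potentials,
the membrane equations take two 0.5-ms Euler substeps under that drive, and
spikes are recorded.  Plasticity accumulates every tick; weights are
applied (with homeostatic scaling) once per simulated second on global
1000-tick boundaries, which persist across stimulus segments.

All Izhikevich neurons live in flat state arrays ordered
[On buffers | Off buffers | Exc | Inh]; the Poisson input groups are pure
spike sources generated per segment.  The scalar operations in
:mod:`snnevo.neurons` define the per-neuron semantics this engine
replicates; the test suite checks the two paths spike-for-spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network
from .neurons import (
    SPIKE_CUTOFF,
    TAU_AMPA,
    TAU_GABA_A,
    TAU_GABA_B,
    TAU_NMDA,
    V_FLOOR,
)
from .plasticity import apply_weight_update, update_rate_estimate
from .stimulus import poisson_spike_trains

__all__ = ["SimConfig", "SegmentResult", "Simulator"]

_TAUS = np.array([TAU_NMDA, TAU_AMPA, TAU_GABA_A, TAU_GABA_B])


@dataclass(frozen=True)
class SimConfig:
    """Numerical settings of the engine.

    tick_ms : network tick; conductance decay, delivery and plasticity step.
    dt_substep_ms : Euler substep of the membrane equations (two per tick).
    nmda_split / ampa_split : fraction of an excitatory weight added to each
        excitatory channel per spike (both 1 by default).
    gaba_a_split / gaba_b_split : likewise for inhibitory spikes.
    homeostasis_period_ms : interval between weight applications.
    """

    tick_ms: float = 1.0
    dt_substep_ms: float = 0.5
    nmda_split: float = 1.0
    ampa_split: float = 1.0
    gaba_a_split: float = 1.0
    gaba_b_split: float = 1.0
    homeostasis_period_ms: int = 1000


@dataclass
class SegmentResult:
    """Spike totals of one stimulus segment (and optionally the raster)."""

    duration_ms: float
    buffer_counts: np.ndarray
    exc_counts: np.ndarray
    inh_counts: np.ndarray
    raster: tuple[np.ndarray, np.ndarray] | None = None  # (neuron ids, times ms)


class Simulator:
    """Stateful engine bound to one built :class:`~snnevo.network.Network`."""

    def __init__(self, network: Network, config: SimConfig = SimConfig()) -> None:
        self.net = network
        self.config = config
        n_buf = network.n_buffer
        self.n_izh = n_buf + 8
        self.buf = slice(0, n_buf)
        self.exc = slice(n_buf, n_buf + 4)
        self.inh = slice(n_buf + 4, n_buf + 8)

        p_buf, p_exc, p_inh = network.group_params()
        self.a = np.empty(self.n_izh)
        self.b = np.empty(self.n_izh)
        self.c = np.empty(self.n_izh)
        self.d = np.empty(self.n_izh)
        for sl, p in ((self.buf, p_buf), (self.exc, p_exc), (self.inh, p_inh)):
            self.a[sl], self.b[sl], self.c[sl], self.d[sl] = p.a, p.b, p.c, p.d

        self.v = self.c.copy()
        self.u = self.b * self.v
        self.g = np.zeros((4, self.n_izh))  # rows: NMDA, AMPA, GABA_A, GABA_B
        self._decay = 1.0 - config.tick_ms / _TAUS

        self.global_tick = 0
        self._pending = np.zeros((4, self.n_izh))
        self._exc_second_count = np.zeros(4)
        self._inh_second_count = np.zeros(4)

    # -- per-tick pieces ----------------------------------------------------

    def _drive(self) -> np.ndarray:
        """Depolarizing synaptic drive from the conductances, all neurons."""
        v = self.v
        s = ((v + 80.0) / 60.0) ** 2
        gate = s / (1.0 + s)
        g = self.g
        return -(
            g[0] * gate * v + g[1] * v + g[2] * (v + 70.0) + g[3] * (v + 90.0)
        )

    def _substeps(self, drive: np.ndarray) -> np.ndarray:
        """Two Euler substeps under one drive; returns the fired mask."""
        dt = self.config.dt_substep_ms
        fired = np.zeros(self.n_izh, dtype=bool)
        v, u = self.v, self.u
        for _ in range(2):
            spiking = v >= SPIKE_CUTOFF
            fired |= spiking
            v_int = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
            np.clip(v_int, V_FLOOR, SPIKE_CUTOFF, out=v_int)
            v = np.where(spiking, self.c, v_int)
            u = np.where(spiking, u + self.d, u + dt * self.a * (self.b * v - u))
        self.v, self.u = v, u
        return fired

    def _deliver_recurrent(self, buf_spikes, exc_spikes, inh_spikes) -> None:
        """Queue this tick's spikes for delivery at the next tick."""
        cfg = self.config
        net = self.net
        if buf_spikes.size:
            inc = net.buff_exc.w[buf_spikes].sum(axis=0)
            self._pending[0, self.exc] += inc * cfg.nmda_split
            self._pending[1, self.exc] += inc * cfg.ampa_split
        if exc_spikes.size:
            inc = net.exc_inh.w[exc_spikes].sum(axis=0)
            self._pending[0, self.inh] += inc * cfg.nmda_split
            self._pending[1, self.inh] += inc * cfg.ampa_split
        if inh_spikes.size:
            inc = net.w_inh_exc[inh_spikes].sum(axis=0)
            self._pending[2, self.exc] += inc * cfg.gaba_a_split
            self._pending[3, self.exc] += inc * cfg.gaba_b_split

    def _apply_plasticity(self, buf_spikes, exc_spikes, inh_spikes, t_ms: float) -> None:
        if buf_spikes.size or exc_spikes.size:
            self.net.buff_exc.on_spikes(t_ms, buf_spikes, exc_spikes)
        if exc_spikes.size or inh_spikes.size:
            self.net.exc_inh.on_spikes(t_ms, exc_spikes, inh_spikes)

    def _second_boundary(self) -> None:
        """EMA rate update and homeostatically scaled weight application."""
        period_s = self.config.homeostasis_period_ms / 1000.0
        update_rate_estimate(self.net.homeo_exc, self._exc_second_count / period_s)
        update_rate_estimate(self.net.homeo_inh, self._inh_second_count / period_s)
        apply_weight_update(self.net.buff_exc, self.net.homeo_exc)
        apply_weight_update(self.net.exc_inh, self.net.homeo_inh)
        self._exc_second_count[:] = 0.0
        self._inh_second_count[:] = 0.0

    # -- segment driver -----------------------------------------------------

    def run_segment(
        self,
        input_rates_hz: np.ndarray,
        duration_ms: float,
        rng: np.random.Generator,
        plastic: bool = True,
        record_raster: bool = False,
    ) -> SegmentResult:
        """Advance the network under constant Poisson input rates.

        Parameters
        ----------
        input_rates_hz : (2 * grid^2,) per-neuron rates for the On and Off
            Poisson groups (concatenated, On first); each Poisson neuron is
            wired one-to-one to the buffer neuron of the same index.
        duration_ms : integer number of milliseconds to simulate.
        plastic : whether STDP accumulation and homeostatic weight
            application are active (training phase) or frozen (testing).
        record_raster : collect (neuron id, time) pairs for the Izhikevich
            groups, ids in flat [buffers | Exc | Inh] order.
        """
        n_ticks = int(round(duration_ms))
        if abs(duration_ms - n_ticks) > 1e-9 or n_ticks < 0:
            raise ValueError("duration must be a nonnegative whole number of ms")
        cfg = self.config
        w_in = self.net.w_poiss_buffer

        # Input spikes for the whole segment, bucketed by delivery tick
        # (generation time rounded down, plus the 1-ms delay).
        times, ids = poisson_spike_trains(input_rates_hz, n_ticks, rng)
        deliver_tick = times.astype(np.int64) + 1
        order = np.argsort(deliver_tick, kind="stable")
        deliver_tick = deliver_tick[order]
        input_ids = ids[order]
        bounds = np.searchsorted(deliver_tick, np.arange(n_ticks + 1))

        buffer_counts = np.zeros(self.net.n_buffer)
        exc_counts = np.zeros(4)
        inh_counts = np.zeros(4)
        raster_ids: list[np.ndarray] = []
        raster_t: list[np.ndarray] = []

        for local_tick in range(n_ticks):
            # 1. deliver spikes emitted at t - 1 ms
            self.g += self._pending
            self._pending[:] = 0.0
            lo, hi = bounds[local_tick], bounds[local_tick + 1]
            if hi > lo:
                tick_ids = input_ids[lo:hi]
                np.add.at(self.g[0], tick_ids, w_in * cfg.nmda_split)
                np.add.at(self.g[1], tick_ids, w_in * cfg.ampa_split)
            # 2. conductance decay
            self.g *= self._decay[:, None]
            # 3. membrane update, one drive for both substeps
            drive = self._drive()
            fired = self._substeps(drive)
            # 4. queue deliveries and run plasticity on this tick's spikes
            spike_ids = np.flatnonzero(fired)
            n_buf = self.net.n_buffer
            buf_spikes = spike_ids[spike_ids < n_buf]
            mid = spike_ids[spike_ids >= n_buf] - n_buf
            exc_spikes = mid[mid < 4]
            inh_spikes = mid[mid >= 4] - 4
            self._deliver_recurrent(buf_spikes, exc_spikes, inh_spikes)
            t_ms = float(self.global_tick)
            if plastic:
                self._apply_plasticity(buf_spikes, exc_spikes, inh_spikes, t_ms)
            # 5. bookkeeping
            buffer_counts += fired[self.buf]
            exc_fired = fired[self.exc]
            inh_fired = fired[self.inh]
            exc_counts += exc_fired
            inh_counts += inh_fired
            self._exc_second_count += exc_fired
            self._inh_second_count += inh_fired
            if record_raster and spike_ids.size:
                raster_ids.append(spike_ids)
                raster_t.append(np.full(spike_ids.size, t_ms))
            self.global_tick += 1
            if plastic and self.global_tick % cfg.homeostasis_period_ms == 0:
                self._second_boundary()

        if not np.all(np.isfinite(self.v)) or not np.all(np.isfinite(self.u)):
            raise FloatingPointError("membrane state diverged")

        raster = None
        if record_raster:
            if raster_ids:
                raster = (np.concatenate(raster_ids), np.concatenate(raster_t))
            else:
                raster = (np.empty(0, dtype=np.int64), np.empty(0))
        return SegmentResult(
            duration_ms=float(n_ticks),
            buffer_counts=buffer_counts,
            exc_counts=exc_counts,
            inh_counts=inh_counts,
            raster=raster,
        )
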