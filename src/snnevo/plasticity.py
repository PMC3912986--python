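"""Nearest-neighbor STDP and homeostatic synaptic scaling.

Two exponential STDP windows are used, one per plastic projection type:

* E->E ("traditional" curves): potentiation when the presynaptic spike
  precedes the postsynaptic one (dt = t_post - t_pre > 0), depression when
  it follows.
* E->I (reversed curves): depression for pre-before-post pairings and
  potentiation for pre-after-post pairings.

The nearest-neighbor scheme pairs each spike only with the single most
recent partner spike on the other side of the synapse.  Pair contributions
accumulate every millisecond into per-synapse LTP/LTD accumulators; the
weights themselves move only once per simulated second, when the
accumulated STDP drive is combined with a multiplicative homeostatic term
that pulls the postsynaptic neuron's average rate Rbar toward its target:

    dw = [ alpha * w * (1 - Rbar/Rtarget) + beta * (LTP + LTD) ] * K

with the stability factor, in its damping form,

    K = Rbar / ( T * (1 + |1 - Rbar/Rtarget| * gamma) ),

alpha = 0.1, beta = 1.0, gamma = 50, T = 10 s.  Rbar is an exponential
moving average of 1-second rate samples with time constant T.  Weights are
clipped to [0, w_max] after every application and the accumulators reset.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPPolarity",
    "STDPRule",
    "stdp_window",
    "PlasticConnectionState",
    "HomeostasisState",
    "stability_factor",
    "update_rate_estimate",
    "apply_weight_update",
    "ALPHA",
    "BETA",
    "GAMMA",
    "T_AVG_S",
]

#: Homeostatic scaling factor.
ALPHA = 0.1
#: STDP learning rate.
BETA = 1.0
#: Damping tuning factor in the stability term.
GAMMA = 50.0
#: Rate-averaging time scale (seconds).
T_AVG_S = 10.0


class STDPPolarity(enum.Enum):
    E_E = "E_E"
    E_I = "E_I"


@dataclass(frozen=True)
class STDPRule:
    """Window amplitudes (weight units) and time constants (ms) of one curve."""

    a_plus: float
    a_minus: float
    tau_plus: float
    tau_minus: float
    polarity: STDPPolarity = STDPPolarity.E_E

    def __post_init__(self) -> None:
        if min(self.a_plus, self.a_minus) < 0:
            raise ValueError("STDP amplitudes must be nonnegative")
        if min(self.tau_plus, self.tau_minus) <= 0:
            raise ValueError("STDP time constants must be positive")


def stdp_window(dt_post_minus_pre, rule: STDPRule):
    """Weight change for a single spike pairing at lag dt = t_post - t_pre (ms).

    E->E: dt > 0 -> +a_plus * exp(-dt/tau_plus); dt < 0 -> -a_minus * exp(dt/tau_minus).
    E->I: the curve is reversed — dt > 0 -> -a_minus * exp(-dt/tau_minus);
    dt < 0 -> +a_plus * exp(dt/tau_plus).  Simultaneous spikes (dt == 0)
    contribute nothing.  Accepts scalars or arrays.
    """
    dt = np.asarray(dt_post_minus_pre, dtype=float)
    out = np.zeros_like(dt)
    pos = dt > 0
    neg = dt < 0
    # np.where evaluates both branches; the unused branch may overflow exp
    with np.errstate(over="ignore"):
        if rule.polarity is STDPPolarity.E_E:
            out = np.where(pos, rule.a_plus * np.exp(-dt / rule.tau_plus), out)
            out = np.where(neg, -rule.a_minus * np.exp(dt / rule.tau_minus), out)
        else:
            out = np.where(pos, -rule.a_minus * np.exp(-dt / rule.tau_minus), out)
            out = np.where(neg, rule.a_plus * np.exp(dt / rule.tau_plus), out)
    if np.ndim(dt_post_minus_pre) == 0:
        return float(out)
    return out


@dataclass
class PlasticConnectionState:
    """Weights, accumulators and last-spike registers of one plastic projection.

    Weights are an (n_pre, n_post) matrix bounded elementwise by w_max.
    ``ltp_acc``/``ltd_acc`` collect the positive/negative window
    contributions between weight applications; ``last_pre``/``last_post``
    hold the most recent spike time (ms) per neuron, -inf before any spike.
    """

    w: np.ndarray
    w_max: float
    rule: STDPRule
    delta: float = 0.0  # bias of the weight-update ODE; zero here
    beta: float = BETA
    ltp_acc: np.ndarray = field(init=False)
    ltd_acc: np.ndarray = field(init=False)
    last_pre: np.ndarray = field(init=False)
    last_post: np.ndarray = field(init=False)
    _last_time: float = field(init=False, default=-math.inf)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0) or np.any(self.w > self.w_max + 1e-12):
            raise ValueError("initial weights must lie in [0, w_max]")
        n_pre, n_post = self.w.shape
        self.ltp_acc = np.zeros((n_pre, n_post))
        self.ltd_acc = np.zeros((n_pre, n_post))
        self.last_pre = np.full(n_pre, -np.inf)
        self.last_post = np.full(n_post, -np.inf)

    # -- nearest-neighbor event handlers ------------------------------------

    def _check_time(self, t: float) -> None:
        if t < self._last_time:
            raise RuntimeError(f"spike time went backwards: {t} < {self._last_time}")
        self._last_time = t

    def on_spikes(self, t: float, pre_ids: np.ndarray, post_ids: np.ndarray) -> None:
        """Process all spikes occurring at time t (ms).

        Each postsynaptic spike pairs every incoming synapse with that
        presynaptic neuron's most recent earlier spike; each presynaptic
        spike pairs every outgoing synapse with the most recent earlier
        postsynaptic spike.  Registers are updated afterwards, so spikes
        coincident at t pair with dt = 0 and contribute nothing.
        """
        self._check_time(t)
        pre_ids = np.asarray(pre_ids, dtype=np.intp)
        post_ids = np.asarray(post_ids, dtype=np.intp)
        rule = self.rule
        ee = rule.polarity is STDPPolarity.E_E
        if post_ids.size:
            # pre-before-post pairings; dt = +inf (no pre spike yet) -> exp 0
            dt = t - self.last_pre
            if ee:
                vals = np.where(dt > 0, rule.a_plus * np.exp(-dt / rule.tau_plus), 0.0)
                self.ltp_acc[:, post_ids] += vals[:, None]
            else:
                vals = np.where(dt > 0, -rule.a_minus * np.exp(-dt / rule.tau_minus), 0.0)
                self.ltd_acc[:, post_ids] += vals[:, None]
        if pre_ids.size:
            # post-before-pre pairings; lag since the last post spike
            lag = t - self.last_post
            if ee:
                vals = np.where(lag > 0, -rule.a_minus * np.exp(-lag / rule.tau_minus), 0.0)
                self.ltd_acc[pre_ids] += vals[None, :]
            else:
                vals = np.where(lag > 0, rule.a_plus * np.exp(-lag / rule.tau_plus), 0.0)
                self.ltp_acc[pre_ids] += vals[None, :]
            self.last_pre[pre_ids] = t
        if post_ids.size:
            self.last_post[post_ids] = t

    def reset_accumulators(self) -> None:
        self.ltp_acc[:] = 0.0
        self.ltd_acc[:] = 0.0


@dataclass
class HomeostasisState:
    """Running rate estimate of one postsynaptic group and its target.

    ``r_bar`` (Hz) is updated once per second from the spike count of that
    second by an exponential moving average with time constant T = 10 s.
    """

    r_target: float
    r_bar: float = 0.0
    alpha: float = ALPHA
    gamma: float = GAMMA
    t_avg_s: float = T_AVG_S
    damping_form: bool = True

    def __post_init__(self) -> None:
        if self.r_target <= 0:
            raise ValueError("target rate must be positive")


def update_rate_estimate(h: HomeostasisState, rate_sample_hz) -> None:
    """Fold a 1-second rate sample (Hz) into the EMA estimate, in place.

    r_bar <- r_bar + (sample - r_bar) / T, the discrete EMA whose time
    constant is the averaging window T.  ``rate_sample_hz`` may be an array
    (per-neuron estimates share one state object with vector r_bar).
    """
    sample = np.asarray(rate_sample_hz, dtype=float)
    if np.any(sample < 0):
        raise ValueError("spike counts cannot be negative")
    h.r_bar = h.r_bar + (sample - h.r_bar) / h.t_avg_s
    if np.ndim(h.r_bar) == 0:
        h.r_bar = float(h.r_bar)


def stability_factor(
    r_bar, r_target: float, gamma: float = GAMMA, t_avg_s: float = T_AVG_S,
    damping_form: bool = True,
):
    """The factor K that damps weight updates far from the target rate.

    Damping form (default): K = Rbar / (T * (1 + |1 - Rbar/Rtarget| * gamma)).
    The alternative multiplicative reading Rbar/T * (1 + |...| * gamma) is
    selectable for comparison.  K has units 1/s scaled by Rbar and vanishes
    at Rbar = 0, freezing all updates for silent neurons.
    """
    r_bar = np.asarray(r_bar, dtype=float)
    mismatch = np.abs(1.0 - r_bar / r_target) * gamma
    if damping_form:
        k = r_bar / (t_avg_s * (1.0 + mismatch))
    else:
        k = r_bar / t_avg_s * (1.0 + mismatch)
    if k.ndim == 0:
        return float(k)
    return k


def apply_weight_update(conn: PlasticConnectionState, h: HomeostasisState) -> np.ndarray:
    """Once-per-second weight application with homeostatic scaling, in place.

    Computes, per synapse (i, j) with postsynaptic rate estimate Rbar_j,

        dw = [alpha * w * (1 - Rbar_j/Rtarget) + beta * (LTP + LTD)] * K_j

    then clips weights to [0, w_max] and resets the accumulators.  Returns
    the applied (pre-clip) dw matrix, mainly for inspection and testing.
    """
    r_bar = np.broadcast_to(np.asarray(h.r_bar, dtype=float), (conn.w.shape[1],))
    k = stability_factor(r_bar, h.r_target, h.gamma, h.t_avg_s, h.damping_form)
    homeo = h.alpha * conn.w * (1.0 - r_bar / h.r_target)[None, :]
    stdp = conn.beta * (conn.ltp_acc + conn.ltd_acc)
    dw = (conn.delta + homeo + stdp) * k[None, :]
    if not np.all(np.isfinite(dw)):
        raise FloatingPointError("non-finite weight update: plasticity diverged")
    conn.w = np.clip(conn.w + dw, 0.0, conn.w_max)
    conn.reset_accumulators()
    return dw
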