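"""Independent reference implementations used as oracles by the test suite.

Everything here is deliberately written straight from the definitions
(plain loops over events, pairs and sums) and kept separate from the
production code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

from snnevo.plasticity import STDPPolarity, STDPRule


# -- fitness: direct-summation oracles --------------------------------------

def oracle_decorr(theta_max, d_target=math.pi / 4):
    """Brute force over all neuron pairs with the circular period-pi metric."""
    theta = list(theta_max)
    total = 0.0
    for i, ti in enumerate(theta):
        d_min = math.inf
        for j, tj in enumerate(theta):
            if i == j:
                continue
            d = abs(ti - tj) % math.pi
            d = min(d, math.pi - d)
            d_min = min(d_min, d)
        total += abs(d_min - d_target)
    return total


def oracle_gauss(rates, angles, sigma=15 * math.pi / 180):
    """Direct double sum of |normalized rate - normalized Gaussian|.

    Assumes every neuron has a positive peak rate.
    """
    total = 0.0
    for row in np.asarray(rates, dtype=float):
        r_max = row.max()
        theta_max = angles[int(np.argmax(row))]
        for rate, angle in zip(row, angles):
            d = abs(angle - theta_max) % math.pi
            d = min(d, math.pi - d)
            g = math.exp(-0.5 * (d / sigma) ** 2)
            total += abs(rate / r_max - g)
    return total


def oracle_max_rate(r_max, target=60.0):
    return sum(abs(r - target) for r in r_max)


def oracle_total(decorr, gauss, max_rate, k=4.4, limits=(15.0, 1300.0, 160.0),
                 penalty=240.0, epsilon=1e-9):
    n_viol = (decorr > limits[0]) + (gauss > limits[1]) + (max_rate > limits[2])
    denom = decorr + gauss + k * max_rate + penalty * n_viol
    return 1.0 / max(denom, epsilon)


# -- STDP: exhaustive event-list oracle --------------------------------------

def oracle_nearest_neighbor(events, n_pre, n_post, rule: STDPRule):
    """Accumulators from an exhaustive search over the full event list.

    ``events`` is a chronological list of (t, pre_ids, post_ids).  For each
    postsynaptic spike at time T and each presynaptic neuron, the single
    latest presynaptic spike strictly before T is paired (and symmetrically
    for presynaptic spikes).  Events sharing a timestamp pair with dt = 0
    and contribute nothing.  Returns (ltp_acc, ltd_acc).
    """
    pre_trains = [[] for _ in range(n_pre)]
    post_trains = [[] for _ in range(n_post)]
    ltp = np.zeros((n_pre, n_post))
    ltd = np.zeros((n_pre, n_post))
    ee = rule.polarity is STDPPolarity.E_E

    def window(dt):
        # np.exp (not math.exp): bit-identical to the vectorized production
        # path, so the comparison can demand exact equality
        if dt > 0:
            if ee:
                return rule.a_plus * np.exp(-dt / rule.tau_plus)
            return -rule.a_minus * np.exp(-dt / rule.tau_minus)
        if dt < 0:
            if ee:
                return -rule.a_minus * np.exp(dt / rule.tau_minus)
            return rule.a_plus * np.exp(dt / rule.tau_plus)
        return 0.0

    for t, pre_ids, post_ids in events:
        for j in post_ids:
            for i in range(n_pre):
                earlier = [s for s in pre_trains[i] if s < t]
                if earlier:
                    val = window(t - max(earlier))
                    if val > 0:
                        ltp[i, j] += val
                    else:
                        ltd[i, j] += val
        for i in pre_ids:
            for j in range(n_post):
                earlier = [s for s in post_trains[j] if s < t]
                if earlier:
                    val = window(max(earlier) - t)
                    if val > 0:
                        ltp[i, j] += val
                    else:
                        ltd[i, j] += val
        for i in pre_ids:
            pre_trains[i].append(t)
        for j in post_ids:
            post_trains[j].append(t)
    return ltp, ltd


def random_event_train(rng, n_events, n_pre, n_post, t_max=1000.0):
    """Random chronological spike events for the STDP oracle comparison."""
    times = np.sort(rng.uniform(0, t_max, size=n_events))
    events = []
    for t in times:
        pre_ids = list(np.flatnonzero(rng.random(n_pre) < 0.4))
        post_ids = list(np.flatnonzero(rng.random(n_post) < 0.4))
        if not pre_ids and not post_ids:
            pre_ids = [int(rng.integers(n_pre))]
        events.append((float(t), pre_ids, post_ids))
    return events


# -- population decoding: direct vector-sum oracle ---------------------------

def oracle_population_decode(preferred, rates, true_angle):
    """Vector sum in doubled-angle space, written as an explicit loop."""
    sx = sy = 0.0
    for theta, r in zip(preferred, rates):
        sx += (r / 2.0) * math.cos(2.0 * theta)
        sy += (r / 2.0) * math.sin(2.0 * theta)
    decoded = 0.5 * math.atan2(sy, sx)
    if decoded <= 0:
        decoded += math.pi
    d = abs(decoded - true_angle) % math.pi
    d = min(d, math.pi - d)
    return decoded, math.degrees(d)


# -- synthetic Gaussian-tuned population -------------------------------------

def synthetic_population(rng, n_neurons=400, sigma=15 * math.pi / 180,
                         peak_rate=60.0, noise_sd=5.0):
    """Preferred angles uniform on (0, pi] and noisy Gaussian responses.

    Returns (preferred, respond(theta)) where respond draws per-neuron rates
    to a presented orientation with additive truncated Gaussian noise.
    """
    preferred = rng.uniform(0, math.pi, size=n_neurons) + 1e-9

    def respond(theta):
        d = np.abs(preferred - theta) % math.pi
        d = np.minimum(d, math.pi - d)
        clean = peak_rate * np.exp(-0.5 * (d / sigma) ** 2)
        noisy = clean + rng.normal(0, noise_sd, size=n_neurons)
        return np.maximum(noisy, 0.0)

    return preferred, respond
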