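"""Numba kernels for exact stochastic simulation of the antenna model.

Two samplers produce statistically identical realizations of the two-state
birth-death process:

``direct_*``
    Textbook Gillespie stepping: every reaction event (polymerize,
    depolymerize, inhibitor bind, inhibitor unbind) is drawn individually.

``aggregated_lengths_at_times``
    Exact acceleration for stiff switching.  Between length-changing events
    the cable length is constant, so the formin state follows a two-state
    Markov chain with fixed rates; the number of complete ON/OFF cycles
    before the next length event is geometric and the elapsed time is a sum
    of Erlang variables, both sampled in O(1).  The law of the length process
    is exactly that of the direct sampler — no tau-leaping or timescale
    approximation is involved — but the cost scales with the number of
    length events instead of the (possibly vastly larger) number of
    switching events.

Boundary convention at length 0: depolymerization is disabled (reflecting
boundary).  A cable that shrinks to zero while inhibited simply waits for
the inhibitor to unbind.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def direct_trajectory(r, d, w, koff, roff, t_end, seed, l0, on0, cap):
    """One Gillespie realization, recording every event.

    Returns (times, lengths, on_flags, n_records, absorbed, overflowed).
    Record 0 is the initial state; each later record follows one event.
    """
    np.random.seed(seed)
    ts = np.empty(cap, np.float64)
    ls = np.empty(cap, np.int64)
    ons = np.empty(cap, np.uint8)
    t = 0.0
    l = l0
    on = on0
    ts[0] = 0.0
    ls[0] = l
    ons[0] = 1 if on else 0
    n = 1
    absorbed = False
    while True:
        a_poly = r if on else roff
        a_dep = d if l > 0 else 0.0
        a_bind = w * l if on else 0.0
        a_unb = 0.0 if on else koff
        a0 = a_poly + a_dep + a_bind + a_unb
        if a0 <= 0.0:
            absorbed = True
            break
        t += np.random.exponential(1.0 / a0)
        if t >= t_end:
            break
        u = np.random.random() * a0
        if u < a_poly:
            l += 1
        elif u < a_poly + a_dep:
            l -= 1
        elif u < a_poly + a_dep + a_bind:
            on = False
        else:
            on = True
        if n >= cap:
            return ts, ls, ons, n, False, True
        ts[n] = t
        ls[n] = l
        ons[n] = 1 if on else 0
        n += 1
    return ts, ls, ons, n, absorbed, False


@njit(cache=True)
def direct_lengths_at_times(r, d, w, koff, roff, times, seed, l0, on0):
    """Cable length at each requested time along one direct realization."""
    np.random.seed(seed)
    n_times = times.shape[0]
    out = np.empty(n_times, np.int64)
    t = 0.0
    l = l0
    on = on0
    k = 0
    while k < n_times:
        a_poly = r if on else roff
        a_dep = d if l > 0 else 0.0
        a_bind = w * l if on else 0.0
        a_unb = 0.0 if on else koff
        a0 = a_poly + a_dep + a_bind + a_unb
        if a0 <= 0.0:
            break  # absorbed: length frozen from here on
        t_next = t + np.random.exponential(1.0 / a0)
        while k < n_times and times[k] < t_next:
            out[k] = l
            k += 1
        t = t_next
        u = np.random.random() * a0
        if u < a_poly:
            l += 1
        elif u < a_poly + a_dep:
            l -= 1
        elif u < a_poly + a_dep + a_bind:
            on = False
        else:
            on = True
    while k < n_times:
        out[k] = l
        k += 1
    return out


@njit(cache=True)
def aggregated_lengths_at_times(r, d, w, koff, times, seed, l0, on0):
    """Exact switching-aggregated sampler (requires r_off = 0).

    Starting an ON period at length l > 0, the next length event terminates
    either an ON sojourn (polymerize r / depolymerize d) or an OFF sojourn
    entered by inhibitor binding (depolymerize d).  A full ON->OFF->ON cycle
    with no length event has probability
        c = (w*l / a_on) * (koff / a_off),
    with a_on = r + d + w*l and a_off = koff + d, so the number N of
    complete cycles is geometric and the waiting time is a sum of Erlang
    variables in the two sojourn rates.  Competing-exponential event types
    are independent of the sojourn durations, so sampling (N, side, Erlang
    times) reproduces the direct sampler's law exactly.
    """
    np.random.seed(seed)
    n_times = times.shape[0]
    out = np.empty(n_times, np.int64)
    t = 0.0
    l = l0
    on = on0
    k = 0
    while k < n_times:
        if l == 0:
            if on:
                if r <= 0.0:
                    break  # absorbed at the origin
                t_next = t + np.random.exponential(1.0 / r)
                while k < n_times and times[k] < t_next:
                    out[k] = l
                    k += 1
                t = t_next
                l = 1
            else:
                if koff <= 0.0:
                    break
                t_next = t + np.random.exponential(1.0 / koff)
                while k < n_times and times[k] < t_next:
                    out[k] = l
                    k += 1
                t = t_next
                on = True
            continue
        a_off = koff + d
        if not on:
            # single OFF sojourn: depolymerize (d) vs unbind (koff)
            t_next = t + np.random.exponential(1.0 / a_off)
            while k < n_times and times[k] < t_next:
                out[k] = l
                k += 1
            t = t_next
            if np.random.random() * a_off < d:
                l -= 1
            else:
                on = True
            continue
        a_on = r + d + w * l
        if a_on <= 0.0:
            break
        c = (w * l / a_on) * (koff / a_off)
        if c > 0.0:
            u = 1.0 - np.random.random()  # in (0, 1]
            n_cycles = np.int64(np.floor(np.log(u) / np.log(c)))
        else:
            n_cycles = np.int64(0)
        elapsed = 0.0
        if n_cycles > 0:
            elapsed += np.random.gamma(float(n_cycles), 1.0 / a_on)
            elapsed += np.random.gamma(float(n_cycles), 1.0 / a_off)
        # terminal side: length event during an ON sojourn (weight (r+d)/a_on)
        # vs during the OFF sojourn after one more binding
        # (weight (w*l/a_on) * (d/a_off))
        p_on_side = (r + d) / a_on
        p_off_side = (w * l / a_on) * (d / a_off)
        if np.random.random() * (p_on_side + p_off_side) < p_on_side:
            elapsed += np.random.exponential(1.0 / a_on)
            t_next = t + elapsed
            while k < n_times and times[k] < t_next:
                out[k] = l
                k += 1
            t = t_next
            if np.random.random() * (r + d) < r:
                l += 1
            else:
                l -= 1
            # formin remains ON
        else:
            elapsed += np.random.exponential(1.0 / a_on)
            elapsed += np.random.exponential(1.0 / a_off)
            t_next = t + elapsed
            while k < n_times and times[k] < t_next:
                out[k] = l
                k += 1
            t = t_next
            l -= 1
            on = False
    while k < n_times:
        out[k] = l
        k += 1
    return out
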