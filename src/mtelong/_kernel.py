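"""Numba-compiled Gillespie inner loop.

The event system is small (three channels per protofilament: association,
tip dissociation, tip nucleotide exchange), so the kernel recomputes the
full per-protofilament rate table at every step rather than maintaining it
incrementally; for 13 protofilaments this is cheap and leaves no room for
stale-rate bugs.  Rates span ~1e-3 to ~1e5 s^-1 across nucleotide states,
which is why an exact event-driven chain is used instead of fixed time
steps.

State encoding: ``heights[pf]`` is the stack height in dimers (including
the immutable seed); ``nt[pf, layer]`` is 0 for GMPCPP, 1 for GDP.  The
lateral contact weight of position (pf, L) with a neighbour q is
``(1-frac) * [h_q >= L + base] + frac * [h_q >= L + base + 1]`` with
(base, frac) precomputed per crossing (base 1, frac 0 on regular
interfaces; the seam splits its half-dimer-staggered contact across two
layers).  Site affinity is ``KD_long * (KD_corner/KD_long)**w``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# counter indices in the returned array
N_ASSOC, N_DISS, N_EXCH = 0, 1, 2


@njit(cache=True)
def _lateral_weight(heights, pf, layer, base_r, frac_r, base_l, frac_l, n_pf):
    if n_pf == 1:
        return 0.0
    w = 0.0
    q = (pf + 1) % n_pf
    if heights[q] >= layer + base_r[pf]:
        w += 1.0 - frac_r[pf]
    if frac_r[pf] > 0.0 and heights[q] >= layer + base_r[pf] + 1:
        w += frac_r[pf]
    if n_pf > 2:
        q = (pf - 1) % n_pf
        if heights[q] >= layer + base_l[pf]:
            w += 1.0 - frac_l[pf]
        if frac_l[pf] > 0.0 and heights[q] >= layer + base_l[pf] + 1:
            w += frac_l[pf]
    return w


@njit(cache=True)
def run_kernel(
    heights,          # int64[n_pf], modified in place
    nt,               # uint8[n_pf, capacity], modified in place
    seed_layers,      # int
    is_plus,          # bool
    is_interface,     # bool
    kon,              # uM^-1 s^-1 per protofilament
    tub_total,        # uM
    frac_gdp_tub,     # fraction of the tubulin pool GDP-bound
    kd_long,          # uM
    kd_corner,        # uM
    gdp_factor,       # fold weakening of GDP-governed interfaces
    k_exch_gdp,       # s^-1
    affinity_ratio,   # GMPCPP off-rate multiplier for exchange
    p_cpp_replace,    # P(replacement nucleotide is GMPCPP)
    base_r, frac_r,   # right-crossing contact terms, per pf
    base_l, frac_l,   # left-crossing contact terms, per pf
    duration,         # s
    record_times,     # float64[n_samples], strictly increasing, <= duration
    seed,             # seeds numba's per-thread RNG
):
    """Simulate one trajectory; returns (samples, counters).

    ``samples[k]`` is the number of subunits above the seed at
    ``record_times[k]``; counters hold total association / dissociation /
    exchange event counts.
    """
    np.random.seed(seed)
    n_pf = heights.shape[0]
    capacity = nt.shape[1]
    lat_f = kd_corner / kd_long

    n_samples = record_times.shape[0]
    samples = np.zeros(n_samples, dtype=np.int64)
    counters = np.zeros(3, dtype=np.int64)

    rate_assoc = kon * tub_total
    rates = np.zeros(3 * n_pf, dtype=np.float64)

    grown = 0  # subunits above seed
    t = 0.0
    sample_i = 0

    while True:
        # rebuild the rate table
        total = 0.0
        for pf in range(n_pf):
            rates[3 * pf] = rate_assoc
            total += rate_assoc
            r_diss = 0.0
            r_exch = 0.0
            h = heights[pf]
            if h > seed_layers:
                L = h - 1
                w = _lateral_weight(heights, pf, L, base_r, frac_r, base_l, frac_l, n_pf)
                kd = kd_long * lat_f**w
                if is_plus and is_interface:
                    gov = nt[pf, L - 1]
                else:
                    gov = nt[pf, L]
                if gov == 1:
                    kd *= gdp_factor
                r_diss = kon * kd
                if is_plus and k_exch_gdp > 0.0:
                    if nt[pf, L] == 1:
                        r_exch = k_exch_gdp
                    else:
                        r_exch = k_exch_gdp * affinity_ratio
            rates[3 * pf + 1] = r_diss
            rates[3 * pf + 2] = r_exch
            total += r_diss + r_exch

        if total <= 0.0:
            break
        dt = -np.log(np.random.random()) / total
        t_next = t + dt

        # emit samples passed by this waiting interval
        while sample_i < n_samples and record_times[sample_i] < t_next:
            samples[sample_i] = grown
            sample_i += 1
        if t_next >= duration:
            t = duration
            break
        t = t_next

        # select the channel
        target = np.random.random() * total
        acc = 0.0
        chan = 3 * n_pf - 1
        for i in range(3 * n_pf):
            acc += rates[i]
            if target < acc:
                chan = i
                break
        pf = chan // 3
        kind = chan - 3 * pf

        if kind == 0:  # association
            h = heights[pf]
            if h >= capacity:
                break  # out of storage; sizing makes this unreachable
            if np.random.random() < frac_gdp_tub:
                nt[pf, h] = 1
            else:
                nt[pf, h] = 0
            heights[pf] = h + 1
            grown += 1
            counters[N_ASSOC] += 1
        elif kind == 1:  # dissociation
            heights[pf] -= 1
            grown -= 1
            counters[N_DISS] += 1
        else:  # nucleotide exchange at the tip
            L = heights[pf] - 1
            if np.random.random() < p_cpp_replace:
                nt[pf, L] = 0
            else:
                nt[pf, L] = 1
            counters[N_EXCH] += 1

    # remaining samples see the final state
    while sample_i < n_samples:
        samples[sample_i] = grown
        sample_i += 1
    return samples, counters
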