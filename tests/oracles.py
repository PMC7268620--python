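"""Independent reference implementations used as test oracles.

Deliberately naive: plain Python loops, datetime.date arithmetic and
exhaustive enumeration, sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
import math
from datetime import timedelta

import numpy as np
from scipy.special import expit
from scipy.stats import binom

R_EARTH = 6_371_000.0


def haversine_naive(lon1, lat1, lon2, lat2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2) - math.radians(lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * R_EARTH * math.asin(min(1.0, math.sqrt(a)))


def brute_members(track, center_index, radius):
    """O(n) pairwise scan for one buffer; O(n^2) over all centers."""
    out = []
    for j in range(track.n_fixes):
        d = haversine_naive(
            track.lon[center_index], track.lat[center_index], track.lon[j], track.lat[j]
        )
        if d <= radius:
            out.append(j)
    return out


def brute_metrics(track, members, tz="UTC"):
    """Reference revisitation metrics via datetime.date bookkeeping."""
    local = track.times.tz_convert(tz)
    all_days = [ts.date() for ts in local]
    mem_days = sorted({all_days[i] for i in members})
    first, last = mem_days[0], mem_days[-1]
    # longest consecutive-date run
    best = run = 1
    for a, b in zip(mem_days, mem_days[1:]):
        run = run + 1 if b - a == timedelta(days=1) else 1
        best = max(best, run)
    span = (last - first).days + 1
    perc_days = 100.0 * len(mem_days) / span
    top = 0.0
    for d in mem_days:
        tot = sum(1 for x in all_days if x == d)
        mem = sum(1 for i in members if all_days[i] == d)
        top = max(top, 100.0 * mem / tot)
    return {
        "consec_days": best,
        "perc_days_vis": perc_days,
        "perc_top_vis": top,
        "n_fixes_in": len(members),
        "first_day": first,
        "last_day": last,
    }


def enumerate_fate_probability(history, params):
    """Pr(z_T = 1 | Y) by summing over all 2^(T-1) latent paths."""
    T = history.T
    t = np.arange(1, T + 1)
    phi = expit(params.beta_phi0 + params.beta_phi1 * t)
    p = expit(params.beta_p0 + params.beta_p1 * t)
    total = alive_end = 0.0
    for tail in itertools.product([0, 1], repeat=T - 1):
        z = (1,) + tail
        pr = 1.0
        for j in range(1, T):
            trans = z[j - 1] * phi[j - 1]
            pr *= trans if z[j] == 1 else 1.0 - trans
        for j in range(T):
            pr *= binom.pmf(history.Y[j], history.N[j], z[j] * p[j])
        total += pr
        if z[-1] == 1:
            alive_end += pr
    if total == 0:
        raise ValueError("history impossible under parameters")
    return alive_end / total


def best_disjoint_first(intervals):
    """Greedy most-visited-first interval selection, re-derived naively.

    ``intervals`` is a list of (n_visits, first_day, last_day, key);
    returns the keys the greedy rule accepts.
    """
    order = sorted(intervals, key=lambda x: (-x[0], x[1], x[3]))
    chosen = []
    for n, f, l, key in order:
        if all(l < cf or f > cl for _, cf, cl, _ in chosen):
            chosen.append((n, f, l, key))
    return {key for _, _, _, key in chosen}
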