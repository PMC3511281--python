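"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: runs are found with
itertools.groupby over boolean labels, and the Mann-Whitney null
distribution is enumerated by direct pairwise comparison over every
permutation of group labels.
"""

from itertools import combinations, groupby

import numpy as np


def oracle_detect(counts, n_pre, sd_multiplier=2.0, min_run=2):
    """Run-scanning reference for the PSTH response detector.

    Returns one of "NONE", "INCREASE", "DECREASE", "COMBINATION".
    """
    counts = list(counts)
    base = counts[:n_pre]
    mu = sum(base) / len(base)
    var = sum((c - mu) ** 2 for c in base) / (len(base) - 1)
    sd = var**0.5
    hi, lo = mu + sd_multiplier * sd, mu - sd_multiplier * sd
    post = counts[n_pre:]

    def runs(flags):
        out, i = [], 0
        for val, grp in groupby(flags):
            n = len(list(grp))
            if val and n >= min_run:
                out.append((i, i + n))
            i += n
        return out

    inc = runs([c > hi for c in post])
    dec = runs([c < lo for c in post])
    if inc and dec and any(ir[1] - 1 < dr[0] for ir in inc for dr in dec):
        return "COMBINATION"
    if inc:
        return "INCREASE"
    if dec:
        return "DECREASE"
    return "NONE"


def _u_pairwise(a, b):
    """U of group a by direct pairwise comparison (0.5 per tie)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def oracle_mannwhitney_p(a, b):
    """Exact two-sided p by enumerating all label permutations.

    p = P(min(U_a, U_b) <= observed min) under random assignment of the
    pooled values to groups of the observed sizes.
    """
    a, b = list(a), list(b)
    na = len(a)
    pooled = a + b
    idx = range(len(pooled))
    obs = _u_pairwise(a, b)
    obs_min = min(obs, na * len(b) - obs)
    total = extreme = 0
    for combo in combinations(idx, na):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in idx if i not in combo]
        u = _u_pairwise(ga, gb)
        u_min = min(u, na * len(gb) - u)
        total += 1
        if u_min <= obs_min + 1e-9:
            extreme += 1
    return extreme / total


def expected_evoked_per_pulse(rate, t_ms, m, pulse_onsets_ms, period_ms):
    """Expected baseline-corrected spikes per pulse from a modulation trace.

    Numerical integration of rate * (m(t) - 1) over each inter-pulse
    window; the independent expectation against which sampled decrement
    ratios are checked.
    """
    out = []
    for on in pulse_onsets_ms:
        mask = (t_ms > on) & (t_ms <= on + period_ms)
        out.append(rate * np.trapezoid(m[mask] - 1.0, t_ms[mask]) / 1000.0)
    return np.array(out)
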