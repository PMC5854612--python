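"""Independent brute-force oracles used to check the optimized implementations.

Everything here is written as a literal transcription of the score
definitions — plain loops over genes, gene pairs and modules — and stays
deliberately independent of the package internals.
"""

from __future__ import annotations

import math


def _jaccard(a, b):
    u = a | b
    return len(a & b) / len(u) if u else 0.0


def bcubed_precision_oracle(known, observed, subset=None):
    """Literal triple-loop CICE-BCubed precision.

    ``known``/``observed`` are lists of gene sets (duplicates allowed, kept
    distinct by position). Recall = same call with the arguments swapped.
    """

    def mods_with(mods, *genes):
        return [m for m in mods if all(g in m for g in genes)]

    def neighbourhood(mods, g):
        out = {g}
        for m in mods:
            if g in m:
                out |= m
        return out

    def phi(g, gp):
        obs_both = mods_with(observed, g, gp)
        known_both = mods_with(known, g, gp)
        if not obs_both:
            return 0.0
        vals = [max((_jaccard(mp, m) for m in known_both), default=0.0) for mp in obs_both]
        return sum(vals) / len(vals)

    genes = set().union(*known) | set().union(*observed)
    if subset is None:
        population = sorted(g for g in genes if mods_with(observed, g))
    else:
        population = sorted(subset)
    total = 0.0
    for g in population:
        if not mods_with(observed, g):
            continue
        e = neighbourhood(observed, g)
        inner = 0.0
        for gp in e:
            n_obs = len(mods_with(observed, g, gp))
            n_known = len(mods_with(known, g, gp))
            if min(n_obs, n_known) == 0:
                continue
            inner += min(n_obs, n_known) * phi(g, gp) / n_obs
        total += inner / len(e)
    return total / len(population)


def match_oracle(known, observed):
    """(recovery, relevance) as plain best-match Jaccard averages."""
    recovery = sum(max(_jaccard(m, mp) for mp in observed) for m in known) / len(known)
    relevance = sum(max(_jaccard(mp, m) for m in known) for mp in observed) / len(observed)
    return recovery, relevance


def hypergeom_upper_tail(n_universe, n_geneset, n_module, overlap):
    """P(X >= overlap) by exhaustive enumeration with exact integer binomials."""
    total = math.comb(n_universe, n_module)
    acc = 0
    for k in range(overlap, min(n_geneset, n_module) + 1):
        if n_module - k <= n_universe - n_geneset:
            acc += math.comb(n_geneset, k) * math.comb(n_universe - n_geneset, n_module - k)
    return acc / total


def holm_sidak_oracle(pvalues):
    """Direct step-down formula: sort ascending, adjust p_(i) to
    1-(1-p_(i))^(m-i), enforce monotonicity, return in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        adj = 1.0 - (1.0 - pvalues[i]) ** (m - rank)
        running = max(running, min(1.0, adj))
        adjusted[i] = running
    return adjusted


def aucodds_step_oracle(odds_ratios, lo=1.0, hi=1000.0, n_steps=200000):
    """Numeric step integration of the fraction-above-cutoff curve over
    log10 cutoffs (midpoint rule)."""
    clipped = [min(max(v, lo), hi) for v in odds_ratios]
    log_lo, log_hi = math.log10(lo), math.log10(hi)
    width = log_hi - log_lo
    acc = 0.0
    for i in range(n_steps):
        c = 10 ** (log_lo + (i + 0.5) * width / n_steps)
        acc += sum(1 for v in clipped if v >= c) / len(clipped)
    return acc / n_steps
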