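"""Independent reference implementations used only to check the package.

Each oracle is a literal, slow transcription of the published definition of
the quantity it checks, deliberately sharing no code path with the package:
pure-Python loops, enumeration and recursion instead of vectorized linear
algebra or library calls.
"""
from __future__ import annotations

import itertools
import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# TMM: literal transcription of the trimmed-mean-of-M-values definition
# ---------------------------------------------------------------------------

def _quantile_linear(values: list[float], q: float) -> float:
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def _ordinal_ranks(values: list[float]) -> list[int]:
    order = sorted(range(len(values)), key=lambda i: (values[i], i))
    ranks = [0] * len(values)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def tmm_factors_literal(table: list[list[float]], trim_m: float = 0.30, trim_a: float = 0.05):
    """TMM factors for a genes x samples table, step by step.

    Reference sample: upper-quartile/library ratio closest to the mean such
    ratio.  Per sample: M and A over genes positive in both, drop the lowest
    and highest floor(n*trim) genes by M-rank and by A-rank, then a weighted
    mean of the surviving M with inverse delta-method variance weights, and a
    final rescale of all factors to geometric mean 1.
    """
    n_genes = len(table)
    n_samples = len(table[0])
    libs = [sum(table[g][s] for g in range(n_genes)) for s in range(n_samples)]
    uq = [
        _quantile_linear([table[g][s] for g in range(n_genes)], 0.75) / libs[s]
        for s in range(n_samples)
    ]
    mean_uq = sum(uq) / n_samples
    ref = min(range(n_samples), key=lambda s: (abs(uq[s] - mean_uq), s))
    n_ref = libs[ref]
    factors = []
    for s in range(n_samples):
        n_s = libs[s]
        ms, as_, ws = [], [], []
        for g in range(n_genes):
            x, r = table[g][s], table[g][ref]
            if x > 0 and r > 0:
                ms.append(math.log2((x / n_s) / (r / n_ref)))
                as_.append(0.5 * math.log2((x / n_s) * (r / n_ref)))
                ws.append((n_s - x) / (n_s * x) + (n_ref - r) / (n_ref * r))
        n = len(ms)
        if n == 0:
            factors.append(1.0)
            continue
        rank_m = _ordinal_ranks(ms)
        rank_a = _ordinal_ranks(as_)
        lo_m = math.floor(n * trim_m)
        lo_a = math.floor(n * trim_a)
        kept = [
            i
            for i in range(n)
            if lo_m < rank_m[i] <= n - lo_m and lo_a < rank_a[i] <= n - lo_a
        ]
        if len(kept) < 10:
            kept = list(range(n))
        num = sum(ms[i] / ws[i] for i in kept)
        den = sum(1.0 / ws[i] for i in kept)
        factors.append(2.0 ** (num / den))
    log_mean = sum(math.log(f) for f in factors) / n_samples
    geo = math.exp(log_mean)
    return [f / geo for f in factors], ref


# ---------------------------------------------------------------------------
# NB conditional exact test: pmf-ratio recursion + direct summation
# ---------------------------------------------------------------------------

def nb_exact_oracle(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Conditional exact p-value by full enumeration over k in [0, t].

    The unnormalized conditional weight obeys, for phi > 0 with r_a = n_a/phi,
    r_b = n_b/phi,

        w(k+1)/w(k) = (k + r_a) (t - k) / ((k + 1) (t - k - 1 + r_b)),

    and for phi = 0 the binomial-ratio analogue; weights are accumulated by
    that recursion, normalized, and outcomes no more probable than the
    observed one are summed.
    """
    t = s_a + s_b
    if t == 0:
        return 1.0
    w = [1.0]
    if phi <= 1e-12:
        ratio_ab = n_a / n_b
        for k in range(t):
            w.append(w[-1] * (t - k) / (k + 1) * ratio_ab)
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        for k in range(t):
            w.append(w[-1] * (k + r_a) * (t - k) / ((k + 1) * (t - k - 1 + r_b)))
    # normalize from the largest weight for stability
    m = max(w)
    probs = [x / m for x in w]
    z = sum(probs)
    probs = [x / z for x in probs]
    p_obs = probs[s_a]
    total = sum(p for p in probs if p <= p_obs * (1.0 + 1e-10))
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg by the step-up definition
# ---------------------------------------------------------------------------

def bh_oracle(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adj[i] = running_min
    return adj


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum: full permutation enumeration (tie-free inputs)
# ---------------------------------------------------------------------------

def wilcoxon_exact_oracle(obs_a: list[float], obs_b: list[float], direction: str) -> Fraction:
    """Exact one-tailed rank-sum p-value by enumerating all group assignments."""
    pooled = sorted(obs_a + obs_b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(obs_a)
    observed = sum(ranks[v] for v in obs_a)
    n_total = len(pooled)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n_total + 1), n_a):
        s = sum(combo)
        total += 1
        if direction == "less":
            if s <= observed:
                count += 1
        elif direction == "greater":
            if s >= observed:
                count += 1
        else:
            raise ValueError(direction)
    return Fraction(count, total)


# ---------------------------------------------------------------------------
# Trinucleotide context: brute-force reverse-complement reading
# ---------------------------------------------------------------------------

def context_oracle(triplet: str) -> str:
    """Classify a 5'->3' cytosine-leading triplet: CG, CHG or CHH."""
    assert triplet[0] == "C"
    if triplet[1] == "G":
        return "CG"
    if triplet[2] == "G":
        return "CHG"
    return "CHH"


def revcomp_oracle(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Hypergeometric upper tail by exact rational enumeration
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(overlap: int, background: int, set_size: int, query: int) -> Fraction:
    """P(X >= overlap) for X ~ Hypergeom(background, set_size, query)."""
    denom = math.comb(background, query)
    total = Fraction(0)
    for k in range(overlap, min(set_size, query) + 1):
        total += Fraction(math.comb(set_size, k) * math.comb(background - set_size, query - k), denom)
    return total
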