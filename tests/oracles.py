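"""Independent reference implementations used to check the package.

Everything here is deliberately written as plain scalar loops over
hand-enumerable genotype lists, sharing no code with the package's
vectorised implementations.
"""

from __future__ import annotations

import math


def nei_oracle(geno_by_pop: dict[str, list[list[int]]]) -> dict:
    """Nei diversity from per-population genotype lists (no missing data).

    ``geno_by_pop[pop][locus]`` is a list of diploid dosages.  Returns the
    multi-locus ho/hs/ht/fst/fis under the same definitions as the package:
    unbiased per-population gene diversity 2p(1-p)*2n/(2n-1), unweighted
    means over populations, ratio-of-averages combination.
    """
    pops = list(geno_by_pop)
    n_loci = len(geno_by_pop[pops[0]])
    ho_list, hs_list, ht_list = [], [], []
    for l in range(n_loci):
        ho_pop, h_pop, p_pop = [], [], []
        for pop in pops:
            calls = geno_by_pop[pop][l]
            n = len(calls)
            het = sum(1 for c in calls if c == 1)
            alt = sum(calls)
            p = alt / (2 * n)
            ho_pop.append(het / n)
            h_pop.append(2 * p * (1 - p) * (2 * n) / (2 * n - 1))
            p_pop.append(p)
        ho_list.append(sum(ho_pop) / len(pops))
        hs_list.append(sum(h_pop) / len(pops))
        pbar = sum(p_pop) / len(pops)
        ht_list.append(2 * pbar * (1 - pbar))
    ho = sum(ho_list) / n_loci
    hs = sum(hs_list) / n_loci
    ht = sum(ht_list) / n_loci
    return {
        "ho": ho,
        "hs": hs,
        "ht": ht,
        "fst": (ht - hs) / ht if ht > 0 else float("nan"),
        "fis": 1 - ho / hs if hs > 0 else float("nan"),
    }


def wc_theta_oracle(calls_a: list[int], calls_b: list[int]) -> float:
    """Weir-Cockerham (1984) theta for one locus and two populations,
    from the variance components a, b, c written out term by term."""
    r = 2
    n1, n2 = len(calls_a), len(calls_b)
    p1 = sum(calls_a) / (2 * n1)
    p2 = sum(calls_b) / (2 * n2)
    h1 = sum(1 for c in calls_a if c == 1) / n1
    h2 = sum(1 for c in calls_b if c == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def bh_qvalues_oracle(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j: p_j >= p_i} m*p_j/rank_j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = float("inf")
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, m * p[i] / rank_from_top)
        val = min(val, 1.0)
        q[i] = val
        prev = val
    return q


def folded_sfs_expectation(n_hap: int) -> list[float]:
    """Neutral-equilibrium folded SFS proportions for n_hap haplotypes:
    eta_i proportional to 1/i + 1/(n_hap - i), halved at the fold point."""
    out = []
    for i in range(1, n_hap // 2 + 1):
        x = 1.0 / i
        if i != n_hap - i:
            x += 1.0 / (n_hap - i)
        out.append(x)
    s = sum(out)
    return [x / s for x in out]
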