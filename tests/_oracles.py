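"""Independent test oracles.

Brute-force enumeration of the permutation null of the Kruskal-Wallis
statistic for tiny samples.  Deliberately independent of the package's
analytic chi-square path: it re-labels the pooled observations in every
possible order and counts how often H is at least as extreme as observed.
"""

from itertools import chain, permutations

from oocyteswell.group_stats import kruskal_wallis


def exact_kruskal_p(groups):
    """Exact permutation p value for the Kruskal-Wallis H statistic.

    Enumerates all N! orderings of the pooled sample (uniform over label
    assignments, which handles ties correctly).  Only feasible for N <= 8.
    """
    sizes = [len(g) for g in groups]
    pooled = tuple(chain.from_iterable(groups))
    h_obs, _, _ = kruskal_wallis(groups)
    n_extreme = 0
    total = 0
    for perm in permutations(pooled):
        regrouped = []
        start = 0
        for n in sizes:
            regrouped.append(perm[start : start + n])
            start += n
        h, _, _ = kruskal_wallis(regrouped)
        if h >= h_obs - 1e-9:
            n_extreme += 1
        total += 1
    return n_extreme / total
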