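"""Independent brute-force oracles used by the statistics tests.

Deliberately naive implementations: complete enumeration for the exact
tests and O(n^2) pair counting for the AUC, written without reference to
the production code paths they verify.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_p_bruteforce(a, b, c, d, rel_tol=1e-7):
    """Two-sided Fisher p by enumerating every table with the observed
    margins and summing the probabilities of those no more likely than
    the observed table (probability-mass convention)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1.0 + rel_tol):
            total += px
    return min(total, 1.0)


def auc_pair_counting(pos, neg):
    """AUC as the fraction of (positive, negative) pairs the positive
    wins, ties counting one half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def mann_whitney_exact_p_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by complete enumeration of all
    C(n1+n2, n1) group labelings of the pooled (tie-free) sample."""
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs tie-free data"
    n1 = len(x)

    def u_stat(first):
        first = sorted(first)
        rest = sorted(v for v in pooled if v not in set(first))
        return sum(1 for a in first for b in rest if a > b)

    u_obs = u_stat(list(x))
    n1n2 = n1 * (len(pooled) - n1)
    # two-sided via distance of U from its null mean
    dev_obs = abs(u_obs - n1n2 / 2.0)
    hits = 0
    total = 0
    for first in combinations(pooled, n1):
        total += 1
        if abs(u_stat(list(first)) - n1n2 / 2.0) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def type_one_error_study(n_reps, seed, alpha=0.05, subsample=8):
    """Rejection rates of each test on label-permuted synthetic cohorts.

    Each replicate generates a default-calibration cohort, permutes the
    culture labels (breaking every group association), and applies the
    full battery: asymptotic Mann-Whitney on the second-timing platelet
    count, exact Mann-Whitney on a random tie-free CRP subsample,
    uncorrected chi-square and two-sided Fisher on the falling-platelet
    indicator.  Returns {test: (rejections, valid_replicates)}.
    """
    from neolos.cohort_io import derive_changes
    from neolos.stats_engine import (
        ContingencyTable2x2,
        StatsError,
        chi2_uncorrected,
        fisher_two_sided,
        mann_whitney,
    )
    from neolos.synthetic_cohort import default_config_from_table1, generate

    rng = np.random.default_rng(seed)
    out = {k: [0, 0] for k in ("mann_whitney_asymptotic", "mann_whitney_exact",
                               "chi2_uncorrected", "fisher_two_sided")}

    def tally(key, p):
        if p is not None:
            out[key][0] += p < alpha
            out[key][1] += 1

    for rep in range(n_reps):
        cohort = generate(default_config_from_table1(seed=rep)).cohort
        perm = rng.permutation([e.culture_positive for e in cohort])
        plt2 = np.array([e.obs_t2.plt if e.obs_t2.plt is not None else np.nan
                         for e in cohort])
        crp2 = np.array([e.obs_t2.crp if e.obs_t2.crp is not None else np.nan
                         for e in cohort])
        ok = ~np.isnan(plt2)
        tally("mann_whitney_asymptotic",
              mann_whitney(plt2[ok & ~perm], plt2[ok & perm]).p_value)
        # random tie-free subsample keeps the exact test's exchangeability
        ok2 = ~np.isnan(crp2)
        g0, g1 = np.flatnonzero(ok2 & ~perm), np.flatnonzero(ok2 & perm)
        p_exact = None
        if len(g0) >= subsample and len(g1) >= subsample:
            xs = crp2[rng.choice(g0, subsample, replace=False)]
            ys = crp2[rng.choice(g1, subsample, replace=False)]
            if len(np.unique(np.concatenate([xs, ys]))) == 2 * subsample:
                p_exact = mann_whitney(xs, ys, mode="exact_if_small").p_value
        tally("mann_whitney_exact", p_exact)
        counts = {(g, f): 0 for g in (0, 1) for f in (0, 1)}
        for e, g in zip(cohort, perm):
            flag = derive_changes(e).plt_decreased
            if flag is not None:
                counts[(int(g), int(flag))] += 1
        table = ContingencyTable2x2(counts[(0, 1)], counts[(0, 0)],
                                    counts[(1, 1)], counts[(1, 0)])
        try:
            tally("chi2_uncorrected", chi2_uncorrected(table).p_value)
        except StatsError:
            pass
        tally("fisher_two_sided", fisher_two_sided(table).p_value)
    return {k: (v[0], v[1]) for k, v in out.items()}
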