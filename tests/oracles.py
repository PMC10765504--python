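"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np


def fstat(groups):
    k = len(groups)
    n = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    gm = pooled.mean()
    ssb = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def exhaustive_permutation_anova_p(groups):
    """Exact label-permutation p-value for a 3-group one-way layout."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    f_obs = fstat(groups)
    n = len(pooled)
    idx = set(range(n))
    count = total = 0
    for c1 in itertools.combinations(range(n), sizes[0]):
        rest = sorted(idx - set(c1))
        for c2 in itertools.combinations(rest, sizes[1]):
            c3 = sorted(set(rest) - set(c2))
            g = [pooled[list(c1)], pooled[list(c2)], pooled[c3]]
            total += 1
            if fstat(g) >= f_obs - 1e-12:
                count += 1
    return count / total


def exhaustive_sign_flip_p(diffs):
    """Exact sign-flip permutation p-value for a paired mean test."""
    d = np.asarray(diffs, float)
    obs = abs(d.mean())
    count = 0
    for signs in itertools.product([1.0, -1.0], repeat=len(d)):
        if abs((d * signs).mean()) >= obs - 1e-12:
            count += 1
    return count / 2 ** len(d)
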